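"""Fold-change, threshold, percent-positive, and selectivity readouts."""

import numpy as np
import pytest

from sarmap import bioactivity as bio
from sarmap import io as sio
from sarmap import synthetic as syn
from sarmap.exceptions import SarmapError
from tests.conftest import make_marker_table


def table_of(values, name="m", scale="raw"):
    return make_marker_table({name: np.asarray(values, dtype=float)}, scale)


class TestFoldChange:
    def test_identity_is_zero(self, rng):
        t = table_of(rng.lognormal(8, 0.4, 500))
        assert bio.mfi_fold_change(t, t, "m", cofactor=6000.0) == 0.0

    def test_closed_form_medians(self):
        """Raw medians 18000 vs 6000 at cofactor 6000:
        asinh(3) - asinh(1) = 0.9370."""
        treated = table_of([18000.0] * 3)
        vehicle = table_of([6000.0] * 3)
        fc = bio.mfi_fold_change(treated, vehicle, "m", cofactor=6000.0)
        assert fc == pytest.approx(0.937073, abs=1e-5)

    def test_antisymmetry(self, rng):
        a = table_of(rng.lognormal(8, 0.5, 301))
        b = table_of(rng.lognormal(8.6, 0.5, 301))
        f = bio.mfi_fold_change(a, b, "m", cofactor=6000.0)
        g = bio.mfi_fold_change(b, a, "m", cofactor=6000.0)
        assert f == pytest.approx(-g, abs=1e-12)

    def test_arcsinh_scaled_input_uses_median_difference(self, rng):
        raw = rng.lognormal(8, 0.5, 401)
        t_raw, v_raw = table_of(2 * raw), table_of(raw)
        t_sc = make_marker_table({"m": np.arcsinh(2 * raw / 6000.0)}, "arcsinh")
        v_sc = make_marker_table({"m": np.arcsinh(raw / 6000.0)}, "arcsinh")
        assert bio.mfi_fold_change(t_sc, v_sc, "m") == pytest.approx(
            bio.mfi_fold_change(t_raw, v_raw, "m", cofactor=6000.0), abs=1e-9
        )

    def test_empty_table_is_an_error(self):
        empty = table_of([])
        full = table_of([1.0, 2.0])
        with pytest.raises(SarmapError):
            bio.mfi_fold_change(empty, full, "m", cofactor=100.0)


class TestThreshold:
    def test_degenerate_identical_values(self):
        with pytest.warns(UserWarning):
            th = bio.bioactivity_threshold([0.0, 0.0, 0.0, 0.0])
        assert th.threshold == 0.0

    def test_linear_interpolation_quartiles(self):
        """{1,2,3,4}: median 2.5, IQR 1.5, threshold 2.5 + 3*1.5 = 7.0."""
        th = bio.bioactivity_threshold([1.0, 2.0, 3.0, 4.0])
        assert th.vehicle_median == 2.5
        assert th.vehicle_iqr == 1.5
        assert th.threshold == 7.0

    def test_translation_equivariance(self, rng):
        values = rng.normal(0, 1, 51)
        t0 = bio.bioactivity_threshold(values).threshold
        t1 = bio.bioactivity_threshold(values + 2.5).threshold
        assert t1 == pytest.approx(t0 + 2.5, abs=1e-12)

    def test_classification_any_marker_mode(self):
        import pandas as pd

        matrix = bio.FoldChangeMatrix(
            pd.DataFrame({"m1": [0.1, 0.9], "m2": [0.0, 0.1]}, index=["a", "b"])
        )
        th = bio.BioactivityThreshold.from_components(0.0, 0.1)  # threshold 0.3
        flags = bio.classify_bioactive(matrix, th)
        assert flags.to_dict() == {"a": False, "b": True}

    def test_null_plates_rarely_exceed_threshold(self, eleven_markers):
        """Vehicle-only fold changes exceed the median + 3 IQR rule at a
        small rate (< 2% per readout) across repeated null plates."""
        markers = eleven_markers[:4]
        exceed, total = 0, 0
        for seed in range(500):
            wells = [syn.WellSpec(f"A{i + 1}", "vehicle", f"v{i}") for i in range(6)]
            design = syn.PlateDesign(
                wells=wells, markers=markers, cells_per_well=150,
                debris_fraction=0.0, doublet_fraction=0.0, dead_fraction=0.0,
                count_model="fixed", seed=seed,
            )
            table, truth = syn.simulate_plate(design, [])
            wl = truth.events.well.to_numpy()
            pooled = table
            fcs = np.array([
                bio.mfi_fold_change(table.subset(wl == w), pooled, m.name, m.cofactor)
                for w in design.barcode_scheme.well_grid()[:6]
                for m in markers
            ])
            th = bio.bioactivity_threshold(fcs)
            exceed += int((fcs > th.threshold).sum())
            total += fcs.size
        assert exceed / total < 0.02


class TestCountRatio:
    def test_ratios(self, rng):
        t1 = table_of(rng.lognormal(8, 0.4, 5000))
        t2 = table_of(rng.lognormal(8, 0.4, 10000))
        assert bio.count_ratio(t1, t1) == 1.0
        assert bio.count_ratio(t1, t2) == 0.5
        with pytest.raises(SarmapError):
            bio.count_ratio(t1, table_of([]))


class TestPercentPositive:
    def test_threshold_above_maximum_gives_zero(self, rng):
        t = table_of(rng.normal(0, 1, 1000))
        res = bio.percent_positive(t, "m", bio.ThresholdGate("m", 10.0))
        assert res.percent == 0.0

    def test_threshold_at_median_gives_half(self, rng):
        values = rng.normal(0, 1, 1001)
        t = table_of(values)
        res = bio.percent_positive(t, "m", bio.ThresholdGate("m", float(np.median(values))))
        assert abs(res.n_inside - 500) <= 1

    def test_invariant_to_event_order_and_monotone_rescaling(self, rng):
        values = rng.normal(0, 1, 500)
        gate = bio.ThresholdGate("m", 0.7)
        base = bio.percent_positive(table_of(values), "m", gate).percent
        shuffled = bio.percent_positive(table_of(rng.permutation(values)), "m", gate).percent
        rescaled = bio.percent_positive(
            table_of(np.exp(values)), "m", bio.ThresholdGate("m", float(np.exp(0.7)))
        ).percent
        assert base == shuffled == rescaled

    def test_derived_gate_lands_at_the_equal_density_point(self, rng):
        """Vehicle ~N(0,1), control ~N(3,1): the difference of survival
        functions peaks at the equal-density point 1.5."""
        vehicle = table_of(rng.normal(0, 1, 10_000))
        control = table_of(rng.normal(3, 1, 10_000))
        gate = bio.derive_positivity_gate(vehicle, control, "m")
        assert 1.0 <= gate.threshold <= 2.0

    def test_polygon_gate_boundary_counts_inside(self):
        import pandas as pd

        data = pd.DataFrame({"SSC-A": [0.0, 0.5, 2.0], "m": [0.0, 0.5, 2.0]})
        channels = [sio.Channel("SSC-A", sio.ROLE_SCATTER), sio.Channel("m", sio.ROLE_MARKER)]
        t = sio.EventTable(data, channels, "raw")
        gate = bio.PolygonGate("SSC-A", "m", ((0, 0), (1, 0), (1, 1), (0, 1)))
        res = bio.percent_positive(t, "m", gate)
        assert res.n_inside == 2  # (0,0) on the boundary and (.5,.5) inside


class TestSelectivity:
    def test_equal_percents_give_zero(self):
        assert bio.selectivity_log2(12.0, 12.0).log2_ratio == 0.0

    def test_fourfold_ratio_without_pseudocount(self):
        assert bio.selectivity_log2(40.0, 10.0, pseudocount=0.0).log2_ratio == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "pa,pb,quadrant",
        [(30, 5, "selective-a"), (5, 30, "selective-b"), (30, 30, "both"), (5, 5, "neither")],
    )
    def test_quadrants(self, pa, pb, quadrant):
        res = bio.selectivity_log2(pa, pb, threshold_a=13.3, threshold_b=13.3)
        assert res.quadrant == quadrant

    def test_negative_input_is_an_error(self):
        with pytest.raises(SarmapError):
            bio.selectivity_log2(-1.0, 5.0)
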