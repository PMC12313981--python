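"""Fold-change matrices, clustering, subclass statistics, paired
signatures, and the end-to-end pipeline."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sarmap import bioactivity as bio
from sarmap import io as sio
from sarmap import report
from sarmap import synthetic as syn
from sarmap.exceptions import ConfigurationError, SarmapError
from tests.conftest import make_marker_table


def small_plate(markers, effects_by_compound, cells=1200, seed=17):
    wells = [
        syn.WellSpec("A1", "vehicle", "veh-1", subclass="vehicle"),
        syn.WellSpec("A2", "vehicle", "veh-2", subclass="vehicle"),
    ]
    grid = iter([f"{r}{c}" for r in "BCD" for c in range(1, 7)])
    effects = []
    for cid, eff in effects_by_compound.items():
        wells.append(syn.WellSpec(next(grid), "test", cid, subclass=eff.pop("subclass", "")))
        effects.append(syn.CompoundEffect(cid, **eff))
    design = syn.PlateDesign(
        wells=wells, markers=markers, cells_per_well=cells,
        debris_fraction=0.0, doublet_fraction=0.0, dead_fraction=0.0,
        count_model="fixed", seed=seed,
    )
    table, truth = syn.simulate_plate(design, effects)
    annotated = syn.annotate_from_truth(table, truth)
    scaled = sio.arcsinh_scale(annotated, design.panel())
    wells_map = sio.split_by_well(scaled)
    return wells_map, design.layout(), design.panel(), truth


class TestFoldChangeMatrix:
    def test_vehicle1_row_is_exactly_zero(self, eleven_markers):
        wells, layout, panel, _ = small_plate(eleven_markers[:4], {"c1": {}})
        matrix = report.fold_change_matrix(wells, layout, panel, vehicle_mode="vehicle1")
        assert np.allclose(matrix.values.loc["veh-1"], 0.0)

    def test_planted_single_marker_effect(self, eleven_markers):
        wells, layout, panel, _ = small_plate(
            eleven_markers[:4], {"c1": {"effect_vector": {"gH2AX": 2.0}}}, cells=20_000
        )
        matrix = report.fold_change_matrix(wells, layout, panel, vehicle_mode="pooled")
        m = syn.default_markers()[0]  # gH2AX
        expected = np.arcsinh(2 * m.baseline_location / m.cofactor) - np.arcsinh(
            m.baseline_location / m.cofactor
        )
        assert matrix.values.loc["c1", "gH2AX"] == pytest.approx(expected, abs=0.03)
        others = matrix.values.loc["c1"].drop("gH2AX")
        assert np.all(np.abs(others) < 0.05)

    def test_no_vehicle_is_an_error(self, eleven_markers):
        wells, layout, panel, _ = small_plate(eleven_markers[:4], {"c1": {}})
        wells = {w: t for w, t in wells.items() if w not in ("A1", "A2")}
        with pytest.raises(SarmapError):
            report.fold_change_matrix(wells, layout, panel)


class TestHierarchicalCluster:
    def block_matrix(self):
        rows = {}
        for i in range(4):
            rows[f"x{i}"] = {"m1": 2.0 + 0.01 * i, "m2": 0.0}
        for i in range(4):
            rows[f"y{i}"] = {"m1": 0.0, "m2": 2.0 + 0.01 * i}
        return bio.FoldChangeMatrix(pd.DataFrame.from_dict(rows, orient="index"))

    def test_orthogonal_signatures_split_at_k2(self):
        res = report.hierarchical_cluster(self.block_matrix(), k=2)
        groups = res.assignments.groupby(res.assignments).groups
        members = {tuple(sorted(v)) for v in groups.values()}
        assert members == {("x0", "x1", "x2", "x3"), ("y0", "y1", "y2", "y3")}

    def test_input_order_invariance(self):
        m = self.block_matrix()
        shuffled = bio.FoldChangeMatrix(m.values.sample(frac=1, random_state=3))
        a = report.hierarchical_cluster(m, k=3).assignments.sort_index()
        b = report.hierarchical_cluster(shuffled, k=3).assignments.sort_index()
        # same partition (cluster ids may permute)
        for c1, c2 in itertools.combinations(a.index, 2):
            assert (a[c1] == a[c2]) == (b[c1] == b[c2])

    def test_default_cut_is_five_clusters(self):
        res = report.hierarchical_cluster(self.block_matrix())
        assert res.k == 5 and res.assignments.nunique() == 5

    def test_single_compound_and_bad_k(self):
        single = bio.FoldChangeMatrix(pd.DataFrame({"m": [1.0]}, index=["only"]))
        res = report.hierarchical_cluster(single, k=1)
        assert res.assignments.to_dict() == {"only": 1}
        with pytest.raises(SarmapError):
            report.hierarchical_cluster(self.block_matrix(), k=50)


class TestSubclassStats:
    def test_identical_distributions_are_not_significant(self, rng):
        values = pd.Series(rng.normal(0, 1, 24), index=[f"c{i}" for i in range(24)])
        subclasses = pd.Series(["A"] * 12 + ["B"] * 12, index=values.index)
        res = report.subclass_stats(values, subclasses, "A")
        assert res.p_value >= 0.05 and not res.significant

    def test_complete_separation_is_highly_significant(self, rng):
        vals = np.concatenate([rng.uniform(10, 11, 9), rng.uniform(0, 1, 28)])
        values = pd.Series(vals, index=[f"c{i}" for i in range(37)])
        subclasses = pd.Series(["RP"] * 9 + ["other"] * 28, index=values.index)
        res = report.subclass_stats(values, subclasses, "RP")
        assert res.p_value < 0.001 and res.significant
        assert res.location_shift > 9.0

    def test_one_sided_p_values_sum_to_at_most_one_plus_tie_mass(self, rng):
        vals = pd.Series(rng.normal(0, 1, 16), index=[f"c{i}" for i in range(16)])
        sub = pd.Series(["A"] * 8 + ["B"] * 8, index=vals.index)
        p_ab = report.subclass_stats(vals, sub, "A").p_value
        p_ba = report.subclass_stats(vals, sub, "B").p_value
        # exact tails overlap only in the observed statistic's point mass
        assert p_ab + p_ba <= 1.0 + 0.05

    def test_wilcoxon_matches_permutation_enumeration(self, rng):
        """One-sided rank-sum p agrees with brute-force enumeration of
        every group relabeling on small tie-free samples."""
        from scipy.stats import rankdata

        for trial in range(5):
            x = rng.normal(0, 1, 5)
            y = rng.normal(0.5, 1, 6)
            values = pd.Series(np.r_[x, y], index=[f"c{i}" for i in range(11)])
            sub = pd.Series(["T"] * 5 + ["R"] * 6, index=values.index)
            res = report.subclass_stats(values, sub, "T")
            ranks = rankdata(np.r_[x, y])
            observed = ranks[:5].sum()
            count = total = 0
            for combo in itertools.combinations(range(11), 5):
                total += 1
                if ranks[list(combo)].sum() >= observed - 1e-12:
                    count += 1
            assert res.p_value == pytest.approx(count / total, abs=1e-10)

    def test_consistency_iqr_ranks_the_tight_subclass_first(self, rng):
        rows = {}
        for i in range(6):  # tight subclass
            rows[f"t{i}"] = {"m1": 1.0 + 0.01 * rng.normal(), "m2": -0.5 + 0.01 * rng.normal()}
        for i in range(6):  # loose subclass
            rows[f"l{i}"] = {"m1": rng.normal(0, 1), "m2": rng.normal(0, 1)}
        matrix = bio.FoldChangeMatrix(pd.DataFrame.from_dict(rows, orient="index"))
        sub = pd.Series(["tight"] * 6 + ["loose"] * 6, index=matrix.values.index)
        cons = report.subclass_consistency(matrix, sub)
        assert cons["tight"] < cons["loose"]


class TestSignaturePair:
    def test_self_comparison_is_zero(self, eleven_markers, rng):
        t = make_marker_table({m.name: rng.lognormal(9, 0.4, 400) for m in eleven_markers[:4]})
        panel = sio.PanelConfig([sio.PanelMarker(m.name, m.name, m.cofactor) for m in eleven_markers[:4]])
        cmp_ = report.signature_pair_compare(t, t, panel)
        assert np.allclose(cmp_.table.delta_arcsinh, 0.0)
        assert np.allclose(cmp_.table.fold_difference, 1.0)

    def test_planted_sixteen_fold_drop(self, eleven_markers, rng):
        m = eleven_markers[0]
        panel = sio.PanelConfig([sio.PanelMarker(m.name, m.name, m.cofactor)])
        base = rng.lognormal(np.log(m.baseline_location), 0.5, 20_000)
        a = make_marker_table({m.name: base})
        b = make_marker_table({m.name: rng.lognormal(np.log(m.baseline_location / 16), 0.5, 20_000)})
        cmp_ = report.signature_pair_compare(a, b, panel)
        assert cmp_.table.fold_difference[0] == pytest.approx(16.0, rel=0.05)

    def test_pairs_must_differ_in_exactly_one_flag(self):
        layout = sio.PlateLayout(pd.DataFrame({
            "well": ["A1", "B1", "B2", "B3"],
            "compound": ["veh", "p1", "p2", "p3"],
            "subclass": ["vehicle", "RP", "RP", "RP"],
            "dose": [0.0, 10.0, 10.0, 10.0],
            "role": ["vehicle", "test", "test", "test"],
            "methoxy_4p": [0, 1, 0, 0],
            "aryl_r": [0, 0, 0, 1],
        }))
        assert report.validate_pair(layout, "p1", "p2") == "methoxy_4p"
        with pytest.raises(ConfigurationError, match="2 flags"):
            report.validate_pair(layout, "p1", "p3")


class TestWilcoxonThresholdBounds:
    def test_bounds_are_below_the_target_median(self, rng):
        x = rng.normal(30, 5, 37)
        y = rng.normal(5, 2, 37)
        bounds = report.wilcoxon_threshold_bounds(x, y)
        assert bounds["hodges_lehmann_shift_lower"] < np.median(x) - np.median(y)
        assert bounds["target_median_lower"] < np.median(x)
        assert bounds["target_median_lower"] > np.quantile(x, 0.1)


@pytest.fixture(scope="module")
def mini_config(tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    markers = syn.default_markers()[:5]
    wells = [
        syn.WellSpec("A1", "vehicle", "veh-1", subclass="vehicle"),
        syn.WellSpec("A2", "vehicle", "veh-2", subclass="vehicle"),
        syn.WellSpec("B1", "test", "rp-1", subclass="RP"),
        syn.WellSpec("B2", "test", "rr-1", subclass="RR"),
    ]
    effects = [
        syn.CompoundEffect("rp-1", effect_vector={"gH2AX": 3.0},
                           responder_fraction=0.3,
                           responder_signature={"gH2AX": 25.0, "p-4EBP1": 12.0}),
        syn.CompoundEffect("rr-1", effect_vector={"p-S6 S240/244": 1.8}),
    ]
    design = syn.PlateDesign(
        wells=wells, markers=markers, cells_per_well=700, count_model="fixed", seed=21
    )
    return {
        "design": (design, effects),
        "seed": 21,
        "outdir": str(out / "bundle"),
        "debarcode": False,
        "n_per_group": 500,
        "perplexity": 25,
        "tsne_iterations": 300,
        "vehicle_group": "vehicle",
    }


class TestPipeline:
    def test_pipeline_writes_the_report_bundle(self, mini_config):
        res = report.run_pipeline(dict(mini_config))
        outdir = res["outdir"]
        for name in ("fold_change_matrix.csv", "bioactivity.csv", "qc_report.csv",
                     "embedding.csv", "trex_degree_of_difference.csv", "clusters.csv",
                     "manifest.yaml"):
            assert (outdir / name).exists(), name
        assert res["bioactive"]["rp-1"]

    def test_rerun_reproduces_tabular_outputs_byte_for_byte(self, mini_config, tmp_path):
        cfg2 = dict(mini_config)
        cfg2["outdir"] = str(tmp_path / "again")
        report.run_pipeline(cfg2)
        first, second = mini_config["outdir"], cfg2["outdir"]
        from pathlib import Path

        for name in ("fold_change_matrix.csv", "embedding.csv", "clusters.csv"):
            assert (Path(first) / name).read_bytes() == (Path(second) / name).read_bytes()

    def test_stage_failure_is_reported_with_the_stage_name(self, tmp_path):
        bad = {"design": "/nonexistent/design.yaml", "outdir": str(tmp_path / "x"), "seed": 0}
        with pytest.raises(report.StageFailure) as err:
            report.run_pipeline(bad)
        assert err.value.stage == "simulate"
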