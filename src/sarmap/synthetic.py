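"""Ground-truth-annotated synthetic barcoded phospho-flow plates.

The generator emulates a pooled, fluorescently barcoded 96-well (or
half-plate) phospho-flow screen: each well's cells carry a two-dye barcode
signature, marker intensities are lognormal on the raw scale (hence
approximately Gaussian after the arcsinh transform), compound wells apply
per-marker multiplicative shifts to the raw medians, and a configurable
fraction of cells forms a distinct responder subpopulation with its own
signature (the phenotype the downstream neighborhood analyses hunt for).
Debris (low scatter, dim everything), doublets (sums of two cells), and
dead cells (bright viability stain) provide material for QC gating.

Every emitted event has exactly one ground-truth row, so each downstream
stage can be scored against what was planted. A single integer seed
governs all draws; per-well substreams are derived from (seed, well
index), so adding wells never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError
from .io import (
    ROLE_BARCODE,
    ROLE_MARKER,
    ROLE_SCATTER,
    ROLE_TEST,
    ROLE_VEHICLE,
    ROLE_VIABILITY,
    BarcodeScheme,
    Channel,
    EventTable,
    PanelConfig,
    PanelMarker,
    PlateLayout,
)

POP_MAIN = "main"
POP_RESPONDER = "responder"
POP_DEBRIS = "debris"
POP_DOUBLET = "doublet"
POP_DEAD = "dead"


@dataclass(frozen=True)
class MarkerModel:
    """Baseline raw-intensity model for one marker.

    ``baseline_location`` is the raw-scale median; intensities are drawn
    lognormal, ``location * exp(scale * z)``, so a multiplicative effect
    shifts the median exactly by its factor. ``cofactor`` is the arcsinh
    cofactor used downstream for this marker.
    """

    name: str
    baseline_location: float = 2000.0
    baseline_scale: float = 0.6
    cofactor: float = 6000.0

    def __post_init__(self):
        if not self.baseline_scale > 0:
            raise ConfigurationError(f"{self.name}: baseline_scale must be > 0")
        if not self.cofactor > 0:
            raise ConfigurationError(f"{self.name}: cofactor must be > 0")


@dataclass(frozen=True)
class WellSpec:
    well: str
    role: str  # vehicle | positive-control | test
    compound: str
    dose: float = 10.0  # uM; screening concentration unless overridden
    subclass: str = ""


@dataclass
class CompoundEffect:
    """Per-marker multiplicative effect of a compound on raw medians.

    ``effect_vector`` maps marker name -> shift (1.0 = no effect) applied
    to every surviving cell; ``responder_fraction`` of surviving cells
    instead express ``responder_signature`` (an island phenotype);
    ``kill_fraction`` removes cells before acquisition, emulating
    compound-induced killing read out as cell-count ratio.
    """

    compound: str
    effect_vector: Mapping[str, float] = field(default_factory=dict)
    kill_fraction: float = 0.0
    responder_fraction: float = 0.0
    responder_signature: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name, v in list(self.effect_vector.items()) + list(self.responder_signature.items()):
            if not v > 0:
                raise ConfigurationError(f"{self.compound}: shift for {name!r} must be > 0")
        for fname in ("kill_fraction", "responder_fraction"):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{self.compound}: {fname} must be in [0, 1]")


@dataclass
class PlateDesign:
    """Design of one synthetic barcoded plate."""

    wells: list[WellSpec]
    markers: list[MarkerModel]
    cells_per_well: int = 5000
    barcode_scheme: BarcodeScheme = field(default_factory=BarcodeScheme)
    barcode_cv: float = 0.15
    debris_fraction: float = 0.05
    doublet_fraction: float = 0.03
    dead_fraction: float = 0.05
    count_model: str = "poisson"  # "poisson" | "fixed"
    seed: int = 0

    def validate(self) -> None:
        fracs = (self.debris_fraction, self.doublet_fraction, self.dead_fraction)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ConfigurationError("debris/doublet/dead fractions must be in [0, 1]")
        if sum(fracs) > 1.0:
            raise ConfigurationError("debris + doublet + dead fractions exceed 1")
        if self.cells_per_well < 1:
            raise ConfigurationError("cells_per_well must be >= 1")
        if self.count_model not in ("poisson", "fixed"):
            raise ConfigurationError(f"unknown count_model {self.count_model!r}")
        names = [w.well for w in self.wells]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate well ids in design")
        if not any(w.role == ROLE_VEHICLE for w in self.wells):
            raise ConfigurationError("design must contain at least one vehicle well")
        grid = set(self.barcode_scheme.well_grid())
        off = [n for n in names if n not in grid]
        if off:
            raise ConfigurationError(f"wells outside the barcode grid: {off}")

    def panel(self) -> PanelConfig:
        return PanelConfig([PanelMarker(m.name, m.name, m.cofactor) for m in self.markers])

    def layout(self) -> PlateLayout:
        rows = [
            {"well": w.well, "compound": w.compound, "subclass": w.subclass, "dose": w.dose, "role": w.role}
            for w in self.wells
        ]
        return PlateLayout(pd.DataFrame(rows))


@dataclass
class DoseDesign:
    """Dose ladder with a planted Hill-shaped responder fraction.

    The default ladder is the eight-point screening ladder
    0, 0.01, 0.05, 0.1, 0.5, 1, 5, 10 uM; the planted curve is
    ``floor + (ceiling - floor) * x^h / (x^h + ec50^h)``.
    """

    dose_ladder: tuple[float, ...] = (0.0, 0.01, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0)
    planted_ec50: float = 0.5  # uM (500 nM)
    planted_hill: float = 1.0
    floor: float = 0.02
    ceiling: float = 0.85

    def __post_init__(self):
        doses = sorted(self.dose_ladder)
        if any(d < 0 for d in doses):
            raise ConfigurationError("doses must be non-negative")
        if len(set(doses)) != len(doses):
            raise ConfigurationError("doses must be strictly increasing after sorting")
        if not 0.0 <= self.floor < self.ceiling <= 1.0:
            raise ConfigurationError("need 0 <= floor < ceiling <= 1")
        if not self.planted_ec50 > 0:
            raise ConfigurationError("planted_ec50 must be > 0")

    def responder_fraction(self, dose: float) -> float:
        if dose == 0:
            return self.floor
        h, e = self.planted_hill, self.planted_ec50
        return self.floor + (self.ceiling - self.floor) * dose**h / (dose**h + e**h)


@dataclass
class GroundTruth:
    """One row per emitted event plus per-well truth.

    ``events`` columns: well, population, compound, dose, subclass.
    ``wells`` columns: well, compound, dose, role, n_events plus the true
    per-marker median shift (``shift_<marker>``) and responder fraction.
    """

    events: pd.DataFrame
    wells: pd.DataFrame


# ---------------------------------------------------------------------------
# default panels (screening conventions: 6000-family cofactors for the
# 11-marker panel, 150 for the compact 4-marker panel)
# ---------------------------------------------------------------------------

_ELEVEN = [
    ("gH2AX", 6000.0),
    ("p-HH3", 12000.0),
    ("p-S6 S235/236", 12000.0),
    ("Ki67", 25000.0),
    ("p-S6 S240/244", 12000.0),
    ("p-STAT3", 12000.0),
    ("p-STAT5", 25000.0),
    ("p-ERK1/2", 6000.0),
    ("p-4EBP1", 12000.0),
    ("p-SFK", 6000.0),
    ("p-AKT", 6000.0),
]

_FOUR = [("c-CAS3", 150.0), ("gH2AX", 150.0), ("p-S6 S240/244", 150.0), ("p-HH3", 150.0)]


def default_markers(panel: str = "eleven") -> list[MarkerModel]:
    """The 11-marker screening panel (default) or the compact 4-marker one.

    Baseline medians scale with each marker's cofactor: cofactors are
    chosen in practice a few-fold below the stained-population intensity,
    so baseline medians sit at ~3x the cofactor (arcsinh ~1.8). This
    keeps arcsinh-scale distributions comparable across markers and gives
    enrichment magnitudes a realistic dynamic range.
    """
    spec = {"eleven": _ELEVEN, "four": _FOUR}.get(panel)
    if spec is None:
        raise ConfigurationError(f"unknown default panel {panel!r}")
    return [
        MarkerModel(name, baseline_location=3.0 * cf, baseline_scale=0.6, cofactor=cf)
        for name, cf in spec
    ]


def default_responder_signature() -> dict[str, float]:
    """The island phenotype planted by default: a complete alternative
    signaling state for cells mounting a DNA-damage response while
    retaining mTOR output.

    gH2AX is strongly induced (tens-fold raw shifts are typical of potent
    double-strand-break inducers), mTOR/translation outputs (p-4EBP1,
    both p-S6 epitopes) stay up, and RTK/JAK-STAT signaling plus
    proliferation readouts are shut down, as expected of cells in
    damage-induced arrest.
    """
    return {
        "gH2AX": 25.0,
        "p-4EBP1": 12.0,
        "p-S6 S240/244": 8.0,
        "p-S6 S235/236": 8.0,
        "p-ERK1/2": 0.4,
        "p-STAT3": 0.4,
        "p-STAT5": 0.4,
        "p-AKT": 0.4,
        "p-SFK": 0.4,
        "p-HH3": 0.4,
        "Ki67": 0.4,
    }


def default_bulk_effect() -> dict[str, float]:
    """Default bulk (non-responder) effect of a translation-inhibitor-like
    compound: mTOR/translation and proliferative readouts suppressed."""
    return {
        "p-4EBP1": 0.35,
        "p-S6 S240/244": 0.35,
        "p-S6 S235/236": 0.35,
        "p-ERK1/2": 0.35,
        "p-STAT5": 0.6,
        "Ki67": 0.7,
    }


# ---------------------------------------------------------------------------
# event synthesis
# ---------------------------------------------------------------------------

_SCATTER = {"FSC-A": (50000.0, 0.18), "SSC-A": (30000.0, 0.30)}
_VIABILITY_LIVE = (300.0, 0.5)
_VIABILITY_DEAD = (30000.0, 0.3)
_DEBRIS_FACTOR = 0.05


def _lognormal(rng, median, sigma, n):
    return median * np.exp(sigma * rng.standard_normal(n))


def _draw_cells(rng, markers: Sequence[MarkerModel], shifts: Mapping[str, float], n: int) -> dict:
    cols = {}
    for m in markers:
        med = m.baseline_location * float(shifts.get(m.name, 1.0))
        cols[m.name] = _lognormal(rng, med, m.baseline_scale, n)
    fsc = _lognormal(rng, *_SCATTER["FSC-A"], n)
    cols["FSC-A"] = fsc
    cols["FSC-H"] = fsc * 0.95 * np.exp(0.04 * rng.standard_normal(n))
    cols["SSC-A"] = _lognormal(rng, *_SCATTER["SSC-A"], n)
    cols["Ax700"] = _lognormal(rng, *_VIABILITY_LIVE, n)
    return cols


def _barcode_columns(rng, scheme: BarcodeScheme, cv: float, row_level: int, col_level: int, n: int) -> dict:
    sigma = np.sqrt(np.log1p(cv * cv))
    out = {}
    for dye, level in (
        (scheme.dye_row, row_level),
        (scheme.dye_col, col_level),
        (scheme.control, 1),
    ):
        mean = dye.level_means()[level - 1]
        # mean-preserving lognormal noise at the requested CV
        out[dye.channel] = mean * np.exp(sigma * rng.standard_normal(n) - sigma * sigma / 2.0)
    return out


def _channels_for(design: PlateDesign) -> list[Channel]:
    scheme = design.barcode_scheme
    chans = [
        Channel("FSC-A", ROLE_SCATTER),
        Channel("FSC-H", ROLE_SCATTER),
        Channel("SSC-A", ROLE_SCATTER),
        Channel("Ax700", ROLE_VIABILITY),
        Channel(scheme.dye_row.channel, ROLE_BARCODE),
        Channel(scheme.dye_col.channel, ROLE_BARCODE),
        Channel(scheme.control.channel, ROLE_BARCODE),
    ]
    chans += [Channel(m.name, ROLE_MARKER) for m in design.markers]
    return chans


def _simulate_well(
    rng: np.random.Generator,
    design: PlateDesign,
    well: WellSpec,
    effect: CompoundEffect | None,
    row_level: int,
    col_level: int,
) -> tuple[pd.DataFrame, pd.Series]:
    markers = design.markers
    if design.count_model == "poisson":
        n_total = int(rng.poisson(design.cells_per_well))
    else:
        n_total = design.cells_per_well
    kill = effect.kill_fraction if effect else 0.0
    n_surv = int(rng.binomial(n_total, 1.0 - kill)) if kill > 0 else n_total

    probs = np.array(
        [design.debris_fraction, design.doublet_fraction, design.dead_fraction], dtype=float
    )
    probs = np.append(probs, 1.0 - probs.sum())
    n_debris, n_doublet, n_dead, n_main = rng.multinomial(n_surv, probs)

    shifts = dict(effect.effect_vector) if effect else {}
    resp_frac = effect.responder_fraction if effect else 0.0
    n_resp = int(rng.binomial(n_main, resp_frac)) if resp_frac > 0 else 0
    n_plain = n_main - n_resp

    frames, pops = [], []

    def emit(cols: dict, population: str, n: int):
        if n == 0:
            return
        frames.append(pd.DataFrame(cols))
        pops.extend([population] * n)

    emit(_draw_cells(rng, markers, shifts, n_plain), POP_MAIN, n_plain)
    if n_resp:
        # the responder signature is an alternative phenotype relative to
        # baseline, not a modifier stacked on the bulk effect
        emit(_draw_cells(rng, markers, dict(effect.responder_signature), n_resp), POP_RESPONDER, n_resp)
    if n_debris:
        cols = _draw_cells(rng, markers, shifts, n_debris)
        for k in cols:
            cols[k] = cols[k] * _DEBRIS_FACTOR
        emit(cols, POP_DEBRIS, n_debris)
    if n_doublet:
        a = _draw_cells(rng, markers, shifts, n_doublet)
        b = _draw_cells(rng, markers, shifts, n_doublet)
        cols = {k: a[k] + b[k] for k in a}
        cols["FSC-H"] = np.maximum(a["FSC-H"], b["FSC-H"])  # height tracks the larger cell
        emit(cols, POP_DOUBLET, n_doublet)
    if n_dead:
        cols = _draw_cells(rng, markers, {}, n_dead)
        cols["Ax700"] = _lognormal(rng, *_VIABILITY_DEAD, n_dead)
        emit(cols, POP_DEAD, n_dead)

    if frames:
        data = pd.concat(frames, ignore_index=True)
    else:
        data = pd.DataFrame({c.name: np.empty(0) for c in _channels_for(design)})
    n = len(data)
    bc = _barcode_columns(rng, design.barcode_scheme, design.barcode_cv, row_level, col_level, n)
    for k, v in bc.items():
        # debris is unlabeled junk: its barcode signal is dim as well
        v = v.copy()
        v[np.asarray(pops) == POP_DEBRIS] *= _DEBRIS_FACTOR
        data[k] = v

    truth = pd.DataFrame(
        {
            "well": well.well,
            "population": pops,
            "compound": well.compound,
            "dose": well.dose,
            "subclass": well.subclass,
        }
    )
    well_row = pd.Series(
        {
            "well": well.well,
            "compound": well.compound,
            "dose": well.dose,
            "role": well.role,
            "subclass": well.subclass,
            "n_events": n,
            "responder_fraction": resp_frac,
            **{f"shift_{m.name}": float(shifts.get(m.name, 1.0)) for m in markers},
        }
    )
    return pd.concat([data], axis=1), (truth, well_row)


def simulate_plate(
    design: PlateDesign,
    effects: Sequence[CompoundEffect] = (),
    seed: int | None = None,
) -> tuple[EventTable, GroundTruth]:
    """Simulate a pooled, barcoded plate.

    Every test well's compound must have a :class:`CompoundEffect`;
    vehicle wells draw from the baseline distributions only. Identical
    (design, effects, seed) reproduce identical output bit-for-bit.
    """
    design.validate()
    seed = design.seed if seed is None else seed
    by_compound = {e.compound: e for e in effects}
    grid = design.barcode_scheme.well_grid()
    grid_index = {w: i for i, w in enumerate(grid)}

    frames, truths, well_rows = [], [], []
    for spec in design.wells:
        effect = by_compound.get(spec.compound)
        if spec.role == ROLE_TEST and effect is None:
            raise ConfigurationError(
                f"well {spec.well}: no CompoundEffect for compound {spec.compound!r}"
            )
        idx = grid_index[spec.well]
        row_level = idx // design.barcode_scheme.dye_col.levels + 1
        col_level = idx % design.barcode_scheme.dye_col.levels + 1
        rng = np.random.default_rng([seed, idx])
        data, (truth, well_row) = _simulate_well(rng, design, spec, effect, row_level, col_level)
        frames.append(data)
        truths.append(truth)
        well_rows.append(well_row)

    data = pd.concat(frames, ignore_index=True)
    events = pd.concat(truths, ignore_index=True)
    table = EventTable(data[[c.name for c in _channels_for(design)]], _channels_for(design), "raw")
    return table, GroundTruth(events=events, wells=pd.DataFrame(well_rows))


def simulate_dose_series(
    effect: CompoundEffect,
    dose_design: DoseDesign,
    cells_per_dose: int,
    seed: int = 0,
    markers: Sequence[MarkerModel] | None = None,
) -> tuple[EventTable, GroundTruth]:
    """Simulate one compound's dose ladder, one condition per dose.

    The responder fraction at dose x follows the planted Hill curve; at
    dose 0 it equals the floor. The emitted table carries ``well`` and
    ``dose`` annotations directly (dose ladders are acquired one tube per
    compound and deconvoluted manually, so no two-dye barcode is drawn).
    """
    if cells_per_dose < 1:
        raise ConfigurationError("cells_per_dose must be >= 1")
    markers = list(markers) if markers is not None else default_markers()
    doses = sorted(dose_design.dose_ladder)

    design = PlateDesign(
        wells=[WellSpec("A1", ROLE_VEHICLE, "vehicle")],
        markers=markers,
        cells_per_well=cells_per_dose,
        debris_fraction=0.0,
        doublet_fraction=0.0,
        dead_fraction=0.0,
        count_model="fixed",
        seed=seed,
    )
    frames, truths, well_rows = [], [], []
    for i, dose in enumerate(doses):
        frac = dose_design.responder_fraction(dose)
        dose_effect = CompoundEffect(
            compound=effect.compound,
            effect_vector=effect.effect_vector,
            responder_fraction=frac,
            responder_signature=effect.responder_signature or default_responder_signature(),
        )
        spec = WellSpec(f"D{i}", ROLE_TEST, effect.compound, dose=dose)
        rng = np.random.default_rng([seed, i])
        data, (truth, well_row) = _simulate_well(rng, design, spec, dose_effect, 1, 1)
        data = data.assign(well=spec.well, dose=dose)
        frames.append(data)
        truths.append(truth)
        well_rows.append(well_row)

    chans = _channels_for(design)
    data = pd.concat(frames, ignore_index=True)
    table = EventTable(data, chans, "raw")
    return table, GroundTruth(events=pd.concat(truths, ignore_index=True), wells=pd.DataFrame(well_rows))


def annotate_from_truth(table: EventTable, truth: GroundTruth) -> EventTable:
    """Attach the true well/compound/dose annotations to an event table
    produced by :func:`simulate_plate` (bypassing debarcoding)."""
    if table.n_events != len(truth.events):
        raise ConfigurationError("table and ground truth are misaligned")
    out = table
    for col in ("well", "compound", "dose", "subclass"):
        out = out.with_annotation(col, truth.events[col].to_numpy())
    return out


# ---------------------------------------------------------------------------
# YAML design loading (CLI surface)
# ---------------------------------------------------------------------------

def load_design(path) -> tuple[PlateDesign, list[CompoundEffect]]:
    """Parse a plate design + compound effects from a single YAML config."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    markers = [
        MarkerModel(
            m["name"],
            baseline_location=float(m.get("baseline_location", 2000.0)),
            baseline_scale=float(m.get("baseline_scale", 0.6)),
            cofactor=float(m.get("cofactor", 6000.0)),
        )
        for m in spec.get("markers", [])
    ] or default_markers()
    wells = [
        WellSpec(
            w["well"],
            w.get("role", ROLE_TEST),
            w["compound"],
            dose=float(w.get("dose", 10.0)),
            subclass=w.get("subclass", ""),
        )
        for w in spec["wells"]
    ]
    design = PlateDesign(
        wells=wells,
        markers=markers,
        cells_per_well=int(spec.get("cells_per_well", 5000)),
        barcode_cv=float(spec.get("barcode_cv", 0.15)),
        debris_fraction=float(spec.get("debris_fraction", 0.05)),
        doublet_fraction=float(spec.get("doublet_fraction", 0.03)),
        dead_fraction=float(spec.get("dead_fraction", 0.05)),
        count_model=spec.get("count_model", "poisson"),
        seed=int(spec.get("seed", 0)),
    )
    effects = [
        CompoundEffect(
            compound=e["compound"],
            effect_vector=e.get("effect_vector", {}),
            kill_fraction=float(e.get("kill_fraction", 0.0)),
            responder_fraction=float(e.get("responder_fraction", 0.0)),
            responder_signature=e.get("responder_signature", {}),
        )
        for e in spec.get("effects", [])
    ]
    return design, effects


__all__ = [
    "CompoundEffect",
    "DoseDesign",
    "GroundTruth",
    "MarkerModel",
    "PlateDesign",
    "WellSpec",
    "annotate_from_truth",
    "default_bulk_effect",
    "default_markers",
    "default_responder_signature",
    "load_design",
    "simulate_dose_series",
    "simulate_plate",
]
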