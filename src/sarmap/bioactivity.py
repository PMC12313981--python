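"""Per-well, per-marker bioactivity readouts.

The screening readout for a marker is the arcsinh fold change of its
median fluorescence intensity (MFI) versus vehicle, implemented as the
difference of arcsinh-transformed medians::

    asinh(MFI_treated / cofactor) - asinh(MFI_vehicle / cofactor)

so that equal medians map to exactly 0 ("no change"). A literal
``asinh(MFI_treated / MFI_vehicle)`` variant is available behind the
``convention`` switch for comparison. Compounds are called bioactive when
any marker's fold change exceeds the vehicle-derived threshold
``median + multiplier x IQR`` (multiplier 3 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, SarmapError
from .io import EventTable, iqr


def _median_raw(table: EventTable, marker: str) -> float:
    if table.n_events == 0:
        raise SarmapError("empty event table")
    return float(np.median(table.values(marker)))


def mfi_fold_change(
    treated: EventTable,
    vehicle: EventTable,
    marker: str,
    cofactor: float | None = None,
    convention: str = "difference",
) -> float:
    """Arcsinh fold change of a marker's MFI in treated vs vehicle cells.

    Both tables may be raw (``cofactor`` required) or already
    arcsinh-scaled (median commutes with the monotone transform, so the
    difference of medians is taken directly). Antisymmetric by
    construction: ``f(T, V) == -f(V, T)``.
    """
    if treated.scale != vehicle.scale:
        raise ConfigurationError("treated and vehicle tables are on different scales")
    m_t, m_v = _median_raw(treated, marker), _median_raw(vehicle, marker)
    if treated.scale == "arcsinh":
        if convention != "difference":
            raise ConfigurationError("ratio convention needs raw-scale tables")
        return m_t - m_v
    if cofactor is None:
        raise ConfigurationError("cofactor required for raw-scale tables")
    if convention == "difference":
        return float(np.arcsinh(m_t / cofactor) - np.arcsinh(m_v / cofactor))
    if convention == "ratio":
        if m_v == 0:
            raise SarmapError("vehicle median is 0; ratio convention undefined")
        return float(np.arcsinh(m_t / m_v))
    raise ConfigurationError(f"unknown convention {convention!r}")


@dataclass
class FoldChangeMatrix:
    """Compounds x markers arcsinh fold-change matrix."""

    values: pd.DataFrame  # index: compound, columns: marker
    vehicle_reference: str = "pooled"
    cofactors: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ConfigurationError("fold-change matrix contains non-finite entries")

    @property
    def compounds(self) -> list[str]:
        return list(self.values.index)

    @property
    def markers(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path) -> None:
        self.values.to_csv(path)


@dataclass
class BioactivityThreshold:
    """Vehicle-derived activity cutoff: ``median + multiplier x IQR``."""

    threshold: float
    vehicle_median: float
    vehicle_iqr: float
    multiplier: float = 3.0

    @classmethod
    def from_components(cls, median: float, iqr_value: float, multiplier: float = 3.0):
        return cls(median + multiplier * iqr_value, median, iqr_value, multiplier)


def bioactivity_threshold(vehicle_values, multiplier: float = 3.0) -> BioactivityThreshold:
    """Threshold from vehicle fold-change values (>= 2 required).

    Quartiles use linear interpolation between order statistics. All
    values identical yields a zero-IQR threshold with a warning.
    """
    values = np.asarray(vehicle_values, dtype=float)
    if values.size < 2:
        raise SarmapError("need at least 2 vehicle values for a threshold")
    med = float(np.median(values))
    spread = iqr(values)
    if spread == 0.0:
        warnings.warn("vehicle IQR is 0; threshold degenerates to the median", stacklevel=2)
    return BioactivityThreshold.from_components(med, spread, multiplier)


def classify_bioactive(
    matrix: FoldChangeMatrix, threshold: BioactivityThreshold, mode: str = "any"
) -> pd.Series:
    """Per-compound bioactivity flag.

    ``mode="any"`` (default): a compound is bioactive iff any marker's
    fold change exceeds the single pooled threshold. ``mode="per-marker"``
    expects ``threshold`` to be a mapping marker -> BioactivityThreshold.
    """
    if mode == "any":
        return (matrix.values > threshold.threshold).any(axis=1)
    if mode == "per-marker":
        flags = pd.DataFrame(
            {m: matrix.values[m] > threshold[m].threshold for m in matrix.markers}
        )
        return flags.any(axis=1)
    raise ConfigurationError(f"unknown mode {mode!r}")


def count_ratio(treated: EventTable, vehicle: EventTable) -> float:
    """Ratio of QC-passing event counts, a basic cell-killing readout."""
    if vehicle.n_events == 0:
        raise SarmapError("vehicle table has zero events")
    return treated.n_events / vehicle.n_events


# ---------------------------------------------------------------------------
# percent-positive gating
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThresholdGate:
    """1-D gate: positive iff marker intensity > threshold."""

    marker: str
    threshold: float


@dataclass(frozen=True)
class PolygonGate:
    """Closed 2-D polygon over (x_channel, y_channel); boundary counts inside."""

    x_channel: str
    y_channel: str
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self):
        verts = list(self.vertices)
        if len(verts) >= 2 and tuple(verts[0]) == tuple(verts[-1]):
            verts = verts[:-1]
        if len(verts) < 3:
            raise ConfigurationError("polygon gate needs >= 3 distinct vertices (closed)")
        object.__setattr__(self, "vertices", tuple(tuple(v) for v in verts))


@dataclass
class PositivityResult:
    percent: float
    gate: object
    n_inside: int
    n_total: int

    def __post_init__(self):
        if not (0.0 <= self.percent <= 100.0) or self.n_inside > self.n_total:
            raise SarmapError("inconsistent positivity result")


def _polygon_mask(xy: np.ndarray, vertices) -> np.ndarray:
    import shapely

    poly = shapely.polygons(np.asarray(vertices, dtype=float))
    pts = shapely.points(xy)
    return shapely.covers(poly, pts)


def percent_positive(table: EventTable, marker: str, gate) -> PositivityResult:
    """Percent of events inside a 1-D threshold or closed polygon gate."""
    if table.n_events == 0:
        raise SarmapError("empty event table")
    if isinstance(gate, ThresholdGate):
        inside = table.values(gate.marker) > gate.threshold
    elif isinstance(gate, PolygonGate):
        xy = np.column_stack([table.values(gate.x_channel), table.values(gate.y_channel)])
        inside = _polygon_mask(xy, gate.vertices)
    else:
        raise ConfigurationError(f"unsupported gate type {type(gate).__name__}")
    n_inside = int(np.count_nonzero(inside))
    return PositivityResult(100.0 * n_inside / table.n_events, gate, n_inside, table.n_events)


def derive_positivity_gate(
    vehicle: EventTable,
    positive_control: EventTable,
    marker: str,
    n_grid: int = 512,
) -> ThresholdGate:
    """1-D threshold maximizing %positive(control) - %positive(vehicle).

    Candidates are ``n_grid`` evenly spaced thresholds between the pooled
    1st and 99.9th percentiles; ties resolve to the highest threshold, a
    deterministic surrogate for the expert-drawn gate.
    """
    v = vehicle.values(marker)
    c = positive_control.values(marker)
    pooled = np.concatenate([v, c])
    lo, hi = np.quantile(pooled, [0.01, 0.999])
    grid = np.linspace(lo, hi, n_grid)
    pct_c = 100.0 * (c[None, :] > grid[:, None]).mean(axis=1)
    pct_v = 100.0 * (v[None, :] > grid[:, None]).mean(axis=1)
    diff = pct_c - pct_v
    best = np.flatnonzero(diff == diff.max())[-1]  # ties -> highest threshold
    return ThresholdGate(marker, float(grid[best]))


# ---------------------------------------------------------------------------
# selectivity
# ---------------------------------------------------------------------------

QUADRANTS = ("selective-a", "selective-b", "both", "neither")


@dataclass
class SelectivityResult:
    log2_ratio: float
    quadrant: str | None
    pct_a: float
    pct_b: float


def selectivity_log2(
    pct_a: float,
    pct_b: float,
    pseudocount: float = 0.1,
    threshold_a: float | None = None,
    threshold_b: float | None = None,
) -> SelectivityResult:
    """log2 ratio of percent-positive between two cell types, with the
    quadrant call from per-cell-type thresholds when supplied.

    The pseudocount (default 0.1 percentage points) keeps zero-percent
    wells finite.
    """
    if pct_a < 0 or pct_b < 0:
        raise SarmapError("percent-positive values must be non-negative")
    if pct_a > 100 or pct_b > 100:
        raise SarmapError("percent-positive values must be <= 100")
    ratio = float(np.log2((pct_a + pseudocount) / (pct_b + pseudocount)))
    quadrant = None
    if threshold_a is not None and threshold_b is not None:
        above_a, above_b = pct_a > threshold_a, pct_b > threshold_b
        quadrant = {
            (True, False): "selective-a",
            (False, True): "selective-b",
            (True, True): "both",
            (False, False): "neither",
        }[(above_a, above_b)]
    return SelectivityResult(ratio, quadrant, pct_a, pct_b)


def set_composition(counts: dict[str, int], total: int) -> pd.Series:
    """Percent composition of a compound set from member counts
    (reporting-layer arithmetic for e.g. chemotype representation)."""
    if total <= 0:
        raise SarmapError("total must be positive")
    return pd.Series({k: 100.0 * v / total for k, v in counts.items()})


__all__ = [
    "BioactivityThreshold",
    "FoldChangeMatrix",
    "PolygonGate",
    "PositivityResult",
    "SelectivityResult",
    "ThresholdGate",
    "bioactivity_threshold",
    "classify_bioactive",
    "count_ratio",
    "derive_positivity_gate",
    "mfi_fold_change",
    "percent_positive",
    "selectivity_log2",
    "set_composition",
]
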