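"""Null-reference Marker Enrichment Modeling (MEM).

A population's per-marker enrichment combines its median magnitude on the
arcsinh scale with the spread of the population relative to a reference::

    raw score  s_m = MAG_m + (IQR_ref / IQR_m,pop - 1)     if MAG_m != 0
               s_m = 0                                      if MAG_m == 0

The reference here is a statistical null: magnitude 0 for every marker
and a single shared IQR equal to the median of the per-marker IQRs of the
full dataset. The IQR term therefore rewards populations tighter than a
typical feature and is zeroed out entirely for markers with no magnitude.
Raw scores are floored at 0 (absolute enrichment labels) and mapped
linearly so the analysis-wide maximum raw score is +10.

Label-to-label similarity is the root-mean-square deviation over markers,
reported as a percent: ``100 * (1 - rmsd / 10)``, so identical labels are
100% similar and labels differing by the full 10-point range on every
marker are 0%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigurationError, SarmapError
from .io import EventTable

IQR_CONTRIBUTION_CAP = 10.0


@dataclass
class MEMReference:
    """Reference point for MEM scoring.

    In null mode every magnitude is 0 and one shared IQR (the median
    feature IQR of the dataset) applies to all markers.
    """

    markers: tuple[str, ...]
    magnitudes: np.ndarray
    iqr: float
    mode: str = "null"

    def __post_init__(self):
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.mode == "null":
            if not np.all(self.magnitudes == 0.0):
                raise ConfigurationError("null reference requires all magnitudes 0")
            if not self.iqr > 0:
                raise ConfigurationError("null reference requires a positive shared IQR")


def _marker_iqrs(table: EventTable, markers: Sequence[str]) -> np.ndarray:
    X = table.values(list(markers))
    q25, q75 = np.quantile(X, [0.25, 0.75], axis=0)
    return q75 - q25


def build_null_reference(dataset: EventTable, markers: Sequence[str] | None = None) -> MEMReference:
    """Statistical-null reference from the full analysis dataset.

    Markers with zero dataset IQR are replaced by the smallest positive
    marker IQR (with a warning) before the median is taken.
    """
    if dataset.scale != "arcsinh":
        raise SarmapError("MEM operates on arcsinh-scaled data")
    if dataset.n_events < 2:
        raise SarmapError("need at least 2 events to build a reference")
    markers = tuple(markers) if markers is not None else tuple(dataset.marker_names)
    iqrs = _marker_iqrs(dataset, markers)
    if np.any(iqrs == 0.0):
        positive = iqrs[iqrs > 0]
        if positive.size == 0:
            raise SarmapError("every marker has zero IQR; reference undefined")
        warnings.warn("zero-IQR markers replaced by the smallest positive marker IQR", stacklevel=2)
        iqrs = np.where(iqrs == 0.0, positive.min(), iqrs)
    return MEMReference(markers=markers, magnitudes=np.zeros(len(markers)), iqr=float(np.median(iqrs)))


@dataclass
class MEMLabel:
    """Per-marker enrichment label on the 0..+10 scale."""

    markers: tuple[str, ...]
    scores: np.ndarray       # scaled, in [0, 10]
    raw_scores: np.ndarray   # pre-scaling (floored at 0 in absolute mode)
    population_size: int
    scale_max: float
    reference_mode: str = "null"

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.raw_scores = np.asarray(self.raw_scores, dtype=float)
        if np.any(self.scores < 0) or np.any(self.scores > 10):
            raise ConfigurationError("MEM scores must lie in [0, 10]")

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=list(self.markers))

    def top_markers(self, n: int = 2) -> list[str]:
        order = np.argsort(-self.scores, kind="stable")
        return [self.markers[i] for i in order[:n]]

    def to_yaml(self, path) -> None:
        spec = {
            "markers": [
                {"marker": m, "score": float(s), "raw": float(r)}
                for m, s, r in zip(self.markers, self.scores, self.raw_scores)
            ],
            "population_size": self.population_size,
            "scale_max": float(self.scale_max),
            "reference_mode": self.reference_mode,
            "scaling": "per-run maximum raw score maps to +10",
        }
        with open(path, "w") as fh:
            yaml.safe_dump(spec, fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path) -> "MEMLabel":
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        markers = tuple(m["marker"] for m in spec["markers"])
        return cls(
            markers=markers,
            scores=np.array([m["score"] for m in spec["markers"]], dtype=float),
            raw_scores=np.array([m["raw"] for m in spec["markers"]], dtype=float),
            population_size=int(spec.get("population_size", 0)),
            scale_max=float(spec["scale_max"]),
            reference_mode=spec.get("reference_mode", "null"),
        )


def raw_mem_scores(
    magnitudes: np.ndarray,
    iqrs: np.ndarray,
    reference: MEMReference,
    signed: bool = False,
) -> np.ndarray:
    """Raw (pre-scaled) MEM scores for one or many populations.

    Accepts 1-D (markers,) or 2-D (populations, markers) arrays. A zero
    population IQR with nonzero magnitude caps the IQR contribution at
    ``IQR_CONTRIBUTION_CAP`` rather than diverging.
    """
    mag = np.asarray(magnitudes, dtype=float)
    iqr_pop = np.asarray(iqrs, dtype=float)
    with np.errstate(divide="ignore"):
        contrib = reference.iqr / iqr_pop - 1.0
    capped = ~np.isfinite(contrib) | (contrib > IQR_CONTRIBUTION_CAP)
    if np.any(capped & (mag != 0)):
        warnings.warn("zero/near-zero population IQR; IQR contribution capped", stacklevel=2)
    contrib = np.where(capped, IQR_CONTRIBUTION_CAP, contrib)
    raw = np.where(mag == 0.0, 0.0, mag + contrib)
    if not signed:
        raw = np.maximum(raw, 0.0)
    return raw


def scale_scores(raw: np.ndarray, scale_max: float | None = None) -> tuple[np.ndarray, float]:
    """Map raw scores to the 0..+10 display scale.

    ``scale_max`` is the run-wide maximum raw score; when omitted it is
    taken from ``raw`` itself (single-population run). Values are clipped
    into [0, 10].
    """
    raw = np.asarray(raw, dtype=float)
    if scale_max is None:
        top = float(raw.max()) if raw.size else 0.0
        scale_max = top if top > 0 else 1.0
    scaled = np.clip(10.0 * raw / scale_max, 0.0, 10.0)
    return scaled, float(scale_max)


def mem_label(
    population: EventTable,
    reference: MEMReference,
    markers: Sequence[str] | None = None,
    scale_max: float | None = None,
    signed: bool = False,
) -> MEMLabel:
    """MEM enrichment label for one cell population.

    Pass ``scale_max`` to score several populations on a common scale
    (see :func:`mem_labels`); otherwise the population's own maximum raw
    score maps to +10.
    """
    if population.n_events == 0:
        raise SarmapError("empty population")
    if population.scale != "arcsinh":
        raise SarmapError("MEM operates on arcsinh-scaled data")
    markers = tuple(markers) if markers is not None else reference.markers
    if tuple(markers) != tuple(reference.markers):
        raise ConfigurationError("marker set/order must match the reference")
    X = population.values(list(markers))
    mag = np.median(X, axis=0)
    q25, q75 = np.quantile(X, [0.25, 0.75], axis=0)
    raw = raw_mem_scores(mag, q75 - q25, reference, signed=signed)
    scores, used_max = scale_scores(raw, scale_max)
    return MEMLabel(
        markers=markers,
        scores=scores,
        raw_scores=raw,
        population_size=population.n_events,
        scale_max=used_max,
        reference_mode=reference.mode,
    )


def mem_labels(
    populations: Mapping[str, EventTable],
    reference: MEMReference,
    markers: Sequence[str] | None = None,
) -> dict[str, MEMLabel]:
    """Label several populations on one shared 0..+10 scale (the run-wide
    maximum raw score maps to +10)."""
    markers = tuple(markers) if markers is not None else reference.markers
    prelim = {
        name: mem_label(pop, reference, markers, scale_max=1.0) for name, pop in populations.items()
    }
    run_max = max((float(lbl.raw_scores.max()) for lbl in prelim.values()), default=0.0)
    run_max = run_max if run_max > 0 else 1.0
    return {
        name: MEMLabel(
            markers=markers,
            scores=scale_scores(lbl.raw_scores, run_max)[0],
            raw_scores=lbl.raw_scores,
            population_size=lbl.population_size,
            scale_max=run_max,
            reference_mode=reference.mode,
        )
        for name, lbl in prelim.items()
    }


def label_similarity(a: MEMLabel, b: MEMLabel) -> tuple[float, float]:
    """RMSD between two labels and the percent similarity
    ``100 * (1 - rmsd / 10)`` (clipped to [0, 100])."""
    if tuple(a.markers) != tuple(b.markers):
        only_a = set(a.markers) - set(b.markers)
        only_b = set(b.markers) - set(a.markers)
        raise ConfigurationError(
            f"marker sets differ (only in a: {sorted(only_a)}, only in b: {sorted(only_b)})"
            if only_a or only_b
            else "marker order differs between labels"
        )
    rmsd = float(np.sqrt(np.mean((a.scores - b.scores) ** 2)))
    similarity = float(np.clip(100.0 * (1.0 - rmsd / 10.0), 0.0, 100.0))
    return rmsd, similarity


__all__ = [
    "IQR_CONTRIBUTION_CAP",
    "MEMLabel",
    "MEMReference",
    "build_null_reference",
    "label_similarity",
    "mem_label",
    "mem_labels",
    "raw_mem_scores",
    "scale_scores",
]
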