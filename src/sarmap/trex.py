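"""Equal-representation sampling, 2-D embedding, and the KNN
difference-hotspot comparison (degree of difference).

Two equally sized groups of cells are pooled, embedded in 2-D with t-SNE,
and every cell's k nearest embedding neighbors are inspected: a cell whose
neighborhood is at least the hotspot cutoff (default 95%) from one group
is a hotspot cell (red for group A, blue for group B). The scalar
``degree of difference`` is the percent of hotspot cells,
``100 * (red + blue) / total`` - near zero for two samples of the same
condition, near 100 for fully separated conditions.

The embedding backend is pluggable; the default t-SNE honors the study
settings (perplexity 60, 10,000 iterations, early exaggeration 12,
automatic learning rate). All downstream statistics are computed from the
stored 2-D coordinates, so a run is reproducible from the coordinate file
alone.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .exceptions import ConfigurationError, SarmapError
from .io import EventTable, concat_tables


def equal_sample(
    groups: Mapping[str, EventTable],
    n_per_group: int,
    seed: int = 0,
    strict: bool = True,
) -> EventTable:
    """Sample exactly ``n_per_group`` events per group without replacement.

    In strict mode a group smaller than ``n_per_group`` is an error naming
    the group; otherwise every group is downsampled to the minimum
    available size. The pooled table carries a ``condition`` annotation.
    """
    if n_per_group < 1:
        raise ConfigurationError("n_per_group must be >= 1")
    sizes = {label: t.n_events for label, t in groups.items()}
    short = [label for label, n in sizes.items() if n < n_per_group]
    if short and strict:
        raise SarmapError(f"groups smaller than {n_per_group}: {short}")
    n_take = n_per_group if not short else min(n_per_group, min(sizes.values()))
    sampled = []
    for label in groups:  # insertion order: deterministic
        # stable per-label substream: adding a group never perturbs others
        rng = np.random.default_rng([seed, zlib.crc32(str(label).encode())])
        sampled.append(groups[label].sample(n_take, rng).with_annotation("condition", label))
    return concat_tables(sampled)


@dataclass(frozen=True)
class EmbedParams:
    """t-SNE settings; defaults are the screening-analysis settings."""

    perplexity: float = 60.0
    iterations: int = 10_000
    early_exaggeration: float = 12.0
    learning_rate: str | float = "auto"
    init: str = "pca"
    seed: int = 0


@dataclass
class EmbeddingResult:
    """2-D coordinates with per-cell condition labels and the parameters
    recorded verbatim."""

    coords: np.ndarray  # (n, 2)
    params: EmbedParams
    labels: np.ndarray | None = None  # per-cell condition, if known
    event_index: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ConfigurationError("embedding coordinates must be (n, 2)")
        if self.labels is not None and len(self.labels) != len(self.coords):
            raise ConfigurationError("one label per embedded cell required")

    @property
    def n_cells(self) -> int:
        return len(self.coords)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coords, columns=["tsne_1", "tsne_2"])
        df.insert(0, "event", self.event_index if self.event_index is not None else np.arange(len(df)))
        if self.labels is not None:
            df["condition"] = self.labels
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, params: EmbedParams | None = None) -> "EmbeddingResult":
        df = pd.read_csv(path)
        return cls(
            coords=df[["tsne_1", "tsne_2"]].to_numpy(),
            params=params or EmbedParams(),
            labels=df["condition"].to_numpy() if "condition" in df else None,
            event_index=df["event"].to_numpy() if "event" in df else None,
        )


def embed(
    table: EventTable,
    markers: Sequence[str] | None = None,
    params: EmbedParams | None = None,
) -> EmbeddingResult:
    """t-SNE embedding of the arcsinh-scaled marker channels.

    Requires at least ``2 x perplexity`` events; a fixed seed reproduces
    coordinates on the same platform.
    """
    params = params or EmbedParams()
    if table.scale != "arcsinh":
        raise SarmapError("embed expects arcsinh-scaled markers")
    markers = list(markers) if markers is not None else table.marker_names
    n_min = int(np.ceil(2 * params.perplexity))
    if table.n_events < n_min:
        raise SarmapError(
            f"too few events for perplexity {params.perplexity}: need >= {n_min}, got {table.n_events}"
        )
    X = table.values(markers)
    tsne = TSNE(
        n_components=2,
        perplexity=params.perplexity,
        max_iter=params.iterations,
        early_exaggeration=params.early_exaggeration,
        learning_rate=params.learning_rate,
        init=params.init,
        random_state=params.seed,
        method="barnes_hut",
    )
    coords = tsne.fit_transform(X)
    labels = (
        table.data["condition"].to_numpy() if "condition" in table.data.columns else None
    )
    return EmbeddingResult(coords=coords, params=params, labels=labels)


def knn_fractions(
    coords: np.ndarray,
    is_a: np.ndarray,
    k: int,
    include_self: bool = False,
) -> np.ndarray:
    """Fraction of each cell's k nearest Euclidean neighbors in group A.

    Self is excluded by default (a cell is not its own neighbor); distance
    ties at the k-th neighbor resolve by event index.
    """
    n = len(coords)
    if k <= 0:
        raise ConfigurationError("k must be positive")
    if k >= n:
        raise ConfigurationError(f"k={k} must be below the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + (0 if include_self else 1)).fit(coords)
    _, idx = nn.kneighbors(coords)
    if not include_self:
        # drop self when present in the first k+1, else trim the extra column
        mask = idx != np.arange(n)[:, None]
        cleaned = np.empty((n, k), dtype=int)
        for i in range(n):
            cleaned[i] = idx[i][mask[i]][:k]
        idx = cleaned
    return np.asarray(is_a, dtype=float)[idx].mean(axis=1)


@dataclass
class TRexResult:
    """Per-cell neighbor fractions and hotspot bins, with the scalar
    degree of difference."""

    fraction_a: np.ndarray
    bins: np.ndarray  # "red" | "blue" | "neutral"
    degree_of_difference: float
    k: int
    hotspot_cutoff: float
    label_a: str = "A"
    label_b: str = "B"

    @property
    def n_red(self) -> int:
        return int(np.count_nonzero(self.bins == "red"))

    @property
    def n_blue(self) -> int:
        return int(np.count_nonzero(self.bins == "blue"))


def trex_compare(
    embedding: EmbeddingResult,
    label_a: str,
    label_b: str,
    k: int = 60,
    hotspot_cutoff: float = 0.95,
    balance_tolerance: float = 0.02,
    labels: np.ndarray | None = None,
) -> TRexResult:
    """KNN hotspot comparison of two equally represented conditions.

    red: neighborhood fraction of ``label_a`` >= cutoff; blue: fraction of
    ``label_b`` >= cutoff; degree of difference =
    ``100 * (red + blue) / total``. Groups unbalanced beyond
    ``balance_tolerance`` (relative) are an error - equal representation
    is enforced upstream by :func:`equal_sample`.
    """
    labels = labels if labels is not None else embedding.labels
    if labels is None:
        raise ConfigurationError("no condition labels available for the embedding")
    labels = np.asarray(labels)
    present = set(np.unique(labels))
    missing = {label_a, label_b} - present
    if missing:
        raise ConfigurationError(f"labels not present in embedding: {sorted(missing)}")
    keep = np.isin(labels, [label_a, label_b])
    coords = embedding.coords[keep]
    sub = labels[keep]
    n_a, n_b = int((sub == label_a).sum()), int((sub == label_b).sum())
    if abs(n_a - n_b) > balance_tolerance * (n_a + n_b):
        raise SarmapError(f"groups unbalanced: {label_a}={n_a}, {label_b}={n_b}")
    frac_a = knn_fractions(coords, sub == label_a, k)
    bins = np.full(len(frac_a), "neutral", dtype=object)
    bins[frac_a >= hotspot_cutoff] = "red"
    bins[(1.0 - frac_a) >= hotspot_cutoff] = "blue"
    dod = 100.0 * np.count_nonzero(bins != "neutral") / len(bins)
    return TRexResult(frac_a, bins, float(dod), k, hotspot_cutoff, label_a, label_b)


@dataclass(frozen=True)
class Region2D:
    """Named closed polygon in embedding coordinates."""

    vertices: tuple[tuple[float, float], ...]
    name: str = "region"

    def __post_init__(self):
        verts = [tuple(v) for v in self.vertices]
        if len(verts) >= 2 and verts[0] == verts[-1]:
            verts = verts[:-1]
        if len(verts) < 3:
            raise ConfigurationError("region needs >= 3 vertices (closed polygon)")
        object.__setattr__(self, "vertices", tuple(verts))

    @classmethod
    def from_yaml(cls, path) -> "Region2D":
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        return cls(tuple(tuple(v) for v in spec["vertices"]), spec.get("name", "region"))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"name": self.name, "vertices": [list(v) for v in self.vertices]}, fh)


def percent_in_region(
    embedding: EmbeddingResult,
    region: Region2D,
    condition: str | None = None,
) -> float:
    """Percent of (optionally condition-filtered) cells inside a polygon
    region of the embedding; boundary points count as inside."""
    import shapely

    coords = embedding.coords
    if condition is not None:
        if embedding.labels is None:
            raise ConfigurationError("embedding has no condition labels to filter on")
        keep = np.asarray(embedding.labels) == condition
        coords = coords[keep]
    if len(coords) == 0:
        raise SarmapError("condition filter matches no cells")
    poly = shapely.polygons(np.asarray(region.vertices, dtype=float))
    inside = shapely.covers(poly, shapely.points(coords))
    return 100.0 * np.count_nonzero(inside) / len(coords)


__all__ = [
    "EmbedParams",
    "EmbeddingResult",
    "Region2D",
    "TRexResult",
    "embed",
    "equal_sample",
    "knn_fractions",
    "percent_in_region",
    "trex_compare",
]
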