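"""Per-cell neighborhood phenotyping against a search MEM label, and
four-parameter log-logistic dose-response fitting.

Every cell in a 2-D embedding is characterized by the MEM label of its
k-nearest-neighbor neighborhood (k = 60 by default, the cell plus its 59
nearest neighbors), and scored for similarity to a search label by RMSD.
The per-dose fraction of cells above a similarity threshold (default 75%)
is the dose-response variable, fit with the four-parameter log-logistic

    f(x) = c + (d - c) / (1 + (x / e)^b)

with hill slope b, minimum c, maximum d and EC50 e all free. Zero-dose
points enter through the model's own x -> 0 limit (c for an increasing
curve, i.e. b < 0 in this parameterization) rather than on the log axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.neighbors import NearestNeighbors

from .exceptions import ConfigurationError, FitConvergenceError, SarmapError
from .io import EventTable
from .mem import MEMLabel, MEMReference, raw_mem_scores, scale_scores
from .trex import EmbeddingResult

_CHUNK = 4096


@dataclass
class SimilarityMap:
    """Per-cell percent similarity to the search label."""

    similarity: np.ndarray  # in [0, 100], one per embedded cell
    k: int
    search_label: MEMLabel
    include_self: bool = True

    def __post_init__(self):
        self.similarity = np.asarray(self.similarity, dtype=float)
        if np.any((self.similarity < 0) | (self.similarity > 100)):
            raise ConfigurationError("similarities must lie in [0, 100]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"event": np.arange(len(self.similarity)), "similarity": self.similarity})


def vreye_similarity(
    coords: EmbeddingResult | np.ndarray,
    table: EventTable,
    search: MEMLabel,
    reference: MEMReference,
    k: int = 60,
    include_self: bool = True,
) -> SimilarityMap:
    """Score every cell's k-neighborhood MEM label against a search label.

    The neighborhood of size k includes the index cell itself by default
    (a cell plus its k-1 nearest surround); neighborhood labels are scaled
    with the search label's own scaling constant so RMSD compares like
    with like.
    """
    xy = coords.coords if isinstance(coords, EmbeddingResult) else np.asarray(coords, dtype=float)
    n = len(xy)
    if table.n_events != n:
        raise ConfigurationError(f"coords ({n}) and events ({table.n_events}) are misaligned")
    if k <= 0:
        raise ConfigurationError("k must be positive")
    if k >= n:
        raise ConfigurationError(f"k={k} must be below the number of cells ({n})")
    if table.scale != "arcsinh":
        raise SarmapError("vreye expects arcsinh-scaled markers")
    markers = list(search.markers)
    X = table.values(markers)

    nn = NearestNeighbors(n_neighbors=k if include_self else k + 1).fit(xy)
    sims = np.empty(n)
    for start in range(0, n, _CHUNK):
        stop = min(start + _CHUNK, n)
        _, idx = nn.kneighbors(xy[start:stop])
        if not include_self:
            rows = np.arange(start, stop)[:, None]
            keep = idx != rows
            idx = np.stack([idx[i][keep[i]][:k] for i in range(len(idx))])
        hood = X[idx]  # (chunk, k, markers)
        mag = np.median(hood, axis=1)
        q25, q75 = np.quantile(hood, [0.25, 0.75], axis=1)
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # per-neighborhood IQR caps are routine
            raw = raw_mem_scores(mag, q75 - q25, reference)
        scores, _ = scale_scores(raw, search.scale_max)
        rmsd = np.sqrt(np.mean((scores - search.scores[None, :]) ** 2, axis=1))
        sims[start:stop] = np.clip(100.0 * (1.0 - rmsd / 10.0), 0.0, 100.0)
    return SimilarityMap(similarity=sims, k=k, search_label=search, include_self=include_self)


def fraction_similar(
    simmap: SimilarityMap,
    conditions: Sequence,
    threshold_percent: float = 75.0,
) -> pd.Series:
    """Per-condition percent of cells with similarity above the threshold.

    ``conditions`` gives one group key per cell (e.g. the dose). Every
    condition must contain at least one cell.
    """
    if not 0.0 < threshold_percent < 100.0:
        raise ConfigurationError("threshold must be in (0, 100)")
    conditions = np.asarray(conditions)
    if len(conditions) != len(simmap.similarity):
        raise ConfigurationError("one condition per cell required")
    out = {}
    for cond in pd.unique(conditions):
        mask = conditions == cond
        if not mask.any():
            raise SarmapError(f"condition {cond!r} has no cells")
        out[cond] = 100.0 * np.mean(simmap.similarity[mask] > threshold_percent)
    return pd.Series(out).sort_index()


# ---------------------------------------------------------------------------
# four-parameter log-logistic fit
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseFit:
    """LL4 fit: f(x) = c + (d - c) / (1 + (x / e)^b), all four free.

    ``p_value`` is a Wald test of the amplitude d - c against 0 (no dose
    dependence); ``se_log_ec50`` is the Wald standard error of log(e).
    Canonical form has c <= d (the (b, c, d) -> (-b, d, c) reflection
    leaves the curve unchanged).
    """

    hill: float
    minimum: float
    maximum: float
    ec50: float
    residual_ss: float
    p_value: float
    se: dict = field(default_factory=dict)
    se_log_ec50: float = float("nan")
    converged: bool = True
    doses: np.ndarray | None = None
    responses: np.ndarray | None = None

    def predict(self, x) -> np.ndarray:
        return _ll4(np.asarray(x, dtype=float), self.hill, self.minimum, self.maximum, np.log(self.ec50))

    def to_dict(self) -> dict:
        return {
            "hill": self.hill,
            "minimum": self.minimum,
            "maximum": self.maximum,
            "ec50": self.ec50,
            "residual_ss": self.residual_ss,
            "p_value": self.p_value,
            "se": self.se,
            "se_log_ec50": self.se_log_ec50,
            "converged": self.converged,
            "p_value_test": "Wald on amplitude (d - c); H0: no dose dependence",
        }


def _ll4(x: np.ndarray, b: float, c: float, d: float, log_e: float) -> np.ndarray:
    """LL4 on the natural-log dose axis, with the exact x = 0 limit."""
    out = np.empty_like(x, dtype=float)
    zero = x == 0
    with np.errstate(over="ignore"):
        eta = np.exp(np.clip(b * (np.log(x[~zero]) - log_e), -500, 500))
    out[~zero] = c + (d - c) / (1.0 + eta)
    if b > 0:
        out[zero] = d
    elif b < 0:
        out[zero] = c
    else:
        out[zero] = (c + d) / 2.0
    return out


def fit_ll4(
    doses,
    responses,
    weights=None,
) -> DoseResponseFit:
    """Least-squares four-parameter log-logistic fit.

    Multi-start optimization (EC50 initialized at each nonzero dose, hill
    slopes +-0.5, +-1, +-2, min/max from the response extremes in both
    orders) with a fixed start ordering makes the fit deterministic; the
    best residual sum of squares wins. Non-convergence from every start
    raises :class:`FitConvergenceError` with diagnostics.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ConfigurationError("doses and responses must align")
    if np.any(x < 0):
        raise SarmapError("negative doses")
    if not np.all(np.isfinite(y)):
        raise SarmapError("responses must be finite")
    if len(np.unique(x)) < 5:
        raise SarmapError("need at least 5 dose levels")
    if not np.any(x > 0):
        raise SarmapError("need at least one nonzero dose")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

    def residuals(theta):
        b, c, d, log_e = theta
        return np.sqrt(w) * (_ll4(x, b, c, d, log_e) - y)

    lo, hi = float(y.min()), float(y.max())
    starts = []
    for e0 in sorted(np.unique(x[x > 0])):
        for b0 in (0.5, -0.5, 1.0, -1.0, 2.0, -2.0):
            for c0, d0 in ((lo, hi), (hi, lo)):
                starts.append((b0, c0, d0, np.log(e0)))

    best, best_ss, failures = None, np.inf, []
    for theta0 in starts:
        try:
            sol = optimize.least_squares(residuals, theta0, method="lm", max_nfev=2000)
        except Exception as err:  # pragma: no cover - lm rarely raises
            failures.append((theta0, str(err)))
            continue
        if not sol.success or not np.all(np.isfinite(sol.x)):
            failures.append((theta0, sol.message))
            continue
        ss = float(2.0 * sol.cost)
        if ss < best_ss - 1e-12:
            best, best_ss = sol, ss
    if best is None:
        raise FitConvergenceError("LL4 fit did not converge from any start", diagnostics=failures)

    b, c, d, log_e = (float(v) for v in best.x)
    n, p = len(y), 4
    dof = max(n - p, 1)
    s2 = best_ss / dof
    J = best.jac
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    se = {k: float(np.sqrt(max(cov[i, i], 0.0))) if np.isfinite(cov[i, i]) else float("nan")
          for i, k in enumerate(("hill", "minimum", "maximum", "log_ec50"))}
    if c > d:  # canonicalize the (b, c, d) -> (-b, d, c) reflection symmetry
        b, c, d = -b, d, c
        se["minimum"], se["maximum"] = se["maximum"], se["minimum"]
    # Wald test of amplitude d - c = 0 (gradient [0, -1, 1, 0])
    var_amp = cov[2, 2] + cov[1, 1] - 2.0 * cov[1, 2]
    if np.isfinite(var_amp) and var_amp > 0:
        t_stat = (d - c) / np.sqrt(var_amp)
        p_value = float(2.0 * stats.t.sf(abs(t_stat), dof))
    else:
        p_value = float("nan")

    return DoseResponseFit(
        hill=b,
        minimum=c,
        maximum=d,
        ec50=float(np.exp(log_e)),
        residual_ss=best_ss,
        p_value=p_value,
        se=se,
        se_log_ec50=se["log_ec50"],
        converged=True,
        doses=x,
        responses=y,
    )


def dose_response(
    simmap: SimilarityMap,
    doses: Sequence[float],
    threshold_percent: float = 75.0,
) -> DoseResponseFit:
    """Convenience wrapper: per-dose fraction of label-similar cells, then
    the LL4 fit."""
    responses = fraction_similar(simmap, doses, threshold_percent)
    return fit_ll4(responses.index.to_numpy(dtype=float), responses.to_numpy())


__all__ = [
    "DoseResponseFit",
    "SimilarityMap",
    "dose_response",
    "fit_ll4",
    "fraction_similar",
    "vreye_similarity",
]
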