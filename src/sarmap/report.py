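"""Compound-level structure-activity synthesis and pipeline orchestration.

Assembles the compounds-by-markers fold-change matrix, clusters it
(complete linkage, Euclidean distances), computes subclass statistics
(consistency IQRs and one-sided Wilcoxon rank-sum tests with a
Hodges-Lehmann location shift), compares matched compound pairs that
differ in a single structural feature, and drives the full synthetic or
file-based pipeline end to end with a reproducibility manifest.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy import stats

from . import __version__ as _pkg_version
from .bioactivity import FoldChangeMatrix, bioactivity_threshold, classify_bioactive, mfi_fold_change
from .exceptions import ConfigurationError, SarmapError
from .io import (
    ROLE_VEHICLE,
    EventTable,
    PanelConfig,
    PlateLayout,
    concat_tables,
    default_qc_rules,
    iqr,
    qc_gate,
    split_by_well,
    arcsinh_scale,
)
from .mem import build_null_reference, mem_label
from .trex import EmbedParams, embed, equal_sample, trex_compare


# ---------------------------------------------------------------------------
# fold-change matrix
# ---------------------------------------------------------------------------

def fold_change_matrix(
    wells: Mapping[str, EventTable],
    layout: PlateLayout,
    panel: PanelConfig,
    vehicle_mode: str = "pooled",
) -> FoldChangeMatrix:
    """Compounds x markers arcsinh fold-change matrix versus vehicle.

    ``vehicle_mode="pooled"`` pools every vehicle well into one reference;
    ``"vehicle1"`` uses the first vehicle well alone. Vehicle wells also
    appear as rows (each against the common reference), so a pooled-mode
    vehicle row is near zero and a vehicle1-mode Vehicle-1 row is exactly
    zero.
    """
    vehicle_wells = layout.wells(ROLE_VEHICLE)
    missing = [w for w in vehicle_wells if w not in wells]
    if len(missing) == len(vehicle_wells):
        raise SarmapError("no vehicle well present in the event data")
    vehicle_wells = [w for w in vehicle_wells if w in wells]
    if vehicle_mode == "pooled":
        reference = concat_tables([wells[w] for w in vehicle_wells])
    elif vehicle_mode == "vehicle1":
        reference = wells[vehicle_wells[0]]
    else:
        raise ConfigurationError(f"unknown vehicle_mode {vehicle_mode!r}")

    rows: dict[str, dict] = {}
    cofactors = {m.name: m.cofactor for m in panel.markers}
    for well, table in wells.items():
        info = layout.row(well)
        compound = str(info["compound"])
        values = {
            m.name: mfi_fold_change(table, reference, m.channel, m.cofactor)
            for m in panel.markers
        }
        if compound in rows:  # replicate wells: pool by averaging
            prev = rows[compound]
            rows[compound] = {k: (prev[k] + values[k]) / 2.0 for k in values}
        else:
            rows[compound] = values
    matrix = pd.DataFrame.from_dict(rows, orient="index")[panel.marker_names]
    return FoldChangeMatrix(matrix, vehicle_reference=vehicle_mode, cofactors=cofactors)


def count_ratios(wells: Mapping[str, EventTable], layout: PlateLayout, vehicle_mode: str = "vehicle1") -> pd.Series:
    """Per-compound cell-count ratio versus the vehicle reference."""
    vehicle_wells = [w for w in layout.wells(ROLE_VEHICLE) if w in wells]
    if not vehicle_wells:
        raise SarmapError("no vehicle well present in the event data")
    if vehicle_mode == "pooled":
        ref_count = float(np.mean([wells[w].n_events for w in vehicle_wells]))
    else:
        ref_count = wells[vehicle_wells[0]].n_events
    out = {}
    for well, table in wells.items():
        compound = str(layout.row(well)["compound"])
        out[compound] = table.n_events / ref_count
    return pd.Series(out)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    linkage: np.ndarray
    assignments: pd.Series  # compound -> cluster id (1..k)
    leaf_order: list[str]
    k: int

    def cluster_members(self) -> dict[int, list[str]]:
        return {int(c): sorted(idx) for c, idx in self.assignments.groupby(self.assignments).groups.items()}


def hierarchical_cluster(matrix: FoldChangeMatrix, k: int = 5, metric: str = "euclidean") -> ClusterResult:
    """Complete-linkage agglomerative clustering of the fold-change matrix.

    Compounds are sorted lexicographically before linkage so the
    dendrogram is invariant to input order (distance ties resolve by
    compound id). The default cut keeps the top ``k=5`` clusters.
    """
    values = matrix.values.sort_index()
    n = len(values)
    if n < 2:
        if k == 1 and n == 1:
            only = values.index[0]
            return ClusterResult(np.empty((0, 4)), pd.Series({only: 1}), [only], 1)
        raise SarmapError("need at least 2 compounds to cluster")
    if k > n:
        raise SarmapError(f"k={k} exceeds the number of compounds ({n})")
    dist = pdist(values.to_numpy(dtype=float), metric=metric)
    Z = hierarchy.linkage(dist, method="complete")
    # cut_tree guarantees exactly k clusters even with tied merge heights
    flat = hierarchy.cut_tree(Z, n_clusters=k).ravel() + 1
    order = hierarchy.leaves_list(Z)
    return ClusterResult(
        linkage=Z,
        assignments=pd.Series(flat, index=values.index),
        leaf_order=[values.index[i] for i in order],
        k=k,
    )


# ---------------------------------------------------------------------------
# subclass statistics
# ---------------------------------------------------------------------------

@dataclass
class SubclassStats:
    """One-sided Wilcoxon rank-sum comparison of a target subclass against
    the remaining compounds, with a Hodges-Lehmann location shift."""

    target: str
    p_value: float
    location_shift: float
    significant: bool
    alpha: float = 0.05
    n_target: int = 0
    n_rest: int = 0
    median_iqr: float | None = None

    def __post_init__(self):
        if not 0.0 < self.p_value <= 1.0:
            raise SarmapError("p-value outside (0, 1]")
        if self.significant != (self.p_value < self.alpha):
            raise SarmapError("significance flag inconsistent with p-value")


def hodges_lehmann_shift(x, y) -> float:
    """Median of all pairwise differences x_i - y_j (the rank-sum
    location-shift estimate)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.median(x[:, None] - y[None, :]))


def subclass_stats(
    values: pd.Series,
    subclasses: pd.Series,
    target_subclass: str,
    alternative: str = "greater",
    alpha: float = 0.05,
    matrix: FoldChangeMatrix | None = None,
) -> SubclassStats:
    """Wilcoxon rank-sum (one-sided by default) of a per-compound metric
    for the target subclass vs the rest.

    Uses the exact null distribution when both sides are small and
    tie-free, else the normal approximation. When the fold-change
    ``matrix`` is supplied, the subclass consistency metric (median
    across markers of the within-subclass IQR) is attached.
    """
    values, subclasses = values.align(subclasses, join="inner")
    in_target = subclasses == target_subclass
    x = values[in_target].to_numpy(dtype=float)
    y = values[~in_target].to_numpy(dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise SarmapError("need at least 2 compounds on each side")
    method = "exact" if (len(x) + len(y) <= 25 and len(np.unique(np.r_[x, y])) == len(x) + len(y)) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    med_iqr = None
    if matrix is not None:
        med_iqr = subclass_consistency(matrix, subclasses).get(target_subclass)
    p = float(res.pvalue)
    return SubclassStats(
        target=target_subclass,
        p_value=p,
        location_shift=hodges_lehmann_shift(x, y),
        significant=p < alpha,
        alpha=alpha,
        n_target=len(x),
        n_rest=len(y),
        median_iqr=med_iqr,
    )


def subclass_consistency(matrix: FoldChangeMatrix, subclasses: pd.Series) -> pd.Series:
    """Per-subclass consistency: for each marker the IQR of fold changes
    across the subclass's compounds, then the median across markers.
    Lower values mean a more uniform signature within the subclass."""
    out = {}
    for sub, idx in subclasses.groupby(subclasses).groups.items():
        members = [c for c in idx if c in matrix.values.index]
        if len(members) < 2:
            continue
        block = matrix.values.loc[members]
        marker_iqrs = [iqr(block[m].to_numpy()) for m in block.columns]
        out[sub] = float(np.median(marker_iqrs))
    return pd.Series(out)


def wilcoxon_threshold_bounds(x, y, confidence: float = 0.95) -> dict:
    """One-sided lower confidence bounds from the rank-sum comparison of
    two percent-positive samples: on the Hodges-Lehmann shift and on the
    target median. Both constructions are reported because screening
    thresholds have been derived from either; the output labels which is
    which."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    m, n = len(x), len(y)
    mu = m * n / 2.0
    sigma = np.sqrt(m * n * (m + n + 1) / 12.0)
    z = stats.norm.ppf(confidence)
    k = int(np.floor(mu - z * sigma))
    shift_lower = float(diffs[max(k, 0)])
    # one-sample lower bound on the target median via the sign-rank walsh averages
    walsh = np.sort([(a + b) / 2.0 for a, b in itertools.combinations_with_replacement(x, 2)])
    n_w = len(walsh)
    mu_w = m * (m + 1) / 4.0
    sigma_w = np.sqrt(m * (m + 1) * (2 * m + 1) / 24.0)
    k_w = int(np.floor(mu_w - z * sigma_w))
    median_lower = float(walsh[max(k_w, 0)]) if n_w else float("nan")
    return {
        "hodges_lehmann_shift_lower": shift_lower,
        "target_median_lower": median_lower,
        "confidence": confidence,
    }


# ---------------------------------------------------------------------------
# paired-compound signature comparison
# ---------------------------------------------------------------------------

@dataclass
class SignatureComparison:
    """Per-marker comparison of two compounds matched in all metadata but
    one structural flag."""

    compound_a: str
    compound_b: str
    table: pd.DataFrame  # marker, delta_arcsinh, fold_difference
    differing_flag: str | None = None


def validate_pair(layout: PlateLayout, compound_a: str, compound_b: str) -> str:
    """The pair must differ in exactly one structural-feature flag."""
    rows = {c: layout.table[layout.table["compound"] == c] for c in (compound_a, compound_b)}
    for c, r in rows.items():
        if r.empty:
            raise ConfigurationError(f"compound {c!r} not in layout")
    a, b = rows[compound_a].iloc[0], rows[compound_b].iloc[0]
    flags = layout.feature_flags
    if not flags:
        raise ConfigurationError("layout has no structural-feature flags")
    differing = [f for f in flags if a[f] != b[f]]
    if len(differing) != 1:
        raise ConfigurationError(
            f"{compound_a} and {compound_b} differ in {len(differing)} flags ({differing}); need exactly 1"
        )
    return differing[0]


def signature_pair_compare(
    a: EventTable,
    b: EventTable,
    panel: PanelConfig,
    markers: Sequence[str] | None = None,
    compound_a: str = "A",
    compound_b: str = "B",
    layout: PlateLayout | None = None,
) -> SignatureComparison:
    """Per-marker arcsinh-median differences and raw-median fold
    differences between a matched compound pair.

    Both tables must be raw-scale so the fold difference of raw medians
    is meaningful; pass the layout to enforce the single-differing-flag
    pairing rule.
    """
    if a.scale != "raw" or b.scale != "raw":
        raise SarmapError("pair comparison expects raw-scale tables")
    differing = validate_pair(layout, compound_a, compound_b) if layout is not None else None
    markers = list(markers) if markers is not None else panel.marker_names
    rows = []
    for m in panel.markers:
        if m.name not in markers:
            continue
        med_a = float(np.median(a.values(m.channel)))
        med_b = float(np.median(b.values(m.channel)))
        if med_b == 0:
            raise SarmapError(f"zero median for {m.name} in {compound_b}")
        rows.append(
            {
                "marker": m.name,
                "delta_arcsinh": float(np.arcsinh(med_a / m.cofactor) - np.arcsinh(med_b / m.cofactor)),
                "fold_difference": med_a / med_b,
            }
        )
    return SignatureComparison(compound_a, compound_b, pd.DataFrame(rows), differing)


def signature_histograms(
    tables: Mapping[str, EventTable],
    panel: PanelConfig,
    markers: Sequence[str],
    path,
    bins: int = 64,
) -> None:
    """Histogram overlays of arcsinh-scaled marker intensities, each
    annotated with the arcsinh ratio of the well median to the per-marker
    minimum median across the overlaid wells."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    markers = list(markers)
    fig, axes = plt.subplots(1, len(markers), figsize=(4 * len(markers), 3), squeeze=False)
    for j, marker in enumerate(markers):
        cofactor = panel.cofactor(marker)
        ax = axes[0][j]
        medians = {name: float(np.median(t.values(marker))) for name, t in tables.items()}
        floor = min(medians.values())
        for name, t in tables.items():
            y = np.arcsinh(t.values(marker) / cofactor)
            scale_note = np.arcsinh(medians[name] / cofactor) - np.arcsinh(floor / cofactor)
            ax.hist(y, bins=bins, histtype="step", density=True, label=f"{name} (+{scale_note:.2f})")
        ax.set_title(marker)
        ax.set_xlabel("arcsinh intensity")
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

class StageFailure(SarmapError):
    def __init__(self, stage: str, err: Exception, manifest_path):
        self.stage = stage
        self.manifest_path = manifest_path
        super().__init__(f"pipeline stage {stage!r} failed: {err}")


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Run the synthetic (or file-based) screen end to end.

    Stages: simulate/ingest -> QC -> debarcode/annotate -> arcsinh ->
    fold-change matrix + bioactivity + count ratios -> equal sampling ->
    embedding -> hotspot comparison per subclass -> island MEM label ->
    clustering. Every tabular intermediate plus a manifest (version, seed,
    parameters) is written to ``outdir``; a stage failure halts with the
    stage name after persisting the partial manifest.
    """
    from . import synthetic

    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    outdir = Path(outdir or config.get("outdir", "sarmap_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "sarmap_version": _pkg_version,
        "seed": seed,
        "parameters": {k: v for k, v in config.items() if k not in ("design",)},
        "stages": [],
    }
    manifest_path = outdir / "manifest.yaml"

    def checkpoint(stage: str):
        manifest["stages"].append(stage)
        with open(manifest_path, "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)

    results: dict = {"outdir": outdir}
    stage = "configure"
    try:
        if "design" in config:
            stage = "simulate"
            design, effects = _design_from_config(config["design"])
            table, truth = synthetic.simulate_plate(design, effects, seed=seed)
            truth.events.to_csv(outdir / "ground_truth.csv", index=False)
            panel = design.panel()
            layout = design.layout()
        else:
            stage = "ingest"
            from .io import read_events

            panel = PanelConfig.from_yaml(config["panel"])
            layout = PlateLayout.from_csv(config["layout"])
            table = read_events(config["events"], panel)
            truth = None
        layout.to_csv(outdir / "layout.csv")
        checkpoint(stage)

        use_debarcode = bool(config.get("debarcode", True)) or truth is None
        if truth is not None and not use_debarcode:
            # bypass the mixture model: carry the generator's true wells
            table = synthetic.annotate_from_truth(table, truth)

        stage = "qc"
        rules = default_qc_rules()
        gated, qc_report = qc_gate(table, rules)
        qc_report.table.to_csv(outdir / "qc_report.csv", index=False)
        checkpoint(stage)

        stage = "debarcode"
        if use_debarcode:
            from .io import BarcodeScheme, debarcode as _debarcode

            scheme = design.barcode_scheme if truth is not None else BarcodeScheme()
            kept, db_report = _debarcode(gated, scheme)
            db_report.table.to_csv(outdir / "debarcode_report.csv", index=False)
            manifest["unassigned_fraction"] = db_report.unassigned_fraction
        else:
            kept = gated
        # restrict to designed wells and attach compound/subclass metadata
        in_layout = kept.data["well"].isin(set(layout.wells())).to_numpy()
        kept = kept.subset(in_layout)
        compound_of = {str(r["well"]): str(r["compound"]) for _, r in layout.table.iterrows()}
        subclass_of_well = {str(r["well"]): str(r["subclass"]) for _, r in layout.table.iterrows()}
        kept = kept.with_annotation("compound", kept.data["well"].map(compound_of).to_numpy())
        kept = kept.with_annotation("subclass", kept.data["well"].map(subclass_of_well).to_numpy())
        checkpoint(stage)

        stage = "arcsinh"
        scaled = arcsinh_scale(kept, panel)
        checkpoint(stage)

        stage = "bioactivity"
        wells = split_by_well(scaled)
        matrix = fold_change_matrix(wells, layout, panel, config.get("vehicle_mode", "pooled"))
        matrix.to_csv(outdir / "fold_change_matrix.csv")
        vehicle_compounds = {str(layout.row(w)["compound"]) for w in layout.wells(ROLE_VEHICLE)}
        vehicle_rows = matrix.values.loc[[c for c in matrix.compounds if c in vehicle_compounds]]
        threshold = bioactivity_threshold(vehicle_rows.to_numpy().ravel())
        flags = classify_bioactive(matrix, threshold)
        flags.rename("bioactive").to_csv(outdir / "bioactivity.csv")
        ratios = count_ratios({w: t for w, t in wells.items() if w in set(layout.wells())}, layout)
        ratios.rename("count_ratio").to_csv(outdir / "count_ratio.csv")
        results.update(matrix=matrix, threshold=threshold, bioactive=flags, count_ratios=ratios)
        checkpoint(stage)

        stage = "embedding"
        groups: dict[str, EventTable] = {}
        cond = scaled.data["subclass"].where(lambda s: s != "", scaled.data["compound"])
        by_subclass = scaled.with_annotation("group", cond.to_numpy())
        for label, grp in by_subclass.data.groupby("group", sort=True):
            groups[str(label)] = EventTable(grp.reset_index(drop=True), scaled.channels, scaled.scale)
        n_per = int(config.get("n_per_group", 2000))
        pooled = equal_sample(groups, n_per, seed=seed, strict=False)
        params = EmbedParams(
            perplexity=float(config.get("perplexity", 60)),
            iterations=int(config.get("tsne_iterations", 1000)),
            seed=seed,
        )
        embedding = embed(pooled, panel.marker_names, params)
        embedding.to_csv(outdir / "embedding.csv")
        results["embedding"] = embedding
        checkpoint(stage)

        stage = "trex"
        vehicle_label = config.get("vehicle_group", "vehicle")
        trex_rows = []
        hotspots = {}
        for label in groups:
            if label == vehicle_label:
                continue
            pair = equal_sample(
                {label: groups[label], vehicle_label: groups[vehicle_label]},
                n_per,
                seed=seed,
                strict=False,
            )
            pair_embedding = embed(pair, panel.marker_names, params)
            res = trex_compare(pair_embedding, label, vehicle_label, k=int(config.get("k", 60)))
            trex_rows.append(
                {"group": label, "degree_of_difference": res.degree_of_difference, "red": res.n_red, "blue": res.n_blue}
            )
            hotspots[label] = (pair, pair_embedding, res)
        trex_table = pd.DataFrame(trex_rows)
        trex_table.to_csv(outdir / "trex_degree_of_difference.csv", index=False)
        results["trex"] = trex_table
        checkpoint(stage)

        stage = "mem"
        reference = build_null_reference(scaled, panel.marker_names)
        island_labels = {}
        for label, (pair, pair_embedding, res) in hotspots.items():
            red = res.bins == "red"
            if red.sum() >= 20:
                island = pair.subset(red)
                lbl = mem_label(island, reference, panel.marker_names)
                lbl.to_yaml(outdir / f"mem_label_{label}.yaml")
                island_labels[label] = lbl
        results["mem_labels"] = island_labels
        checkpoint(stage)

        stage = "cluster"
        test_rows = [c for c in matrix.compounds if c not in vehicle_compounds]
        k = min(int(config.get("clusters", 5)), max(len(test_rows), 1))
        cluster = hierarchical_cluster(
            FoldChangeMatrix(matrix.values.loc[test_rows], matrix.vehicle_reference, matrix.cofactors), k=k
        )
        cluster.assignments.rename("cluster").to_csv(outdir / "clusters.csv")
        results["clusters"] = cluster
        checkpoint(stage)
    except Exception as err:
        manifest["failed_stage"] = stage
        with open(manifest_path, "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        raise StageFailure(stage, err, manifest_path) from err

    return results


def _design_from_config(design_spec):
    from . import synthetic

    if isinstance(design_spec, (str, Path)):
        return synthetic.load_design(design_spec)
    if isinstance(design_spec, tuple):
        return design_spec
    raise ConfigurationError("design must be a YAML path or (PlateDesign, effects) tuple")


def demo_config(outdir: str | Path = "sarmap_demo", seed: int = 7) -> dict:
    """Packaged demonstration: a synthetic 48-well plate with three
    compound subclasses, one of which plants a responder island."""
    from . import synthetic
    from .io import ROLE_TEST, ROLE_VEHICLE

    markers = synthetic.default_markers()
    wells = [
        synthetic.WellSpec("A1", ROLE_VEHICLE, "vehicle-1", subclass="vehicle"),
        synthetic.WellSpec("A2", ROLE_VEHICLE, "vehicle-2", subclass="vehicle"),
        synthetic.WellSpec("A3", ROLE_VEHICLE, "vehicle-3", subclass="vehicle"),
    ]
    effects = []
    rng = np.random.default_rng(seed)
    grid = iter([f"{r}{c}" for r in "BCDEFGH" for c in range(1, 7)])
    for i in range(4):  # island-forming subclass
        cid = f"RP-{i + 1:02d}"
        wells.append(synthetic.WellSpec(next(grid), ROLE_TEST, cid, subclass="RP"))
        effects.append(
            synthetic.CompoundEffect(
                cid,
                effect_vector={"gH2AX": 2.5, "p-ERK1/2": 0.6},
                responder_fraction=0.25,
                responder_signature=synthetic.default_responder_signature(),
            )
        )
    for i in range(4):
        cid = f"RR-{i + 1:02d}"
        wells.append(synthetic.WellSpec(next(grid), ROLE_TEST, cid, subclass="RR"))
        effects.append(synthetic.CompoundEffect(cid, effect_vector={"p-S6 S240/244": 1.8, "p-STAT5": 1.5}))
    for i in range(4):
        cid = f"ADR-{i + 1:02d}"
        wells.append(synthetic.WellSpec(next(grid), ROLE_TEST, cid, subclass="ADR"))
        effects.append(
            synthetic.CompoundEffect(
                cid, effect_vector={"gH2AX": 0.5, "p-AKT": 1.8, "p-STAT5": 1.6}, kill_fraction=0.4
            )
        )
    design = synthetic.PlateDesign(wells=wells, markers=markers, cells_per_well=1500, seed=seed)
    return {
        "design": (design, effects),
        "seed": seed,
        "outdir": str(outdir),
        "debarcode": True,
        "n_per_group": 1200,
        "perplexity": 30,
        "tsne_iterations": 500,
        "vehicle_group": "vehicle",
    }


__all__ = [
    "ClusterResult",
    "SignatureComparison",
    "StageFailure",
    "SubclassStats",
    "count_ratios",
    "demo_config",
    "fold_change_matrix",
    "hierarchical_cluster",
    "hodges_lehmann_shift",
    "run_pipeline",
    "signature_histograms",
    "signature_pair_compare",
    "subclass_consistency",
    "subclass_stats",
    "validate_pair",
    "wilcoxon_threshold_bounds",
]
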