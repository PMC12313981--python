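# Methods

This note documents the models, conventions, and numerical choices behind
`sarmap`, and what the synthetic-data tests do and do not demonstrate
about real cytometry data.

## Scales and conventions

All marker intensities are transformed per marker as
`y = asinh(x / cofactor)`. The cofactor sets the linear-to-log
transition; defaults follow common screening practice (6000 for most
fluorescence channels, 12000 for the brighter phospho-epitopes, 25000
for Ki67 and p-STAT5, and 150 for the compact four-marker panel).
Channel names are matched case-insensitively with punctuation stripped,
so `p-S6 S240/244` and `pS6_S240_244` resolve to the same channel.

Every quantile in the package (medians, IQRs, percentile gates) uses
linear interpolation between order statistics. This is stated once and
used everywhere so that IQR-based thresholds are bit-reproducible.

The **arcsinh fold change** of a marker is the difference of
arcsinh-transformed medians, `asinh(MFI_t/cf) − asinh(MFI_v/cf)`, so that
equal medians map to exactly 0. The literal `asinh(MFI_t/MFI_v)` variant
(which maps a ratio of 1 to `asinh(1) ≈ 0.88`, not 0) is available via
`convention="ratio"` for comparison, but the difference form is the
default because a zero-centred "no change" point is what the downstream
threshold rule assumes. Since the median commutes with monotone
transforms, already-scaled tables give the same answer via a plain
median difference.

## Synthetic plate generator

The generator is the package's study-condition definition: it produces
data with exactly the statistical structure the analysis stack assumes,
plus a ground-truth row per event so each stage can be scored.

- **Marker model.** Raw intensities are lognormal,
  `x = location · exp(scale · z)`, so the raw median is `location` and a
  multiplicative compound effect shifts it exactly. Default
  `location = 3 × cofactor` (stained populations sit a few-fold above
  the cofactor, arcsinh ≈ 1.8) and `scale = 0.6`. The brightness
  convention matters: it gives enrichment magnitudes a realistic dynamic
  range so that the 0…+10 label scale is dominated by magnitude rather
  than IQR-ratio noise.
- **Compound effects.** `effect_vector` multiplies raw medians of every
  surviving cell; `kill_fraction` thins the well before acquisition
  (cell count as a killing readout); `responder_fraction` of surviving
  cells instead express `responder_signature`, an *alternative* phenotype
  relative to baseline (it does not stack on the bulk effect). The
  default responder signature is a DNA-damage-plus-retained-mTOR island:
  gH2AX ×25 (tens-fold raw shifts are typical of potent double-strand
  break inducers), p-4EBP1 ×12, both p-S6 epitopes ×8, with RTK/JAK-STAT
  and proliferation readouts at ×0.4 as expected of damage-arrested
  cells. The default bulk effect is translation-inhibitor-like
  (mTOR/translation outputs suppressed).
- **QC material.** Debris = all channels scaled to 5% (low scatter, dim
  everything); doublets = channel-wise sums of two cells with
  height = max of the two heights (so the area/height ratio roughly
  doubles); dead = bright viability stain. Cell counts per well are
  Poisson around the design mean (a `fixed` mode exists for exact-count
  designs); no published dispersion estimate was available, so Poisson
  is a stand-in.
- **Barcodes.** Two gradient dyes (8 levels × 6 levels, level means
  decreasing by the serial-dilution ratio 1.71) plus one internal-control
  dye; dye intensities are mean-preserving lognormal at a configurable
  CV (default 0.15).
- **Dose ladders.** One condition per dose on the eight-point ladder
  0, 0.01, 0.05, 0.1, 0.5, 1, 5, 10 µM; the responder fraction follows
  `floor + (ceiling − floor) · x^h / (x^h + EC50^h)` with defaults
  floor 0.02, ceiling 0.85, hill 1, EC50 0.5 µM. Dose ladders are
  acquired one tube per compound and deconvoluted by annotation, so no
  two-dye barcode is drawn there.
- **Reproducibility.** One integer seed; per-well substreams are derived
  from `(seed, grid index)`, so adding wells never perturbs existing
  wells and identical inputs reproduce identical tables bit-for-bit.

What the generator does *not* emulate: spectral spillover/compensation,
acquisition-time drift, correlated marker noise, autofluorescence, or
continuous (non-mixture) phenotype gradients. Passing tests on this data
demonstrates the correctness and calibration of the algorithms under the
stated model, not their robustness to those instrument effects.

## QC gating

Gates run in a declared order (intact → single → live), each pass-set a
subset of its input. Defaults: the intact gate keeps events with FSC-A
above 0.25 × median FSC-A (the median is robust to a sizeable low-scatter
debris mode, which a pure percentile box cannot remove) and below the
99.9th percentile on both scatter channels; the singlet gate keeps
area/height < 1.5 when a height channel exists and is skipped otherwise;
the live gate keeps viability below a vehicle-derived 99th percentile
when a reference is supplied, else below a two-component mixture cut.

## Debarcoding

A deliberately simple per-dye model: each barcode dye's arcsinh-scaled
intensity is fit with a 1-D Gaussian mixture (components initialized at
the expected level means and matched to levels by mean rank); an event is
assigned the (row level, column level) pair maximizing the product of
per-dye posteriors, and is left unassigned when that product falls below
the confidence threshold (default 0.9). Accuracy on synthetic ground
truth — not equivalence to any published debarcoding model — is the
design goal; at the default grid and CV 0.15 the assignments are ≥ 95%
accurate at ~60–65% yield, and approach 100%/100% as CV → 0.

## Embedding and difference hotspots

Default t-SNE settings are perplexity 60, 10,000 iterations, early
exaggeration 12, automatic learning rate, PCA initialization, Barnes–Hut
gradients. The backend is pluggable behind `EmbedParams`; any t-SNE
honoring those parameters qualifies, and all downstream statistics are
computed from stored 2-D coordinates so a run is reproducible from the
coordinate file alone. Tests and the acceptance script run 300–1,000
iterations at up to 12,000 cells — a deliberate problem-size choice: the
statistics being checked (hotspot nulls, cluster separations) are flat in
iteration count long before 10,000.

The hotspot comparison takes two equally represented conditions
(enforced by `equal_sample`, which samples without replacement under a
per-label substream), finds each cell's k = 60 nearest Euclidean
neighbors in the embedding (self excluded; ties at the k-th neighbor
broken by event index), and bins cells whose neighbor fraction reaches
the 95% cutoff. The degree of difference is the percent of binned cells.
Neighbor search runs in the 2-D embedding; brute-force all-pairs
distances serve as the oracle in tests.

## Enrichment labels

The null reference has magnitude 0 for every marker and one shared IQR:
the median over markers of each marker's full-dataset IQR (zero-IQR
markers are replaced by the smallest positive marker IQR, with a
warning). Per population and marker,

    raw = MAG + (IQR_ref / IQR_pop − 1),   raw = 0 when MAG = 0,

where MAG is the arcsinh-scale median. A zero population IQR with
nonzero magnitude caps the IQR contribution at 10 rather than diverging.
Raw scores are floored at 0 (absolute labels; a signed mode exists
behind a flag) and scaled linearly so the analysis-run maximum raw score
maps to +10; the scaling constant is stored on every label and recorded
in serialized output, since a label is only interpretable together with
its normalizer. Label similarity is
`100 × (1 − rmsd/10)` clipped to [0, 100]; the divisor 10 is pinned by
the bounded score range.

## Neighborhood similarity search

Every cell's neighborhood (k = 60, the cell plus its 59 nearest
embedding neighbors; a self-excluded mode is configurable) gets a MEM
label against the null reference, scaled with the *search label's*
normalizer so RMSD compares like with like, then scored for similarity.
Cells above 75% similarity are counted per condition as the
dose-response variable. Two systematic effects are worth knowing:
embedding neighborhoods are phenotypically tighter than whole
populations, so the IQR term adds a roughly common-mode positive offset
to neighborhood labels; and that offset cancels in RMSD only to the
extent that the search label differs from the background in both
directions. Search phenotypes that differ from the background on several
markers are therefore classified much more cleanly than
single-marker phenotypes — a property of the label geometry, not of this
implementation.

## Dose-response fitting

The four-parameter log-logistic
`f(x) = c + (d − c)/(1 + (x/e)^b)` is fit by least squares on the
percent scale (binomial-variance weighting available by config), with
the dose entering through `log x` internally and zero-dose points
entering as the model's own x → 0 limit (`c` for an increasing curve,
b < 0) rather than on the log axis. Multi-start optimization —
EC50 initialized at each nonzero dose, b ∈ {±0.5, ±1, ±2}, (c, d) from
the response extremes in both orders, fixed ordering, best residual sum
of squares wins — makes the fit deterministic; total failure raises a
structured error with per-start diagnostics rather than extrapolating.
The family has an exact reflection symmetry (b, c, d) → (−b, d, c);
fits are canonicalized to c ≤ d. The reported p-value is a Wald test of
the amplitude `d − c` against 0, i.e. of dose dependence — a Wald
statistic on log(e) alone does not test that null — and the standard
error of log(EC50) is reported alongside. Both choices are recorded in
the fit's serialized metadata.

## SAR reporting

The fold-change matrix is compounds × markers versus either the pooled
vehicles (default; averages out single-well noise) or the first vehicle
well alone — both appear in practice, so both are exposed. Clustering is
agglomerative complete linkage on Euclidean distances (cosine by
config), with compounds sorted lexicographically before linkage so the
dendrogram is input-order invariant, and an exact-k cut (default k = 5)
that is well-defined even under tied merge heights. Subclass comparisons
use the one-sided Wilcoxon rank-sum test (exact when both sides are
small and tie-free, normal approximation otherwise) with the
Hodges–Lehmann median-of-pairwise-differences shift, at α = 0.05; the
within-subclass consistency metric is the median across markers of the
subclass's per-marker fold-change IQR. For percent-positive thresholds
derived from a rank-sum comparison, both one-sided lower confidence
bounds — on the location shift and on the target median — are reported
with labels, because either construction appears in screening practice
and they are not interchangeable.

Matched-pair comparisons require the two compounds to differ in exactly
one structural-feature flag (flags are categorical metadata columns in
the plate layout; no chemical-structure parsing is performed), and
report per-marker arcsinh-median differences plus raw-median fold
differences, with histogram overlays scaled by the arcsinh ratio to the
per-marker minimum median.

`run_pipeline` chains simulate/ingest → QC → debarcode → arcsinh →
bioactivity → embedding → hotspots → island MEM → clustering, writes
every tabular intermediate plus a YAML manifest (package version, seed,
parameters, completed stages), halts on the failing stage by name with
the partial manifest persisted, and reproduces byte-identical tabular
outputs on rerun.

## Known limitations

- The debarcoding model is intentionally simpler than published
  regression-based debarcoders; its yield at high CV is conservative.
- MEM labels depend on their run-wide normalizer; labels from different
  runs are comparable only after rescaling to a common constant.
- EC50 confidence statements are Wald-based only; no profile or
  bootstrap intervals, and no model selection across dose-response
  families.
- t-SNE coordinates are platform-reproducible for a fixed seed but not
  identical across BLAS builds; all statistics can be recomputed from
  persisted coordinates to sidestep this.
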