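# Methods

This note documents the statistical model behind `regulon2t`, the
defaults that matter, the numerical conventions, and what the
synthetic benchmarks do and do not establish.

## Mutual-information regulon inference

**Estimator.** MI between two expression profiles is estimated by a
plug-in (maximum-likelihood) estimate on an equal-frequency 2-D
histogram: each vector is rank-transformed and cut into
`n_bins = floor(sqrt(n_samples / 5))` equal-count bins (≥ 2), and the
joint cell probabilities give MI in nats. The Miller–Madow correction
`(K_x + K_y − K_xy − 1) / (2n)` (K = occupied bins) removes most of the
plug-in's upward bias; the result is clipped at 0. Rank binning makes
the estimate exactly symmetric and exactly invariant under strictly
monotone transforms of either argument, and gives it a cheap
brute-force oracle. With the default bin rule, the estimate tracks the
bivariate-Gaussian closed form −½·ln(1 − r²) to within ±0.05 nats at
n = 5000.

**Permutation test.** The null for an edge shuffles the target's
sample labels, which breaks the pairing while preserving both
marginals. Because rank binning maps any continuous vector to the same
multiset of bin labels, this null depends only on (n_samples, n_bins)
— so one shared null of `n_permutations` draws serves all candidate
edges of a network. The edge threshold is the empirical (1 − α)
quantile taken with the "higher" order statistic, which matches the
calibration of the add-one p-value
`p = (1 + #{null ≥ obs}) / (1 + n_permutations)`; retention is
`MI > threshold`. The realised false-positive rate at α is therefore
Beta-distributed around α across runs (the threshold itself is a
Monte-Carlo estimate); at the reference design this keeps the median
FDR of regulon recovery below 0.1 while sensitivity stays ≈ 1.

**Bootstrap consensus.** Optionally, each candidate edge must show MI
above the same threshold in ≥ `min_support` (default 0.6) of
`n_bootstraps` resamples of samples (with replacement). Resampling
duplicates sample pairs, which inflates resampled MI for edges near
the threshold, so this step guards against instability of strong edges
rather than sharpening the false-positive rate; `n_bootstraps = 0`
skips it (support reported as 1.0).

**DPI filter.** For every triangle (R₁, R₂, t) with both
regulator→target edges present and the R₁–R₂ MI available, the
strictly weakest of the three MIs is removed — if it is a
regulator→target edge — whenever it is below
`(1 − tolerance) × min(other two)`. Removals are marked against the
unfiltered network and applied simultaneously, so the result does not
depend on traversal order. `tolerance = 0` is the most stringent
setting; the pipeline sweeps a tolerance list (default
`[0.2, 0.1, 0.0]`) and carries the most stringent regulon forward.
Regulator–regulator links are context for the test, not removable
edges. Exact ties leave the triangle untouched (no strictly weakest
edge).

**Mode of regulation.** Retained targets are split by the sign of
their Pearson correlation with the regulator; |r| below 1e−12 (an
exactly-zero guard) drops the target with a warning rather than
assigning an arbitrary mode.

## Ranked phenotypes

The phenotype score is the plain log₂ fold change — a difference of
per-condition means on already-log₂ data — with the contrast label
recording the direction (treated minus reference). Ranking is
descending with exact ties broken lexicographically by gene id, so the
ranking is reproducible without a seed. Welch t statistics with
Benjamini–Hochberg adjustment are available as a secondary call;
variance-moderated (empirical-Bayes) statistics are deliberately out
of scope.

## Two-tailed GSEA

For a gene set S in a ranked list L of N genes, the running sum adds
`|score|^w / Σ_hits |score|^w` at hits and subtracts `1/(N − |S∩L|)` at
misses; the enrichment score is the signed extreme of the running sum.
When the positive and negative extremes tie in magnitude (within
1e−12, which happens for rational increments at w = 0), the positive
extreme is taken — a fixed rule shared with the test oracles, since
`argmax` of near-tied floats is not stable. Default weight w = 1
(classic weighted GSEA); w = 0 is kept for the analytic extreme cases
(a set occupying the top k ranks scores ES = +1 up to float
accumulation, the bottom k scores −1).

The two-tailed statistic runs the activated subgroup A and repressed
subgroup B independently and tests dES = ES(A) − ES(B). The null
permutes gene labels — implemented as redrawing |A| and |B| disjoint
hit positions uniformly, vectorised over permutations — rather than
permuting phenotype samples, because stimulation designs have too few
arrays for sample permutation. p is two-sided on |dES| with the
add-one rule (never exactly 0); a one-sided value and a "separation"
flag (ES(A) and ES(B) on opposite sides of 0) are reported alongside.
Under a random regulon the p-values are uniform (checked by
Kolmogorov–Smirnov at 200 runs × 1000 permutations). Alternative
differential statistics (maximum gap, signed average) were considered
and not implemented; dES is the simplest statistic that rewards
opposite-extreme deviation.

Negating every phenotype score reverses the ranking and flips ES(A),
ES(B) and dES exactly up to float accumulation (asserted at 1e−9);
the permutation p is unchanged under the same seed.

## Peak-proximity validation

Distances run from each TSS to the nearest point of the nearest peak
on the same chromosome: 0 inside a peak, sign positive when the peak
lies downstream in the gene's transcription direction, and "none"
beyond a symmetric window (default W = 250 kb, the larger of the two
conventional window sizes). The implementation uses sorted starts with
a cumulative maximum of ends, which is exact for overlapping peaks; on
an exact distance tie the peak with the smaller genomic coordinate
wins (the oracle uses the same rule).

The descriptive density is a Gaussian KDE on a 512-point grid over
[−W, +W], bandwidth by a Silverman-type rule
`0.9 · min(sd, IQR/1.34) · n^(−1/5)` (always recorded), rescaled so the
trapezoidal integral equals the fraction of regulon TSS with a peak in
the window — mass outside the grid is folded back in by the rescaling,
keeping the normalisation invariant exact to 1e−6.

The scalar test statistic is that fraction. Two nulls: *random
regulons* (gene sets of matched size drawn uniformly from the
annotation universe, without replacement) and *random positions* (peak
starts redrawn uniformly per chromosome, preserving each chromosome's
peak count and widths). `p = (1 + #{null ≥ obs}) / (1 + n_null)`. The
fraction is discrete, so exact observed/null ties bias the mean null p
slightly above 0.5; the calibration benchmark therefore uses sizes
(universe 8000, regulon 1000, ~300 background peaks on a 5 × 50 Mb
genome) at which the tie probability is ~2% and the mean p over 200
repeats sits within [0.45, 0.55].

## Synthetic data: what it emulates, and what it does not

The generator plants a single linear-Gaussian regulator: regulator
expression ~ N(0, 1) across samples, target = coupling × regulator +
N(0, noise_sd²), null genes pure noise, everything shifted to a
log₂-intensity-like baseline of 8. Coupling magnitudes are a shifted
half-normal `coupling_sd · (0.5 + |N(0, 1)|)`, signs fixed by
activated/repressed membership. Bounding couplings away from zero is
deliberate: a planted "target" with vanishing coupling would be
operationally indistinguishable from a null gene, making sensitivity
ill-defined; benchmark generators for network inference commonly bound
interaction strengths for the same reason. With the reference design
(coupling_sd 0.8, noise_sd 0.5, n = 200) the weakest target has
|r| ≈ 0.6, comfortably above the α = 0.01 detection threshold — which
is what makes near-perfect recovery the correct expectation rather
than a tuned outcome.

Stimulation designs shift each gene's condition-B mean by a planted
log₂ fold change (default +1 for activated, −1 for repressed targets)
with i.i.d. Gaussian replicate noise; `scaled_effects(−1)` yields the
antagonist/reversal contrast and fractional factors emulate receptor
knock-down. Peaks are placed at TSS + Laplace(0, offset_scale) — a
stand-in for the sharply-peaked-at-TSS displacement shape, not an
inference about any real peak set — with uniform background peaks,
width 200 bp, clipped to chromosome bounds. A cascade variant
(regulator → mediator → indirect targets) provides planted
direct/indirect structure for the DPI-stringency benchmark: as the
tolerance tightens (0.2 → 0.1 → 0), inferred regulons shed indirect
targets and the peak-within-window fraction rises monotonically.

What passing these benchmarks does **not** show: robustness to
nonlinear regulation, heteroscedastic or heavy-tailed array noise,
batch effects, probe-level artefacts, correlated nulls
(co-expression modules), or realistic genomic peak clustering. The
linear-Gaussian model is chosen precisely because it admits analytic
oracles, not because it exhausts real data.

## Determinism and problem sizes

Every generator and test is a pure function of its parameters and
seed; pipeline stage seeds are derived from the global seed and the
stage name (SHA-256, reduced below 2³¹), so adding a stage never
perturbs earlier ones. Artifacts are text with fixed float formatting
— 17 significant digits for expression matrices (bit-exact round
trips), 9 for derived tables — and the run manifest records a SHA-256
digest per output; a rerun under the same config reproduces every
digest.

Benchmark problem sizes were chosen to keep the full suite and the
acceptance script in the tens of seconds on one CPU while leaving
estimator behaviour asymptotically representative: compendia of
200–1000 genes × 120–200 samples, 1000 permutations, 10 recovery
seeds, 200 calibration repeats, 999 resampling nulls.

## Known limitations

- MI inference is regulator-anchored (plus regulator–regulator links
  for DPI), not a genome-wide all-pairs network.
- The bootstrap consensus does not tighten false-positive control (see
  above); it is kept for its original purpose, stability of retained
  edges.
- The random-positions null preserves peak widths and per-chromosome
  counts but ignores mappability/accessibility structure.
- `ordinary_t` assumes independent replicates; no paired or
  multi-factor designs.
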