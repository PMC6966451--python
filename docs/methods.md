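# Methods

## Coordinates and formats

All intervals are held 0-based half-open. Published TAD coordinates with
inclusive 1 kb-grid ends (e.g. `chr9:21240000-24400999`) are converted on
input by `end ← end + 1` and back on output, so both dialects round-trip
losslessly. Readers cover BED3/BED4, SEG-style CNV tables (sample, chrom,
start, end, num_probes, segment_mean; header tolerated), clinical TSVs
and two-column chrom.sizes. Unknown chromosomes are dropped with a
warning rather than failing, to tolerate alternate-contig rows in real
files; sample barcodes collapse to patients by a configurable prefix
(default: first 12 characters, the TCGA patient prefix) because no single
rule fits every consortium.

## Tissue weights

Tissues represented by similar transcriptomes should not multiply their
vote in the consensus. Counts are variance-stabilized as
`log2(count/size_factor + 1)` with median-of-ratios size factors (the
reference is the per-gene geometric mean over tissues). This replaces the
blind variance-stabilizing transform of a differential-expression
framework with a dependency-free transform of the same monotone,
variance-flattening intent. The 2000 genes with the largest
`max_t |x_gt − median_t(x_g)|` feed a correlation dendrogram
(distance 1 − Pearson r, average linkage). The agglomeration is
implemented directly (≈40 lines) so equal merge heights break
deterministically by lexicographically smallest member label; the test
suite cross-checks heights and topology against
`scipy.cluster.hierarchy.linkage`. Negative correlations give distances
in (1, 2] and are used as-is.

Leaf weights use the *equal-splits* rule: every edge's length is divided
equally among the leaves below it and a leaf's raw score sums its shares
along the root-to-leaf path, normalized to 1. The rule is exposed behind
`leaf_weights(method=...)` so an alternative branch-attribution scheme
can be swapped in without touching callers. Equal-splits has the
properties that matter here: redundant tissues share weight (splitting a
leaf into two zero-length children halves its weight and leaves all
others untouched — an exact identity, tested), and weights are invariant
to leaf order. A tissue with two TAD maps contributes half its weight to
each; per-map weights are renormalized to sum to 1.

## Consensus construction

Windows of L = 40 kb are generated per chromosome from position 0 at a
1 kb step (adjacent windows overlap by 97.5%); the final windows are
truncated at the chromosome end and scored over their actual length.
Conservation `c_i` is the weighted mean fraction of window nucleotides
inside a TAD; boundary `b_i` is the weighted indicator that the window
contains a TAD start or end (half-open containment, `s ≤ p < e`). The
implementation uses coverage prefix sums over the sorted disjoint TAD
intervals and is tested for exact agreement with a per-nucleotide
brute-force oracle on toy genomes.

Merging: the phrase "nucleotide-wise average conservation" is ambiguous
between a per-window and a per-run reading, so both are implemented
behind `build_consensus(mode=...)`. The default (`"greedy"`) first
defines a per-nucleotide score m(x) = mean of c_i over all windows
covering x (piecewise constant on the step grid, so it is computed at
step resolution with prefix sums), excludes every window with
b ≥ 0.5 from any run, and extends a run while the mean of m over the
merged region stays ≥ 0.5. `mode="window"` instead requires each
window's own c_i ≥ 0.5. On clean tracks the two coincide; the greedy
default reproduces the boundaries of N identical input maps within one
window step, the property that anchors the whole construction. When a
run is terminated by a low running mean (not by a boundary window), a
new run may start on the very next window whose own extent overlaps the
closed region; its emitted region is clipped at the previous region's
end so the output always partitions the covered genome. Runs ≥ 40 kb
become TADs; gaps between consecutive TADs are TBRs (≤ 400 kb) or
disorganized chromatin (> 400 kb). Gaps before the first and after the
last TAD of a chromosome are not labeled.

Map-to-map similarity is the median, over TADs of map A, of the largest
fraction of each TAD covered by a single TAD of B (0 when nothing
overlaps) — deliberately asymmetric.

## CNV enrichment

Filters follow the strict inequalities: keep segments with
1 kb < length ≤ 10 Mb, |segment mean| > 0.1, ≥ 10 probes. The patient ×
TAD matrix marks ≥ 1 bp overlap; patients with no filtered CNVs are
dropped (logged). For the permutation null, each TAD draws `n_perm`
random regions of identical length, the chromosome chosen with
probability proportional to its number of valid placements and the start
uniform, so placement is uniform over all valid genome positions and
never crosses a chromosome end. Empirical p-values are plain null
fractions including ties (`p_enriched = #(null ≥ obs)/n_perm`); a
`plus_one` flag adds the observed region to the null for users who
prefer the conservative variant. No mappability masking is applied by
default; an optional BED exclusion mask triggers rejection resampling.
Gains and losses are pooled by default with a sign-stratified matrix
behind a flag. Patient counting over candidate regions uses sorted
per-chromosome arrays with vectorized scans rather than per-query tree
walks; 141 TADs × 1000 permutations complete in seconds.

## Survival modeling

Cohort eligibility: ≥ 100 patients with CNVs and ≥ 10% deaths. Features
are binary: CNV presence per enriched TAD, `age_high` (strictly above
the training median; the final model uses the median over all included
patients since no single training split exists there), and sex (1 =
female). Constant columns are dropped with a warning.

Each repetition splits patients 2/3 : 1/3, fits the L1 Cox path
(`CoxnetSurvivalAnalysis`, l1_ratio = 1), and picks the regularization
strength by 5-fold cross-validation, scoring each path value by held-out
concordance and taking the best mean — the concordance analogue of
"minimum prediction error". The top ten features by |coefficient|
(ties by name) are the run's selection; if the path shrinks everything
to zero the fallback ranks features by their order of appearance in the
regularization path. Runs with event-free splits or optimizer failures
are recorded as failed and excluded; K in the aggregation is the number
of completed runs.

Aggregation implements the run weighting
`w_i = (1/K)·exp(ln2 · devCI_i/0.1)` for CI_i ≥ 0.5 and 0 otherwise,
with devCI_i the run's c-index minus the mean over completed runs: a run
0.1 of c-index above the mean counts exactly twice a run at the mean
(asserted exactly in the tests). Normalized weights aggregate selection
indicators into P_j ∈ [0, 1]; the feature universe is the union of
features ever selected, indicators are 0 where a feature was not a
candidate, and no re-normalization is applied per feature.

The final model refits the top ten P_j features with an unpenalized Cox
model (lifelines), dropping the largest-Wald-p feature (ties by name)
until all p ≤ 0.05. Exactly duplicated columns are reduced to the
alphabetically first before fitting; convergence trouble retries with a
1e-6 ridge. Retention is governed by raw p ≤ 0.05; Benjamini–Hochberg
q-values are reported alongside so marginal features are visible.
Risk scores are Σ coefficient × feature; patients at or below the median
score are low-risk (an explicit tie policy). Kaplan–Meier curves and the
two-sample log-rank test come from lifelines. A run set is flagged
"reliable" when its median test c-index lies in [0.55, 0.8]. Harrell's
c-index wraps `sksurv.metrics.concordance_index_censored` (score ties
count 0.5) and is verified against an exhaustive all-pairs oracle.

Known limitation (measured, not hidden): because the top-10 candidates
are chosen by resampling splits of the same cohort, surviving noise
features carry inflated in-sample association, and backward elimination
at raw p ≤ 0.05 retains on average ~1.5 spurious features alongside the
true ones on the synthetic recovery cohorts. Retaining by q ≤ 0.05 would
suppress this but would depart from the modeled procedure; the q-values
are reported for exactly that judgement.

## Perturbation classification and profiles

For each normal TAD, f_N is the largest fraction of it covered by a
single cancer TAD, f_C the largest fraction of that cancer TAD covered
by a single normal TAD, and the pair is reciprocal when the cancer TAD's
best partner is the original TAD. Constitutive requires reciprocal
fractions ≥ 0.95; perturbed requires f_N ≤ 0.7 or f_C ≤ 0.7; everything
else is ambiguous and reported as such, never folded into either class.
Split TADs contain ≥ 2 cancer TADs each ≥ 95% inside them; fused groups
are connected components of normal TADs ≥ 95% inside one cancer TAD,
with all members required to be perturbed (the strict reading; note that
fusing TADs of very unequal size can leave the larger partner covering
> 70% of the fused TAD, which correctly lands in ambiguous rather than
perturbed).

Meta-profiles mirror the deepTools conventions. Scale-regions: each
region's body is linearly rescaled to 2 Mb over 10 kb bins with 1 Mb
unscaled flanks, per-bin values are mean coverage depth of the signal
intervals over the bin span (computed from an exact coverage-integral
F(x) built on sorted starts/ends prefix sums), aggregated across regions
by the median (mean behind a flag). Reference-point: ±200 kb around
region midpoints at 5 kb bins, mean across centers, spans beyond the
chromosome counting as zero. CNV signal is first merged per patient so
depth equals the number of *patients* (not segments) covering each base.

## Synthetic cohorts

The generator draws a base TAD map by walking each chromosome with
log-normal TAD sizes (median 1 Mb, log-sd 0.45, floor 100 kb) and
log-normal gaps (median 80 kb), all on a 1 kb grid — sizes chosen to
match the interval geometry of published human TAD maps. Per-tissue maps
apply boundary jitter (Gaussian, default sd 20 kb), splits and fusions
(default probability 0.05 each); tissues within a clade reuse the
clade's edit template with probability 0.7, which correlates related
tissues the way shared biology would. Expression counts are
negative-binomial with Brownian latent log-means along the clade tree,
so the dendrogram step can recover the generating topology.

Patient CNVs: counts are gamma-Poisson (mean 30, shape 5), lengths
log-uniform on [1 kb, 10 Mb], segment means a two-component mixture
(85% at ±N(0.35, 0.1), 15% near zero) that straddles the ±0.1 filter,
probe counts Poisson(length/3 kb) — so every filter rule is exercised by
construction. Recurrence spiking uses biased placement, not duplication:
a per-TAD redirect probability is calibrated from the closed-form
gamma-Poisson recurrence `r(p) = 1 − (1 + m·p/k)^(−k)` — with m the
filtered per-patient CNV mean and p the per-CNV hit probability under
uniform placement — so that the spiked TAD's patient-recurrence is the
requested factor times background while the length distribution of
spiked and background CNVs is identical.

Survival times are exponential proportional hazards over the binary
features, so Cox coefficients equal the generative log-hazard-ratios
exactly and recovery assertions are sharp; censoring times are uniform
(0, c_max) with c_max bisected so the realized censoring fraction hits
the target. The simulated "cancer genome" applies known split/fusion
edits to the base map, giving labeled ground truth for classification.

What the generator does not emulate: per-cancer-type CNV spectra,
germline variants, chromosome-end clustering of CNVs, batch structure
among Hi-C maps, or covariate-dependent censoring. Passing tests
therefore demonstrate correctness of the algorithms and calibration
under the modeled assumptions, not robustness to every artifact of real
tumor data.

## Problem sizes and determinism

Default synthetic scale: a 140 Mb three-chromosome genome (~116 TADs),
8 tissues, 300 patients; the analysis scripts use K = 200 repetitions
and 1000 permutations, and the recovery experiments in the test suite
use K = 100 with 20 replicates and 200 permutations with 100–150 TADs —
sizes at which every stage's statistical behavior is measurable while
the full pipeline runs in minutes on one CPU. All randomness flows from
explicit seeds through `numpy.random.Generator`; per-run and
per-replicate streams are spawned from a master generator, and identical
seeds reproduce identical outputs bit-for-bit.
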