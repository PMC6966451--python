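# tadprog

Topologically associating domains (TADs) partition the genome into
contiguous blocks of preferential chromatin interaction, and their
disruption — boundary loss, splits, fusions — is increasingly implicated
in cancer. `tadprog` implements a complete analysis pipeline that links
TAD organization to cancer prognosis:

1. **Consensus TAD map construction.** Per-tissue TAD maps (BED
   intervals) are combined into one consensus map. For sliding windows of
   length L = 40 kb stepped by 1 kb, a conservation score
   `c_i = (1/L) Σ_j Σ_k w_k · I_T(j,k)` (weighted fraction of window
   nucleotides inside a TAD) and a boundary score
   `b_i = Σ_k w_k · I_B(i,k)` (weighted indicator of a contained TAD
   boundary) are computed, where the tissue weights `w_k` derive from an
   expression dendrogram so that transcriptionally redundant tissues share
   their influence. Windows are merged while the nucleotide-wise mean
   conservation stays ≥ 0.5 and no window has boundary score ≥ 0.5; runs
   ≥ 40 kb become consensus TADs, inter-TAD gaps ≤ 400 kb are topological
   boundary regions (TBRs), longer gaps disorganized chromatin.
2. **CNV enrichment.** Somatic copy-number segments are filtered
   (1 kb < length ≤ 10 Mb, |segment mean| > 0.1, ≥ 10 probes) and each
   TAD's count of patients with ≥ 1 bp CNV overlap is compared against
   1000 random same-size genomic regions; a TAD is enriched (depleted)
   when ≤ 5% of its random counterparts reach a count ≥ (≤) the observed.
3. **Prognostic modeling.** For cohorts with ≥ 100 patients and ≥ 10%
   lethal outcomes, repeated (K×) 2/3–1/3 splits are fit with L1-penalized
   Cox regression (λ by 5-fold cross-validation), keeping the top-ten
   |coefficient| features and scoring Harrell's c-index on the held-out
   third. Run i is weighted `w_i = (1/K)·exp(ln2·devCI_i/0.1)` for
   CI_i ≥ 0.5 (zero otherwise), weights are normalized, and each feature
   aggregates `P_j = Σ_i w'_i · I_{j,i}`. The ten features with the
   largest P_j enter an unpenalized Cox model pruned by backward
   elimination (Wald p ≤ 0.05); its coefficients define risk scores,
   median-split risk groups (Kaplan–Meier, log-rank), and can be applied
   frozen to an external cohort.
4. **Perturbation classification.** Normal consensus TADs are labeled
   constitutive (reciprocal best-overlap fractions ≥ 0.95), perturbed
   (either fraction ≤ 0.7), or ambiguous against a cancer consensus map;
   perturbed TADs are further split (≥ 2 cancer TADs ≥ 95% inside) or
   fused (≥ 2 normal TADs ≥ 95% inside one cancer TAD). CNV density
   meta-profiles (scale-regions and reference-point) characterize where
   in the TAD body the mutations fall.

Because real Hi-C-derived maps and tumor CNV/clinical cohorts require
large downloads, the package ships a first-class synthetic-cohort
generator (`tadprog.simulate`) that produces every input with the
statistical structure the analysis assumes — jittered/edited multi-tissue
TAD maps, clade-structured expression counts, patient CNV segments with
known spiked recurrence, exponential proportional-hazards survival — so
the whole pipeline is testable with ground truth. The readers accept real
BED/SEG/TSV files unchanged.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
cohort (3 chromosomes totaling 140 Mb, 8 tissues, 300 patients, 8 TADs
spiked 3× for CNV recurrence of which 3 also carry a survival hazard
ratio of 2):

```text
$ python analysis/01_simulate_cohort.py
base map: 116 TADs; 8 tissue maps (jitter sd 20 kb)
CNVs: 8737 segments for 300 patients (4653 pass the size/segment-mean/probe filters)
clinical table: 300 patients, 75% deceased

$ python analysis/02_consensus_map.py
pairwise map similarity: median 0.984
consensus: 141 TADs (median 0.93 Mb), 138 TBRs, 0 disorganized regions
similarity of ground-truth map to consensus: 0.988

$ python analysis/03_cnv_enrichment.py
9 of 141 consensus TADs enriched at alpha=0.05; max log2 fold 2.00
7/8 spiked TADs recovered as enriched

$ python analysis/04_survival_models.py
200/200 runs completed; median test c-index 0.643 (reliable: band 0.55-0.80)
final model hazard ratios: {'age_high': 1.79, 'chr1:40925000-42419000': 2.8, ...}
median-split stratification: log-rank p = 2.83e-11
external validation c-index: 0.629

$ python analysis/05_tad_perturbation.py
classification: 98 constitutive, 24 perturbed, 19 ambiguous
ground truth recovered: 3/3 split, 4/4 fused
```

Reading the output: the consensus step reproduces the generating TAD map
almost exactly (similarity 0.988, on the 0–1 best-overlap scale); the
permutation test finds the spiked TADs with log2 fold-differences near
log2 3; the repeated LASSO Cox procedure lands in the 0.55–0.80
"reliable" c-index band, its final model recovers the three causal TADs
with hazard ratios near the generative value of 2, and the median risk
split separates survival strongly; and the engineered split/fusion edits
of the simulated cancer genome are recovered exactly. Tables land in
`results/`.

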