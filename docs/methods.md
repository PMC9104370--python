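# Methods

## The subtyping procedure

For one tumor type and one gene set, let X be the TPM-like expression
matrix restricted to the set's genes (genes × samples). Genes with zero
variance across samples are dropped; if fewer than two genes remain the
pair is recorded as *unusable* (distinct from *gated out*).

**Gate.** Each gene is rank-transformed across samples (average ranks
for ties) and each sample is treated as a point in the p-dimensional
rank space, p = number of usable genes. The candidate 2-split is the
PAM k=2 partition on the Spearman distance (below). The Duda–Hart
statistic is H = Je(2)/Je(1), where Je(1) is the total within-group sum
of squares of the unsplit points and Je(2) the sum over the two parts
of squared distances to part centroids. The one-cluster null is
rejected when 1 − Φ(z) < α_gate with

    z = (1 − 2/(πp) − H) · sqrt( np / (2 (1 − 8/(π²p))) )

the standard normal approximation of the criterion. α_gate defaults to
0.001. Rank coordinates are the default gate space because ranking is
the more conservative of the two monotone transforms considered
(log2(x+1) is available behind the `gate_space="log"` switch). The
choice of the PAM 2-split as the candidate split, and of rank
coordinates as the test space, are operational decisions: the criterion
itself does not fix either, and we use the same split family as the
downstream clustering for coherence.

**Distance.** d(i, j) = 1 − ρ(i, j), the Spearman rank correlation of
the two samples' expression profiles over the set's genes, giving
d ∈ [0, 2]. The affine variant (1 − ρ)/2 would produce identical
clusterings (PAM and silhouette rankings are invariant under positive
affine maps of d); the [0, 2] form is used and documented for
reproducibility.

**Clustering.** PAM (k-medoids) with the classic BUILD + SWAP phases:
BUILD greedily adds the medoid that most decreases the total distance
to the nearest medoid; SWAP repeatedly applies the best strictly
improving (medoid, non-medoid) exchange until none exists, so the
objective is non-increasing and termination is guaranteed. All ties —
medoid selection, swap choice, nearest-medoid assignment — break toward
the lowest sample index, making every run deterministic. Cluster labels
1..k follow ascending medoid index.

**Choice of k.** k runs over 2..min(10, n−1); the k with maximal
average silhouette width wins, ties toward smaller k. Silhouette uses
the standard conventions: singleton clusters score 0, and the
degenerate a = b = 0 case scores 0.

**Partition comparison.** NMI = I(A;B)/√(H(A)H(B)) from empirical
joint frequencies (natural logs; the normalization makes the base
irrelevant). A single-cluster partition has zero entropy and NMI is
defined as 0.

**Differential genes.** Kruskal–Wallis per gene within the clustered
gene set; constant genes are untestable and assigned p = 1; genes are
ranked by (p, name) and the top 20 reported by default.

## Feature derivation

* **Region copy number.** Gene-level values come from SEG records
  (1-based inclusive coordinates): a gene overlapped by several
  segments gets the length-weighted mean of their segment means;
  uncovered genes get 0 with a warning. Values inside the dead zone
  [−0.5, 0.5] are zeroed (SGOL-style thresholding) and each region's
  score is the mean over its genes, **per sample**. The cohort-level
  variant (sum across samples per gene, then mean over region genes,
  broadcast) exists behind `per_sample=False`; it yields one number per
  cohort and cannot enter a per-sample test, which is why the
  per-sample form is the default for association testing.
* **Global methylation.** Per-sample sum of gene-level methylation;
  missing gene values are ignored (count logged), an all-missing sample
  gets a missing feature.
* **Mutations.** Calls are filtered to non-synonymous variant
  classifications (default set: Missense, Nonsense, Frame_Shift_Del/Ins,
  In_Frame_Del/Ins, Splice_Site, Nonstop, Translation_Start_Site;
  configurable). A sample is mutated in a gene if it carries ≥ 1
  retained call; the point-mutation table has one binary feature per
  distinct (gene, protein change).
* **miRNA.** Because a large share of miRNA measurements are exactly
  zero, average-rank ties would create huge identical blocks; instead
  each tie group receives distinct consecutive ranks in a uniformly
  random order, deterministic given the seed. Every output row is a
  permutation of 1..n.
* **RPPA** passes through as a generic continuous matrix (ordinary
  average-rank tie handling inside the tests).
* **Clinical.** Paired `os_time`/`os_event` (and `rfs_*`) columns become
  survival tables; negative times are dropped with a warning,
  non-{0,1} events are an error. Remaining numeric columns are
  continuous features; non-numeric columns with ≤ 10 levels are
  categorical (more levels are treated as free text and rejected).

## Association testing

Dispatch by feature kind: continuous → Mann–Whitney U for k = 2
(exact enumeration when both groups ≤ 8 and tie-free, otherwise the
normal approximation with tie correction) or Kruskal–Wallis for k > 2;
categorical → Fisher's exact test (two-sided, sum of tables no more
probable than the observed) for 2×2 tables, Pearson chi-square without
continuity correction for larger tables after iteratively removing the
level whose minimum expected count is smallest among levels with any
expected cell < 5 (expectations recomputed each pass; a table reduced
to exactly 2×2 reverts to Fisher); survival → the k-group log-rank test
with the full hypergeometric covariance, declared invalid when any
subtype's expected event count Σ_t d_t·n_g(t)/n(t) falls below 5.
Binary mutation features with fewer than 3 mutated samples overall are
skipped as untestable (degenerate Fisher margins; configurable).
Missing values are dropped pairwise per test and `n_used` recorded.

Bonferroni correction is applied separately per variable class but
pooling all tumor types and gene sets: the family size m counts the
valid tests of the class, and a result is significant iff valid and
p < α/m (α = 0.05). Counting invalid tests in m is available as a
switch since the choice changes thresholds; counting only valid tests
is the default because invalid tests never produced a p-value. An
overall single-family count is reported in the run log as a summary
only. Recurrent associations are (gene set, class, feature) triples
significant in ≥ 2 distinct non-composite tumor types; the shipped
composite-type list {LUNG, KIPAN, GBMLGG, COADREAD, STES} is a
configurable default (composite cohorts are unions of narrower ones and
would recur trivially).

## The synthetic generator

The generator produces the study's data conditions, not realistic TCGA
marginals. Expression is log-normal: gene baselines ~ N(3, 1) on the
log2 scale with within-gene noise SD 1, exported as 2^x (TPM-like). A
planted gene set splits samples into balanced true clusters; half its
genes (configurable `fraction_up`) are "up", half "down", each gene is
driven by one cluster in which its mean moves by ±separation log2
units (and by ∓separation/(k−1) elsewhere, keeping patterns centered).
The "strong" preset uses separation 3.0 — three noise SDs — the regime
in which the subtype structure is unambiguous, which is what the
dominant k=2 outcomes of real pan-cancer screens look like after
gating; separation 0 is the calibration null. Other defaults, chosen
once as field-plausible values: null mutation rate 0.08 per gene,
miRNA zero-inflation 0.3 with log-normal expression (log2 mean 5,
SD 1), methylation Beta(2, 5) per gene, survival baseline hazard
1/365 d⁻¹ with exponential censoring tuned so that the competing-risk
censoring fraction matches the requested rate, age ~ N(60, 10). The
toy genome (2 chromosomes × 10 Mb, 100 genes in 10-gene regions) is
deliberately unrelated to any real build; SEG and BED outputs are
consistent with each other. Copy-number baselines are N(0, 0.05) per
region span — safely inside the SGOL dead zone — with planted regions
shifted by a per-cluster delta.

Each data type draws from its own child stream of the single cohort
seed, so outputs are byte-identical across runs and adding one effect
does not perturb the other data types. A `truth.json` sidecar records
planted assignments and effects, sufficient to score recovered
partitions without re-running the generator.

What the generator does **not** emulate: negative-binomial count noise
(only monotone structure matters to a rank-based pipeline), batch
effects, tumor purity, copy-number–expression coupling, and realistic
linkage between data types. Passing tests therefore demonstrate the
correctness and calibration of the procedure under its own model
assumptions, not performance on real TCGA data.

## Numerical choices and edge cases

* Strict-improvement threshold for SWAP: 10⁻¹²; distance matrices are
  symmetrized and clipped to [0, 2] against floating-point noise.
* k_max clamps to n−1 for tiny cohorts; select_k requires n ≥ 3.
* A sample whose profile is constant across a gene set's genes has no
  rank correlation and raises an error naming the sample.
* Duda–Hart on identical points (Je(1) = 0) is a degenerate-input
  error rather than a p-value.
* Fisher/chi-square routing is decided on the observed 2×2 shape
  first; the expected-count removal rule belongs to the chi-square
  branch (the exact test needs no expected-count guard).
* Problem sizes used by the validation suite and the acceptance
  script: 10,000 replicates for gate and test calibration (n = 100 ×
  p = 10, and 60 samples per group respectively), 100 cohorts of n = 90
  for k-recovery, 200 cohorts of n = 50 for the global-null
  family-wise error check, 100 cohorts each for mutation power
  (n = 200, prevalence 0.25 vs 0.04) and survival power (two arms of
  150, hazard ratio 3, ~30% censoring). These sizes give binomial
  standard errors well below the asserted margins while keeping the
  full suite in the low minutes.

## Known limitations

* The Duda–Hart gate uses a data-derived (PAM) split, which is
  anti-conservative relative to the normal approximation's assumptions;
  the calibration property asserted in the tests fixes the split
  independently of the data. The gate threshold of 0.001 should be
  read as a ranking device, not an exact type-I rate.
* PAM is a local search: on small adversarial (non-metric) random
  distance matrices it stops at a slightly suboptimal objective in a
  minority of cases (measured and bounded in the tests); on separated
  data it matches exhaustive search.
* The literal cohort-level SGOL score is a single number per region
  and cannot be tested per sample; the per-sample thresholded variant
  is the default and the cohort variant is kept only for comparison.
* Survival generation uses exponential times; real cohorts violate
  proportional hazards in ways the power numbers here do not probe.
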