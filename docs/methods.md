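# Methods

This note documents the statistical procedures soilbeta implements, the
generative model behind its synthetic studies, the numerical choices that
matter, and what the validation suite does and does not establish.

## Data model

A `CommunityTable` is a samples × taxa abundance matrix with per-sample
metadata (site, molecule RNA|DNA, x/y coordinates in meters). Raw tables
hold integer sequencing counts; rarefaction-averaged tables hold
fractional counts whose rows sum to the rarefaction depth within 1e-6.
An `EnvTable` holds numeric soil variables per sample. Distance matrices
carry a semantic tag (community | environment | geographic) and a
transform tag (none | similarity | log10); similarity conversion
(1 − d) is only defined for kinds bounded in [0, 1].

## Sampling-effort equalization

Sequencing libraries differ in depth, and most beta-diversity measures —
Canberra especially, through its sensitivity to rare taxa — confound depth
with composition. Each sample is therefore subsampled without replacement
(multivariate hypergeometric) to a common depth, and the analysis table is
the entrywise mean of `n_reps` independent subsamples (defaults: depth
3790, 100 replicates). Samples whose library is below the depth are
dropped with a logged warning rather than erroring, because field studies
routinely lose a few shallow libraries. Averaged entries converge to the
hypergeometric expectation `depth × count / library`; the test suite
checks this at 1000 replicates within three standard errors.

A taxon counts as *detected* in a sample when its averaged count is
positive, i.e. it was drawn in at least one subsample; the threshold is a
parameter everywhere it matters.

## Distances

**Canberra (community).** `d(i,j) = (1/NZ) Σ_k |x_ik − x_jk| /
(x_ik + x_jk)`, summed over the NZ taxa with `x_ik + x_jk > 0`. Double
zeros carry no information about two communities' difference, and the
1/NZ normalization bounds d in [0, 1] so that 1 − d is a usable
similarity. The unaveraged textbook sum is available behind a flag. Each
per-taxon term is scale-free, which makes the measure abundance-weighted
only through presence and noise — the reason rare-taxon sampling noise,
not dominant-taxon turnover, sets the similarity baseline of real tables.

**Gower (environment).** Range-normalized Manhattan for numeric
variables, simple matching for categorical ones, averaged; returned as
the similarity 1 − d. Zero-range variables are dropped with a warning.
Before Gower, collinear chemistry variables are pruned greedily: while
any pair has Pearson R² > 0.6 with p < 0.05, the member with the larger
mean |r| to all remaining variables is removed (each removal logged).
The tie-break is a package choice; which member of a redundant pair
survives does not change the similarity structure materially.

**Geography.** Euclidean distance in meters. Decay regressions use log10
distance by default: the nested design spans 0.1–141 m, and slopes on the
order of a few hundredths of a similarity unit are only dimensionally
sensible per decade of distance, not per meter. Linear distance is a
flag.

## Permutation inference

All tests report the add-one estimate `p = (#{extreme} + 1) /
(n_perm + 1)` and are exactly reproducible from their seed. Nulls are
evaluated in vectorized batches (a permutation of samples is a gather on
the condensed pair vector), so thousand-replicate calibration studies run
in seconds.

* **Mantel** — Pearson (optionally Spearman) correlation over the
  n(n−1)/2 sample pairs; the null relabels one matrix's samples.
  Similarity-tagged inputs are flipped to dissimilarities first, so a
  similarity that decays with distance tests as a *positive* association;
  the default tail is the one-sided positive test in that orientation
  (the convention of the standard implementations). A sign-adaptive tail
  is available but roughly doubles the type-I error, which is why it is
  not the default.
* **Partial Mantel** — first-order partial correlation of A and B given
  C over pair vectors (equivalently, correlation of residuals); the null
  permutes the raw first matrix, the simplest standard choice.
* **Distance-decay** — OLS of pairwise similarity on (log10) distance
  gives slope and intercept; significance comes from the Mantel test on
  the untransformed matrices. By convention a trend line is drawn only at
  Mantel p < 0.05 (`DecayFit.significant`).
* **diffslope** — observed statistic slope₁ − slope₂ of two (distance,
  similarity) pair sets; the null shuffles pair-set membership, keeping
  sizes, and refits both slopes (default 1000 shuffles). The quoted
  procedure is ambiguous about sign, so the default is two-sided on
  |difference| with one-sided tails available.
* **PERMANOVA** — pseudo-F from squared distances,
  `SS_total = Σ_{i<j} d²/n`, `SS_within = Σ_g Σ_{i<j∈g} d²/n_g`,
  `F = (SS_among/(g−1)) / (SS_within/(n−g))`, `R² = SS_among/SS_total`;
  the null permutes group labels. R² ∈ [0, 1] is guaranteed for
  Euclidean-embeddable distances; arbitrary non-metric matrices can
  produce negative SS_among, which is a property of the statistic, not
  the implementation (verified against scikit-bio to machine precision).

Degenerate inputs are errors, not NaNs: matrices with zero off-diagonal
variance, a control matrix that explains the second matrix entirely,
groups of size one, zero distances under a log transform.

## Group comparisons

Mean ± SEM of within-group pairwise similarity, one-way ANOVA across land
types, Tukey HSD post-hoc contrasts, and the pooled-variance two-tailed
Student t for RNA-vs-DNA contrasts (pooled rather than Welch, matching
the named test). Pairwise similarities are not independent — every sample
sits in n−1 pairs — so these classical tests are reproduced as the
field's convention while `permutation_gap_test` permutes *samples* (the
exchangeable unit) and recomputes the mean-similarity gap as a robustness
line; pipeline reports carry both. Zero pooled variance with equal means
returns t = 0, p = 1; with unequal means it is an error.

## Negative-binomial differential abundance

A deliberately compact reimplementation of the DESeq2-style criterion,
for two-group designs on raw integer counts:

1. **Size factors** — median-of-ratios against per-taxon geometric means
   over the taxa present in every sample, normalized to geometric mean 1;
   a positive-count fallback (logged) covers tables with no all-present
   taxon.
2. **Dispersion** — per-taxon NB2 dispersion α by maximizing the Cox–Reid
   adjusted profile likelihood (grid + golden-section on log α, group
   means refit by Newton at every evaluation, floor 1e-8, ceiling 20).
   The likelihood uses `Σ_{k<y} log(1 + kα)` directly, switching to its
   quadratic series below α = 1e-3 where the lgamma form loses precision
   to cancellation.
3. **Moderation** — a trend `α(μ) = a₀ + a₁/μ` is fit to the interior ML
   estimates by reweighted least squares, and each taxon's dispersion is
   the log-space average of its ML estimate and the trend value (weight
   0.5). This stabilizes small-sample estimates without the machinery of
   a full empirical-Bayes MAP.
4. **Wald test** — z = (b_contrast − b_reference)/SE with SE from the
   expected information `Σ_j μ/(1+αμ)` per group; two-sided normal p;
   Benjamini–Hochberg across taxa. The alphabetically first group is the
   reference unless named explicitly.

Omitted relative to the full DESeq2: empirical-Bayes fold-change
shrinkage, Cook's-distance outlier handling, and MAP dispersions.
Consequence: taxon-level calls can differ in detail from DESeq2's; the
cross-check test requires LFC correlation > 0.95 and majority agreement
of significant positive calls on a shared fixture, and the mechanism
analyses depend only on the behavior of the enriched *set*, which the
recovery simulations validate (type-I ≈ 0.05 at n = 13 + 13; power ≈ 1
at fourfold enrichment with moderate dispersion). Under median-of-ratios
normalization a dense differential signal (a large fraction of taxa
changed in one direction) biases fold changes toward zero — a property of
the normalization, shared with the original, visible in simulations that
make most taxa differential.

"Low-abundance sample" exclusion is a configurable minimum-depth filter
(default: the rarefaction depth) applied before fitting; an optional
mean-count independent filter is off by default.

## Mechanism attribution

*Newcomers* are taxa detected in the converted site's averaged table but
in no forest sample (both tables on a shared taxon universe).
*Bloomers* are taxa with positive log2 fold change and adjusted p < 0.05,
converted site vs forest, on raw counts with forest as the reference.
Identification runs on raw counts; removal operates on the raw table
followed by re-rarefaction (lowering the depth to the post-removal
minimum library when necessary, logged), so taxon identity bridges the
two stages.

The verdict rule, made explicit: a mechanism **contributes** to
homogenization iff removing its taxa significantly *lowers* mean pairwise
similarity (Tukey HSD, before vs after, α = 0.05) **and** the post-removal
community is no longer significantly more similar than the forest
baseline. Removal that leaves similarity unchanged or raises it — the
typical outcome for scattered, low-abundance newcomers, whose per-taxon
Canberra terms are large — is a negative verdict. Reports carry both
directions plus the sample-level permutation check, since the
removal-increases-similarity outcome is itself informative.

## The synthetic study generator

The generator is the package's ground truth. It emulates:

* **Design** — 13 cores per site at the corners of a 100 m quadrat and of
  10, 1 and 0.1 m quadrats nested at one corner.
* **Environment** — Gaussian random fields with exponential covariance
  (default range 50 m, nugget 0.01) on the sampling points; seven named
  chemistry variables of which the first is the niche axis, the others
  correlated to it at r ≈ 0.3 (soil suites covary), plus two near-copies
  of the axis that exist to exercise collinearity pruning.
* **Communities** — taxon weight `base_k · ((1−r_k) + r_k·K_k(e))` where
  `base_k` is log-normal (σ = 1.5), `K_k` a product of Gaussian kernels
  over the first three environment axes (optima truncated-normal within
  ±1.5, widths 0.6–1.2), and `r_k ~ Beta(2,1)` the taxon's environmental
  responsiveness. The mixture keeps every taxon detectable off-niche —
  real soil taxa persist at low abundance outside their optimum — which
  is what keeps false "newcomers" rare in converted sites.
* **RNA vs DNA** — the RNA layer uses amplified responsiveness
  `r' = 1−(1−r)^c` (c = 2) restricted to the active fraction (70%); the
  DNA layer mixes the live composition with a spatially flat relic pool
  (40%). This produces the study design's headline contrast: the active
  community tracks the environment more tightly than the DNA-inferred
  one.
* **Conversion** — a directional mean shift of the niche axis (+5 axis
  SD; the chronosequence chemistry change) with modest extra axis scatter
  (variance 2), plus large unstructured variance (6) on the nutrient
  variables. The shift pushes soils beyond most resident optima, so
  communities collapse onto the disturbance-tolerant (low-responsiveness)
  taxa — homogenization through environmental filtering — while the
  nutrient patchiness destroys the environment's spatial signal and
  lowers environmental similarity.
* **Mechanisms** — `apply_bloom` multiplies chosen prevalent residents'
  *expected* abundances by `fold` (4) and mixes each bloomer's per-sample
  share toward its site mean (`occupancy_boost` 0.5), then redraws counts
  at the original depths (operating on observed counts instead would
  compound sampling noise). `apply_invasion` adds novel taxa at a fixed
  community share split log-normally among the newcomers present in each
  core, subsampling residents so depths are conserved exactly. The
  default injection is calibrated to the field observation — about 2% of
  the community at occupancy 0.25 — and at that size newcomer removal
  does *not* lower similarity. The separate `invasion_strong` preset
  (25% share, full occupancy, no environmental disturbance) is the
  positive control in which newcomers demonstrably drive homogenization.
* **Null** — the `pristine` scenario re-surveys the same forest:
  identical environmental field, fresh community and sequencing draws.
  Two *independent* forest realizations differ genuinely (their
  responsive taxa track different fields) and are therefore not a
  mechanism-attribution null.
* **Counts** — multinomial at per-sample depths drawn uniformly from the
  configured range, with a configurable shallow minority (4%) below the
  rarefaction depth to exercise sample dropping. NB-distributed per-taxon
  marginals for the differential-abundance power studies are generated
  inside that module's simulations instead, where per-taxon control
  matters more than compositional realism.

**Problem sizes.** Full-scale defaults are 2000 taxa and depths
5000–20000 at rarefaction depth 3790. Replicated validation studies use
`ScenarioConfig.desk()` — 250 taxa, depths 1200–2500, rarefaction depth
800, proportional mechanism sizes (25 bloomers, 50 newcomers) — which
preserves every effect *size* (niche structure, coupling, relic fraction,
fold, injection share) while making a full mechanism report run in under
a second, so fifty-replicate recovery studies are desk-scale. Tests and
the acceptance script use 15–50 rarefaction replicates and 99–999
permutations depending on what the check needs.

**What passing does and does not show.** The generator produces the
qualitative structure the analyses assume — log-normal abundance,
niche-driven spatial turnover, an active layer, relic DNA, and isolated,
known mechanisms. It does not emulate phylogenetic structure, taxon
interactions, temporal dynamics, chimeras/sequencing artifacts, or the
compositional coupling of real libraries; recovery rates here bound what
the pipeline can do when its assumptions hold, not what any particular
field dataset will yield.

## Numerical and reproducibility choices

Every stochastic operation takes an explicit seed; the pipeline derives
per-stage seeds from one master seed by fixed offsets and records them in
its JSON summary. Rarefaction uses numpy's multivariate hypergeometric
generator. Permutation engines tolerate ties with a 1e-12 comparison
slack. The Canberra implementation broadcasts over sample pairs (memory
~n²·taxa doubles; fine for n ≤ ~50 samples). Cholesky factorization of
environment covariances adds 1e-8 jitter on failure.

## Known limitations

* Canberra similarity is noise-dominated for rare taxa; comparisons
  between tables of very different depth or richness should be read with
  that in mind (rarefaction averaging equalizes within a study, not
  across studies).
* The NB module handles exactly two groups with no covariates; multi-
  factor designs are out of scope.
* The classical group tests inherit pair-level pseudoreplication (see
  the permutation alternative above).
* Mantel-family tests at n = 13 have limited power; non-significant
  decay in a single site is weak evidence of absence, which is why the
  replicated generator studies report rates rather than single p-values.
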