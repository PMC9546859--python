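# Methods

## The model

`ornmeta` estimates how strongly ornament elaboration covaries with
indicators of condition and fitness in female and male birds, treating the
two sexes' published effect sizes as one bivariate response. Each
association extracted from the literature is a Fisher-transformed
correlation, Zr = atanh(r), with known sampling variance 1/(n − 3). A
female effect and a male effect measured for the same ornament and the same
parameter in the same study form one paired observation
y_i = (Zr_f, Zr_m); either component may be missing when only one sex was
studied.

The bivariate phylogenetic mixed-effects meta-analysis is

y_i = X_i β + u_sp[s(i)] + u_ph[s(i)] + e_i + m_i

* **β** — fixed effects, always sex-specific (separate female and male
  intercepts or cell means), optionally with moderators: the
  condition/fitness split, ornament type, condition or fitness
  subcategories, study design, mean-centred publication year, and the
  sexual-dimorphism score d with its sex interaction.
* **u_sp ~ N(0, Σ_sp)** — independent species effects (2×2 covariance
  across sexes). A study-identity term is deliberately absent: with
  essentially one study per species the two terms would split the same
  variance.
* **u_ph** — phylogenetic effects with cov(u_ph[s,a], u_ph[t,b]) =
  A[s,t]·Σ_ph[a,b], where A is the species correlation matrix from a tree.
* **e_i ~ N(0, Σ_e)** — a bivariate residual per association
  (unstructured 2×2).
* **m_i ~ N(0, diag(se²_f, se²_m))** — fixed, known measurement error.
  Rows with one sex missing still need both variances, so the missing side
  inherits the observed side's SE² (uncertainty augmentation); the missing
  *response* is imputed by the sampler each sweep, which is what lets
  unpaired effects inform both sexes' means through the cross-sex
  covariances.

### Phylogenetic correlation matrix

For tips i, j, A[i,j] = depth(MRCA)/√(depth_i·depth_j) — the shared
root-to-MRCA path length standardised by the geometric mean of the tip
depths. For an ultrametric tree this is the usual scaled Brownian-motion
VCV; the geometric-mean denominator also absorbs the small tip-height
variation of published supertrees, which are not exactly ultrametric.
Polytomies are accepted as-is; zero-length internal branches are allowed.
If a matrix fails a numerical PSD check (tolerance −1e-10 on the smallest
eigenvalue) a ridge of 1e-8 is added to the diagonal and the event logged.
Trees are pruned to the dataset species before matrix construction, which
for correlation matrices is identical to sub-setting the full matrix.

### Priors and sampler

Variance priors follow the (V, ν) inverse-Wishart convention in which
(V, ν) describes a standard IW with scale ν·V and ν degrees of freedom
(prior mode ν·V/(ν + dim + 1)). Defaults: V = I₂, ν = 2 for all three
covariances; the species and phylogenetic terms are in addition
parameter-expanded — levels are stored as u = diag(α)·η with η ~ N(0, Ψ)
and a working scale α ~ N(0, 625·I₂) — the redundant multiplicative
reparameterisation that keeps variance components mixing when they sit
near zero. Fixed effects get independent N(0, 1e8) priors; the posterior
is insensitive to this constant over 1e6–1e10 (tested).

The sampler is blocked Gibbs with conjugate updates, in this order per
sweep: (1) impute each missing response from its bivariate-normal
conditional given the observed twin, with row covariance Σ_e + diag(se²);
(2) draw **all location effects jointly** — β and both sets of levels in
one Gaussian block from the mixed-model equations, with e_i marginalised
into the row covariance. The joint block matters: updating β and the
levels separately mixes extremely poorly here because a grand shift of the
species levels is nearly collinear with the sex intercepts (lag-100
autocorrelations above 0.65 in experiments; the joint block brings lag-1
autocorrelation to ≈0.05). (3) draw the residuals e_i; (4) update the
working scales α and the covariances by inverse-Wishart (2×2 draws via the
Bartlett construction, so the whole chain is driven by one NumPy
generator and is bit-reproducible under a fixed seed).

Tree uncertainty: one chain per tree, seeded seed + tree index, retained
draws concatenated with per-draw provenance — with the default chain
settings (11 000 iterations, burn-in 1000, thin 100 → 100 draws per tree)
and 50 trees this yields the conventional 5000 pooled posterior samples.
Summaries are posterior means with 95% highest-posterior-density
intervals (shortest interval; ties broken by the lowest start).

## Heterogeneity and publication bias

* **I²** uses the typical sampling variance
  s̄² = Σw·(k−1)/((Σw)² − Σw²), w = 1/SE², and per posterior draw
  I²_total = (σ²_ph + σ²_sp + σ²_e)/(σ²_ph + σ²_sp + σ²_e + s̄²), with
  component I² replacing the numerator. Reported as posterior mean + HPD,
  per sex.
* **Egger's test** is run on meta-analytic residuals (observed Zr minus
  fixed-effect fit at the posterior-mean β minus posterior-mean species +
  phylogenetic deviations), per sex: a weighted regression of residual on
  SE with weights 1/SE², whose SE coefficient is the classic Egger
  intercept. When the SEs are all equal this regression is collinear and
  the statistic degenerates to the mean standardised effect, which is what
  the implementation then reports.
* **Trim-and-fill** is the iterative Duval–Tweedie procedure (estimator L0
  by default, R0 selectable): estimate the number k0 of suppressed
  effects from the signed ranks of deviations about the meta-analytic
  centre, trim, re-centre, repeat to convergence, then fill exact mirror
  images of the k0 most extreme effects and report the adjusted weighted
  mean. The centre defaults to the random-effects weighting
  1/(SE² + τ²) with a DerSimonian–Laird τ² re-estimated on each trimmed
  set; with the fixed-effect weights 1/SE² the rank estimators become
  unstable when heterogeneity dwarfs the sampling variances (the trimmed
  centre drifts and k0 can run away — behaviour confirmed identical in an
  independent R implementation). The side is chosen from the sign of
  Egger's intercept unless forced (a positive small-study surplus implies
  suppression on the left). The before/after shift is tested with
  z = (m_orig − m_adj)/√(SE²_orig + SE²_adj), two-sided.
* **Time-lag bias** is the posterior of the mean-centred publication-year
  coefficient; a negative slope means effects decline over time.

## The synthetic-data generator

The generator is the test bed for every stage: it draws a random
ultrametric tree (sequential pair joins at exponential depths — a
Yule-shaped topology — rescaled to unit height), species deviations from
Σ_sp and tree-correlated deviations from Σ_ph, a bivariate residual per
association, and observed effects with exactly the declared sampling noise
1/(n − 3). Missingness uses an RNG stream independent of the structural
draws, so the same seed with different pairing fractions yields identical
underlying effects (this is what makes the missing-at-random vs
missing-the-weaker-sex comparison well-defined). Additional trees for the
phylogenetic-uncertainty pooling are branch-length-jittered copies of the
generating tree.

Default generating values emulate the scale and structure of a large
comparative study of mutually ornamented birds: 64 species; 746
associations of which 235 are observed in both sexes (981 single-sex
effects, 470 in pairs); sex means 0.19 (female) and 0.22 (male) with
small domain offsets (condition above fitness); publication years
1987–2019 with a year slope of −0.006; per-effect sample sizes lognormal
(median ≈ 40, clipped to 10–200); Σ_ph = 0.015, Σ_sp = 0.008,
Σ_e = 0.135 on the diagonal with cross-sex correlations of 0.3 — i.e. a
residual-dominated variance mix giving total I² around 0.85. An optional
publication-bias switch suppresses each negative below-median-n effect
with a chosen probability, and an optional year trend and dimorphism
interaction give the bias detectors and moderator models known signals.

What the generator does **not** emulate: real taxonomic structure or trait
biology, between-study differences in methodology, correlated moderators,
non-Gaussian effect distributions, and selective reporting mechanisms more
subtle than one-sided small-study suppression. Passing tests therefore
demonstrate internal correctness of the estimator and detectors under the
assumed model, not robustness to real-literature pathologies.

## Numerical choices and experiment sizes

* Chains in the test suite are scaled down (hundreds to a few thousand
  iterations) from the 11 000/1000/100 defaults; the coverage experiment
  uses 3000 iterations, burn-in 1000, thin 20 (100 retained draws),
  60 species and ≈600 effects per replicate, 100 replicates.
* The closed-form check pins all three covariances at 1e-12·I, which
  reduces the posterior of β to the inverse-variance GLS solution.
* Correlations |r| within 1e-9 of 1 are clipped to 0.999999 before atanh;
  anything further out is an error (no silent infinities).
* Mann–Whitney U is converted through the large-sample normal
  approximation with no tie or continuity correction, then r = z/√n; the
  convention is recorded in a `conversion_note` column. Chi-square and F
  statistics are convertible only with one (numerator) degree of freedom;
  other rows are rejected with a diagnostic.
* Comparisons between means go through Cohen's d and the unequal-n
  correction r = d/√(d² + (n₁+n₂)²/(n₁n₂)).
* The trim-and-fill recovery experiment uses a "pinned-centre"
  construction — a high-precision symmetric bulk that anchors the
  inverse-variance centre plus low-precision mirrored extremes whose left
  copies are suppressed — and runs with the fixed-effect centre, the
  regime the construction is designed around. Rank-based k0 estimators
  are only informative when the suppressed studies carry little weight in
  the centre estimate; with arbitrary suppression the estimate is
  extremely noisy (verified against an independent R implementation,
  which shows the same behaviour), so the construction, not the
  estimator, is what makes a sharp recovery test possible.
* The Egger power experiment simulates under a zero true mean, where
  suppression of negative small studies produces the strongest funnel
  asymmetry; with a clearly positive true mean few effects are negative
  and the detector's power is intrinsically lower.

## Known limitations

* One chain per tree with a shared design; the alternative of treating the
  tree as a per-iteration random draw is not implemented.
* Egger and trim-and-fill operate on per-effect residuals, not
  study-aggregated values.
* No REML/frequentist path, no model selection, no selection-model or
  PET-PEESE bias corrections.
* Cross-study pairing is supported only through an explicit override
  table; fuzzy label matching is off by default.
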