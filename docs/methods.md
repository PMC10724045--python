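# Methods

This note documents the models, estimators and numerical choices behind
`disconseq`, and what its synthetic validation does and does not establish.

## Disconnectivity scoring

The score for region *p* under a lesion mask is the fraction of the
normative database's streamlines *connected to p* that are *disrupted* by
the mask. Two conventions had to be fixed, since tools in this family differ:

- **Connection = endpoint label.** A streamline connects the regions holding
  its two endpoint voxels (once per distinct label; a loop within one region
  counts once). This matches connectome construction, where a streamline is
  an edge between its endpoint regions. Pass-through membership is not used.
- **Disruption = any traversed voxel lesioned,** endpoints included: a
  lesion anywhere along a tract severs it.

Continuous streamline coordinates (e.g. TRK) are mapped to voxels by
flooring the world-to-voxel transform of each vertex and collapsing
consecutive duplicates; inputs are expected to be densely sampled so that
the vertex chain visits every traversed voxel. Scores are kept as fractions
in [0, 1] everywhere; per cent is a display concern. Regions that no
streamline connects score 0 with a warning (not an error), and subjects
without a lesion of the scored class receive all-zero rows — the convention
for, e.g., rim-lesion scores of subjects who have no rim lesions. The fast
scorer (flattened voxel index + one fancy lookup per mask) is tested for
exact equality against a brute-force voxel-by-voxel oracle.

## Preprocessing

- **Log transform** `log(x + ε)` with ε = 0.01 by default, on the fraction
  scale. Disconnectivity is heavily right-skewed, and Shapiro–Wilk per-region
  checks (exposed as `normality_check`) motivate the transform. ε matters
  more than is obvious: with a tiny ε (say 10⁻⁶) an exact-zero score maps
  ~10 SD below the healthy bulk, and that outlier spike inflates every
  downstream mixture variance — on planted cohorts it alone dropped sequence
  recovery from τ ≈ 1.0 to τ ≈ 0.4. ε = 0.01 sits at the scale of the
  measurement floor (1% disconnectivity) and removes the pathology. It is
  configurable.
- **Group comparison**: pooled-variance (Student) two-sample *t* per region,
  positive when the more-impaired group is higher; two-sided p;
  Benjamini–Hochberg step-up adjustment (via statsmodels, verified against a
  brute-force implementation). Zero-pooled-variance columns give t = 0,
  p = 1 when the group means agree and are flagged undefined otherwise.
  Constant columns are detected by range, not variance, because the two-pass
  variance of a constant column can round to ~10⁻³⁰ and silently produce
  junk t values.
- **Selection**: each of `n_boot` (default 100) bootstraps resamples
  subjects with replacement *within* group, preserving group sizes; regions
  are ranked 1..P by descending signed t (the direction of worsening is
  one-sided by design; a hook switches to |t|), and the `top_k` (default 20)
  smallest mean ranks are kept, ties toward the smaller region index. A
  region with zero within-group variance but unequal means separates the
  groups perfectly and is ranked at the corresponding extreme (±∞) rather
  than discarding the bootstrap. `resample=False` is a test hook that
  reduces the procedure to ranking by the full-sample t.
- **Covariates**: OLS residualization of each selected metric on intercept +
  age + sex (residuals exactly orthogonal to both), applied after selection
  and before the event model.

## The event-based model

### Likelihood

For subject *n* with latent stage *k* (events 1..*k* of order *S* have
occurred), the data likelihood marginalizes the stage:

    P(x_n | S) = Σ_{k=0}^{P} P(k) · Π_{p≤k} P(x_{S(p)n} | E) · Π_{p>k} P(x_{S(p)n} | ¬E)

computed in log space with cumulative sums and log-sum-exp. The stage prior
is uniform over {0..P} by default (configurable as any explicit
distribution); the model is cross-sectional and identifies only the order of
events, never their timing or spacing.

### Mixture estimation

Each region's P(x | E) and P(x | ¬E) are the component densities of a
two-component Gaussian mixture. Three estimation layers are used, in order
of increasing information:

1. **Per-region EM** (`fit_gmm`): pooled data, initialization from group
   means/SDs (the mixture, not the group label, decides final membership —
   mildly impaired subjects may already harbour events). The two components
   **share one variance** by default: unconstrained heteroscedastic 1-D
   mixtures at n of a few hundred are weakly identified, and their ML
   solutions collapse a narrow component onto a sub-cluster of the dominant
   mode, wrecking the event probabilities of regions whose true pathological
   fraction is near 0 or 1. Tying the variances (the homoscedastic "E" model
   in mclust's nomenclature) removes this failure mode. SDs are floored at
   10⁻³ of the column SD; weights clipped to (10⁻³, 1−10⁻³); if EM does not
   converge the initialization fit is returned with a warning flag; fits with
   component separation under 0.2 pooled SD are flagged near-degenerate.
2. **Pooled shared-component initialization** (used by `fit_event_model`):
   all columns are z-scored and their N×P values pooled into one
   tied-variance mixture whose mixing weights differ by group. A single
   column's marginal mixture is essentially unidentifiable when components
   overlap by ~1 SD; the pooled fit pins a shared component geometry that is
   mapped back to every column as a starting point.
3. **Joint refinement**: mixtures and sequence are then alternated —
   E-step: the staging posterior gives each region's event responsibility
   γₙₚ = P(k ≥ pos(p) | xₙ), which aggregates evidence from *all* regions;
   M-step: per-region tied-variance component refit under γ; then the
   sequence is re-optimized warm-started. Iterate until the sequence is
   stable (≤ 8 rounds). This is coordinate ascent on the joint likelihood
   and is what makes ordering recovery possible at 1 SD component
   separation, where oracle densities recover the order almost perfectly but
   any per-region marginal fit fails.

   Two alternatives were evaluated and rejected: multi-start joint
   refinement selected by final likelihood (unreliable — refitted densities
   let wrong orders inflate their own likelihood) and deterministic
   annealing of the likelihood ratios (no measurable gain).

### Search

Greedy steepest-ascent over all P(P−1)/2 position swaps, repeated until no
swap improves the log-likelihood, from 25 random restarts (default).
Swapping positions i < j shifts the stage terms for k ∈ (i, j] by a single
per-subject constant, so a full sweep is scored from prefix/suffix
log-sum-exps in O(N·P²) rather than O(N·P³). Ties break first-found, then
lexicographic. An exhaustive enumerator (guarded to P ≤ 8) serves as the
optimality oracle; the greedy search attains its maximum on 100/100 random
instances at P = 5 and is deterministic given a seed. MCMC was deliberately
omitted: the exhaustive oracle covers correctness at small P and planted
recovery covers P = 20.

### Uncertainty and staging

The full data set yields the reported sequence. Each of `n_boot` (default
100) stratified bootstrap resamples refits all mixtures and re-optimizes the
order, warm-started from the full-data sequence with 2 extra random restarts
(warm-starting changes no result on planted cohorts and halves the cost).
Row *r* of the positional-variance matrix is the empirical distribution of
region *r*'s position over bootstraps (rows sum to 1); the event centre is
the mean 1-based bootstrap position and its SE the bootstrap SD/√n_boot.
The randomness test takes, per region, the frequency of occupying its
final-sequence position across bootstraps and compares the P frequencies
against 1/P with a one-sample Student t (one-sided p for mean > 1/P reported
alongside two-sided; all-equal frequencies at exactly 1/P give t = 0, other
zero-variance cases are flagged degenerate). Staging returns each subject's
posterior over {0..P} under the final model; probabilities are floored at
10⁻¹² so log-space arithmetic stays finite — this touches likelihoods only
for extreme outliers.

## Synthetic data

The generator's defaults define the validation conditions: 482 subjects,
86 regions, 103/482 in the more-impaired group; healthy component mean 0.05,
SD 0.03, pathological mean 0.11 (2 SD separation), SD 0.03 on the fraction
scale; group 0 stages from a discrete triangular distribution favouring low
stages, group 1 favouring high stages (severity correlates with stage but
stage stays latent); age ~ U(25, 60), sex ~ Bernoulli(0.7), optional linear
covariate effects (age centred at 42.5 years so slopes do not saturate the
clip); values clipped to [0, 1] because disconnectivity is a fraction. All
draws are determined by one seed.

The geometric level realizes the same planted order as lesions: cubic
parcellation blobs on a lattice, straight densely-voxelized streamlines
between blob pairs (every region covered), and per-region "critical voxel
sets" — streamline voxels excluding all labelled blobs — so masks model
white-matter damage, not grey-matter removal. A subject at stage k receives
the union of the first k critical sets plus optional noise voxels outside
every critical set.

What passing on these cohorts shows: the estimator recovers a planted
ordering under the model's own assumptions at realistic n, and the whole
pipeline is deterministic and internally consistent. What it does not show:
robustness to real lesion morphology (periventricular clustering, lesion
growth), non-Gaussian biomarker noise, registration error, or heterogeneity
of effect size across regions — the pooled initialization assumes rough
comparability of per-region dynamic ranges, which log-transformed,
residualized metrics approximate but real data may not.

## Pipeline

Order of operations: score → log transform → group t-tests + BH →
bootstrapped top-k selection (on logged values) → covariate residualization
of the selected columns → event model with bootstrap → randomness test →
staging. One master seed spawns independent per-stage seeds
(`numpy.random.SeedSequence`), so identical config + seed reproduces every
artifact byte for byte; the provenance block records a hash of the analysis
config (output location excluded), the seed and library versions. Each stage
failure aborts with a stage-tagged error. For two lesion-mask classes the
matrix is the 2P-column concatenation of per-class scores
(`class:region` namespacing, zero rows for subjects lacking a class; overlap
between classes warns, since classes should partition lesions) and the
downstream processing is unchanged.

## Problem sizes used in validation

Unit and acceptance tests run at the scales the estimators are designed
for: sequence recovery at P = 20, N = 480 over 10 seeds per separation;
selection recovery at 86 regions, n = 400, 100 bootstraps, 20 seeds;
randomness-test behaviour at P = 10, N = 240, 100 bootstraps with 3 SD
(strong) vs 0 SD (noise) separation; disconnectivity oracle equality on 50
random toy databases; end-to-end determinism at P = 20, N = 200, 10
bootstraps. The acceptance script reruns all of these from a single seed.

## Known limitations

- Timing is unidentifiable by design; only order is estimated.
- The event model assumes a single common ordering across subjects; mixtures
  of progression subtypes are out of scope.
- One normative streamline database is the contract; averaging over many
  healthy-control connectomes (as normative-disconnectome tools do at scale)
  is not implemented.
- The tied-variance mixture trades flexibility for identifiability; markedly
  heteroscedastic biomarkers are fit only approximately
  (`fit_gmm(tied_sd=False)` restores the unconstrained fit).
- Greedy swap ascent guarantees only local optimality for P > 8, mitigated
  by restarts and joint refinement.
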