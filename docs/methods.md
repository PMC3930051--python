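# Methods

`aflpscape` reimplements, as one tested pipeline, the analytical chain
used in small landscape-genetics surveys of dominant AFLP markers
sampled across an environmental gradient: within-population diversity,
hierarchical structure (AMOVA, UPGMA), distance-matrix mixed models
with parametric-bootstrap inference, permutational matrix regression,
three candidate-locus selection scans, and locus–phenotype
correlation.  This note records the models, the defaults and why they
were chosen, the numerical decisions, and what the synthetic-data
generator does and does not emulate.

## Dominant-marker model

An AFLP locus is scored per plant as band present (1) or absent (0).
The presence allele has frequency `p`, the recessive null allele
`q = 1 − p`; under Hardy–Weinberg equilibrium a plant shows the band
with probability `1 − q²`.  Within-population inbreeding is assumed
absent (F_IS = 0) throughout — the same assumption the standard He
calculation for dominant data makes.  Two null-frequency estimators
are provided:

* `sqrt`: `q̂ = √(absent/n)` — the plug-in estimator used by common
  diversity calculators; the default for P%, uHe and Nei distances.
* `bias_corrected` (off by default): the sqrt estimator with a
  second-order Taylor bias correction,
  `q̂ = √x · (1 + (1−x)/(8nx))` for absent fraction `x` — small-sample
  dominant-marker estimates are biased downward and this flag undoes
  most of it; kept off by default so the default chain matches the
  conventions of the common diversity calculators.
* `bayes_uniform`: the posterior mean of `q` under a uniform prior
  with `absent ~ Binomial(n, q²)`.  Substituting `u = q²` gives the
  exact closed form `E[q|a,n] = B(a+1, n−a+1) / B(a+½, n−a+1)`,
  evaluated with log-Beta functions.  It is strictly inside (0, 1) for
  any finite sample — required by the F_ST scans, where fixed
  estimated frequencies would degenerate — and converges to the sqrt
  estimator as n grows.

## Diversity and structure

* **P%**: a locus is polymorphic in a population when `p̂` lies
  strictly inside (1 − level, level); level defaults to 0.99.
* **uHe**: per locus `2 p̂ q̂ · 2n/(2n−1)`, averaged over loci.
* **Nei (1972) distance** treats each dominant locus as biallelic,
  with the locus-summed identity form; population pairs sharing no
  alleles get a finite sentinel (1e3) instead of +∞.
* **UPGMA** is implemented directly (average linkage on Nei
  distances) because a deterministic tie rule is part of the contract:
  tied merge heights are broken by the lexicographically smallest pair
  of cluster leaf-label tuples.  Node support comes from resampling
  loci with replacement (B = 1000 by default), recomputing distances
  and trees, and counting recovered bipartitions — individuals are
  never resampled.
* **AMOVA** works on squared individual distances: the count of loci
  with differing calls among jointly scored loci, rescaled by
  `L/shared` (unbiased under missing-at-random scoring).  Variance
  components use the standard unequal-sample-size coefficients; the
  three-level design yields Phi_CT / Phi_SC / Phi_ST.  Permutation
  schemes: individuals among populations (Phi_ST), whole populations
  among groups (Phi_CT), individuals among populations within groups
  (Phi_SC); `p = (1 + #{perm ≥ obs}) / (n_perm + 1)`.  Negative
  pairwise Phi_ST estimates are reported as-is and only clamped at the
  linearization step.

## Distance-matrix mixed model

Pairwise genetic distances are linearized as `Phi/(1 − Phi)` (Phi
clamped to [0, 0.999]; negative estimates are sampling noise),
geographic distances as `ln(max(km, 0.1))` (the 0.1 km floor avoids
ln 0 for nearly co-located sites), and environmental distances as
Euclidean distances over the first four axes (configurable) of a
correlation-matrix PCA of the site variables.  Population substructure
enters as a *random intercept over pair categories* — within-cluster,
between-cluster, admixed-involved (a 3-level pooling; a per-cluster
5-level split is available via ``fine_categories``).  Because a
variance component estimated from three levels is weakly identified,
``category_mode="fixed"`` offers a sensitivity fit with the categories
as fixed dummy contrasts instead.  The model on the unfolded 36-pair vector is

    y = Xβ + Z u + ε,   u ~ N(0, σ_u² I),   ε ~ N(0, σ² I)

fitted by **ML** (not REML), because the inferential target is a
likelihood-ratio comparison of fixed-effect structures.  The
likelihood is profiled over the variance ratio λ = σ_u²/σ²: one
eigendecomposition of `ZZᵀ` reduces each profile evaluation to
diagonal weighting, and a bounded scalar optimization over `log λ`
(tolerance 1e-10, with the σ_u² = 0 boundary checked explicitly)
returns the fit.  A dense-GLS evaluation of the same likelihood is
used as an independent oracle in the tests (agreement 1e-6).  R² is
the squared correlation of observed and fitted values, with fitted
values including the BLUP random effects — note this measure can move
by tiny amounts in either direction when a fixed effect is added,
because BLUP shrinkage changes too.

Fixed effects are tested by **parametric bootstrap**: fit the reduced
model, simulate B responses from it (fresh `u*` and `ε*` at the
estimated variances), refit both models to each simulated response,
and compare the observed `2Δℓ` with the simulated distribution,
`p = (1 + #{LR* ≥ LR}) / (B + 1)`.  The observed and simulated LR are
clipped at 0 (nested ML fits give LR ≥ 0 up to optimizer tolerance).

## Matrix regression

MRM unfolds lower triangles, fits OLS, and permutes the dependent
matrix's rows and columns jointly, refitting per permutation;
coefficient p-values are two-sided on |coefficient|, the R² p-value
upper-tailed.  Forward stepwise selection adds, at each step, the
candidate with the largest R² increase if its permutation p-value
(refitting current + candidate under permutations of y) is at most
P-to-enter (0.05 default).  The partial Mantel statistic is the
Pearson correlation of the two residualized matrices (each regressed
on the controls); significance permutes the residualized first matrix
(residual-permutation method — the variant is not universally
standardized, so it is fixed and documented here).  Genetic-cluster
control enters as a 0/1 same/different-cluster dissimilarity with
admixed populations coded 0.5 to both clusters (configurable).

## Selection scans

All scans run on the loci polymorphic in the total sample (99% level)
and estimate allele frequencies with `bayes_uniform`.

**Per-locus F_ST** is the variance-partition (ANOVA) theta computed
from the estimated frequencies and per-cell sample sizes; He is
`2 p̄ q̄` at the pooled mean frequency; the global mean is the
untrimmed arithmetic mean.

**F_ST outlier scan.**  The neutral reference is a symmetric island
approximation: ancestral frequencies Uniform(0.01, 0.99), population
frequencies Beta-distributed around them with a common F, dominant
phenotypes binomially sampled at the observed per-population sample
sizes, loci monomorphic in the sample rejected, and the *same
estimation path* applied as to real data.  F is calibrated by
bisection (common random numbers per evaluation) so the simulated mean
F_ST matches the observed untrimmed mean.  The (He, F_ST) cloud is
binned into 20 equal-width He bins (bins with fewer than 1000
simulated loci merge rightward); the conditional envelope quantile is
monotone-smoothed across bins; the per-locus p-value is the upper tail
mass of the locus's He bin, and candidates satisfy
`p ≤ 1 − envelope_quantile` (0.99 default).  Only the upper
(divergent) tail flags candidates; the lower tail is reported
informationally.  With iterative removal the target mean is recomputed
without current candidates and the scan repeated (≤5 rounds); each
locus keeps the p-value from the round in which it was flagged.  This
Beta-model engine intentionally replaces a coalescent simulator: it
preserves the He-conditional envelope logic and the trimming
iteration at desk scale, and is validated by calibration (neutral flag
rate ≈ 1%) rather than by matching any particular program's output.
The `theta` parameter (0.018 default) is accepted for interface
fidelity; in this approximation it only conditions the polymorphism
screening of simulated loci, consistent with the observation that the
scan is insensitive to it over a tenfold range.

**Bayesian locus-effect decomposition.**  Locus-by-population F values
decompose on the logit scale as `logit(F_ij) = δ_i α_i + β_j`, with
population effects β_j ~ N(−1, 1), locus effects α_i ~ N(0, 1) gated
by inclusion indicators δ_i with prior odds 1:10, latent population
frequencies `p_ij ~ Beta(θ_ij p_i, θ_ij (1 − p_i))`,
`θ_ij = (1 − F_ij)/F_ij`, uniform ancestral frequencies p_i, and the
dominant absence likelihood `Binomial(n_ij, (1 − p_ij)²)`.  Sampling
is random-walk Metropolis within Gibbs, fully vectorized across loci;
the locus-effect toggle is indicator-variable (Kuo–Mallick-style)
selection — α_i is retained and refreshed from its prior while
excluded — which realizes the same inclusion/exclusion move as a
transdimensional sampler with a fixed-dimension state.  Proposal
scales adapt toward ~30% acceptance during burn-in.  A locus's
q-value is the mean of (1 − PIP) over all loci with PIP at least its
own (the expected false-positive fraction at that cutoff; monotone in
PIP by construction); candidates satisfy q ≤ 0.05.  Mixing is
monitored with split-R̂ of the population effects (warning above 1.2).

**Logistic environmental association.**  For each polymorphic locus ×
predictor (typically the first two environmental PCA axes, broadcast
from sites to individuals), a univariate logistic regression is fitted
by vectorized IRLS (tolerance 1e-8).  Both a Wald test (slope/SE) and
a G-test (2Δℓ against intercept-only, 1 df) are computed; an
association is significant only when *both* fall below the Bonferroni
threshold `alpha/m`, `m = #loci × #predictors` (e.g. 186 × 2 = 372
models gives 0.01/372 ≈ 2.69e-5).  Complete separation (diverging
slope) flags the locus unstable and excludes it from the significant
set.  Caveat: the test treats individuals as independent, so genuine
population structure (drift) inflates its error rate — a known
property of this scan family, visible in the package's own
calibration experiments; the Bonferroni level is honest only under
exchangeability of individuals.

**Consensus and trait correlation.**  Candidates are merged across
methods with per-method flags and counts.  Candidate-locus band
frequencies are correlated with population trait means; within each
experiment, traits are greedily pruned until no pair exceeds |r| >
0.7 (dropping the trait with the larger mean absolute correlation to
the rest), then Pearson r with two-sided t-tests and Holm correction
across all tested pairs (Bonferroni by flag).  With only nine
populations, chance inter-trait correlations above 0.7 are common, so
pruning can occasionally remove a genuinely associated trait; the
reproduction script therefore reports the designated locus–trait pair
with pruning disabled.

## Cluster surrogate

Downstream stages take population cluster labels as explicit input
(the faithful path when labels come from external Bayesian clustering
software).  When none are supplied, k-means on population
band-frequency vectors (K chosen by silhouette over 2–6) provides a
deterministic surrogate.  A population is flagged admixed when the
ratio of its distances to the two nearest centroids exceeds 0.6:
binomial noise at n ≈ 15 floors every population's ratio near 0.4 and
caps a 50/50 mixture's ratio near 0.8, so 0.6 cleanly separates the
regimes (the cutoff is configurable).

## Synthetic-data generator

The generator is first-class, tested code; its defaults *are* the
emulated study conditions: 9 populations (2 clusters × 4 + 1 admixed)
of 15 plants, 229 dominant loci, F_CT = 0.08 and F_SC = 0.06 (the
magnitudes a hierarchical AMOVA attributes ~8%/6% of variance to),
ancestral frequencies Beta(0.8, 0.8) (giving ~60–65% polymorphic loci
per population and uHe ≈ 0.2, matching a typical AFLP survey), 2%
missing calls, 15 replicate pairs with flip probability 0.0078
(a 0.78% mismatch rate), 3 loci under divergent selection with logit
slope 2 along the standardized climate score, and population trait
means driven by environment plus one trait-linked locus
(stem-trichome score, coefficient 3.0 on the band-frequency scale,
noise 0.35 — yielding |r| ≈ 0.95 for the planted pair).

Frequencies follow a two-level Balding–Nichols Beta cascade — chosen
over coalescent simulation because it matches exactly the moment
structure AMOVA and F_ST estimators measure, is fast, and is seedable
to byte-identical output.  The admixed population is a 50/50 *frequency*
mixture of one donor population per cluster (individual-level
admixture is out of scope).  Planted loci are drawn among loci with
intermediate ancestral frequency (0.2–0.8): dominant masking makes
selection at near-fixed loci unobservable at n = 15, and real scans
only see markers that were scorable in the first place.  Sites sit on
a 1-D latitude gradient; climatic variables are linear in latitude
plus noise, edaphic variables follow a second gradient correlated
with climate at 0.5 (configurable), and the net-house experiment
zeroes the environmental trait responses (an insect-free, pot-grown
environment expresses no field response), mirroring the plasticity
contrast between a common garden and a controlled net-house.

What the generator does **not** emulate: linkage/LD among loci,
spatially explicit dispersal, individual-level admixture,
non-equilibrium demography (bottlenecks, expansions), scoring
artifacts beyond symmetric flips, and F_IS ≠ 0.  Tests passing on
this generator therefore certify the *estimators and inference
machinery* under the stated model, not robustness of the scans to
realistic demographic confounding — the hierarchical-structure
false-positive problem of island-model outlier scans is real and is
deliberately visible here (the fdist scan flags ~1.7% of loci at the
0.99 envelope under a neutral hierarchy, and more when clusters are
strong).

## Problem sizes used in the test suite

Calibration and power suites run at deliberately modest sizes chosen
as a sensible desk-scale compromise: fdist calibration 20 replicates ×
1000 loci with 10,000 simulated loci per envelope; bootstrap-LMM
calibration 200 outer replicates × B = 199; env-effect power 100
replicates; fdist power 15 replicates; three-method consensus 12
replicates with 5000-iteration chains; Bayesian-scan FDR 20
replicates × 200 loci with 3000-iteration chains.  Estimator
consistency is checked at n = 2000 individuals (tolerance 0.02).

## Known limitations

* The Bayesian scan's chains are short by production standards;
  split-R̂ warnings should be heeded and chains lengthened for real
  analyses.
* The logistic association scan inherits the pseudo-replication
  problem described above.
* AMOVA permutation p-values use the full distance matrix and are
  O(n_perm · N² · P); fine at survey scale, not optimized for
  thousands of individuals.
* The fdist engine is an island-model approximation: its p-values are
  calibrated against its own neutral model, not against a coalescent
  with the data's true demography.
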