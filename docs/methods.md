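# Methods

This note documents the statistical procedures `fragbeta` implements, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data tests do and do not demonstrate about real data.

## Diversity partitioning

**Alpha and gamma.** Diversity is measured throughout as the Hill number
of order 1 — the exponential of Shannon entropy on relative abundances
(natural logarithm), in units of effective species.  γ applies the same
estimator to the column sums of all sites in a fragment.  Two estimators
are available: the plug-in `exp(-Σ p ln p)` (default of the low-level
functions) and the Chao–Shen coverage-adjusted Horvitz–Thompson estimator
(`bias_correction="chao_shen"`, the pipeline default), which multiplies
the observed shares by the estimated sample coverage `C = 1 − f₁/n` and
weights each term by the probability of having observed the species at
all.  No particular bias-correction method is canonical for this kind of
survey data; Chao–Shen is the standard ecological choice, and the toggle
isolates its effect.  A corrected α can exceed the observed richness and,
rarely, the fragment γ.

**Proportional β.** `β = 1 − α/γ`, the multiplicative partition
expressed as turnover.  It is deliberately *not* clamped: a negative
value (bias-corrected α above γ) is reported with a warning rather than
truncated, so pathologies stay visible.

**The null model.** `β_dev` standardizes β_obs against randomizations
that hold each species' *occurrence frequency* fixed: per species,
independently, the set of occupied sites is redrawn uniformly among
equally-sized site subsets and the observed positive abundances are
permuted onto it.  Occupancy counts, species totals — and therefore
column sums, the grand total and γ — are conserved exactly; per-site
richness and evenness are not.  γ is nevertheless recomputed inside each
randomization (a toggle exists) so variant nulls that break column-sum
conservation remain correct.  An incidence-only variant
(`incidence_only=True`) reduces the matrix to presence/absence first.
With the default abundance-preserving null, β_dev on data generated by
the null itself is centred at 0 with standard deviation ≈ 1 (verified by
simulation in the acceptance suite).  `n_rand` defaults to 999; the
standardization uses the sample SD (ddof = 1) of the null β values, and a
site whose null SD is zero gets a missing β_dev with a warning.

## Differentiation diversity

**Dissimilarity.** Bray–Curtis `Σ|x−y| / Σ(x+y)` on raw or square-root
transformed abundances (default sqrt, which tempers the influence of
hyperabundant species).  Internally everything is a dissimilarity;
"similarity" inputs must be converted by the caller.

**PCoA.** Gower double-centring of −½D², symmetric eigendecomposition,
eigenvalues reported in descending order.  Negative eigenvalues (Bray–
Curtis is a semimetric) are reported but their axes are excluded from the
coordinates; no Lingoes/Cailliez correction is applied.

**PERMANOVA.** McArdle–Anderson partitioning: sums of squares are traces
of hat-matrix products with the Gower-centred matrix, terms entered
sequentially (Type I) in user order, pseudo-F against the full-model
residual.  p-values permute rows/columns of the dissimilarity matrix
simultaneously and count the observed statistic in numerator and
denominator, so p > 0 and the test is valid by construction.  When `n!`
does not exceed the requested permutation count (or 720, whichever is
larger), all `n!` permutations are enumerated and the p-value is exact —
on six sites this reproduces brute-force enumeration over the distinct
group relabellings, which the test suite checks.

**CAP (db-RDA).** Predictors are z-transformed; the PCoA coordinates on
non-negative axes (scaled by √eigenvalue, so their inner products equal
the centred matrix restricted to those axes) are regressed on the
predictors.  Each term's explained variation is its sequential SS as a
fraction of the total inertia (sum of positive eigenvalues); inference
uses reduced-model residual permutation: for term *j* the fitted part of
the model with terms 1..j−1 is kept and its residuals permuted.  Only
sequential term tests are implemented; a marginal-terms mode was left out
to keep one inference path (callers can reorder predictors or fit
single-predictor models to assess marginal importance, as the acceptance
suite does).  Collinear predictor sets (condition number > 1e8) are
rejected with the offending pair named.

**Multivariate dispersion.** Per site, Sørensen distances among
vegetation subplots are embedded by PCoA and the mean distance of
subplots to their centroid is returned, subtracting the squared
contribution of negative-eigenvalue axes (the standard dispersion
procedure for semimetric distances).  Note a counterintuitive fact,
confirmed by brute force: duplicating a *single* subplot can slightly
*increase* this dispersion (the centroid shifts, the other subplots'
distances grow); only duplicating the whole subplot set is guaranteed to
leave it unchanged.  The tests assert the true properties.

## Indicator species

IndVal per species × group: specificity `A = mean abundance in g / Σ
group mean abundances` (unweighted per-site means, robust to unequal
group sizes), fidelity `B = occupied fraction of g's sites`, statistic
`max_g A·B`, tested by permuting site-group labels; exact enumeration of
all distinct label assignments when there are at most ~1000.  No
multiple-testing correction is applied inside the module; the pipeline
applies BH-FDR table-wise on request.

## Environmental predictors

**PCQ forest structure.** Density uses Pollard's unbiased
point-centered-quarter estimator, `λ̂ = 10⁴·4(4n−1)/(π Σ d²)` trees/ha
over n complete points (the classic Cottam–Curtis mean-distance form is
available via `estimator="cottam"` for comparison).  Points missing a
quarter are excluded with a warning.  Basal area per tree is `π(dbh/2)²`
(cm²); per-class cover (deciduous vs conifer) multiplies the class's
density share by its mean basal area, so the two covers sum exactly to
density × overall mean basal area (in m²/ha).

**Ellenberg means.** Unweighted means over the species present at a
site, skipping species with a missing value for that index; a site with
no scorable species yields a missing value with a warning.

**Functional dispersion.** Gower distance on the mixed trait table
(range-normalized numeric differences, 0/1 categorical mismatches,
missing values dropped pairwise), PCoA embedding of the species present
at the site, FDis = mean distance to the centroid with the
negative-axis correction.  Species are equally weighted because the
vegetation data are incidences; abundance weighting is a parameter away
if abundance data exist.

**Landscape metrics.** Habitat diversity is the Shannon index (natural
log) of the renormalized natural-habitat fractions {forest, reed,
grassland} only — water and human-modified classes are excluded from the
diversity by design.  Edge density divides boundary length by buffer
area (π r²·10⁻⁴ ha); the modified-areas fraction sums agriculture and
urban/industrial cover; distances pass through.

**Varimax PCA.** Correlation-matrix PCA (the variables mix units, so
covariance PCA would be dominated by scale); axes retained by the strict
Kaiser criterion (eigenvalue > 1.00); normalized varimax rotation
(Kaiser normalization) of the retained loadings; site scores by the
regression method (`Z R⁻¹ Λ_rot`); rotated axes reordered by explained
variance and signed so each axis's largest-magnitude loading is
positive, making scores reproducible.  Rotation preserves per-variable
communalities and total explained variance (asserted to 1e-8).  The
rotation uses the standard one-step-SVD iteration; its convergence is
linear and can need a few thousand (microsecond) sweeps near-degenerate
cases, so the sweep cap is 20000 at tolerance 1e-6 and non-convergence
is an error.  Axis *names* are user metadata — interpretation is never
inferred from loadings.

## Screening and linear models

Mann–Whitney U uses the normal approximation with tie correction and
(by default) continuity correction, returning the signed z; the
approximation stays within 0.02 of the exact p for group sizes ≥ 8
(asserted by simulation).  BH-FDR is the textbook step-up procedure
(via statsmodels), applied table-wise.  β_dev models are ordinary least
squares — no random-effect structure is posited for 30 sites per
fragment; a fragment fixed effect can be added as a predictor.
Stepwise selection starts from the full additive model, evaluates all
single-term additions and removals, moves to the lowest AIC (Gaussian
likelihood with constant, k = 2) and stops at a local optimum; AIC ties
break toward the smaller model, making the search deterministic.
Standardized coefficients are `b·sd(x)/sd(y)`.

## Synthetic scenarios

The generator emulates a paired-reserve light-trapping design: two
fragments × 30 sites, a 392-species pool with log-normal base
abundances, Gaussian niche responses to latent site gradients, a
between-fragment composition shift, Poisson counts.  Expected counts are

    λ_ik = effort_i · base_k · m_k(fragment_i) · Π_g exp(−(x_ig − o_kg)² / 2t²)

Defaults were calibrated once against the design's published scale and
then frozen: `base_k ~ LogNormal(0.2, 1.8)` with two latent gradients
(a humidity–nutrient gradient with a between-fragment mean shift of 1.0,
and a succession gradient; niche tolerance 0.7, optimum spread 1.4) and
a two-fold composition shift on 30% of the species.  One default
scenario draw yields ≈ 22–25k individuals, ≈ 330 observed species with a
long singleton tail (~10–13% of the pool), per-site α in the mid-30s,
fragment γ near 60–70 effective species, mean proportional β ≈ 0.4–0.5,
and a fragment PERMANOVA R² ≈ 0.07–0.10 at p ≤ 0.01 — the scale of the
motivating field system.  The composition shift is applied symmetrically
(half of the affected species boosted in each fragment): boosting only
one fragment systematically depresses that fragment's evenness and hence
its γ, which contradicts the target system's roughly equal fragment
γ values.

Observed environmental variables are linear in the latent gradients plus
Gaussian noise with declared loadings and group offsets; plant surveys
(incidence, traits, Ellenberg values, subplots), point-centered-quarter
records (nearest-tree distances drawn from the exact Poisson-forest law
`P(D>d) = exp(−λπd²/4)` per quarter) and landscape buffer tables are
simulated alongside.  `ScenarioTruth.null_scenario()` zeroes *every*
between-fragment effect, making the fragments exchangeable by
construction — this is the null oracle used to calibrate the type-I
error of the whole pipeline.  `degrade_sites` binomially thins a
fraction of species at chosen sites, planting the subtractive-
heterogenization signature (higher proportional β at impoverished
sites).

**What the synthetic tests do not show.** The generator has no spatial
autocorrelation, no phenology or between-year structure, no
overdispersion beyond Poisson (a toggle point for future work), and its
environmental variables are cleanly linear in the latent gradients.
Passing calibration and recovery tests therefore demonstrates the
correctness and statistical validity of the machinery under the stated
model — not robustness to the messier dependence structures of field
data.

## Pipeline and reproducibility

`run_study` executes: species-pool overlap → environmental screening
(Mann–Whitney + table-wise BH-FDR) → four varimax PCAs (local and
landscape variable sets per fragment) → diversity partition with β_dev
per fragment (+ Mann–Whitney comparison of β between fragments) →
stepwise-AIC β_dev models on the PC scores → between-fragment PERMANOVA
→ per-fragment CAP on the leading local and landscape axes → IndVal.
Every stochastic stage receives a sub-seed derived from the run seed, so
identical config + seed reproduces the output bundle byte for byte (the
manifest records seed and config hash).  The first failing stage raises
a named error; earlier tables are still written and the manifest marks
the run incomplete.  Analysis sizes in the test and acceptance suites
are scaled-down versions of the same machinery (e.g. 8-site fragments
with 60 species for the 500-replicate calibration, 199 randomizations
for β_dev validity); the statistical claims they assert are
size-calibrated accordingly (binomial confidence bounds, Monte-Carlo
tolerances).

## Known limitations

- Sequential (Type I) term tests only, in PERMANOVA and CAP; term order
  matters and is the caller's choice.
- No NMDS, no phylogenetic (UniFrac-type) distances, no additive
  diversity partitioning, no Hill orders beyond q = 0/1.
- OLS only for β_dev models; no spatial or mixed-effect error
  structures.
- The Chao–Shen correction assumes counts of individuals; it refuses
  non-integer data.
- Single-subplot-duplication monotonicity of multivariate dispersion
  does not hold (see above) — a property of the method, not a bug.
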