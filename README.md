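# fragbeta

Beta-diversity partitioning and community analysis for fragmented insect
assemblages.

`fragbeta` is built for the question a community ecologist faces when one
historic habitat has been split into isolated reserve fragments: how do the
assemblages (here, nocturnal moths sampled by light traps) differ between
fragments, and which local and landscape factors structure the variation
inside each one?  It bundles, behind one consistent data model, the full
analysis chain that this kind of study needs:

- **Diversity partitioning.** Per-site α as the exponential Shannon
  diversity (Hill number of order 1, optionally with the Chao–Shen
  coverage correction), pooled γ per fragment, and proportional
  β-diversity **β = 1 − α/γ** — the fraction of regional diversity a local
  community fails to represent.  Because all sites of a fragment share one
  γ, observed β is standardized against a null model with fixed species
  occurrence frequencies: **β_dev = (β_obs − β̄_null)/SD_null** over (by
  default) 999 matrix randomizations.
- **Differentiation diversity.** Bray–Curtis dissimilarities on
  square-root-transformed abundances, PCoA, PERMANOVA (sequential
  McArdle–Anderson partitioning with permutation pseudo-F tests, exact
  enumeration on tiny designs), and constrained analysis of principal
  coordinates (CAP / db-RDA) with per-predictor explained variation.
- **Indicator species.** Dufrêne–Legendre IndVal = specificity ×
  fidelity per species × fragment, with permutation (or exact) p-values.
- **Environmental predictors.** Point-centered-quarter forest structure
  (Pollard's unbiased density estimator), mean Ellenberg indicator values,
  functional dispersion from Gower trait distances, landscape buffer
  metrics (habitat Shannon diversity, edge density), and condensation of
  variable sets into varimax-rotated principal components retained by the
  Kaiser criterion.
- **Screening and models.** Mann–Whitney U comparisons with
  Benjamini–Hochberg FDR, and stepwise-AIC ordinary-least-squares models
  of β_dev on PC-axis scores.
- **Synthetic scenarios.** A generator for two-fragment communities with
  a log-normal species pool, Gaussian niche responses to latent
  environmental gradients, a planted between-fragment composition shift
  and Poisson sampling noise — with the ground truth recorded, so the
  whole pipeline can be calibrated (type-I error) and power-tested
  (planted-effect recovery) end to end.

## Worked example

```python
from fragbeta import (ScenarioTruth, generate_scenario, beta_dev,
                      bray_curtis, permanova)

data = generate_scenario(ScenarioTruth(seed=42))   # 2 fragments x 30 sites
cm = data.community

part = beta_dev(cm, "A", n_rand=999, seed=1, bias_correction="chao_shen")
print(part.table.head(3).round(3))

dm = bray_curtis(cm, transform="sqrt")
print(permanova(dm, cm.group.rename("fragment"), n_perm=999, seed=2).table.round(3))
```

prints

```
      alpha   gamma  beta_obs  beta_null_mean  beta_null_sd  beta_dev
A01  15.441  45.627     0.662           0.347         0.192     1.637
A02  27.700  45.627     0.393           0.332         0.193     0.314
A03  35.579  45.627     0.220           0.328         0.195    -0.552

            df      SS     R2  pseudo_F      p
fragment   1.0   1.052  0.091     5.793  0.001
Residual  58.0  10.537  0.909       NaN    NaN
Total     59.0  11.590  1.000       NaN    NaN
```

Site A01 holds 15.4 effective species against a fragment pool of 45.6, so
two thirds of the fragment's diversity is missing locally (β_obs = 0.66);
that deficit is 1.6 null standard deviations above what random assembly
with the same species occurrence frequencies would produce (β_dev = 1.64).
The PERMANOVA row says fragment identity explains 9% of the community
variation (pseudo-F = 5.79, p = 0.001 over 999 permutations) — the two
fragments host distinctly composed assemblages.

The same workflow runs from the shell:

```sh
fragbeta simulate --seed 7 --out demo/
fragbeta run --config demo/config.yaml
```

which writes the full result bundle (screening table, four PCAs,
partition, β_dev models, PERMANOVA, CAP, IndVal) as CSVs plus a JSON
manifest recording the seed and config hash.  Single stages are exposed as
`fragbeta partition|permanova|cap|indval|pcq`.

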