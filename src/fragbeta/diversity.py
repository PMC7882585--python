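"""Diversity partitioning: Hill-number diversity, proportional beta and
its null-model standardization.

The partition follows the multiplicative scheme on the Hill number of
order 1 (exponential Shannon diversity, "effective species").  Per-site
alpha is exp(H) of the site's relative abundances; gamma is the same
quantity on the abundances pooled over all sites of a group; proportional
beta is

    beta = 1 - alpha / gamma,

the fraction of the regional (group) diversity that the local community
does not represent.  Because every site's beta shares the same gamma, the
observed values are standardized against a randomization null with fixed
species occurrence frequencies:

    beta_dev = (beta_obs - mean(beta_null)) / sd(beta_null).

The null model redraws, independently per species, the set of occupied
sites uniformly among equally-sized site sets and permutes the species'
positive abundances onto them, conserving per-species occupancy and total
abundance exactly (hence also gamma, per randomization).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CommunityMatrix, ValidationError

logger = logging.getLogger("fragbeta")

__all__ = [
    "hill_shannon",
    "hill_richness",
    "gamma_diversity",
    "proportional_beta",
    "null_randomize",
    "beta_dev",
    "DiversityPartition",
    "overlap_summary",
]


def _shannon_rows(x: np.ndarray, bias_correction: str) -> np.ndarray:
    """Shannon entropy (nats) for each row of a counts matrix."""
    x = np.asarray(x, dtype=float)
    n = x.sum(axis=1, keepdims=True)
    if np.any(n <= 0):
        raise ValidationError("all-zero abundance vector")
    if bias_correction == "none":
        p = x / n
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, -p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        return terms.sum(axis=1)
    if bias_correction == "chao_shen":
        if np.any(x != np.round(x)):
            raise ValidationError("chao_shen correction requires integer counts")
        f1 = (x == 1).sum(axis=1, keepdims=True).astype(float)
        # sample coverage estimate; a sample that is all singletons would give
        # C = 0, degrade gracefully to (n-1)/n coverage in that case
        C = 1.0 - f1 / n
        C = np.where(C <= 0, (n - 1.0) / n, C)
        C = np.where(C <= 0, 1.0, C)  # n == 1 single individual
        p = C * x / n
        with np.errstate(divide="ignore", invalid="ignore"):
            ht = np.where(
                p > 0,
                -p * np.log(np.where(p > 0, p, 1.0)) / (1.0 - np.power(1.0 - p, n)),
                0.0,
            )
        return ht.sum(axis=1)
    raise ValueError(f"unknown bias_correction {bias_correction!r}")


def hill_shannon(counts, bias_correction: str = "none") -> float:
    """Exponential Shannon diversity (Hill number of order 1).

    Parameters
    ----------
    counts
        Species abundance vector (non-negative, at least one positive).
    bias_correction
        ``"none"`` for the plug-in estimator exp(-sum p ln p), or
        ``"chao_shen"`` for the coverage-adjusted Horvitz--Thompson
        estimator of Chao & Shen (requires integer counts; may exceed
        the observed species richness).
    """
    x = np.atleast_2d(np.asarray(counts, dtype=float))
    if (x < 0).any():
        raise ValidationError("negative abundance")
    return float(np.exp(_shannon_rows(x, bias_correction)[0]))


def hill_richness(counts) -> int:
    """Observed species richness (Hill number of order 0); internal helper."""
    x = np.asarray(counts)
    return int((x > 0).sum())


def gamma_diversity(cm: CommunityMatrix, group_label=None, bias_correction: str = "none") -> float:
    """Pooled (gamma) exponential Shannon diversity of one group of sites.

    Column-sums the group's counts, then applies :func:`hill_shannon` with
    the same bias correction used for the per-site alpha values.
    """
    sub = cm if group_label is None else cm.subset_group(group_label)
    pooled = sub.counts.to_numpy().sum(axis=0)
    return hill_shannon(pooled, bias_correction)


def proportional_beta(alpha: float, gamma: float) -> float:
    """Proportional species turnover beta = 1 - alpha/gamma.

    Not clamped: a bias-corrected alpha exceeding gamma yields a negative
    value, which is reported (with a warning at the partition level) rather
    than truncated.
    """
    if alpha <= 0 or gamma <= 0:
        raise ValidationError("alpha and gamma must be positive")
    return 1.0 - alpha / gamma


def _null_counts(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One draw from the fixed-occurrence-frequency null on a counts array."""
    n, S = X.shape
    out = np.zeros_like(X)
    for s in range(S):
        vals = X[X[:, s] > 0, s]
        k = vals.size
        if k == 0:
            continue
        sites = rng.choice(n, size=k, replace=False)
        out[sites, s] = rng.permutation(vals)
    return out


def null_randomize(cm: CommunityMatrix, seed=None) -> CommunityMatrix:
    """Randomize a community matrix under the fixed species occurrence
    frequency null model.

    Per species, the set of occupied sites is redrawn uniformly among all
    site subsets of the same size and the observed positive abundances are
    permuted onto the new sites.  Per-species occupancy counts and totals
    (hence column sums and the grand total) are conserved exactly;
    per-site richness is not.
    """
    rng = np.random.default_rng(seed)
    X = cm.counts.to_numpy()
    out = _null_counts(X, rng)
    df = pd.DataFrame(out, index=cm.counts.index, columns=cm.counts.columns)
    return CommunityMatrix(df, cm.group)


@dataclass
class DiversityPartition:
    """Per-site diversity partition of one group with null summaries.

    ``table`` columns: alpha, gamma, beta_obs, beta_null_mean,
    beta_null_sd, beta_dev; indexed by site id.
    """

    table: pd.DataFrame
    group_label: object
    gamma: float
    n_randomizations: int
    seed: object
    bias_correction: str


def beta_dev(
    cm: CommunityMatrix,
    group_label=None,
    n_rand: int = 999,
    seed=None,
    bias_correction: str = "none",
    incidence_only: bool = False,
    recompute_gamma: bool = True,
) -> DiversityPartition:
    """Standardized deviation of proportional beta from a randomization null.

    For each site of the group, beta_obs = 1 - alpha_i/gamma is compared
    with its distribution over ``n_rand`` draws of the fixed-occurrence-
    frequency null model: beta_dev = (beta_obs - mean_null)/sd_null.

    Parameters
    ----------
    group_label
        Group whose sites form the partition (gamma pools exactly these
        sites); ``None`` treats the whole matrix as one group.
    incidence_only
        Reduce counts to presence/absence before computing diversities
        (alpha then equals site richness and gamma pooled richness).
    recompute_gamma
        Recompute gamma inside each randomization.  The abundance-
        preserving null conserves column sums, so this is a no-op for it,
        but matters for variant nulls; kept as an explicit toggle.
    """
    if n_rand < 1:
        raise ValidationError("n_rand must be >= 1")
    sub = cm if group_label is None else cm.subset_group(group_label)
    if sub.n_sites < 2:
        raise ValidationError("beta_dev needs at least 2 sites in the group")
    X = sub.counts.to_numpy()
    if incidence_only:
        X = (X > 0).astype(np.int64)

    def _alphas_gamma(M: np.ndarray) -> tuple[np.ndarray, float]:
        a = np.exp(_shannon_rows(M, bias_correction))
        g = np.exp(_shannon_rows(M.sum(axis=0, keepdims=True), bias_correction))[0]
        return a, float(g)

    alpha_obs, gamma_obs = _alphas_gamma(X)
    beta_obs = 1.0 - alpha_obs / gamma_obs
    if (beta_obs < 0).any():
        logger.warning(
            "negative proportional beta at sites %s (bias-corrected alpha above gamma)",
            list(sub.counts.index[beta_obs < 0]),
        )

    rng = np.random.default_rng(seed)
    null_betas = np.empty((n_rand, sub.n_sites))
    gamma_r = gamma_obs
    for r in range(n_rand):
        Xr = _null_counts(X, rng)
        if recompute_gamma:
            a_r, gamma_r = _alphas_gamma(Xr)
        else:
            a_r = np.exp(_shannon_rows(Xr, bias_correction))
        null_betas[r] = 1.0 - a_r / gamma_r

    null_mean = null_betas.mean(axis=0)
    null_sd = null_betas.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bdev = np.where(null_sd > 0, (beta_obs - null_mean) / null_sd, np.nan)
    if np.isnan(bdev).any():
        logger.warning(
            "beta_dev undefined (null sd = 0) at sites %s",
            list(sub.counts.index[np.isnan(bdev)]),
        )
    table = pd.DataFrame(
        {
            "alpha": alpha_obs,
            "gamma": gamma_obs,
            "beta_obs": beta_obs,
            "beta_null_mean": null_mean,
            "beta_null_sd": null_sd,
            "beta_dev": bdev,
        },
        index=sub.counts.index,
    )
    return DiversityPartition(
        table=table,
        group_label=group_label,
        gamma=gamma_obs,
        n_randomizations=n_rand,
        seed=seed,
        bias_correction=bias_correction,
    )


def overlap_summary(cm: CommunityMatrix) -> pd.DataFrame:
    """Species-pool overlap between groups.

    Returns one row per group with its observed richness, the number of
    exclusive species (and exclusive singletons), plus a ``shared`` row
    with the number and percentage of species found in every group.
    """
    groups = cm.groups()
    X = cm.counts.to_numpy()
    present = {g: (cm.counts.loc[cm.group == g].sum(axis=0) > 0) for g in groups}
    totals = cm.counts.sum(axis=0)
    observed_any = totals > 0
    n_total = int(observed_any.sum())
    shared = observed_any.copy()
    for g in groups:
        shared &= present[g]
    rows = []
    for g in groups:
        exclusive = present[g].copy()
        for h in groups:
            if h != g:
                exclusive &= ~present[h]
        group_totals = cm.counts.loc[cm.group == g].sum(axis=0)
        rows.append(
            {
                "group": g,
                "richness": int(present[g].sum()),
                "exclusive": int(exclusive.sum()),
                "exclusive_singletons": int((exclusive & (group_totals == 1)).sum()),
            }
        )
    out = pd.DataFrame(rows).set_index("group")
    out.loc["shared"] = {
        "richness": int(shared.sum()),
        "exclusive": 0,
        "exclusive_singletons": 0,
    }
    out["pct_of_pool"] = 100.0 * out["richness"] / n_total
    return out
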