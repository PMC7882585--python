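"""Two-sample screening and linear modelling of standardized beta.

Environmental variables are screened between fragments with Mann-Whitney
U tests (normal approximation with tie and continuity correction),
adjusted table-wise by Benjamini-Hochberg FDR.  Standardized beta
(beta_dev) is modelled by ordinary least squares on principal-component
scores, with bidirectional stepwise selection on the Akaike information
criterion starting from the full additive model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import ValidationError

logger = logging.getLogger("fragbeta")

__all__ = [
    "mann_whitney",
    "bh_fdr",
    "screening_table",
    "stepwise_aic",
    "ModelSelectionResult",
]


def mann_whitney(x, y, correction: str = "continuity") -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U test via the normal approximation.

    Returns (U, z, p) where U is the statistic of the first sample, z the
    signed standardized statistic with tie correction (and continuity
    correction when ``correction="continuity"``), and p the two-sided
    normal-approximation p-value.  Swapping the samples flips the sign of
    z and leaves p unchanged.
    """
    if correction not in ("continuity", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValidationError("each sample needs at least one value")
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    R1 = ranks[:n].sum()
    U = R1 - n * (n + 1) / 2.0
    mu = n * m / 2.0
    N = n + m
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (N * (N - 1.0))
    var = n * m / 12.0 * (N + 1.0 - tie_term)
    if var <= 0:
        logger.warning("all values tied across both samples: p = 1")
        return float(U), 0.0, 1.0
    diff = U - mu
    if correction == "continuity" and diff != 0:
        diff -= 0.5 * np.sign(diff)
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(U), float(z), float(min(p, 1.0))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def screening_table(env_data: pd.DataFrame, group: pd.Series,
                    correction: str = "continuity") -> pd.DataFrame:
    """Per-variable two-group comparison table (means, SDs, U, z, p, q).

    BH-FDR adjustment is table-scoped: q-values are computed across the
    variables of this table only.
    """
    levels = sorted(group.unique(), key=str)
    if len(levels) != 2:
        raise ValidationError("screening_table expects exactly 2 groups")
    a, b = levels
    rows = []
    for var in env_data.columns:
        xa = env_data.loc[group == a, var].dropna()
        xb = env_data.loc[group == b, var].dropna()
        U, z, p = mann_whitney(xa, xb, correction=correction)
        rows.append(
            {
                "variable": var,
                f"mean_{a}": xa.mean(), f"sd_{a}": xa.std(ddof=1),
                f"mean_{b}": xb.mean(), f"sd_{b}": xb.std(ddof=1),
                "U": U, "z": z, "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("variable")
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant_q05"] = out["q"] < 0.05
    return out


@dataclass
class ModelSelectionResult:
    """Outcome of stepwise-AIC selection over OLS fits."""

    selected: list
    coefficients: pd.DataFrame       # coef, std_beta, t, p per retained term
    aic_trace: list = field(default_factory=list)
    aic: float = np.nan
    adj_r2: float = np.nan
    model: object = None


def _fit_ols(y: pd.Series, X: pd.DataFrame, terms: list):
    design = sm.add_constant(X[list(terms)], has_constant="add") if terms else \
        pd.DataFrame({"const": np.ones(len(y))}, index=y.index)
    return sm.OLS(y, design).fit()


def stepwise_aic(response: pd.Series, candidates: pd.DataFrame) -> ModelSelectionResult:
    """Bidirectional stepwise OLS selection by AIC, starting from the full
    additive model.

    At each step every single-term addition and removal is evaluated and
    the move with the lowest AIC taken; AIC ties are broken toward the
    smaller model.  AIC uses the Gaussian log-likelihood with its constant
    and penalty k = 2.  Standardized beta coefficients are reported as
    coef x sd(x)/sd(y).
    """
    y = pd.Series(response).astype(float)
    X = candidates.loc[y.index].astype(float)
    n, k = X.shape
    if n <= k + 2:
        raise ValidationError("need n > number of candidates + 2")
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(n), X.to_numpy()]))
    if rank < k + 1:
        corr = X.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        raise ValidationError(
            f"rank-deficient design; aliased terms include {X.columns[i]!r}, {X.columns[j]!r}"
        )

    current = list(X.columns)
    fit = _fit_ols(y, X, current)
    trace = [(tuple(current), float(fit.aic))]
    while True:
        best_move, best_aic, best_size = None, fit.aic, len(current)
        for term in current:
            cand = [t for t in current if t != term]
            a = float(_fit_ols(y, X, cand).aic)
            # strictly better AIC wins; ties go to the smaller model
            if a < best_aic - 1e-10 or (abs(a - best_aic) <= 1e-10 and len(cand) < best_size):
                best_move, best_aic, best_size = ("drop", term), a, len(cand)
        for term in X.columns:
            if term in current:
                continue
            cand = current + [term]
            a = float(_fit_ols(y, X, cand).aic)
            if a < best_aic - 1e-10:
                best_move, best_aic, best_size = ("add", term), a, len(cand)
        if best_move is None:
            break
        action, term = best_move
        current = [t for t in current if t != term] if action == "drop" else current + [term]
        fit = _fit_ols(y, X, current)
        trace.append((tuple(current), float(fit.aic)))

    sd_y = y.std(ddof=1)
    rows = []
    for term in current:
        rows.append(
            {
                "term": term,
                "coef": fit.params[term],
                "std_beta": fit.params[term] * X[term].std(ddof=1) / sd_y,
                "t": fit.tvalues[term],
                "p": fit.pvalues[term],
            }
        )
    coef = pd.DataFrame(rows).set_index("term") if rows else pd.DataFrame(
        columns=["coef", "std_beta", "t", "p"]
    )
    return ModelSelectionResult(
        selected=current,
        coefficients=coef,
        aic_trace=trace,
        aic=float(fit.aic),
        adj_r2=float(fit.rsquared_adj) if current else 0.0,
        model=fit,
    )
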