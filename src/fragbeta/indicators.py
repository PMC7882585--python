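"""Dufrene-Legendre indicator value (IndVal) analysis.

For species k and site group g:

    A_kg = mean abundance of k in g / sum over groups of its mean abundances
    B_kg = fraction of g's sites where k occurs
    IndVal_kg = A_kg * B_kg

A (specificity) and B (fidelity) both lie in [0,1]; a perfect indicator
(present at every site of exactly one group) scores 1.  The species
statistic is the maximum over groups, tested by permuting site-group
labels.  Group means are unweighted per-site means, making the statistic
robust to unequal group sizes.  No multiple-testing correction is applied
here; apply BH-FDR across species downstream if desired.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CommunityMatrix, ValidationError

logger = logging.getLogger("fragbeta")

__all__ = ["indval", "IndValResult"]


def _indval_stats(X: np.ndarray, group_masks: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A, B, indval matrices (groups x species) for counts X (sites x species)."""
    n_g = group_masks.sum(axis=1, keepdims=True)          # groups x 1
    means = (group_masks @ X) / n_g                       # groups x species
    occ = (group_masks @ (X > 0)) / n_g
    denom = means.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(denom > 0, means / np.where(denom > 0, denom, 1.0), np.nan)
    iv = A * occ
    return A, occ, iv


@dataclass
class IndValResult:
    """Per-species indicator values with permutation p-values.

    ``table`` columns: best group, A (specificity), B (fidelity), indval,
    p; NaN statistics flag species absent everywhere.  ``by_group`` holds
    the full species x group A/B/indval breakdown.
    """

    table: pd.DataFrame
    by_group: pd.DataFrame
    n_permutations: int
    seed: object
    exact: bool = False

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p"] <= alpha]


def indval(
    cm: CommunityMatrix,
    groups=None,
    n_perm: int = 999,
    seed=None,
    exact_limit: int = 100000,
) -> IndValResult:
    """Indicator value analysis of a grouped community matrix.

    ``groups`` defaults to the matrix's own group labels.  p-values come
    from permuting site-group labels; when the number of distinct label
    assignments is small (at most ``exact_limit`` and at most the number
    of requested permutations would sample it poorly), all distinct
    assignments are enumerated for exact p-values.
    """
    if groups is None:
        groups = cm.group
    if groups is None:
        raise ValidationError("no grouping supplied")
    groups = pd.Series(groups)
    if not groups.index.equals(cm.counts.index):
        groups = groups.loc[cm.counts.index]
    levels = sorted(groups.unique(), key=str)
    if len(levels) < 2:
        raise ValidationError("need at least 2 groups")
    X = cm.counts.to_numpy(dtype=float)
    n = X.shape[0]
    masks = np.stack([(groups == l).to_numpy(float) for l in levels])
    A, B, iv = _indval_stats(X, masks)
    absent = X.sum(axis=0) == 0
    if absent.any():
        logger.warning("species absent everywhere, indval undefined: %s",
                       list(cm.counts.columns[absent]))
    best_idx = np.nanargmax(np.where(np.isnan(iv), -np.inf, iv), axis=0)
    best_iv = iv[best_idx, np.arange(iv.shape[1])]
    best_A = A[best_idx, np.arange(iv.shape[1])]
    best_B = B[best_idx, np.arange(iv.shape[1])]

    counts = [int(m.sum()) for m in masks]
    n_distinct = math.factorial(n)
    for c in counts:
        n_distinct //= math.factorial(c)
    # enumerate exactly when the label-assignment space is small
    exact = n_distinct <= min(exact_limit, max(n_perm, 1000))

    count_ge = np.zeros(X.shape[1])
    if exact:
        n_used = n_distinct
        labels = _distinct_assignments(n, counts)
        for assign in labels:
            pm = np.zeros((len(levels), n))
            pm[assign, np.arange(n)] = 1.0
            _, _, iv_p = _indval_stats(X, pm)
            stat_p = np.nanmax(np.where(np.isnan(iv_p), -np.inf, iv_p), axis=0)
            count_ge += stat_p >= best_iv - 1e-12
        pvals = count_ge / n_distinct
    else:
        n_used = n_perm
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            idx = rng.permutation(n)
            pm = masks[:, idx]
            _, _, iv_p = _indval_stats(X, pm)
            stat_p = np.nanmax(np.where(np.isnan(iv_p), -np.inf, iv_p), axis=0)
            count_ge += stat_p >= best_iv - 1e-12
        pvals = (1.0 + count_ge) / (1.0 + n_perm)
    pvals = np.where(absent, np.nan, pvals)

    table = pd.DataFrame(
        {
            "group": [levels[i] for i in best_idx],
            "A": np.where(absent, np.nan, best_A),
            "B": np.where(absent, np.nan, best_B),
            "indval": np.where(absent, np.nan, best_iv),
            "p": pvals,
        },
        index=cm.counts.columns,
    )
    by_group = pd.concat(
        {
            l: pd.DataFrame(
                {"A": A[i], "B": B[i], "indval": iv[i]}, index=cm.counts.columns
            )
            for i, l in enumerate(levels)
        },
        names=["group", "species_id"],
    )
    return IndValResult(table, by_group, n_used, seed, exact=exact)


def _distinct_assignments(n: int, counts: list[int]):
    """Yield all distinct assignments of n sites to groups of given sizes,
    as arrays of group indices."""
    sites = list(range(n))

    def rec(remaining, group_idx, assign):
        if group_idx == len(counts) - 1:
            out = assign.copy()
            for s in remaining:
                out[s] = group_idx
            yield out
            return
        for combo in itertools.combinations(remaining, counts[group_idx]):
            out = assign.copy()
            for s in combo:
                out[s] = group_idx
            rest = [s for s in remaining if s not in combo]
            yield from rec(rest, group_idx + 1, out)

    yield from rec(sites, 0, np.zeros(n, dtype=int))
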