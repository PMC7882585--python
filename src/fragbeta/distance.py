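"""Dissimilarity, ordination and permutation tests on community structure.

Bray-Curtis dissimilarities (optionally on square-root transformed
abundances) feed principal coordinates analysis (PCoA), permutational
multivariate ANOVA (PERMANOVA) and constrained analysis of principal
coordinates (CAP, also known as distance-based RDA).  A per-site
multivariate dispersion (distance to group centroid in PCoA space, with
the standard imaginary-axis correction) is provided for vegetation
subplot data.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datamodel import CommunityMatrix, ValidationError

logger = logging.getLogger("fragbeta")

__all__ = [
    "DistanceMatrix",
    "bray_curtis",
    "pcoa",
    "PCoAResult",
    "permanova",
    "PermanovaResult",
    "cap_fit",
    "OrdinationModel",
    "multivariate_dispersion",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with zero diagonal."""

    values: pd.DataFrame
    transform_tag: str = "none"

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.shape[0] != v.shape[1]:
            raise ValidationError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("distance matrix must have zero diagonal")
        if (v < -1e-12).any():
            raise ValidationError("negative dissimilarity")

    @property
    def site_ids(self) -> list:
        return list(self.values.index)

    @property
    def array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def bray_curtis(cm: CommunityMatrix, transform: str = "sqrt") -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sites.

    d(i,j) = sum|x_i - x_j| / sum(x_i + x_j), computed on raw or
    square-root transformed abundances.  The square-root transform
    down-weights hyperabundant species before ordination.
    """
    if transform not in ("none", "sqrt"):
        raise ValueError(f"unknown transform {transform!r}")
    X = cm.counts.to_numpy(dtype=float)
    if cm.n_sites < 2:
        raise ValidationError("need at least 2 sites")
    zero = X.sum(axis=1) == 0
    if zero.any():
        raise ValidationError(f"zero-total sites: {list(cm.counts.index[zero])}")
    if transform == "sqrt":
        X = np.sqrt(X)
    D = squareform(pdist(X, metric="braycurtis"))
    df = pd.DataFrame(D, index=cm.counts.index, columns=cm.counts.index)
    return DistanceMatrix(df, transform_tag=transform)


def _gower_center(D: np.ndarray) -> np.ndarray:
    """Gower double-centering of squared dissimilarities: G = -1/2 J D^2 J."""
    A = -0.5 * D ** 2
    n = A.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


@dataclass
class PCoAResult:
    eigenvalues: np.ndarray          # all, descending (may include negatives)
    coordinates: pd.DataFrame        # positive axes only, scaled by sqrt(eig)
    site_ids: list

    @property
    def positive_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues > 1e-10]


def pcoa(dm: DistanceMatrix) -> PCoAResult:
    """Principal coordinates analysis (classical metric MDS).

    Eigen-decomposes the Gower-centred matrix.  Negative eigenvalues are
    reported but their axes are excluded from the returned coordinates
    (no Lingoes/Cailliez correction).
    """
    G = _gower_center(dm.array)
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-10
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    cols = [f"PCo{i + 1}" for i in range(int(pos.sum()))]
    return PCoAResult(
        eigenvalues=eigval,
        coordinates=pd.DataFrame(coords, index=dm.site_ids, columns=cols),
        site_ids=dm.site_ids,
    )


def _design_blocks(design) -> tuple[list[str], list[np.ndarray]]:
    """Expand a grouping Series or predictor DataFrame into per-term
    column blocks (categoricals become full dummy sets; the intercept is
    implicit)."""
    if isinstance(design, pd.Series):
        design = design.to_frame(design.name or "group")
    names, blocks = [], []
    for col in design.columns:
        s = design[col]
        if np.issubdtype(s.dtype, np.number):
            block = s.to_numpy(dtype=float)[:, None]
        else:
            levels = sorted(pd.unique(s), key=str)
            if len(levels) < 2:
                raise ValidationError(f"grouping {col!r} has a single level")
            block = np.column_stack([(s == l).to_numpy(float) for l in levels[1:]])
        names.append(col)
        blocks.append(block)
    return names, blocks


def _hat_ranks(blocks: list[np.ndarray], n: int) -> tuple[list[np.ndarray], list[int]]:
    """Sequential hat matrices H_0..H_K (intercept-only up to full model)
    and the rank increment of each term."""
    hats = []
    ones = np.ones((n, 1))
    X = ones
    prev_rank = 1
    hats.append(ones @ ones.T / n)
    ranks = []
    for block in blocks:
        X = np.hstack([X, block])
        Q, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        keep = diag > 1e-9 * max(diag.max(), 1.0)
        rank = int(keep.sum())
        Qk = Q[:, keep]
        hats.append(Qk @ Qk.T)
        ranks.append(rank - prev_rank)
        prev_rank = rank
    return hats, ranks


def _term_ss(G: np.ndarray, hats: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Sequential (Type I) sums of squares per term and the residual SS."""
    traces = np.array([float(np.sum(H * G)) for H in hats])
    ss_terms = np.diff(traces)
    ss_res = float(np.trace(G)) - traces[-1]
    return ss_terms, ss_res


@dataclass
class PermanovaResult:
    table: pd.DataFrame              # per-term df, SS, R2, pseudo_F, p
    total_ss: float
    n_permutations: int
    seed: object
    exact: bool = False


def permanova(
    dm: DistanceMatrix,
    design,
    n_perm: int = 999,
    seed=None,
    exact_limit: int = 720,
) -> PermanovaResult:
    """Permutational multivariate analysis of variance on a dissimilarity
    matrix (McArdle-Anderson partitioning, sequential terms).

    ``design`` is a grouping Series or a DataFrame of predictors (numeric
    and/or categorical), aligned with the distance matrix sites.  The
    pseudo-F of each term uses the residual of the full model; p-values
    come from simultaneous row/column permutation of the dissimilarities,
    with the observed statistic counted in numerator and denominator.
    When n! does not exceed ``max(n_perm, exact_limit)`` all n!
    permutations are enumerated instead and exact p-values returned.
    """
    if isinstance(design, pd.Series) or isinstance(design, pd.DataFrame):
        if list(design.index) != dm.site_ids:
            design = design.loc[dm.site_ids]
    n = dm.n
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    names, blocks = _design_blocks(design)
    hats, ranks = _hat_ranks(blocks, n)
    if any(r == 0 for r in ranks):
        bad = [nm for nm, r in zip(names, ranks) if r == 0]
        raise ValidationError(f"aliased (collinear) terms: {bad}")
    G = _gower_center(dm.array)
    total_ss = float(np.trace(G))
    ss_terms, ss_res = _term_ss(G, hats)
    df_terms = np.array(ranks, dtype=float)
    df_res = n - 1 - df_terms.sum()
    if df_res <= 0:
        raise ValidationError("no residual degrees of freedom")
    F_obs = (ss_terms / df_terms) / (ss_res / df_res)

    exact = math.factorial(n) <= max(n_perm, exact_limit)
    if exact:
        perms = list(itertools.permutations(range(n)))
        logger.info("permanova: exact enumeration of %d permutations", len(perms))
        count = np.zeros_like(F_obs)
        for p in perms:
            idx = np.array(p)
            Gp = G[np.ix_(idx, idx)]
            ss_t, ss_r = _term_ss(Gp, hats)
            Fp = (ss_t / df_terms) / (ss_r / df_res)
            count += Fp >= F_obs - 1e-12
        pvals = count / len(perms)
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros_like(F_obs)
        for _ in range(n_perm):
            idx = rng.permutation(n)
            Gp = G[np.ix_(idx, idx)]
            ss_t, ss_r = _term_ss(Gp, hats)
            Fp = (ss_t / df_terms) / (ss_r / df_res)
            count += Fp >= F_obs - 1e-12
        pvals = (1.0 + count) / (1.0 + n_perm)
        n_used = n_perm
    table = pd.DataFrame(
        {
            "df": df_terms.astype(int),
            "SS": ss_terms,
            "R2": ss_terms / total_ss,
            "pseudo_F": F_obs,
            "p": pvals,
        },
        index=names,
    )
    table.loc["Residual"] = [int(df_res), ss_res, ss_res / total_ss, np.nan, np.nan]
    table.loc["Total"] = [n - 1, total_ss, 1.0, np.nan, np.nan]
    return PermanovaResult(table, total_ss, n_used, seed, exact=exact)


@dataclass
class OrdinationModel:
    """Constrained ordination result (CAP / db-RDA)."""

    eigenvalues: np.ndarray
    coordinates: pd.DataFrame
    terms: pd.DataFrame = field(default_factory=pd.DataFrame)
    total_constrained: float = np.nan
    total_inertia: float = np.nan
    n_permutations: int = 0
    seed: object = None


def cap_fit(
    dm: DistanceMatrix,
    predictors: pd.DataFrame,
    n_perm: int = 999,
    seed=None,
    condition_threshold: float = 1e8,
) -> OrdinationModel:
    """Constrained analysis of principal coordinates.

    PCoA site scores on the non-negative-eigenvalue axes are regressed on
    z-transformed predictors.  Terms are assessed sequentially (Type I) in
    the order given; each term's explained variation is reported as a
    fraction of the total inertia (sum of positive PCoA eigenvalues), with
    a pseudo-F and a reduced-model residual-permutation p-value.
    """
    if list(predictors.index) != dm.site_ids:
        predictors = predictors.loc[dm.site_ids]
    n = dm.n
    p = predictors.shape[1]
    if predictors.shape[0] != n:
        raise ValidationError("predictor rows must align with distance matrix")
    if n < p + 2:
        raise ValidationError("need n >= p + 2 sites")
    sds = predictors.std(axis=0, ddof=1)
    zero_var = list(sds.index[sds == 0])
    if zero_var:
        raise ValidationError(f"zero-variance predictors: {zero_var}")
    Z = (predictors - predictors.mean(axis=0)) / sds
    cond = np.linalg.cond(Z.to_numpy())
    if cond > condition_threshold:
        corr = np.corrcoef(Z.to_numpy(), rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValidationError(
            f"collinear predictors (condition number {cond:.3g}): "
            f"{Z.columns[i]!r} vs {Z.columns[j]!r}"
        )

    ord_res = pcoa(dm)
    Y = ord_res.coordinates.to_numpy()          # n x m, inner products = G on pos axes
    total_inertia = float(ord_res.positive_eigenvalues.sum())
    names, blocks = _design_blocks(Z)
    hats, ranks = _hat_ranks(blocks, n)
    df_terms = np.array(ranks, dtype=float)
    df_res = n - 1 - df_terms.sum()
    G = Y @ Y.T
    ss_terms, ss_res = _term_ss(G, hats)
    F_obs = (ss_terms / df_terms) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    pvals = np.empty(len(names))
    for j in range(len(names)):
        # reduced-model residual permutation for term j
        H_red = hats[j]
        fitted = H_red @ Y
        resid = Y - fitted
        count = 0
        for _ in range(n_perm):
            idx = rng.permutation(n)
            Yp = fitted + resid[idx]
            Gp = Yp @ Yp.T
            ss_t, ss_r = _term_ss(Gp, hats)
            Fp = (ss_t[j] / df_terms[j]) / (ss_r / df_res)
            if Fp >= F_obs[j] - 1e-12:
                count += 1
        pvals[j] = (1.0 + count) / (1.0 + n_perm)

    terms = pd.DataFrame(
        {
            "df": df_terms.astype(int),
            "SS": ss_terms,
            "explained_fraction": ss_terms / total_inertia,
            "pseudo_F": F_obs,
            "p": pvals,
        },
        index=names,
    )
    return OrdinationModel(
        eigenvalues=ord_res.eigenvalues,
        coordinates=ord_res.coordinates,
        terms=terms,
        total_constrained=float(ss_terms.sum() / total_inertia),
        total_inertia=total_inertia,
        n_permutations=n_perm,
        seed=seed,
    )


def multivariate_dispersion(subplot_incidence, metric: str = "sorensen") -> float:
    """Mean distance of a site's subplots to their multivariate centroid.

    ``subplot_incidence`` is a plots x species 0/1 array for one site.
    Sorensen (Bray-Curtis on presence/absence) distances among subplots
    are embedded by PCoA; each subplot's squared distance to the centroid
    subtracts the squared contribution of negative-eigenvalue axes, as in
    the standard dispersion (betadisper) procedure.
    """
    if metric != "sorensen":
        raise ValueError(f"unknown metric {metric!r}")
    X = np.asarray(subplot_incidence, dtype=float)
    X = (X > 0).astype(float)
    nonzero = X.sum(axis=1) > 0
    if not nonzero.all():
        logger.warning("excluding %d empty subplots", int((~nonzero).sum()))
        X = X[nonzero]
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 non-empty subplots")
    D = squareform(pdist(X, metric="braycurtis"))
    G = _gower_center(D)
    eigval, eigvec = np.linalg.eigh(G)
    coords = eigvec * np.sqrt(np.abs(eigval))
    pos = eigval > 1e-10
    neg = eigval < -1e-10
    c_pos = coords[:, pos].mean(axis=0)
    c_neg = coords[:, neg].mean(axis=0)
    d2 = ((coords[:, pos] - c_pos) ** 2).sum(axis=1) - ((coords[:, neg] - c_neg) ** 2).sum(axis=1)
    return float(np.mean(np.sqrt(np.clip(d2, 0.0, None))))
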