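"""Site-level environmental variables from field records, and their
condensation into varimax-rotated principal components.

Field derivations: forest structure from point-centered-quarter (PCQ)
records (Pollard's unbiased density estimator), mean Ellenberg indicator
values over each site's flora, functional dispersion (FDis) of the plant
community from a Gower trait distance, and landscape composition metrics
(habitat Shannon diversity, edge density) from buffer area/length tables.

Condensation: PCA on the correlation matrix of selected variables, axes
retained by the Kaiser criterion (eigenvalue > 1), normalized varimax
rotation, regression-method site scores, deterministic sign convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datamodel import (
    ELLENBERG_INDICES,
    NATURAL_HABITAT_CLASSES,
    LandscapeTable,
    PCQRecords,
    PlantData,
    ValidationError,
)

logger = logging.getLogger("fragbeta")

__all__ = [
    "pcq_metrics",
    "ellenberg_means",
    "gower_distance",
    "functional_dispersion",
    "landscape_metrics",
    "varimax",
    "pca_varimax",
    "PCAResult",
]


def pcq_metrics(records: PCQRecords, estimator: str = "pollard") -> pd.DataFrame:
    """Forest-structure metrics per site from point-centered-quarter records.

    Density uses Pollard's unbiased estimator over n complete points
    (4 quarters each, distances d in meters):

        lambda-hat = 1e4 * 4 (4n - 1) / (pi * sum d^2)   [trees/ha]

    The classic Cottam-Curtis form (mean distance)^-2 is available via
    ``estimator="cottam"`` for comparison.  Basal area per tree is
    pi (dbh/2)^2 in cm^2; per-class cover (deciduous/conifer) is the
    class's share of the density times its mean basal area, converted to
    m^2/ha, so that the two covers sum to density x mean basal area.
    """
    if estimator not in ("pollard", "cottam"):
        raise ValueError(f"unknown estimator {estimator!r}")
    d = records.data
    complete = d.groupby(["site_id", "point_index"])["quarter_index"].transform("nunique") == 4
    if (~complete).any():
        logger.warning("excluding %d trees at incomplete PCQ points", int((~complete).sum()))
    d = d[complete]
    if d.empty:
        raise ValidationError("no complete PCQ points")
    rows = []
    for site, sub in d.groupby("site_id", sort=True):
        n_points = sub.groupby("point_index").ngroups
        dist2 = float((sub["distance_m"] ** 2).sum())
        if estimator == "pollard":
            density = 1e4 * 4.0 * (4.0 * n_points - 1.0) / (np.pi * dist2)
        else:
            mean_d = float(sub["distance_m"].mean())
            density = 1e4 / mean_d**2
        ba = np.pi * (sub["dbh_cm"].to_numpy() / 2.0) ** 2      # cm^2
        conifer = sub["is_conifer"].to_numpy(dtype=bool)
        dead = sub["is_dead"].to_numpy(dtype=bool)

        def class_cover(mask: np.ndarray) -> float:
            if not mask.any():
                return 0.0
            share = mask.mean()
            return density * share * float(ba[mask].mean()) * 1e-4   # m^2/ha

        rows.append(
            {
                "site_id": site,
                "density_trees_ha": density,
                "mean_basal_area_cm2": float(ba.mean()),
                "sd_basal_area_cm2": float(ba.std(ddof=0)),
                "deciduous_cover_m2_ha": class_cover(~conifer),
                "conifer_cover_m2_ha": class_cover(conifer),
                "pct_dead_trees": 100.0 * float(dead.mean()),
            }
        )
    return pd.DataFrame(rows).set_index("site_id")


def ellenberg_means(pd_data: PlantData) -> pd.DataFrame:
    """Unweighted mean Ellenberg indicator value (humidity, nutrients,
    temperature) over the plant species present at each site, skipping
    species with a missing value for that index."""
    inc = pd_data.incidence
    ev = pd_data.ellenberg
    out = {}
    for idx_name in ELLENBERG_INDICES:
        vals = ev[idx_name].reindex(inc.columns).to_numpy(dtype=float)
        present = inc.to_numpy(dtype=float)
        scorable = present * ~np.isnan(vals)
        denom = scorable.sum(axis=1)
        numer = np.where(np.isnan(vals), 0.0, vals)[None, :] * scorable
        with np.errstate(invalid="ignore"):
            out[idx_name] = np.where(denom > 0, numer.sum(axis=1) / denom, np.nan)
        if (denom == 0).any():
            logger.warning("no scorable species for %s at sites %s",
                           idx_name, list(inc.index[denom == 0]))
    return pd.DataFrame(out, index=inc.index)


def gower_distance(traits: pd.DataFrame) -> pd.DataFrame:
    """Gower distance on a mixed numeric/categorical trait table.

    Numeric traits contribute range-normalized absolute differences,
    categorical traits a 0/1 mismatch; missing values drop the trait from
    the pair's average.
    """
    n = traits.shape[0]
    num = np.zeros((n, n))
    wsum = np.zeros((n, n))
    for col in traits.columns:
        s = traits[col]
        if np.issubdtype(s.dtype, np.number):
            v = s.to_numpy(dtype=float)
            rng_ = np.nanmax(v) - np.nanmin(v)
            if not np.isfinite(rng_) or rng_ == 0:
                continue
            diff = np.abs(v[:, None] - v[None, :]) / rng_
            ok = ~np.isnan(v[:, None]) & ~np.isnan(v[None, :])
        else:
            v = s.to_numpy()
            miss = pd.isna(s).to_numpy()
            diff = (v[:, None] != v[None, :]).astype(float)
            ok = ~miss[:, None] & ~miss[None, :]
        num += np.where(ok, diff, 0.0)
        wsum += ok
    with np.errstate(invalid="ignore"):
        D = np.where(wsum > 0, num / np.where(wsum > 0, wsum, 1.0), 0.0)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=traits.index, columns=traits.index)


def functional_dispersion(pd_data: PlantData) -> pd.Series:
    """Functional dispersion (FDis) of each site's plant community.

    Species present at a site are embedded by PCoA of the Gower trait
    distance; FDis is the mean distance of the (equally weighted, since
    the data are incidences) species to their trait-space centroid, with
    the squared contribution of negative-eigenvalue axes subtracted.
    """
    traits = pd_data.traits
    traited = traits.index[~traits.isna().all(axis=1)]
    dropped = set(traits.index) - set(traited)
    if dropped:
        logger.warning("species without traits excluded from FDis: %s", sorted(map(str, dropped)))
    D = gower_distance(traits.loc[traited]).to_numpy()
    # PCoA embedding of the full species pool; per-site FDis restricts to
    # the species present there
    from .distance import _gower_center

    G = _gower_center(D)
    eigval, eigvec = np.linalg.eigh(G)
    coords = eigvec * np.sqrt(np.abs(eigval))
    pos = eigval > 1e-10
    neg = eigval < -1e-10
    sp_index = {sp: i for i, sp in enumerate(traited)}
    out = {}
    for site in pd_data.incidence.index:
        present = [sp for sp in pd_data.incidence.columns
                   if pd_data.incidence.at[site, sp] == 1 and sp in sp_index]
        if len(present) == 0:
            out[site] = np.nan
            continue
        if len(present) == 1:
            out[site] = 0.0
            continue
        rows = [sp_index[sp] for sp in present]
        # Re-embed the present species only, so that the centroid is that of
        # the local community in its own PCoA space.
        Dsub = D[np.ix_(rows, rows)]
        Gs = _gower_center(Dsub)
        ev, evec = np.linalg.eigh(Gs)
        csub = evec * np.sqrt(np.abs(ev))
        pos_s = ev > 1e-10
        neg_s = ev < -1e-10
        cp = csub[:, pos_s].mean(axis=0)
        cn = csub[:, neg_s].mean(axis=0)
        d2 = ((csub[:, pos_s] - cp) ** 2).sum(axis=1) - ((csub[:, neg_s] - cn) ** 2).sum(axis=1)
        out[site] = float(np.mean(np.sqrt(np.clip(d2, 0.0, None))))
    return pd.Series(out, name="fdis")


def landscape_metrics(lt: LandscapeTable) -> pd.DataFrame:
    """Per-site, per-radius derived landscape variables.

    Habitat diversity is the Shannon index (natural log) over the
    renormalized natural-habitat fractions {forest, reed, grassland};
    edge density is boundary length divided by buffer area in hectares
    (pi r^2 x 1e-4); the modified-areas fraction sums agriculture and
    urban/industrial cover.  Distances pass through unchanged.
    """
    rows = []
    for _, r in lt.data.iterrows():
        nat = np.array([r[c] for c in NATURAL_HABITAT_CLASSES], dtype=float)
        tot = nat.sum()
        if tot <= 0:
            logger.warning("site %r radius %s: no natural habitat, diversity missing",
                           r["site_id"], r["radius_m"])
            shannon = np.nan
        else:
            p = nat[nat > 0] / tot
            shannon = float(-(p * np.log(p)).sum())
        area_ha = np.pi * float(r["radius_m"]) ** 2 * 1e-4
        rows.append(
            {
                "site_id": r["site_id"],
                "radius_m": int(r["radius_m"]),
                "habitat_diversity": shannon,
                "edge_density_m_ha": float(r["edge_length_m"]) / area_ha,
                "modified_fraction": float(r["agriculture"]) + float(r["urban_industrial"]),
                "forest": float(r["forest"]),
                "reed": float(r["reed"]),
                "grassland": float(r["grassland"]),
                "dist_to_edge_m": float(r["to_edge_m"]),
                "dist_to_canal_m": float(r["to_canal_m"]),
                "dist_to_industry_m": float(r["to_industry_m"]),
            }
        )
    return pd.DataFrame(rows).set_index(["site_id", "radius_m"])


def varimax(loadings: np.ndarray, normalize: bool = True, tol: float = 1e-6,
            max_iter: int = 20000) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a loading matrix.

    With Kaiser normalization, rows are scaled to unit communality before
    rotation and rescaled after.  Returns (rotated loadings, rotation
    matrix).  Raises if the criterion has not converged in ``max_iter``
    sweeps.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L, np.eye(k)
    comm = np.sqrt((L**2).sum(axis=1))
    if normalize:
        safe = np.where(comm > 0, comm, 1.0)
        L = L / safe[:, None]
    R = np.eye(k)
    var_old = 0.0
    for it in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        )
        R = u @ vt
        var_new = s.sum()
        if var_new - var_old < tol * max(var_new, 1.0):
            break
        var_old = var_new
    else:
        raise RuntimeError(f"varimax did not converge in {max_iter} sweeps")
    L = L @ R
    if normalize:
        L = L * np.where(comm > 0, comm, 1.0)[:, None]
    return L, R


@dataclass
class PCAResult:
    """Varimax-rotated PCA of standardized environmental variables."""

    loadings: pd.DataFrame           # variables x retained axes (rotated)
    scores: pd.DataFrame             # sites x retained axes
    eigenvalues: np.ndarray          # all eigenvalues, descending
    explained_fraction: np.ndarray   # per retained axis, post-rotation
    explained_prerotation: np.ndarray
    n_axes: int
    axis_names: list

    @property
    def total_explained(self) -> float:
        return float(self.explained_fraction.sum())


def pca_varimax(
    env_data: pd.DataFrame,
    variables: list | None = None,
    axis_names: list | None = None,
    kaiser_threshold: float = 1.0,
) -> PCAResult:
    """Correlation-matrix PCA with Kaiser retention and varimax rotation.

    Variables are standardized to zero mean and unit variance; axes with
    eigenvalue strictly above ``kaiser_threshold`` are retained, their
    loadings varimax-rotated (Kaiser normalization) and site scores
    obtained by the regression method.  Axis sign is fixed so that each
    axis's largest-magnitude loading is positive.  ``axis_names`` are
    user metadata labels, never inferred from the data.
    """
    if variables is not None:
        missing = [v for v in variables if v not in env_data.columns]
        if missing:
            raise ValidationError(f"unknown variables: {missing}")
        X = env_data[variables].copy()
    else:
        X = env_data.copy()
    if X.shape[1] < 2:
        raise ValidationError("need at least 2 variables")
    if X.shape[0] <= X.shape[1]:
        logger.warning("fewer sites (%d) than variables+1 (%d): unstable PCA",
                       X.shape[0], X.shape[1] + 1)
    sds = X.std(axis=0, ddof=1)
    const = list(sds.index[sds == 0])
    if const:
        raise ValidationError(f"constant variables: {const}")
    Z = ((X - X.mean(axis=0)) / sds).to_numpy()
    Rmat = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(Rmat)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > kaiser_threshold      # strict Kaiser criterion
    k = int(keep.sum())
    if k == 0:
        raise ValidationError("no axis passes the Kaiser criterion")
    L = eigvec[:, :k] * np.sqrt(eigval[:k])
    L_rot, _ = varimax(L)
    # order rotated axes by explained variance, descending
    ssl = (L_rot**2).sum(axis=0)
    order2 = np.argsort(ssl)[::-1]
    L_rot = L_rot[:, order2]
    ssl = ssl[order2]
    # deterministic sign: largest-|loading| variable positive on each axis
    for j in range(k):
        i = np.argmax(np.abs(L_rot[:, j]))
        if L_rot[i, j] < 0:
            L_rot[:, j] = -L_rot[:, j]
    # regression-method scores: Z R^-1 L
    weights = np.linalg.solve(Rmat, L_rot)
    scores = Z @ weights
    p = X.shape[1]
    names = list(axis_names) if axis_names else [f"PC{j + 1}" for j in range(k)]
    if len(names) != k:
        raise ValidationError(f"{len(names)} axis names given for {k} retained axes")
    return PCAResult(
        loadings=pd.DataFrame(L_rot, index=X.columns, columns=names),
        scores=pd.DataFrame(scores, index=X.index, columns=names),
        eigenvalues=eigval,
        explained_fraction=ssl / p,
        explained_prerotation=eigval[:k] / p,
        n_axes=k,
        axis_names=names,
    )
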