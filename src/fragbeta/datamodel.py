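"""Shared data containers and tabular I/O.

All analysis modules consume the types defined here.  The central
observable is the :class:`CommunityMatrix` — a sites x species grid of
abundance counts.  Environmental covariates, plant survey data,
point-centered-quarter field records and landscape buffer tables each
get a validated container with a CSV/TSV reader.

Conventions
-----------
* Matrices are canonically oriented sites-as-rows.
* CSV and TSV are auto-detected; decimal point only; UTF-8; header row
  mandatory.
* Validation raises :class:`ValidationError` naming the offending
  row/column rather than silently coercing.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("fragbeta")

NATURAL_HABITAT_CLASSES = ("forest", "reed", "grassland")
LANDSCAPE_CLASSES = ("forest", "reed", "grassland", "water", "agriculture", "urban_industrial")
LANDSCAPE_DISTANCES = ("to_edge_m", "to_canal_m", "to_industry_m")
ELLENBERG_INDICES = ("humidity", "nutrients", "temperature")


class ValidationError(ValueError):
    """A table violated one of its structural invariants."""


class ParseError(ValueError):
    """A delimited-text file could not be parsed into the expected type."""


def _read_delimited(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    """Read a CSV/TSV file, auto-detecting the delimiter among comma and tab."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    sep = "\t" if first.count("\t") > first.count(",") else ","
    # pandas silently mangles duplicate header labels; check the raw header
    header = [h.strip() for h in first.rstrip("\n").split(sep)]
    body = header[1:] if index_col == 0 else header
    _check_unique([h for h in body if h], "column")
    return pd.read_csv(path, sep=sep, index_col=index_col)


def _check_unique(labels: Iterable, what: str) -> list:
    labels = list(labels)
    seen, dupes = set(), []
    for lab in labels:
        if lab in seen:
            dupes.append(lab)
        seen.add(lab)
    if dupes:
        raise ValidationError(f"duplicate {what} labels: {sorted(set(map(str, dupes)))}")
    return labels


@dataclass
class CommunityMatrix:
    """Abundance counts of species across sampling sites.

    Parameters
    ----------
    counts
        DataFrame indexed by site id, one column per species, with
        non-negative integer entries (individuals per species per site).
    group
        Optional per-site categorical label, e.g. the reserve fragment a
        site belongs to.  Indexed like ``counts``.
    """

    counts: pd.DataFrame
    group: pd.Series | None = None

    def __post_init__(self) -> None:
        cm = self.counts
        _check_unique(cm.index, "site")
        _check_unique(cm.columns, "species")
        vals = cm.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("community matrix contains non-numeric cells")
        if np.any(~np.isfinite(vals)):
            raise ValidationError("community matrix contains non-finite cells")
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative count at site {cm.index[i]!r}, species {cm.columns[j]!r}"
            )
        if np.any(vals != np.round(vals)):
            i, j = np.argwhere(vals != np.round(vals))[0]
            raise ValidationError(
                f"non-integer count at site {cm.index[i]!r}, species {cm.columns[j]!r}"
            )
        self.counts = cm.astype(np.int64)
        empty_sites = self.counts.index[self.counts.sum(axis=1) == 0]
        if len(empty_sites):
            raise ValidationError(f"sites with no individuals: {list(empty_sites)}")
        # All-zero species stay in the matrix (they matter for gamma-pool
        # bookkeeping when subsetting) but are flagged.
        self.empty_species = list(self.counts.columns[self.counts.sum(axis=0) == 0])
        if self.empty_species:
            logger.warning("species with all-zero columns retained: %s", self.empty_species)
        if self.group is not None:
            g = pd.Series(self.group)
            if not g.index.equals(self.counts.index):
                g = g.reindex(self.counts.index)
                if g.isna().any():
                    missing = list(g.index[g.isna()])
                    raise ValidationError(f"group label missing for sites: {missing}")
            self.group = g

    @property
    def site_ids(self) -> list:
        return list(self.counts.index)

    @property
    def species_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def n_species(self) -> int:
        return self.counts.shape[1]

    def subset_group(self, label) -> "CommunityMatrix":
        """Return the sites belonging to one group, keeping all species columns."""
        if self.group is None:
            raise ValidationError("community matrix has no group labels")
        mask = self.group == label
        if not mask.any():
            raise ValidationError(f"unknown group {label!r}")
        return CommunityMatrix(self.counts.loc[mask], self.group.loc[mask])

    def groups(self) -> list:
        if self.group is None:
            raise ValidationError("community matrix has no group labels")
        return sorted(self.group.unique().tolist())


def read_community_matrix(
    path: str | Path,
    orientation: str = "sites-rows",
    group: Mapping | pd.Series | None = None,
) -> CommunityMatrix:
    """Read an abundance matrix from a delimited-text file.

    ``orientation`` is either ``"sites-rows"`` or ``"species-rows"``;
    species-rows input is transposed so that the in-memory orientation is
    always sites-as-rows.
    """
    if orientation not in ("sites-rows", "species-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_delimited(path)
    if orientation == "species-rows":
        df = df.T
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"non-numeric cell in {path}: {exc}") from exc
    g = pd.Series(group) if group is not None else None
    cm = CommunityMatrix(df, g)
    logger.info(
        "read %s: %d sites x %d species, %d individuals",
        path, cm.n_sites, cm.n_species, int(cm.counts.to_numpy().sum()),
    )
    return cm


@dataclass
class EnvTable:
    """Site-level environmental covariates (one row per site)."""

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "site")
        bad = [c for c in self.data.columns
               if not np.issubdtype(self.data[c].dtype, np.number)]
        if bad:
            raise ValidationError(f"non-numeric environmental columns: {bad}")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            cols = self.data.columns[~np.isfinite(self.data.to_numpy(dtype=float)).all(axis=0)]
            raise ValidationError(f"non-finite values in columns: {list(cols)}")

    @property
    def site_ids(self) -> list:
        return list(self.data.index)

    @property
    def variables(self) -> list:
        return list(self.data.columns)


def read_env_table(path: str | Path) -> EnvTable:
    df = _read_delimited(path).apply(pd.to_numeric)
    return EnvTable(df)


@dataclass
class PlantData:
    """Plant incidence per site plus species-level traits and Ellenberg values.

    ``incidence``: sites x plant-species 0/1; ``traits``: plant-species x trait
    (numeric or categorical); ``ellenberg``: plant-species x
    {humidity, nutrients, temperature}, NaN where a species has no published
    value.
    """

    incidence: pd.DataFrame
    traits: pd.DataFrame
    ellenberg: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.incidence.index, "site")
        _check_unique(self.incidence.columns, "plant species")
        vals = self.incidence.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("incidence entries must be 0 or 1")
        sp = set(self.incidence.columns)
        if set(self.traits.index) != sp:
            raise ValidationError("trait table rows must match plant species")
        if not set(self.ellenberg.index) >= sp:
            raise ValidationError("ellenberg table must cover all plant species")
        missing_cols = [c for c in ELLENBERG_INDICES if c not in self.ellenberg.columns]
        if missing_cols:
            raise ValidationError(f"ellenberg table missing columns: {missing_cols}")
        ev = self.ellenberg[list(ELLENBERG_INDICES)].to_numpy(dtype=float)
        present = ~np.isnan(ev)
        if ((ev < 1) & present).any() or ((ev > 12) & present).any():
            raise ValidationError("ellenberg values must lie in 1..12 where present")

    @property
    def site_ids(self) -> list:
        return list(self.incidence.index)


@dataclass
class PCQRecords:
    """Point-centered-quarter field records.

    One row per sampled tree: site, point index, quarter index (1..4),
    point-to-tree distance in meters, tree species, diameter at breast
    height in cm, conifer and standing-dead flags.
    """

    data: pd.DataFrame
    points_per_site: int = 10

    REQUIRED = ("site_id", "point_index", "quarter_index", "distance_m",
                "tree_species_id", "dbh_cm", "is_conifer", "is_dead")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValidationError(f"PCQ table missing columns: {missing}")
        d = self.data
        if (d["distance_m"] <= 0).any():
            raise ValidationError("PCQ distances must be positive")
        if (d["dbh_cm"] <= 0).any():
            raise ValidationError("PCQ dbh values must be positive")
        if not d["quarter_index"].isin((1, 2, 3, 4)).all():
            raise ValidationError("quarter_index must be in 1..4")
        sizes = d.groupby(["site_id", "point_index"])["quarter_index"].nunique()
        self.incomplete_points = [tuple(k) for k, v in sizes.items() if v != 4]
        if self.incomplete_points:
            logger.warning("PCQ points without 4 quarters: %s", self.incomplete_points)

    @property
    def site_ids(self) -> list:
        return sorted(self.data["site_id"].unique().tolist())


def read_pcq_records(path: str | Path, points_per_site: int = 10) -> PCQRecords:
    df = _read_delimited(path, index_col=None)
    return PCQRecords(df, points_per_site=points_per_site)


@dataclass
class LandscapeTable:
    """Per-site landscape composition inside 200 m and 500 m buffers.

    Columns: area fractions per class (each in [0,1], summing to at most 1),
    total habitat boundary length inside the buffer, and straight-line
    distances to the reserve edge, nearest canal and nearest industrial area.
    """

    data: pd.DataFrame
    radii: tuple[int, ...] = (200, 500)

    def __post_init__(self) -> None:
        d = self.data
        required = ["site_id", "radius_m", "edge_length_m", *LANDSCAPE_CLASSES, *LANDSCAPE_DISTANCES]
        missing = [c for c in required if c not in d.columns]
        if missing:
            raise ValidationError(f"landscape table missing columns: {missing}")
        fr = d[list(LANDSCAPE_CLASSES)].to_numpy(dtype=float)
        if (fr < 0).any() or (fr > 1).any():
            raise ValidationError("class fractions must lie in [0,1]")
        sums = d[list(LANDSCAPE_CLASSES)].sum(axis=1)
        if (sums > 1 + 1e-6).any():
            bad = d.loc[sums > 1 + 1e-6, "site_id"].tolist()
            raise ValidationError(f"class fractions sum above 1 for sites: {bad}")
        if (d[list(LANDSCAPE_DISTANCES)] < 0).to_numpy().any():
            raise ValidationError("distances must be non-negative")
        for sid, sub in d.groupby("site_id"):
            if set(sub["radius_m"]) != set(self.radii):
                raise ValidationError(
                    f"site {sid!r} lacks rows for radii {self.radii}"
                )

    @property
    def site_ids(self) -> list:
        return sorted(self.data["site_id"].unique().tolist())


def read_landscape_table(path: str | Path) -> LandscapeTable:
    df = _read_delimited(path, index_col=None)
    return LandscapeTable(df)


def align_tables(cm: CommunityMatrix, env: EnvTable) -> tuple[CommunityMatrix, EnvTable]:
    """Restrict a community matrix and an environmental table to their shared
    sites, in deterministic (lexicographic) order."""
    shared = sorted(set(cm.site_ids) & set(env.site_ids), key=str)
    if not shared:
        raise ValidationError("community matrix and env table share no sites")
    dropped = (set(cm.site_ids) | set(env.site_ids)) - set(shared)
    if dropped:
        logger.warning("align_tables dropped sites: %s", sorted(map(str, dropped)))
    group = cm.group.loc[shared] if cm.group is not None else None
    return (
        CommunityMatrix(cm.counts.loc[shared], group),
        EnvTable(env.data.loc[shared], env.units),
    )


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    seed: int | None = None,
    config: Mapping | None = None,
) -> dict:
    """Write result tables as CSV plus a JSON manifest.

    The manifest records file names, row counts, the run seed and a hash of
    the configuration so that any output file can be traced to the exact
    run that produced it.  Returns the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "files": {},
    }
    for name, table in tables.items():
        fname = f"{name}.csv"
        table.to_csv(out_dir / fname)
        manifest["files"][fname] = {"rows": int(table.shape[0])}
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
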