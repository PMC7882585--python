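"""Config-driven orchestration of the full analysis workflow.

One :func:`run_study` call reproduces the study workflow on synthetic or
user data: environmental screening between fragments, per-fragment local
and landscape PCAs, diversity partitioning with null-standardized beta,
stepwise-AIC models of beta_dev on PC scores, a between-fragment
PERMANOVA, per-fragment constrained ordinations (CAP) and indicator
species analysis.  Every stochastic stage derives its own seed from the
run seed, so identical config + seed reproduces the output bundle
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import (
    CommunityMatrix,
    EnvTable,
    ValidationError,
    align_tables,
    config_hash,
    read_community_matrix,
    read_env_table,
    write_results,
)
from .distance import bray_curtis, cap_fit, permanova
from .diversity import beta_dev, overlap_summary
from .environment import pca_varimax
from .indicators import indval
from .models import mann_whitney, screening_table, stepwise_aic
from .simulate import ScenarioTruth, generate_scenario

logger = logging.getLogger("fragbeta")


class PipelineError(RuntimeError):
    """A named stage of the pipeline failed."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


_KNOWN_KEYS = {
    "seed", "out_dir", "community_path", "community_orientation", "env_path",
    "group_column", "scenario", "n_rand", "n_perm", "bias_correction",
    "transform", "cap_term_mode", "local_vars", "landscape_vars",
    "cap_local_axes", "cap_landscape_axes", "indval_alpha",
}


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int
    out_dir: str = "results"
    # either file inputs ...
    community_path: str | None = None
    community_orientation: str = "sites-rows"
    env_path: str | None = None
    group_column: str | None = "group"
    # ... or a synthetic scenario
    scenario: dict | None = None
    # analysis toggles
    n_rand: int = 999
    n_perm: int = 999
    bias_correction: str = "chao_shen"
    transform: str = "sqrt"
    cap_term_mode: str = "sequential"
    local_vars: list = field(default_factory=list)
    landscape_vars: list = field(default_factory=list)
    cap_local_axes: int = 3
    cap_landscape_axes: int = 3
    indval_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("a seed is mandatory")
        if self.scenario is None and self.community_path is None:
            raise ValidationError("config needs either a scenario or a community_path")
        if self.bias_correction not in ("none", "chao_shen"):
            raise ValidationError(f"unknown bias_correction {self.bias_correction!r}")
        if self.transform not in ("none", "sqrt"):
            raise ValidationError(f"unknown transform {self.transform!r}")
        if self.cap_term_mode not in ("sequential",):
            raise ValidationError(f"unknown cap_term_mode {self.cap_term_mode!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _load_inputs(config: RunConfig):
    if config.scenario is not None:
        truth = ScenarioTruth(**{**config.scenario, "seed": config.scenario.get("seed", config.seed)})
        data = generate_scenario(truth)
        return data.community, data.env
    cm = read_community_matrix(config.community_path, config.community_orientation)
    env = read_env_table(config.env_path) if config.env_path else None
    if env is not None and config.group_column and config.group_column in env.data.columns:
        raise ValidationError("group labels belong in the community matrix input")
    return cm, env


def run_study(config: RunConfig) -> dict:
    """Execute the full workflow and write the result bundle.

    Returns a dict of result objects keyed by stage; CSV outputs plus a
    JSON manifest land in ``config.out_dir``.  The first failing stage
    raises :class:`PipelineError`; tables produced before the failure are
    still written, and the manifest marks the run incomplete.
    """
    t0 = time.time()
    rng = np.random.default_rng(config.seed)
    stage_seeds = {name: int(rng.integers(2**31)) for name in
                   ("partition", "permanova", "cap", "indval")}
    results: dict = {}
    tables: dict[str, pd.DataFrame] = {}
    failed_stage = None

    def stage(name):
        def deco(fn):
            nonlocal failed_stage
            if failed_stage:
                return
            t = time.time()
            try:
                fn()
                logger.info("stage %s done in %.2fs", name, time.time() - t)
            except Exception as exc:
                failed_stage = (name, exc)
        return deco

    cm, env = _load_inputs(config)
    if cm.group is None:
        raise ValidationError("community matrix must carry fragment group labels")
    if env is not None:
        cm, env = align_tables(cm, env)
    fragments = cm.groups()

    local_vars = config.local_vars or [v for v in (env.variables if env else [])
                                       if not _is_landscape_name(v)]
    landscape_vars = config.landscape_vars or [v for v in (env.variables if env else [])
                                               if _is_landscape_name(v)]
    if env is not None:
        missing = [v for v in (*local_vars, *landscape_vars) if v not in env.variables]
        if missing:
            raise ValidationError(f"config requests missing env columns: {missing}")

    @stage("overlap")
    def _overlap():
        tables["species_overlap"] = overlap_summary(cm)
        results["overlap"] = tables["species_overlap"]

    @stage("screening")
    def _screening():
        if env is None:
            return
        tables["screening"] = screening_table(env.data, cm.group)
        results["screening"] = tables["screening"]

    pca_results: dict = {}

    @stage("pca")
    def _pca():
        if env is None:
            return
        for frag in fragments:
            sub = env.data.loc[cm.group == frag]
            for scale, varlist in (("local", local_vars), ("landscape", landscape_vars)):
                if len(varlist) < 2:
                    continue
                res = pca_varimax(sub, varlist)
                pca_results[(frag, scale)] = res
                tables[f"pca_{scale}_{frag}_loadings"] = res.loadings
                tables[f"pca_{scale}_{frag}_scores"] = res.scores
                tables[f"pca_{scale}_{frag}_summary"] = pd.DataFrame(
                    {
                        "eigenvalue_prerotation": res.eigenvalues[: res.n_axes],
                        "explained_fraction": res.explained_fraction,
                    },
                    index=res.axis_names,
                )
        results["pca"] = pca_results

    partitions: dict = {}

    @stage("partition")
    def _partition():
        parts = []
        for i, frag in enumerate(fragments):
            part = beta_dev(
                cm, frag, n_rand=config.n_rand,
                seed=stage_seeds["partition"] + i,
                bias_correction=config.bias_correction,
            )
            partitions[frag] = part
            t = part.table.copy()
            t.insert(0, "group", frag)
            t["n_rand"] = part.n_randomizations
            t["seed"] = part.seed
            parts.append(t)
        tables["partition"] = pd.concat(parts)
        results["partition"] = partitions
        if len(fragments) == 2:
            a, b = fragments
            U, z, p = mann_whitney(partitions[a].table["beta_obs"],
                                   partitions[b].table["beta_obs"])
            results["beta_comparison"] = {"U": U, "z": z, "p": p}
            tables["beta_comparison"] = pd.DataFrame(
                [{"U": U, "z": z, "p": p}], index=pd.Index([f"{a}_vs_{b}"], name="contrast")
            )

    @stage("beta_models")
    def _models():
        if env is None or not pca_results:
            return
        model_rows = {}
        for frag in fragments:
            scores = [pca_results[(frag, s)].scores.add_prefix(f"{s}_")
                      for s in ("local", "landscape") if (frag, s) in pca_results]
            if not scores:
                continue
            candidates = pd.concat(scores, axis=1)
            response = partitions[frag].table["beta_dev"].dropna()
            sel = stepwise_aic(response, candidates.loc[response.index])
            model_rows[frag] = sel
            t = sel.coefficients.copy()
            t.insert(0, "group", frag)
            t["adj_r2"] = sel.adj_r2
            t["aic"] = sel.aic
            tables[f"beta_model_{frag}"] = t
        results["beta_models"] = model_rows

    @stage("permanova")
    def _permanova():
        dm = bray_curtis(cm, transform=config.transform)
        res = permanova(dm, cm.group.rename("fragment"),
                        n_perm=config.n_perm, seed=stage_seeds["permanova"])
        results["permanova"] = res
        tables["permanova"] = res.table

    @stage("cap")
    def _cap():
        if env is None or not pca_results:
            return
        for frag in fragments:
            sub = cm.subset_group(frag)
            dm = bray_curtis(sub, transform=config.transform)
            preds = []
            if (frag, "local") in pca_results:
                sc = pca_results[(frag, "local")].scores
                preds.append(sc.iloc[:, : config.cap_local_axes].add_prefix("local_"))
            if (frag, "landscape") in pca_results:
                sc = pca_results[(frag, "landscape")].scores
                preds.append(sc.iloc[:, : config.cap_landscape_axes].add_prefix("landscape_"))
            if not preds:
                continue
            predictors = pd.concat(preds, axis=1)
            model = cap_fit(dm, predictors, n_perm=config.n_perm,
                            seed=stage_seeds["cap"])
            results.setdefault("cap", {})[frag] = model
            t = model.terms.copy()
            t["explained_pct"] = 100.0 * t["explained_fraction"]
            t.loc["Total_constrained"] = {
                "explained_fraction": model.total_constrained,
                "explained_pct": 100.0 * model.total_constrained,
            }
            tables[f"cap_{frag}"] = t

    @stage("indval")
    def _indval():
        res = indval(cm, n_perm=config.n_perm, seed=stage_seeds["indval"])
        results["indval"] = res
        tables["indval"] = res.table
        tables["indval_significant"] = res.significant(config.indval_alpha)

    manifest = write_results(tables, config.out_dir, seed=config.seed,
                             config=config.to_dict())
    manifest["complete"] = failed_stage is None
    manifest["runtime_s"] = round(time.time() - t0, 3)
    if failed_stage:
        manifest["failed_stage"] = failed_stage[0]
    with open(Path(config.out_dir) / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    if failed_stage:
        raise PipelineError(failed_stage[0], failed_stage[1])
    results["manifest"] = manifest
    results["tables"] = tables
    return results


_LANDSCAPE_HINTS = ("habitat", "edge", "reed", "modified", "dist_to", "landscape")


def _is_landscape_name(name: str) -> bool:
    return any(h in name for h in _LANDSCAPE_HINTS)
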