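"""Declarative end-to-end pipeline runner.

A single YAML/dict config drives the stages
simulate -> cohort -> standardize -> covariates -> fit -> diagnose,
executed in dependency order. Every written artifact is recorded in an
append-only manifest with a content hash; re-running an identical config
reproduces identical hashes for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import cohort as cohort_mod
from . import covariates as cov_mod
from . import diagnostics as diag_mod
from . import models as models_mod
from . import standardize as stz_mod
from . import synthetic as syn_mod
from .geography import morans_i_test, write_edge_list

__all__ = ["RunConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "cohort",
    "standardize",
    "covariates",
    "fit_spatial",
    "fit_st_main",
    "fit_st_interaction",
    "diagnose",
)


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    outdir: Path
    seed: int
    stages: tuple[str, ...] = STAGES
    # simulate
    n_rows: int = 12
    n_cols: int = 8
    irregularity: float = 0.15
    years: tuple[int, ...] = tuple(range(2000, 2018))
    target_correlation: float = 0.92
    model_form_truth: str = "st_interaction"
    truth_sigma2: dict = field(
        default_factory=lambda: {
            "u": 0.05, "v": 0.01, "gamma": 0.005, "phi": 0.01, "delta": 0.05
        }
    )
    truth_beta: dict = field(default_factory=dict)
    with_records: bool = False
    n_per_region: int = 200
    # standardize
    spatial_window: int = 5
    # models
    covariate_columns: tuple[str, ...] = ("indigenous",)
    hyperprior: str = "gamma"
    interaction_type: str = "IV"
    n_iterations: int = 2000
    n_burnin: int = 1000
    n_chains: int = 2
    thinning: int = 1
    # diagnostics
    exceedance_threshold: float = 1.0
    moran_permutations: int = 999
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        known = {f for f in cls.__dataclass_fields__ if f != "raw"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in d or "seed" not in d:
            raise ValueError("config must set 'outdir' and 'seed'")
        raw = dict(d)
        d["outdir"] = Path(d["outdir"])
        for key in ("years", "stages", "covariate_columns"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d, raw=raw)
        bad = set(cfg.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return cfg


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: Path) -> None:
        self.path = path
        self.entries: list[dict] = []
        if path.exists():
            self.entries = json.loads(path.read_text())

    def add(self, stage: str, artifact: Path, seed: int, wall: float) -> None:
        self.entries.append(
            {
                "stage": stage,
                "artifact": str(artifact),
                "sha256": _sha256(artifact),
                "seed": seed,
                "wall_seconds": round(wall, 4),
            }
        )
        self.path.write_text(json.dumps(self.entries, indent=2))

    def mark_failed(self, stage: str, error: str) -> None:
        self.entries.append({"stage": stage, "failed": True, "error": error})
        self.path.write_text(json.dumps(self.entries, indent=2))


def run_pipeline(config: RunConfig) -> list[dict]:
    """Execute enabled stages in dependency order; returns manifest entries."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_echo.yaml").write_text(yaml.safe_dump(config.raw))
    manifest = _Manifest(out / "manifest.json")
    state: dict[str, Any] = {}
    seeds = {
        stage: int(s.generate_state(1)[0] % (2**31))
        for stage, s in zip(
            STAGES, np.random.SeedSequence(config.seed).spawn(len(STAGES))
        )
    }

    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        try:
            artifacts = _run_stage(stage, config, state, seeds[stage], out)
        except Exception as exc:
            logger.exception("stage %s failed", stage)
            manifest.mark_failed(stage, repr(exc))
            raise
        wall = time.time() - t0
        logger.info("stage %s done in %.2fs (seed %d)", stage, wall, seeds[stage])
        for a in artifacts:
            manifest.add(stage, a, seeds[stage], wall)
    return manifest.entries


def _require(state: dict, key: str, stage: str):
    if key not in state:
        raise RuntimeError(
            f"stage {stage!r} requires {key!r}; enable the producing stage "
            "or provide it via files"
        )
    return state[key]


def _run_stage(
    stage: str, cfg: RunConfig, state: dict, seed: int, out: Path
) -> list[Path]:
    if stage == "simulate":
        truth = syn_mod.TrueParams(
            beta=dict(cfg.truth_beta), sigma2=dict(cfg.truth_sigma2), seed=seed
        )
        bundle = syn_mod.make_bundle(
            cfg.n_rows,
            cfg.n_cols,
            years=cfg.years,
            truth=truth,
            model_form=cfg.model_form_truth,
            irregularity=cfg.irregularity,
            target_correlation=cfg.target_correlation,
            covariate_columns=tuple(cfg.truth_beta),
            seed=seed,
            with_records=cfg.with_records,
            n_per_region=cfg.n_per_region,
        )
        state["bundle"] = bundle
        state["cube"] = bundle.cube
        paths = []
        p = out / "edges.tsv"
        write_edge_list(bundle.graph, p)
        paths.append(p)
        p = out / "census.csv"
        bundle.census.to_csv(p, index=False)
        paths.append(p)
        p = out / "cube.csv"
        bundle.cube.write(p)
        paths.append(p)
        p = out / "truth.csv"
        with open(p, "w") as fh:
            fh.write("parameter,value\n")
            for k, v in bundle.truth.sigma2.items():
                fh.write(f"sigma2_{k},{v}\n")
            for k, v in bundle.truth.beta.items():
                fh.write(f"beta_{k},{v}\n")
        paths.append(p)
        return paths

    if stage == "cohort":
        bundle = _require(state, "bundle", stage)
        if bundle.records is None:
            logger.info("no person records simulated; cohort stage skipped")
            return []
        statuses = [
            cohort_mod.apply_case_definition(r) for r in bundle.records
        ]
        cube = cohort_mod.build_prevalence_cube(
            statuses, bundle.records, years=cfg.years,
            regions=bundle.graph.region_ids,
        )
        state["cohort_cube"] = cube
        p = out / "cohort_cube.csv"
        cube.write(p)
        p2 = out / "crude_prevalence.csv"
        cohort_mod.crude_prevalence(cube).to_csv(p2, index=False)
        return [p, p2]

    if stage == "standardize":
        cube = _require(state, "cube", stage)
        window = [y for y in cfg.years][-cfg.spatial_window :]
        pooled_cube = cube.pooled(window)
        exp_pooled = stz_mod.expected_counts(pooled_cube, pool_time=True)
        exp_yearly = stz_mod.expected_counts(cube, pool_time=False)
        state["pooled_cube"] = pooled_cube
        state["exp_pooled"] = exp_pooled
        state["exp_yearly"] = exp_yearly
        p1 = out / "expected_pooled.csv"
        stz_mod.standardized_ratio(pooled_cube, exp_pooled).to_csv(p1, index=False)
        p2 = out / "expected_yearly.csv"
        stz_mod.standardized_ratio(cube, exp_yearly).to_csv(p2, index=False)
        return [p1, p2]

    if stage == "covariates":
        bundle = _require(state, "bundle", stage)
        table = cov_mod.assemble_covariates(bundle.census)
        state["covariates"] = table
        p = out / "covariates.csv"
        table.write(p)
        return [p, Path(p).with_suffix(".meta.json")]

    if stage in ("fit_spatial", "fit_st_main", "fit_st_interaction"):
        bundle = _require(state, "bundle", stage)
        if stage == "fit_spatial":
            exp = _require(state, "exp_pooled", stage)
            cube = state["pooled_cube"]
            Y = cube.case_totals()[:, 0]
            ratios = np.log(
                (Y + 0.5) / np.maximum(exp.E, 1e-12)
            )
            moran = morans_i_test(
                ratios, bundle.graph, cfg.moran_permutations, seed=seed
            )
            (out / "moran_pretest.json").write_text(
                json.dumps(
                    {
                        "statistic": moran.statistic,
                        "expected_null": moran.expected_null,
                        "p_value": moran.p_value,
                        "n_permutations": moran.n_permutations,
                    },
                    indent=2,
                )
            )
            mc = models_mod.ModelConfig(
                model_form="spatial",
                covariates=cfg.covariate_columns,
                hyperprior=cfg.hyperprior,
                n_iterations=cfg.n_iterations,
                n_burnin=cfg.n_burnin,
                n_chains=cfg.n_chains,
                thinning=cfg.thinning,
                seed=seed,
            )
            fit = models_mod.fit_model(
                Y, exp, state.get("covariates"), bundle.graph, None, mc
            )
            extra = [out / "moran_pretest.json"]
        else:
            exp = _require(state, "exp_yearly", stage)
            cube = state["cube"]
            Y = cube.case_totals()
            form = "st_main" if stage == "fit_st_main" else "st_interaction"
            mc = models_mod.ModelConfig(
                model_form=form,
                hyperprior=cfg.hyperprior,
                interaction_type=cfg.interaction_type,
                n_iterations=cfg.n_iterations,
                n_burnin=cfg.n_burnin,
                n_chains=cfg.n_chains,
                thinning=cfg.thinning,
                seed=seed,
            )
            fit = models_mod.fit_model(
                Y, exp, None, bundle.graph, Y.shape[1], mc
            )
            extra = []
        state[stage] = fit
        p = out / f"{stage}_draws.csv"
        scalars = ["alpha", "beta"] + [
            f"sigma2_{e}" for e in fit.effects
        ]
        models_mod.write_draws(fit, p, parameters=scalars)
        meta = out / f"{stage}_meta.json"
        models_mod.write_run_metadata(fit, meta)
        return [p, meta] + extra

    if stage == "diagnose":
        produced: list[Path] = []
        for fit_stage in ("fit_spatial", "fit_st_main", "fit_st_interaction"):
            fit = state.get(fit_stage)
            if fit is None:
                continue
            report = diag_mod.build_report(
                fit, pit_seed=seed, exceedance_threshold=cfg.exceedance_threshold
            )
            produced += report.write(out, prefix=f"{fit_stage}_diagnostics")
        if not produced:
            raise RuntimeError("diagnose stage needs at least one fitted model")
        return produced

    raise AssertionError(stage)
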