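"""Bayesian hierarchical Poisson models for areal prevalence mapping.

Three model forms share one MCMC backend:

``spatial``
    log(lambda_i) = log(E_i) + X_i beta + v_i + u_i with a convolution
    (BYM) prior: u ICAR over the adjacency graph, v iid Normal.
``st_main``
    adds an unstructured yearly effect gamma_t and a random-walk-1
    structured effect phi_t.
``st_interaction``
    additionally a space-time interaction field delta_it whose Gaussian
    precision is a Kronecker product of spatial and temporal structure
    matrices (fully structured by default; the unstructured variants are
    selectable via ``interaction_type``).

Precisions get Gamma(1, 0.0005) priors by default, with a
uniform-on-standard-deviation sensitivity option. Sum-to-zero constraints
on u, phi, and both margins of delta are imposed by post-sweep centering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _mcmc
from .geography import (
    AdjacencyGraph,
    IslandRegionError,
    icar_structure_matrix,
    rw1_structure_matrix,
)
from .standardize import ExpectedCounts

__all__ = [
    "ModelConfig",
    "FitResult",
    "icar_full_conditional",
    "fit_model",
    "fitted_relative_risks",
    "write_draws",
]

logger = logging.getLogger(__name__)

MODEL_FORMS = ("spatial", "st_main", "st_interaction")
INTERACTION_TYPES = ("I", "II", "III", "IV")


@dataclass
class ModelConfig:
    """Sampler and prior configuration for :func:`fit_model`."""

    model_form: str = "spatial"
    covariates: tuple[str, ...] = ()
    hyperprior: str = "gamma"  # gamma | uniform
    gamma_shape: float = 1.0
    gamma_rate: float = 0.0005
    uniform_sd_bound: float = 10.0
    n_iterations: int = 5000
    n_burnin: int = 2500
    n_chains: int = 4
    thinning: int = 1
    seed: int = 0
    interaction_type: str = "IV"
    sum_to_zero: bool = True
    sigma2_fixed: dict = field(default_factory=dict)
    intercept_prior_var: float = 1000.0
    beta_prior_var: float = 1000.0
    prior_only: bool = False
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        if self.model_form not in MODEL_FORMS:
            raise ValueError(f"model_form must be one of {MODEL_FORMS}")
        if self.hyperprior not in ("gamma", "uniform"):
            raise ValueError("hyperprior must be 'gamma' or 'uniform'")
        if self.interaction_type not in INTERACTION_TYPES:
            raise ValueError(f"interaction_type must be one of {INTERACTION_TYPES}")
        if self.n_iterations <= self.n_burnin:
            raise ValueError("n_iterations must exceed n_burnin")
        if self.seed is None:
            raise ValueError("seed must be set")
        self.covariates = tuple(self.covariates)


@dataclass
class FitResult:
    """Posterior draws plus data references and convergence summaries.

    ``draws`` arrays have the total kept draw count as their leading axis
    (chains concatenated; ``chain_id`` maps draws to chains). ``log_rr``
    reconstructs the linear predictor net of the offset, so relative risks
    are ``exp(log_rr)`` and fitted rates ``E * exp(log_rr)``.
    """

    draws: dict[str, np.ndarray]
    chain_id: np.ndarray
    config: ModelConfig
    region_ids: tuple[str, ...]
    years: tuple[int, ...]
    Y: np.ndarray  # (n, T)
    E: np.ndarray  # (n, T)
    X: np.ndarray | None
    mask: np.ndarray  # (n, T) bool: cells contributing to the likelihood
    effects: tuple[str, ...]
    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    @property
    def n_draws(self) -> int:
        return self.draws["alpha"].shape[0]

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_times(self) -> int:
        return self.Y.shape[1]

    def log_rr_draws(self) -> np.ndarray:
        """Per-draw log relative risk, shape (n_draws, n_regions, n_times)."""
        S = self.n_draws
        n, T = self.Y.shape
        out = np.broadcast_to(
            self.draws["alpha"][:, None, None], (S, n, T)
        ).copy()
        if self.X is not None and self.draws["beta"].shape[1]:
            out += (self.draws["beta"] @ self.X.T)[:, :, None]
        for name in ("u", "v"):
            if name in self.draws:
                out += self.draws[name][:, :, None]
        for name in ("gamma", "phi"):
            if name in self.draws:
                out += self.draws[name][:, None, :]
        if "delta" in self.draws:
            out += self.draws["delta"]
        return out

    def rr_draws(self) -> np.ndarray:
        return np.exp(self.log_rr_draws())

    def lambda_draws(self) -> np.ndarray:
        return self.E[None, :, :] * self.rr_draws()


def icar_full_conditional(
    u: Sequence[float],
    i: int | str,
    graph: AdjacencyGraph,
    sigma2_u: float,
) -> tuple[float, float]:
    """Mean and variance of u_i given its neighbors under the ICAR prior:
    Normal(average of neighboring values, sigma2_u / N_i)."""
    if isinstance(i, str):
        i = graph.index[i]
    u = np.asarray(u, dtype=float)
    A = graph.adjacency_matrix()
    Ni = int(A[i].sum())
    if Ni == 0:
        raise IslandRegionError(
            f"region {graph.region_ids[i]!r} has no neighbors"
        )
    mean = float(A[i].toarray().ravel() @ u) / Ni
    return mean, sigma2_u / Ni


def _effects_for(form: str) -> tuple[str, ...]:
    if form == "spatial":
        return ("v", "u")
    if form == "st_main":
        return ("v", "u", "gamma", "phi")
    return ("v", "u", "gamma", "phi", "delta")


def _interaction_structures(
    itype: str, graph: AdjacencyGraph, T: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """Kronecker factors (and joint rank) for the interaction precision."""
    icar = icar_structure_matrix(graph)
    rw1 = rw1_structure_matrix(T)
    n = graph.n_regions
    Ks = icar.entries if itype in ("III", "IV") else np.eye(n)
    rank_s = icar.rank if itype in ("III", "IV") else n
    Kt = rw1.entries if itype in ("II", "IV") else np.eye(T)
    rank_t = rw1.rank if itype in ("II", "IV") else T
    return Ks, Kt, rank_s * rank_t


def fit_model(
    Y: np.ndarray,
    E: ExpectedCounts | np.ndarray,
    X: np.ndarray | Mapping | None,
    graph: AdjacencyGraph,
    T: int | None,
    config: ModelConfig,
    region_ids: Sequence[str] | None = None,
    years: Sequence[int] | None = None,
) -> FitResult:
    """Fit one of the three hierarchical Poisson forms by MCMC.

    ``Y`` and ``E`` are (n,) for the spatial form or (n, T) for the
    spatio-temporal forms, indexed like ``graph.region_ids``. Cells with
    E <= 0 are excluded from the likelihood (logged). The fit is
    reproducible given ``config.seed``; chains run sequentially from
    independent spawned seeds.
    """
    if graph.islands:
        raise IslandRegionError(
            f"model rejects island regions {sorted(graph.islands)}"
        )
    if isinstance(E, ExpectedCounts):
        if region_ids is None:
            region_ids = E.regions
        if years is None and not E.pooled:
            years = E.years
        E = E.as_matrix()
    E = np.asarray(E, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if E.ndim == 1:
        E = E[:, None]
    n = graph.n_regions
    if Y.shape[0] != n or E.shape != Y.shape:
        raise ValueError(
            f"Y {Y.shape} / E {E.shape} inconsistent with {n} regions"
        )
    form = config.model_form
    if form == "spatial":
        if Y.shape[1] != 1:
            raise ValueError("spatial form expects one time slice")
        T = 1
    else:
        T = Y.shape[1] if T is None else int(T)
        if T < 2 or Y.shape[1] != T:
            raise ValueError("spatio-temporal forms require T >= 2 time slices")

    Xmat = None
    if X is not None and len(config.covariates) > 0:
        if hasattr(X, "design_matrix"):
            Xmat = X.design_matrix(config.covariates, graph.region_ids)
        else:
            Xmat = np.asarray(X, dtype=float)
            if Xmat.ndim == 1:
                Xmat = Xmat[:, None]
        if Xmat.shape != (n, len(config.covariates)):
            raise ValueError("design matrix shape mismatch")

    mask = E > 0
    n_excluded = int((~mask).sum())
    if n_excluded:
        logger.info("excluding %d zero-population cells from likelihood", n_excluded)

    effects = _effects_for(form)
    icar = icar_structure_matrix(graph)
    A = graph.adjacency_matrix()
    Ndiag = graph.neighbor_counts().astype(float)
    Kt = rw1_structure_matrix(T).entries if form != "spatial" else None
    if form == "st_interaction":
        Ks_int, Kt_int, rank_delta = _interaction_structures(
            config.interaction_type, graph, T
        )
    else:
        Ks_int = Kt_int = None
        rank_delta = 0

    data = _mcmc.ChainData(
        y=Y,
        E=E,
        mask=mask,
        X=Xmat,
        A=A,
        Ndiag=Ndiag,
        n_components=graph.n_components(),
        Kt=Kt,
        Ks_int=Ks_int,
        Kt_int=Kt_int,
        rank_delta=rank_delta,
        effects=effects,
    )

    seqs = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = [_mcmc.run_chain(data, config, s) for s in seqs]

    n_keep = chains[0]["alpha"].shape[0]
    draws: dict[str, np.ndarray] = {}
    for key in chains[0]:
        draws[key] = np.concatenate([c[key] for c in chains], axis=0)
    chain_id = np.repeat(np.arange(config.n_chains), n_keep)

    # convergence summaries on monitored scalars
    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    monitored = ["alpha"] + [
        f"sigma2_{e}" for e in effects if e not in config.sigma2_fixed
    ]
    for k in range(0 if Xmat is None else Xmat.shape[1]):
        arr = np.stack([c["beta"][:, k] for c in chains])
        rhat[f"beta[{k}]"] = _mcmc.split_rhat(arr)
        ess[f"beta[{k}]"] = _mcmc.ess_geyer(arr)
    for name in monitored:
        arr = np.stack([c[name] for c in chains])
        rhat[name] = _mcmc.split_rhat(arr)
        ess[name] = _mcmc.ess_geyer(arr)

    converged = all(
        np.isnan(v) or v <= config.rhat_threshold for v in rhat.values()
    ) or config.n_chains < 2
    if not converged:
        worst = max(rhat, key=lambda k: (rhat[k] if np.isfinite(rhat[k]) else np.inf))
        warnings.warn(
            f"possible non-convergence: R-hat({worst}) = {rhat[worst]:.3f}",
            stacklevel=2,
        )

    if region_ids is None:
        region_ids = graph.region_ids
    if years is None:
        years = tuple(range(Y.shape[1]))
    return FitResult(
        draws=draws,
        chain_id=chain_id,
        config=config,
        region_ids=tuple(region_ids),
        years=tuple(int(y) for y in years),
        Y=Y,
        E=E,
        X=Xmat,
        mask=mask,
        effects=effects,
        rhat=rhat,
        ess=ess,
        converged=converged,
    )


def fitted_relative_risks(fit: FitResult) -> pd.DataFrame:
    """Posterior median and equal-tailed 95% credible interval of RR per
    region (and year, for spatio-temporal fits)."""
    rr = fit.rr_draws()  # (S, n, T)
    med = np.median(rr, axis=0)
    lo = np.quantile(rr, 0.025, axis=0)
    hi = np.quantile(rr, 0.975, axis=0)
    rows = []
    single = rr.shape[2] == 1
    for i, r in enumerate(fit.region_ids):
        for t, y in enumerate(fit.years):
            rows.append((r, y, med[i, t], lo[i, t], hi[i, t]))
    df = pd.DataFrame(
        rows, columns=["region", "year", "rr_median", "rr_lo", "rr_hi"]
    )
    if single:
        df = df.drop(columns="year")
    return df


def write_draws(
    fit: FitResult,
    path: str | Path,
    parameters: Sequence[str] | None = None,
) -> None:
    """Persist draws as long-format text: parameter, chain, iteration, value."""
    if parameters is None:
        parameters = list(fit.draws)
    n_per_chain = fit.n_draws // fit.config.n_chains
    with open(path, "w") as fh:
        fh.write("parameter,chain,iteration,value\n")
        for name in parameters:
            arr = fit.draws[name]
            flat = arr.reshape(arr.shape[0], -1)
            for col in range(flat.shape[1]):
                label = name if flat.shape[1] == 1 else f"{name}[{col}]"
                for s in range(flat.shape[0]):
                    fh.write(
                        f"{label},{fit.chain_id[s]},{s % n_per_chain},"
                        f"{flat[s, col]:.10g}\n"
                    )


def write_run_metadata(fit: FitResult, path: str | Path) -> None:
    import json

    meta = {
        "config": asdict(fit.config),
        "rhat": fit.rhat,
        "ess": fit.ess,
        "converged": bool(fit.converged),
        "n_draws": int(fit.n_draws),
        "regions": list(fit.region_ids),
        "years": [int(y) for y in fit.years],
    }
    Path(path).write_text(json.dumps(meta, indent=2, default=float))
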