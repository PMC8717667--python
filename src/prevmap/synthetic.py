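"""Synthetic inputs with known ground truth for the whole pipeline.

Generates an irregular areal lattice, stratified region-year populations,
mutually correlated census covariates, counts drawn generatively from the
fitted model forms (with all latent fields retained as truth), and
person-level administrative record streams that exercise the
case-definition algorithm. Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import (
    AGE_GROUPS,
    SEXES,
    STRATA,
    PersonRecords,
    PrevalenceCube,
    add_years,
)
from .geography import (
    AdjacencyGraph,
    adjacency_from_edges,
    icar_structure_matrix,
    rw1_structure_matrix,
    sample_intrinsic_gmrf,
)

__all__ = [
    "TrueParams",
    "SyntheticBundle",
    "generate_lattice",
    "generate_census",
    "generate_population",
    "simulate_counts",
    "simulate_person_records",
    "make_bundle",
    "DEFAULT_STRATUM_RATES",
]

#: baseline prevalence by age-sex stratum (age-major, F then M within age);
#: rises with age, slightly higher for males — desk-scale defaults only.
DEFAULT_STRATUM_RATES: np.ndarray = np.array(
    [
        r * s
        for r in np.linspace(0.02, 0.22, len(AGE_GROUPS))
        for s in (0.85, 1.15)
    ]
)


@dataclass(frozen=True)
class TrueParams:
    """Ground-truth generative parameters (reporting-scale coefficients)."""

    beta: Mapping[str, float] = field(default_factory=dict)
    sigma2: Mapping[str, float] = field(default_factory=dict)
    baseline_rates: np.ndarray = field(
        default_factory=lambda: DEFAULT_STRATUM_RATES.copy()
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for k, v in self.sigma2.items():
            if v < 0:
                raise ValueError(f"sigma2[{k}] must be nonnegative")


@dataclass
class SyntheticBundle:
    graph: AdjacencyGraph
    census: pd.DataFrame
    population: np.ndarray  # (n_regions, n_years, n_strata)
    cube: PrevalenceCube
    truth: TrueParams
    latents: dict[str, np.ndarray] = field(default_factory=dict)
    records: list[PersonRecords] | None = None


def generate_lattice(
    n_rows: int = 12,
    n_cols: int = 8,
    irregularity: float = 0.0,
    seed: int = 0,
) -> AdjacencyGraph:
    """Rook-contiguity grid with a random fraction of edges rewired.

    ``irregularity`` is the fraction of grid edges removed and replaced with
    random short-range chords; connectivity is preserved (internal retries,
    error after 100 failed attempts).
    """
    import networkx as nx

    if n_rows * n_cols < 4:
        raise ValueError("lattice needs at least 4 cells")
    if not 0.0 <= irregularity <= 1.0:
        raise ValueError("irregularity must lie in [0, 1]")
    base = nx.grid_2d_graph(n_rows, n_cols)
    label = {
        (r, c): f"R{r * n_cols + c:03d}"
        for r in range(n_rows)
        for c in range(n_cols)
    }
    coords = {label[rc]: (float(rc[0]), float(rc[1])) for rc in base.nodes}
    g = nx.relabel_nodes(base, label)
    rng = np.random.default_rng(seed)
    n_rewire = int(round(irregularity * g.number_of_edges()))
    if n_rewire:
        nodes = sorted(g.nodes)
        for _ in range(100):
            trial = g.copy()
            edges = sorted(trial.edges)
            drop_idx = rng.choice(len(edges), size=n_rewire, replace=False)
            trial.remove_edges_from([edges[i] for i in drop_idx])
            added = 0
            guard = 0
            while added < n_rewire and guard < 50 * n_rewire:
                guard += 1
                a, b = rng.choice(len(nodes), size=2, replace=False)
                na, nb = nodes[a], nodes[b]
                (ra, ca), (rb, cb) = coords[na], coords[nb]
                if abs(ra - rb) > 2 or abs(ca - cb) > 2:
                    continue  # keep chords short: plausibly shared borders
                if trial.has_edge(na, nb):
                    continue
                trial.add_edge(na, nb)
                added += 1
            if added == n_rewire and nx.is_connected(trial):
                g = trial
                break
        else:
            raise RuntimeError(
                "could not rewire lattice while preserving connectivity"
            )
    return AdjacencyGraph(
        region_ids=tuple(sorted(g.nodes)),
        edges=frozenset(tuple(sorted(e)) for e in g.edges),
        coords=coords,
    )


def generate_census(
    graph: AdjacencyGraph,
    target_correlation: float = 0.92,
    seed: int = 0,
) -> pd.DataFrame:
    """Census table whose deprivation factor correlates with the Indigenous
    proportion at (approximately) the target value.

    The Indigenous proportion follows a smooth north-south gradient over the
    lattice (logit-scale generation, so proportions land in [0, 1]); the
    shared deprivation factor is built from the standardized Indigenous
    field plus independent noise, then drives the four census variables
    through a one-factor model (loadings 0.8, noise variance 0.36; the
    income loading is negative).
    """
    if not abs(target_correlation) < 1:
        raise ValueError("|target_correlation| must be < 1")
    rng = np.random.default_rng(seed)
    n = graph.n_regions
    if graph.coords is not None:
        rows = np.array([graph.coords[r][0] for r in graph.region_ids])
        grad = (rows - rows.mean()) / (rows.std() + 1e-12)
    else:
        grad = np.linspace(-1.5, 1.5, n)
    latent = grad + 0.4 * rng.standard_normal(n)
    indigenous = expit(-1.2 + 1.3 * (latent - latent.mean()) / latent.std())
    z_ind = (indigenous - indigenous.mean()) / indigenous.std()
    rho = target_correlation
    f = rho * z_ind + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    loading, noise_sd = 0.8, 0.6
    eps = noise_sd * rng.standard_normal((n, 4))
    income = np.exp(np.log(65_000) - 0.25 * (loading * f + eps[:, 0]))
    no_hs = expit(-1.4 + 0.7 * (loading * f + eps[:, 1]))
    unemp = expit(-2.4 + 0.5 * (loading * f + eps[:, 2]))
    lone_parent = expit(-1.7 + 0.6 * (loading * f + eps[:, 3]))
    out = pd.DataFrame(
        {
            "region_id": graph.region_ids,
            "median_household_income": income,
            "prop_no_highschool": np.clip(no_hs, 0.0, 1.0),
            "unemployment_rate": np.clip(unemp, 0.0, 1.0),
            "prop_lone_parent": np.clip(lone_parent, 0.0, 1.0),
            "prop_indigenous": np.clip(indigenous, 0.0, 1.0),
        }
    )
    # ground-truth latent for generator-calibration checks
    out.attrs["deprivation_factor"] = f
    return out


def generate_population(
    graph: AdjacencyGraph,
    years: Sequence[int],
    seed: int = 0,
    mean_region_size: float = 8000.0,
) -> np.ndarray:
    """Region x year x stratum population counts.

    Region totals are log-normal around ``mean_region_size``; the age-sex
    split follows a fixed mildly declining age profile; a small random drift
    perturbs each year.
    """
    rng = np.random.default_rng(seed)
    n = graph.n_regions
    T = len(years)
    region_tot = rng.lognormal(np.log(mean_region_size), 0.5, size=n)
    age_profile = np.linspace(1.4, 0.7, len(AGE_GROUPS))
    stratum_w = np.array([age_profile[AGE_GROUPS.index(ag)] for ag, _ in STRATA])
    stratum_w = stratum_w / stratum_w.sum()
    base = region_tot[:, None] * stratum_w[None, :]
    drift = np.exp(0.02 * rng.standard_normal((n, T, 1)))
    pop = np.maximum(np.round(base[:, None, :] * drift), 5).astype(np.int64)
    return pop


def _draw_latents(
    graph: AdjacencyGraph,
    T: int,
    truth: TrueParams,
    model_form: str,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    n = graph.n_regions
    s2 = dict(truth.sigma2)
    out: dict[str, np.ndarray] = {}
    icar = icar_structure_matrix(graph)
    out["u"] = sample_intrinsic_gmrf(icar, s2.get("u", 0.0), 1, rng)[0]
    out["v"] = np.sqrt(s2.get("v", 0.0)) * rng.standard_normal(n)
    if model_form in ("st_main", "st_interaction"):
        rw1 = rw1_structure_matrix(T)
        out["gamma"] = np.sqrt(s2.get("gamma", 0.0)) * rng.standard_normal(T)
        out["phi"] = sample_intrinsic_gmrf(rw1, s2.get("phi", 0.0), 1, rng)[0]
    if model_form == "st_interaction":
        out["delta"] = _sample_interaction_field(
            icar.entries, rw1_structure_matrix(T).entries,
            s2.get("delta", 0.0), rng,
        )
    return out


def _sample_interaction_field(
    Ks: np.ndarray, Kt: np.ndarray, sigma2: float, rng: np.random.Generator
) -> np.ndarray:
    """Constrained draw from the Kronecker-structured interaction prior.

    Uses the factor eigendecompositions: eigenpairs of the Kronecker
    product are outer products, so coefficients are drawn independently
    with variance sigma2 / (mu_k * nu_l) on the positive spectrum.
    """
    n, T = Ks.shape[0], Kt.shape[0]
    if sigma2 == 0:
        return np.zeros((n, T))
    mu, U = np.linalg.eigh(Ks)
    nu, V = np.linalg.eigh(Kt)
    tol_s = n * np.finfo(float).eps * max(mu.max(), 1.0)
    tol_t = T * np.finfo(float).eps * max(nu.max(), 1.0)
    lam = np.outer(mu, nu)
    pos = (mu[:, None] > tol_s) & (nu[None, :] > tol_t)
    C = np.zeros((n, T))
    C[pos] = rng.standard_normal(int(pos.sum())) * np.sqrt(sigma2 / lam[pos])
    return U @ C @ V.T


def simulate_counts(
    graph: AdjacencyGraph,
    population: np.ndarray,
    covariates,
    truth: TrueParams,
    model_form: str = "spatial",
    years: Sequence[int] | None = None,
    covariate_columns: Sequence[str] = (),
) -> tuple[PrevalenceCube, dict[str, np.ndarray]]:
    """Generate a prevalence cube from the stated model run generatively.

    Latent fields are drawn from their (constrained) priors at the true
    variances; cell intensities are ``population * stratum_rate *
    exp(eta_it)`` and counts are Poisson (clipped to the population in the
    astronomically rare overflow case). Returns the cube and all latent
    truth (including eta).
    """
    rng = np.random.default_rng(truth.seed)
    n, T, J = population.shape
    if n != graph.n_regions or J != len(STRATA):
        raise ValueError("population array misshaped")
    if years is None:
        years = tuple(range(2000, 2000 + T))
    latents = _draw_latents(graph, T, truth, model_form, rng)
    eta = latents["u"][:, None] + latents["v"][:, None]
    if covariate_columns:
        X = covariates.design_matrix(tuple(covariate_columns), graph.region_ids)
        b = np.array([truth.beta[c] for c in covariate_columns])
        eta = eta + (X @ b)[:, None]
    if model_form in ("st_main", "st_interaction"):
        eta = eta + latents["gamma"][None, :] + latents["phi"][None, :]
    if model_form == "st_interaction":
        eta = eta + latents["delta"]
    latents["eta"] = np.broadcast_to(eta, (n, T)).copy()
    rates = truth.baseline_rates
    lam = population * rates[None, None, :] * np.exp(eta)[:, :, None]
    Y = rng.poisson(lam)
    over = Y > population
    if over.any():
        Y = np.minimum(Y, population)
    cube = PrevalenceCube(
        regions=graph.region_ids,
        years=tuple(int(y) for y in years),
        Y=Y,
        n=population,
    )
    return cube, latents


# ---------------------------------------------------------------------------
# Person-level record simulation


#: event patterns and whether they satisfy the case definition
CASE_PATTERNS = ("hospital", "two_claims", "claim_two_drugs")
NONCASE_PATTERNS = ("none", "one_claim", "claim_one_drug", "claims_far_apart")


def simulate_person_records(
    graph: AdjacencyGraph,
    n_per_region: int,
    years: Sequence[int],
    case_fraction: float = 0.10,
    seed: int = 0,
    emigration_rate: float = 0.02,
    death_rate: float = 0.02,
    return_intent: bool = False,
) -> list[PersonRecords] | tuple[list[PersonRecords], dict]:
    """Person histories inducing roughly ``case_fraction`` prevalence.

    Cases receive one of the qualifying event patterns (a hospital event,
    two claims inside the window, or one claim plus two drug events inside
    the window); non-cases get sub-threshold patterns that stress the
    algorithm. A small fraction of persons die or emigrate mid-study.
    """
    rng = np.random.default_rng(seed)
    years = sorted(int(y) for y in years)
    y0, y1 = years[0], years[-1]
    study_start = date(y0 - 3, 4, 1)  # ascertainment run-in
    study_end = date(y1, 12, 31)
    persons: list[PersonRecords] = []
    intents: dict[str, dict] = {}
    for region in graph.region_ids:
        for k in range(n_per_region):
            pid = f"{region}-P{k:05d}"
            sex = "F" if rng.random() < 0.5 else "M"
            age_at_start = int(rng.integers(38, 82))
            birth = add_years(study_start, -age_at_start)
            end: date | None = None
            end_reason = None
            roll = rng.random()
            if roll < emigration_rate:
                end_reason = "emigration"
            elif roll < emigration_rate + death_rate:
                end_reason = "death"
            if end_reason is not None:
                end_year = int(rng.integers(y0 + 1, y1 + 1))
                end = date(end_year, int(rng.integers(1, 13)), 15)
            events: list[tuple[date, str]] = []
            is_case = rng.random() < case_fraction
            onset_year = int(rng.integers(y0 - 2, y1))
            anchor = date(onset_year, int(rng.integers(1, 13)), 10)
            if end is not None and anchor >= end:
                anchor = date(max(y0 - 2, end.year - 1), 1, 10)
            if is_case:
                pattern = CASE_PATTERNS[rng.integers(len(CASE_PATTERNS))]
                if pattern == "hospital":
                    events = [(anchor, "hospital")]
                elif pattern == "two_claims":
                    events = [
                        (anchor, "claim"),
                        (_shift_days(anchor, int(rng.integers(30, 700))), "claim"),
                    ]
                else:
                    events = [
                        (anchor, "claim"),
                        (_shift_days(anchor, 60), "drug"),
                        (_shift_days(anchor, int(rng.integers(90, 700))), "drug"),
                    ]
            else:
                pattern = NONCASE_PATTERNS[rng.integers(len(NONCASE_PATTERNS))]
                if pattern == "one_claim":
                    events = [(anchor, "claim")]
                elif pattern == "claim_one_drug":
                    events = [(anchor, "claim"), (_shift_days(anchor, 90), "drug")]
                elif pattern == "claims_far_apart":
                    second = _shift_days(anchor, int(365.25 * 6) + 30)
                    events = [(anchor, "claim"), (second, "claim")]
            planned = len(events)
            events = [
                (d, s)
                for d, s in events
                if d <= study_end and (end is None or d < end)
            ]
            intents[pid] = {
                "is_case": is_case,
                "pattern": pattern if events or not is_case else "truncated",
                "events_retained": len(events) == planned,
            }
            persons.append(
                PersonRecords(
                    person_id=pid,
                    sex=sex,
                    birth_date=birth,
                    coverage_spells=((study_start, end),),
                    region_by_year={y: region for y in range(y0 - 3, y1 + 1)},
                    events=tuple(sorted(events)),
                    end_reason=end_reason,
                )
            )
    if return_intent:
        return persons, intents
    return persons


def _shift_days(d: date, days: int) -> date:
    from datetime import timedelta

    return d + timedelta(days=days)


def make_bundle(
    n_rows: int = 12,
    n_cols: int = 8,
    years: Sequence[int] = tuple(range(2000, 2018)),
    truth: TrueParams | None = None,
    model_form: str = "st_interaction",
    irregularity: float = 0.15,
    target_correlation: float = 0.92,
    covariate_columns: Sequence[str] = (),
    seed: int = 0,
    with_records: bool = False,
    n_per_region: int = 200,
) -> SyntheticBundle:
    """One-call synthetic bundle with independent seeds per component."""
    from .covariates import assemble_covariates

    ss = np.random.SeedSequence(seed).spawn(5)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    if truth is None:
        truth = TrueParams(
            beta={},
            sigma2={"u": 0.05, "v": 0.01, "gamma": 0.005, "phi": 0.01, "delta": 0.05},
            seed=sub[3],
        )
    graph = generate_lattice(n_rows, n_cols, irregularity, seed=sub[0])
    census = generate_census(graph, target_correlation, seed=sub[1])
    population = generate_population(graph, years, seed=sub[2])
    cov = assemble_covariates(census)
    cube, latents = simulate_counts(
        graph,
        population,
        cov,
        truth,
        model_form=model_form,
        years=years,
        covariate_columns=covariate_columns,
    )
    records = None
    if with_records:
        records = simulate_person_records(
            graph, n_per_region, years, seed=sub[4]
        )
    return SyntheticBundle(
        graph=graph,
        census=census,
        population=population,
        cube=cube,
        truth=truth,
        latents=latents,
        records=records,
    )
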