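"""Region-level covariate construction.

A single deprivation factor score is extracted from four census variables
(median household income, proportion without a high-school diploma,
unemployment rate, lone-parent proportion) by one-factor maximum-likelihood
factor analysis with regression (Thomson) scores, oriented so that larger
scores mean greater deprivation. The design table expresses covariates on
their reporting scales (deprivation per index unit, Indigenous proportion
per 0.1 step).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis

__all__ = [
    "CENSUS_COLUMNS",
    "CovariateTable",
    "validate_census",
    "sefi2_scores",
    "assemble_covariates",
    "read_census",
]

CENSUS_COLUMNS = (
    "median_household_income",
    "prop_no_highschool",
    "unemployment_rate",
    "prop_lone_parent",
    "prop_indigenous",
)
FACTOR_COLUMNS = CENSUS_COLUMNS[:4]
PROPORTION_COLUMNS = CENSUS_COLUMNS[1:]


def validate_census(census: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("region_id", *CENSUS_COLUMNS) if c not in census.columns]
    if missing:
        raise ValueError(f"census table missing columns: {missing}")
    if census["region_id"].duplicated().any():
        raise ValueError("duplicate region_id in census table")
    if (census["median_household_income"] <= 0).any():
        raise ValueError("median_household_income must be positive")
    for c in PROPORTION_COLUMNS:
        col = census[c]
        if ((col < 0) | (col > 1)).any():
            raise ValueError(f"{c} must lie in [0, 1]")
    return census


def sefi2_scores(
    census: pd.DataFrame, weights: np.ndarray | None = None
) -> pd.Series:
    """One-factor scores of the four standardized census variables.

    Returned scores have mean zero and are sign-oriented so their
    correlation with the unemployment rate is nonnegative (larger score =
    greater deprivation). Optional ``weights`` (analytic region weights)
    switch to a weighted principal-factor solution.
    """
    census = validate_census(census)
    if len(census) < 5:
        raise ValueError("need at least 5 regions for a factor analysis")
    X = census.loc[:, FACTOR_COLUMNS].to_numpy(dtype=float)
    sd = X.std(axis=0)
    tol = 1e-12 * (np.abs(X).mean(axis=0) + 1.0)
    if np.any(sd <= tol):
        flat = [c for c, s, t in zip(FACTOR_COLUMNS, sd, tol) if s <= t]
        raise ValueError(f"constant census variable(s): {flat}")
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    corr = np.corrcoef(Z, rowvar=False)
    if weights is not None:
        scores = _principal_factor_scores(Z, np.asarray(weights, dtype=float))
    elif np.linalg.matrix_rank(corr, tol=1e-10) < corr.shape[0]:
        # perfectly collinear inputs: fall back to the shared standardized
        # variable (rank-1 structure), which is the limit of the one-factor fit
        scores = _principal_factor_scores(Z, None)
    else:
        try:
            fa = FactorAnalysis(n_components=1, random_state=0, max_iter=5000)
            scores = fa.fit_transform(Z)[:, 0]
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise ValueError(
                "singular correlation matrix; jitter or drop a collinear "
                "census variable"
            ) from exc
    unemp = census["unemployment_rate"].to_numpy(dtype=float)
    if np.std(scores) > 0 and np.corrcoef(scores, unemp)[0, 1] < 0:
        scores = -scores
    scores = scores - scores.mean()
    return pd.Series(scores, index=census["region_id"].to_numpy(), name="sefi2")


def _principal_factor_scores(Z: np.ndarray, weights: np.ndarray | None) -> np.ndarray:
    """Iterated principal-factor loadings + regression scores.

    Used for the weighted variant (the ML backend has no analytic-weight
    support) and as the degenerate-correlation fallback.
    """
    if weights is None:
        w = np.ones(Z.shape[0])
    else:
        w = weights / weights.sum() * Z.shape[0]
    mu = (w[:, None] * Z).sum(axis=0) / w.sum()
    Zc = Z - mu
    sd = np.sqrt((w[:, None] * Zc**2).sum(axis=0) / w.sum())
    Zc = Zc / sd
    R = (w[:, None] * Zc).T @ Zc / w.sum()
    h2 = np.clip(1.0 - 1.0 / np.diag(np.linalg.pinv(R)), 0.1, 0.995)  # SMC start
    for _ in range(200):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        evals, evecs = np.linalg.eigh(Rr)
        lam = evecs[:, -1] * np.sqrt(max(evals[-1], 0.0))
        h2_new = np.minimum(lam**2, 0.995)
        if np.max(np.abs(h2_new - h2)) < 1e-10:
            h2 = h2_new
            break
        h2 = h2_new
    Rr = R.copy()
    np.fill_diagonal(Rr, h2)
    evals, evecs = np.linalg.eigh(Rr)
    lam = evecs[:, -1] * np.sqrt(max(evals[-1], 0.0))
    beta = np.linalg.lstsq(R, lam, rcond=None)[0]
    return Zc @ beta


@dataclass(frozen=True)
class CovariateTable:
    """Design-ready covariates with their reporting-scale metadata."""

    table: pd.DataFrame  # region_id, sefi2, indigenous (scaled)
    scaling: dict = field(default_factory=dict)
    log: dict = field(default_factory=dict)

    def design_matrix(self, columns: tuple[str, ...], regions) -> np.ndarray:
        df = self.table.set_index("region_id").loc[list(regions)]
        return df.loc[:, list(columns)].to_numpy(dtype=float)

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)
        sidecar = Path(path).with_suffix(".meta.json")
        import json

        sidecar.write_text(
            json.dumps({"scaling": self.scaling, "log": self.log}, indent=2)
        )


def assemble_covariates(
    census: pd.DataFrame,
    scaling: dict | None = None,
    weights: np.ndarray | None = None,
) -> CovariateTable:
    """Build the model design table on reporting scales.

    Default scaling: the deprivation score enters per 1 index unit and the
    Indigenous proportion per 0.1 proportion step (a proportion of 0.25
    becomes a design value of 2.5). Records the realized correlation between
    the two covariates in the assembly log.
    """
    census = validate_census(census)
    scaling = {"sefi2_step": 1.0, "indigenous_step": 0.1, **(scaling or {})}
    scores = sefi2_scores(census, weights=weights)
    indig = census["prop_indigenous"].to_numpy(dtype=float)
    table = pd.DataFrame(
        {
            "region_id": census["region_id"].to_numpy(),
            "sefi2": scores.to_numpy() / scaling["sefi2_step"],
            "indigenous": indig / scaling["indigenous_step"],
        }
    )
    log = {
        "corr_sefi2_indigenous": float(
            np.corrcoef(scores.to_numpy(), indig)[0, 1]
        )
    }
    return CovariateTable(table=table, scaling=scaling, log=log)


def read_census(path: str | Path) -> pd.DataFrame:
    return validate_census(pd.read_csv(path, dtype={"region_id": str}))
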