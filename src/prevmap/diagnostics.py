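"""Model assessment and mapping outputs for fitted prevalence models.

Implements the full diagnostic surface: DIC (posterior-mean deviance plus
effective parameter count), conditional predictive ordinates via the
harmonic-mean identity, randomized probability integral transforms for
count data, empirical variance shares across random-effect terms, posterior
exceedance probabilities Pr(RR > threshold), and ranked credible-interval
tables with a three-way significance class.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, xlogy
from scipy.stats import poisson

from .models import FitResult, fitted_relative_risks

__all__ = [
    "DiagnosticsReport",
    "dic",
    "cpo",
    "pit",
    "variance_shares",
    "exceedance_probabilities",
    "rr_interval_ranking",
    "build_report",
]


def _poisson_loglik_matrix(fit: FitResult) -> np.ndarray:
    """Per-draw, per-cell Poisson log-likelihood over masked cells.

    Returns shape (n_draws, n_obs) where n_obs is the number of cells with
    positive expected counts.
    """
    lam = fit.lambda_draws()  # (S, n, T)
    m = fit.mask
    y = fit.Y[m]
    lam_obs = lam[:, m]
    return xlogy(y[None, :], lam_obs) - lam_obs - gammaln(y + 1.0)[None, :]


def dic(fit: FitResult) -> tuple[float, float]:
    """Deviance information criterion and effective parameter count.

    DIC = Dbar + pD with pD = Dbar - D(posterior mean), where the plug-in
    deviance is evaluated at the posterior mean of the linear predictor.
    """
    if fit.n_draws < 1:
        raise ValueError("no posterior draws")
    ll = _poisson_loglik_matrix(fit)
    dev_draws = -2.0 * ll.sum(axis=1)
    dbar = float(dev_draws.mean())
    eta_mean = fit.log_rr_draws().mean(axis=0)
    lam_hat = (fit.E * np.exp(eta_mean))[fit.mask]
    y = fit.Y[fit.mask]
    d_hat = float(
        -2.0 * np.sum(xlogy(y, lam_hat) - lam_hat - gammaln(y + 1.0))
    )
    p_eff = dbar - d_hat
    return dbar + p_eff, p_eff


def cpo(fit: FitResult) -> tuple[np.ndarray, float]:
    """Conditional predictive ordinates via the harmonic-mean identity.

    CPO_i = [ (1/S) sum_s 1 / p(y_i | theta_s) ]^-1, summarized as
    sum_i log CPO_i. Draws with vanishing likelihood for some observation
    make that CPO_i unstable; a warning is emitted and the harmonic mean is
    computed on the clipped log-likelihoods.
    """
    ll = _poisson_loglik_matrix(fit)  # (S, n_obs)
    S = ll.shape[0]
    bad = ~np.isfinite(ll)
    if bad.any():
        n_bad = int(bad.any(axis=0).sum())
        warnings.warn(
            f"{n_bad} observation(s) have zero-likelihood draws; "
            "their CPO values are unstable",
            stacklevel=2,
        )
        ll = np.clip(ll, -700.0, None)
    log_cpo = np.log(S) - logsumexp(-ll, axis=0)
    return np.exp(log_cpo), float(log_cpo.sum())


def pit(
    fit: FitResult, randomize: bool = True, seed: int = 0
) -> np.ndarray:
    """Probability integral transform against the posterior-predictive CDF.

    For discrete counts the randomized PIT draws U ~ Uniform(F(y-1), F(y))
    per observation, with F the draw-mixture Poisson CDF; the
    non-randomized variant returns the interval midpoint.
    """
    lam = fit.lambda_draws()[:, fit.mask]  # (S, n_obs)
    y = fit.Y[fit.mask]
    F_hi = poisson.cdf(y[None, :], lam).mean(axis=0)
    F_lo = poisson.cdf(y[None, :] - 1.0, lam).mean(axis=0)
    if randomize:
        rng = np.random.default_rng(seed)
        return F_lo + rng.random(y.size) * (F_hi - F_lo)
    return 0.5 * (F_lo + F_hi)


#: display names used in reports, keyed by internal effect names
EFFECT_LABELS = {
    "v": "unstructured_spatial",
    "u": "structured_spatial",
    "gamma": "unstructured_temporal",
    "phi": "structured_temporal",
    "delta": "space_time_interaction",
}


def variance_shares(fit: FitResult) -> dict[str, float]:
    """Percent of total random-effect variance per term.

    Each term's variance is the empirical variance, across its own index,
    of the posterior-mean effect values; shares are normalized to sum to
    100.
    """
    variances: dict[str, float] = {}
    for name in fit.effects:
        mean_field = fit.draws[name].mean(axis=0).ravel()
        if mean_field.size < 2:
            continue
        variances[EFFECT_LABELS[name]] = float(np.var(mean_field, ddof=1))
    total = sum(variances.values())
    if total <= 0:
        raise ValueError("all random-effect variances are zero; shares undefined")
    return {k: 100.0 * v / total for k, v in variances.items()}


def exceedance_probabilities(
    fit: FitResult, threshold: float = 1.0
) -> pd.DataFrame:
    """Posterior Pr(RR > threshold) per region(-year)."""
    rr = fit.rr_draws()  # (S, n, T)
    prob = (rr > threshold).mean(axis=0)
    rows = []
    for i, r in enumerate(fit.region_ids):
        for t, y in enumerate(fit.years):
            rows.append((r, y, prob[i, t]))
    df = pd.DataFrame(rows, columns=["region", "year", "exceedance"])
    if rr.shape[2] == 1:
        df = df.drop(columns="year")
    return df


def rr_interval_ranking(fit: FitResult) -> pd.DataFrame:
    """Units sorted by posterior median RR with a significance class:
    'above'/'below' when the 95% interval excludes 1, else 'null'."""
    df = fitted_relative_risks(fit)

    def classify(row) -> str:
        if row.rr_lo > 1.0:
            return "above"
        if row.rr_hi < 1.0:
            return "below"
        return "null"

    df["class"] = [classify(r) for r in df.itertuples(index=False)]
    return df.sort_values(
        "rr_median", ascending=False, kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class DiagnosticsReport:
    dic: float
    p_effective: float
    sum_log_cpo: float
    cpo_i: np.ndarray
    pit_i: np.ndarray
    variance_shares: dict[str, float]
    exceedance: pd.DataFrame
    rr_summary: pd.DataFrame
    pit_seed: int = 0

    def write(self, out_dir: str | Path, prefix: str = "diagnostics") -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary_path = out_dir / f"{prefix}_summary.json"
        summary_path.write_text(
            json.dumps(
                {
                    "dic": self.dic,
                    "p_effective": self.p_effective,
                    "sum_log_cpo": self.sum_log_cpo,
                    "variance_shares_pct": self.variance_shares,
                    "pit_seed": self.pit_seed,
                },
                indent=2,
            )
        )
        obs_path = out_dir / f"{prefix}_observations.csv"
        pd.DataFrame({"cpo": self.cpo_i, "pit": self.pit_i}).to_csv(
            obs_path, index_label="obs"
        )
        unit_path = out_dir / f"{prefix}_units.csv"
        unit = self.rr_summary.merge(
            self.exceedance,
            on=[c for c in ("region", "year") if c in self.exceedance.columns],
        )
        unit.to_csv(unit_path, index=False)
        return [summary_path, obs_path, unit_path]


def build_report(
    fit: FitResult, pit_seed: int = 0, exceedance_threshold: float = 1.0
) -> DiagnosticsReport:
    d, p_eff = dic(fit)
    cpo_i, sum_log = cpo(fit)
    return DiagnosticsReport(
        dic=d,
        p_effective=p_eff,
        sum_log_cpo=sum_log,
        cpo_i=cpo_i,
        pit_i=pit(fit, randomize=True, seed=pit_seed),
        variance_shares=variance_shares(fit),
        exceedance=exceedance_probabilities(fit, exceedance_threshold),
        rr_summary=rr_interval_ranking(fit),
        pit_seed=pit_seed,
    )


def export_geojson_choropleth(
    fit: FitResult,
    geojson: dict | str | Path,
    out_path: str | Path,
    id_property: str = "region_id",
    exceedance_threshold: float = 1.0,
    year: int | None = None,
) -> None:
    """Join RR summaries and exceedance probabilities onto GeoJSON features."""
    if not isinstance(geojson, dict):
        geojson = json.loads(Path(geojson).read_text())
    rr = rr_interval_ranking(fit)
    exc = exceedance_probabilities(fit, exceedance_threshold)
    if "year" in rr.columns:
        if year is None:
            year = rr["year"].max()
        rr = rr[rr["year"] == year]
        exc = exc[exc["year"] == year]
    rr = rr.set_index("region")
    exc = exc.set_index("region")
    for feat in geojson["features"]:
        rid = str(feat["properties"][id_property])
        if rid not in rr.index:
            continue
        row = rr.loc[rid]
        feat["properties"].update(
            rr_median=float(row.rr_median),
            rr_lo=float(row.rr_lo),
            rr_hi=float(row.rr_hi),
            exceedance=float(exc.loc[rid, "exceedance"]),
            **{"class": str(row["class"])},
        )
    Path(out_path).write_text(json.dumps(geojson))
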