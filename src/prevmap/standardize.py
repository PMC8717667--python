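"""Indirect age-sex standardization against the internal (all-region) reference.

Expected counts are obtained by applying reference stratum rates to each
region's stratum populations: E_i = sum_j (Y_j^ref / n_j^ref) * n_ij, either
pooled over the cube's year span (one E per region) or year-by-year (E per
region-year with year-specific reference rates). Observed/expected is the
standardized ratio whose baseline is the reference prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import PrevalenceCube

__all__ = ["ExpectedCounts", "expected_counts", "standardized_ratio"]


@dataclass(frozen=True)
class ExpectedCounts:
    """E per region (pooled) or per region-year, with the reference rates used.

    ``E`` has shape (n_regions,) when pooled over time, else
    (n_regions, n_years). ``reference_rates`` has shape (n_strata,) or
    (n_strata, n_years) correspondingly.
    """

    regions: tuple[str, ...]
    years: tuple[int, ...]
    E: np.ndarray
    reference_rates: np.ndarray
    pooled: bool

    def __post_init__(self) -> None:
        expected_shape = (
            (len(self.regions),)
            if self.pooled
            else (len(self.regions), len(self.years))
        )
        if self.E.shape != expected_shape:
            raise ValueError(
                f"E has shape {self.E.shape}, expected {expected_shape}"
            )

    def as_matrix(self) -> np.ndarray:
        """E broadcast to shape (n_regions, n_years_effective)."""
        return self.E[:, None] if self.pooled else self.E


def expected_counts(cube: PrevalenceCube, pool_time: bool = True) -> ExpectedCounts:
    """Indirectly standardized expected counts with the cube total as reference.

    With ``pool_time`` the reference rates pool counts and populations over
    every year in the cube and one E_i is produced per region; otherwise
    year-specific reference rates give an E for every region-year.

    Zero-case strata contribute a reference rate of 0. A stratum with
    regional population but zero reference population is impossible for an
    internal reference and raises.
    """
    Y = cube.Y.astype(float)  # (n, T, J)
    n = cube.n.astype(float)
    if pool_time:
        y_ref = Y.sum(axis=(0, 1))  # (J,)
        n_ref = n.sum(axis=(0, 1))
        _check_reference(n.sum(axis=1), n_ref)
        rates = np.divide(y_ref, n_ref, out=np.zeros_like(y_ref), where=n_ref > 0)
        E = (n.sum(axis=1) * rates[None, :]).sum(axis=1)  # (n,)
    else:
        y_ref = Y.sum(axis=0)  # (T, J)
        n_ref = n.sum(axis=0)
        _check_reference(n, n_ref[None, :, :].repeat(n.shape[0], axis=0))
        rates = np.divide(y_ref, n_ref, out=np.zeros_like(y_ref), where=n_ref > 0)
        E = (n * rates[None, :, :]).sum(axis=2)  # (n, T)
        rates = rates.T  # (J, T)
    return ExpectedCounts(
        regions=cube.regions,
        years=cube.years,
        E=E,
        reference_rates=rates,
        pooled=pool_time,
    )


def _check_reference(n_regional: np.ndarray, n_ref: np.ndarray) -> None:
    bad = (n_regional > 0) & (np.broadcast_to(n_ref, n_regional.shape) <= 0)
    if bad.any():
        raise ValueError(
            "stratum with regional population but zero reference population"
        )


def standardized_ratio(
    cube: PrevalenceCube, expected: ExpectedCounts
) -> pd.DataFrame:
    """Observed / expected per region (pooled) or region-year.

    Cells with E = 0 get a missing ratio.
    """
    if expected.regions != cube.regions:
        raise ValueError("region index mismatch between cube and expected counts")
    obs = cube.case_totals().astype(float)  # (n, T)
    rows = []
    if expected.pooled:
        obs_tot = obs.sum(axis=1)
        for i, r in enumerate(cube.regions):
            e = expected.E[i]
            ratio = obs_tot[i] / e if e > 0 else np.nan
            rows.append((r, obs_tot[i], e, ratio))
        return pd.DataFrame(rows, columns=["region", "observed", "E", "ratio"])
    if expected.years != cube.years:
        raise ValueError("year index mismatch between cube and expected counts")
    for i, r in enumerate(cube.regions):
        for t, y in enumerate(cube.years):
            e = expected.E[i, t]
            ratio = obs[i, t] / e if e > 0 else np.nan
            rows.append((r, y, obs[i, t], e, ratio))
    return pd.DataFrame(rows, columns=["region", "year", "observed", "E", "ratio"])


def write_expected(
    table: pd.DataFrame, path: str | Path
) -> None:
    table.to_csv(path, index=False)
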