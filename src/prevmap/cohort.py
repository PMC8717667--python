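"""Administrative-record case ascertainment and the prevalence cube.

A person is ascertained as a prevalent case from pre-classified event
streams (hospital abstracts, physician claims, drug prescriptions) via a
rolling-window algorithm; once a case, the person stays in the prevalence
numerator until censored by death, emigration, or aging out of the study
window. Annual point prevalence is tabulated at a fixed reference date into
a region x year x age-sex-stratum cube.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AGE_GROUPS",
    "SEXES",
    "STRATA",
    "PersonRecords",
    "CaseStatus",
    "PrevalenceCube",
    "apply_case_definition",
    "build_prevalence_cube",
    "crude_prevalence",
    "read_person_records",
    "PROVINCE_LABEL",
]

AGE_GROUPS: tuple[str, ...] = tuple(
    f"{lo}-{lo + 4}" for lo in range(40, 85, 5)
)
SEXES: tuple[str, ...] = ("F", "M")
#: age-major stratum ordering: (40-44,F), (40-44,M), (45-49,F), ...
STRATA: tuple[tuple[str, str], ...] = tuple(
    (ag, sx) for ag in AGE_GROUPS for sx in SEXES
)
PROVINCE_LABEL = "PROVINCE"

EventSource = Literal["hospital", "claim", "drug"]
CensorReason = Literal["death", "emigration", "aged_out", "none"]


def add_years(d: date, years: int) -> date:
    """Calendar-year shift; Feb 29 maps to Feb 28 in non-leap years."""
    try:
        return d.replace(year=d.year + years)
    except ValueError:
        return d.replace(year=d.year + years, day=28)


@dataclass(frozen=True)
class PersonRecords:
    """One person's linked administrative history.

    ``coverage_spells`` are closed-open insurance intervals; an ``end`` of
    ``None`` means coverage is open at the end of the study. ``end_reason``
    of the final spell (death/emigration) drives censoring.
    """

    person_id: str
    sex: str
    birth_date: date
    coverage_spells: tuple[tuple[date, date | None], ...]
    region_by_year: Mapping[int, str]
    events: tuple[tuple[date, str], ...] = ()
    end_reason: str | None = None  # death | emigration | None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        spells = sorted(self.coverage_spells, key=lambda s: s[0])
        for (s1, e1), (s2, _) in zip(spells, spells[1:]):
            if e1 is None or e1 > s2:
                raise ValueError(
                    f"overlapping coverage spells for person {self.person_id}"
                )
        for d, src in self.events:
            if src not in ("hospital", "claim", "drug"):
                raise ValueError(f"unknown event source {src!r}")
            if d < self.birth_date:
                raise ValueError(
                    f"event before birth for person {self.person_id}"
                )
        object.__setattr__(self, "coverage_spells", tuple(spells))

    def covered_on(self, d: date) -> bool:
        return any(
            s <= d and (e is None or d < e) for s, e in self.coverage_spells
        )

    def age_on(self, d: date) -> int:
        had_birthday = (d.month, d.day) >= (self.birth_date.month, self.birth_date.day)
        return d.year - self.birth_date.year - (0 if had_birthday else 1)


@dataclass(frozen=True)
class CaseStatus:
    person_id: str
    is_case: bool
    onset_date: date | None
    censor_date: date | None
    censor_reason: CensorReason

    def __post_init__(self) -> None:
        if self.is_case != (self.onset_date is not None):
            raise ValueError("is_case must match onset_date presence")
        if (
            self.onset_date is not None
            and self.censor_date is not None
            and self.onset_date > self.censor_date
        ):
            raise ValueError("onset_date after censor_date")


def _censoring(records: PersonRecords, age_max: int) -> tuple[date | None, CensorReason]:
    candidates: list[tuple[date, CensorReason]] = []
    aged_out = add_years(records.birth_date, age_max)
    candidates.append((aged_out, "aged_out"))
    if records.end_reason in ("death", "emigration"):
        last_end = max(
            (e for _, e in records.coverage_spells if e is not None),
            default=None,
        )
        if last_end is not None:
            candidates.append((last_end, records.end_reason))  # type: ignore[arg-type]
    return min(candidates, key=lambda c: c[0])


def apply_case_definition(
    records: PersonRecords,
    window_years: int = 5,
    hospital_windowed: bool = False,
    onset_convention: Literal["completing", "first_event"] = "completing",
    age_max: int = 85,
) -> CaseStatus:
    """Classify one person under the rolling-window case definition.

    A person is a case if any window of ``window_years`` (ending at an
    event, covering dates in ``(end - window_years, end]``) contains
    >= 2 claim events, or >= 1 claim together with >= 2 drug events.
    A single hospital event qualifies unconditionally by default
    (``hospital_windowed`` subjects it to the same window, a no-op since one
    event always fits a window ending at itself — the flag exists to make
    the alternative reading explicit).

    ``onset_convention`` picks the onset date: the event that completes the
    first satisfied criterion (default), or the first event of the earliest
    qualifying window.
    """
    if window_years < 1:
        raise ValueError("window_years must be >= 1")
    censor_date, censor_reason = _censoring(records, age_max)

    kept: list[tuple[date, str]] = []
    for d, src in sorted(records.events):
        if not records.covered_on(d):
            warnings.warn(
                f"event on {d} outside coverage for person "
                f"{records.person_id}; ignored",
                stacklevel=2,
            )
            continue
        kept.append((d, src))

    onset: date | None = None
    onset_window_start: date | None = None
    hospital_dates = [d for d, s in kept if s == "hospital"]
    if hospital_dates:
        onset = hospital_dates[0]
        onset_window_start = onset

    for end_date, _src in kept:
        if onset is not None and end_date >= onset:
            break
        start = add_years(end_date, -window_years)  # window is (start, end]
        in_win = [(d, s) for d, s in kept if start < d <= end_date]
        n_claim = sum(1 for _, s in in_win if s == "claim")
        n_drug = sum(1 for _, s in in_win if s == "drug")
        if n_claim >= 2 or (n_claim >= 1 and n_drug >= 2):
            onset = end_date
            onset_window_start = min(d for d, _ in in_win)
            break

    if onset is not None and onset_convention == "first_event":
        onset = onset_window_start
    if onset is not None and censor_date is not None and onset > censor_date:
        onset = None  # qualified only after leaving the study
    return CaseStatus(
        person_id=records.person_id,
        is_case=onset is not None,
        onset_date=onset,
        censor_date=censor_date,
        censor_reason=censor_reason if censor_date is not None else "none",
    )


# ---------------------------------------------------------------------------
# Prevalence cube


@dataclass
class PrevalenceCube:
    """Case counts Y and populations n over region x year x age-sex stratum.

    Arrays are shaped (n_regions, n_years, n_strata) with the stratum axis
    ordered as :data:`STRATA`.
    """

    regions: tuple[str, ...]
    years: tuple[int, ...]
    Y: np.ndarray
    n: np.ndarray
    strata: tuple[tuple[str, str], ...] = STRATA

    def __post_init__(self) -> None:
        shape = (len(self.regions), len(self.years), len(self.strata))
        self.Y = np.asarray(self.Y, dtype=np.int64)
        self.n = np.asarray(self.n, dtype=np.int64)
        if self.Y.shape != shape or self.n.shape != shape:
            raise ValueError(
                f"expected arrays of shape {shape}, got Y{self.Y.shape} n{self.n.shape}"
            )
        if (self.Y < 0).any() or (self.n < 0).any():
            raise ValueError("negative counts")
        if (self.Y > self.n).any():
            raise ValueError("case count exceeds population in some cell")

    @classmethod
    def zeros(
        cls, regions: Sequence[str], years: Sequence[int]
    ) -> "PrevalenceCube":
        shape = (len(regions), len(years), len(STRATA))
        return cls(
            tuple(regions), tuple(int(y) for y in years),
            np.zeros(shape, dtype=np.int64), np.zeros(shape, dtype=np.int64),
        )

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, r in enumerate(self.regions):
            for t, y in enumerate(self.years):
                for j, (ag, sx) in enumerate(self.strata):
                    rows.append((r, y, ag, sx, self.Y[i, t, j], self.n[i, t, j]))
        return pd.DataFrame(
            rows, columns=["region", "year", "age_group", "sex", "Y", "n"]
        )

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "PrevalenceCube":
        regions = tuple(pd.unique(df["region"]))
        years = tuple(int(y) for y in sorted(pd.unique(df["year"])))
        cube = cls.zeros(regions, years)
        ridx = {r: i for i, r in enumerate(regions)}
        yidx = {y: t for t, y in enumerate(years)}
        sidx = {s: j for j, s in enumerate(STRATA)}
        for row in df.itertuples(index=False):
            i = ridx[row.region]
            t = yidx[int(row.year)]
            j = sidx[(row.age_group, row.sex)]
            cube.Y[i, t, j] = row.Y
            cube.n[i, t, j] = row.n
        cube.__post_init__()
        return cube

    def write(self, path: str | Path) -> None:
        self.to_long().to_csv(path, index=False)

    @classmethod
    def read(cls, path: str | Path) -> "PrevalenceCube":
        return cls.from_long(pd.read_csv(path, dtype={"region": str}))

    # aggregates over strata ------------------------------------------------
    def case_totals(self) -> np.ndarray:
        """Y_it summed over strata, shape (n_regions, n_years)."""
        return self.Y.sum(axis=2)

    def population_totals(self) -> np.ndarray:
        return self.n.sum(axis=2)

    def pooled(self, years: Sequence[int] | None = None) -> "PrevalenceCube":
        """Sum counts and populations over a span of years into one slice."""
        if years is None:
            years = self.years
        sel = [self.years.index(int(y)) for y in years]
        Y = self.Y[:, sel, :].sum(axis=1, keepdims=True)
        n = self.n[:, sel, :].sum(axis=1, keepdims=True)
        return PrevalenceCube(self.regions, (int(years[0]),), Y, n)


def _stratum_index(age: int, sex: str) -> int | None:
    if age < 40 or age >= 85:
        return None
    ag = AGE_GROUPS[(age - 40) // 5]
    return STRATA.index((ag, sex))


def build_prevalence_cube(
    statuses: Sequence[CaseStatus],
    records: Sequence[PersonRecords],
    years: Sequence[int],
    age_min: int = 40,
    age_max: int = 85,
    reference_month: int = 4,
    reference_day: int = 1,
    regions: Sequence[str] | None = None,
) -> PrevalenceCube:
    """Tabulate point prevalence at one reference date per year.

    For year ``t`` a person contributes to the population ``n`` iff covered
    and aged in ``[age_min, age_max)`` on the reference date (default
    April 1, the fiscal-year start); they additionally contribute to ``Y``
    iff their onset date is on or before the reference date and they have
    not yet been censored.
    """
    years = sorted(int(y) for y in years)
    if years != list(range(years[0], years[-1] + 1)):
        raise ValueError("years must be contiguous")
    status_by_id = {s.person_id: s for s in statuses}
    if regions is None:
        regions = sorted(
            {r for rec in records for r in rec.region_by_year.values()}
        )
    cube = PrevalenceCube.zeros(regions, years)
    ridx = {r: i for i, r in enumerate(cube.regions)}
    for rec in records:
        status = status_by_id.get(rec.person_id)
        for t, year in enumerate(years):
            ref = date(year, reference_month, reference_day)
            if not rec.covered_on(ref):
                continue
            age = rec.age_on(ref)
            if age < age_min or age >= age_max:
                continue
            region = rec.region_by_year.get(year)
            if region is None:
                raise ValueError(
                    f"person {rec.person_id} covered in {year} but has no region"
                )
            j = _stratum_index(age, rec.sex)
            if j is None:
                continue
            i = ridx[region]
            cube.n[i, t, j] += 1
            if (
                status is not None
                and status.is_case
                and status.onset_date is not None
                and status.onset_date <= ref
                and (status.censor_date is None or status.censor_date > ref)
            ):
                cube.Y[i, t, j] += 1
    return cube


def crude_prevalence(cube: PrevalenceCube) -> pd.DataFrame:
    """Per region-year crude rate plus a provincial (all-region) aggregate.

    Region-years with zero population get a missing rate.
    """
    Y = cube.case_totals().astype(float)
    n = cube.population_totals().astype(float)
    rows = []
    for i, r in enumerate(cube.regions):
        for t, y in enumerate(cube.years):
            rate = Y[i, t] / n[i, t] if n[i, t] > 0 else np.nan
            rows.append((r, y, Y[i, t], n[i, t], rate))
    for t, y in enumerate(cube.years):
        ytot, ntot = Y[:, t].sum(), n[:, t].sum()
        rate = ytot / ntot if ntot > 0 else np.nan
        rows.append((PROVINCE_LABEL, y, ytot, ntot, rate))
    return pd.DataFrame(rows, columns=["region", "year", "Y", "n", "rate"])


# ---------------------------------------------------------------------------
# File IO for person-level tables


def read_person_records(
    registry_path: str | Path,
    events_path: str | Path,
    regions_path: str | Path,
) -> list[PersonRecords]:
    """Assemble :class:`PersonRecords` from the three delimited tables.

    registry: person_id, sex, birth_date, spell_start, spell_end, end_reason
    (one row per spell; empty spell_end = open); events: person_id, date,
    source; regions: person_id, year, region_id.
    """
    reg = pd.read_csv(registry_path, dtype={"person_id": str})
    ev = pd.read_csv(events_path, dtype={"person_id": str})
    rg = pd.read_csv(regions_path, dtype={"person_id": str, "region_id": str})

    events_by_id: dict[str, list[tuple[date, str]]] = {}
    for row in ev.itertuples(index=False):
        events_by_id.setdefault(row.person_id, []).append(
            (date.fromisoformat(row.date), row.source)
        )
    regions_by_id: dict[str, dict[int, str]] = {}
    for row in rg.itertuples(index=False):
        regions_by_id.setdefault(row.person_id, {})[int(row.year)] = row.region_id

    out = []
    for pid, grp in reg.groupby("person_id", sort=True):
        spells = []
        end_reason = None
        for row in grp.itertuples(index=False):
            start = date.fromisoformat(row.spell_start)
            end = (
                None
                if pd.isna(row.spell_end) or row.spell_end == ""
                else date.fromisoformat(row.spell_end)
            )
            spells.append((start, end))
            if isinstance(row.end_reason, str) and row.end_reason in (
                "death",
                "emigration",
            ):
                end_reason = row.end_reason
        first = grp.iloc[0]
        out.append(
            PersonRecords(
                person_id=str(pid),
                sex=first["sex"],
                birth_date=date.fromisoformat(first["birth_date"]),
                coverage_spells=tuple(spells),
                region_by_year=regions_by_id.get(str(pid), {}),
                events=tuple(sorted(events_by_id.get(str(pid), []))),
                end_reason=end_reason,
            )
        )
    return out
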