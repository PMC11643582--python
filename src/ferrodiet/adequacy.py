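"""Population reference intakes (PRI) for iron and adequacy gaps.

The schedule encodes the Italian reference values used to judge iron
adequacy: a PRI in mg/day per sex and age range.  Two female ranges carry a
split reference in the source tables ("10/18" for 11-14 years and "18/10"
for 30-59 years) without a stated switch age; the default schedule resolves
them at configurable split ages (12 years for menarche, 50 years as a
menopause proxy) and the resolved, disjoint table is what validation and
lookups operate on.

The adequacy gap is individual iron intake minus the applicable PRI;
negative gaps mean inadequate intake.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ScheduleError

MALE = "male"
FEMALE = "female"
SEXES = (MALE, FEMALE)

#: Upper age (exclusive, completed years) the schedule must cover.
AGE_COVERAGE_MAX = 75.0


@dataclass(frozen=True)
class PriEntry:
    """One schedule row: PRI (mg/day) for ``sex`` on [age_min, age_max) years."""

    sex: str
    age_min: float
    age_max: float
    pri_mg_day: float


@dataclass
class AdequacyResult:
    """Summary of per-individual adequacy gaps for one population group."""

    group: tuple
    n: int
    mean_gap: float
    median_gap: float
    p5_gap: float
    p95_gap: float
    share_below_pri: float


class PriSchedule:
    """A validated, disjoint sex x age reference-intake table."""

    def __init__(self, entries: list[PriEntry]):
        self.entries = sorted(entries, key=lambda e: (e.sex, e.age_min))
        self._validate()

    def _validate(self) -> None:
        for sex in SEXES:
            rows = [e for e in self.entries if e.sex == sex]
            if not rows:
                raise ScheduleError(f"schedule has no entries for sex {sex!r}")
            cursor = 0.0
            for e in rows:
                if e.pri_mg_day <= 0:
                    raise ScheduleError(
                        f"PRI must be > 0 for {sex} [{e.age_min}, {e.age_max})"
                    )
                if e.age_min >= e.age_max:
                    raise ScheduleError(
                        f"empty age range for {sex}: [{e.age_min}, {e.age_max})"
                    )
                if not math.isclose(e.age_min, cursor, abs_tol=1e-9):
                    raise ScheduleError(
                        f"schedule for {sex} has a gap or overlap at {e.age_min} y "
                        f"(expected coverage from {cursor} y)"
                    )
                cursor = e.age_max
            if cursor < AGE_COVERAGE_MAX:
                raise ScheduleError(
                    f"schedule for {sex} covers only up to {cursor} y "
                    f"(needs {AGE_COVERAGE_MAX})"
                )

    def pri_for(self, sex: str, age_years: float) -> float:
        """The unique PRI applicable to ``sex`` at ``age_years`` (completed years)."""
        if sex not in SEXES:
            raise ScheduleError(f"unknown sex {sex!r}; expected one of {SEXES}")
        if age_years < 0:
            raise ScheduleError(f"age must be >= 0, got {age_years}")
        completed = math.floor(age_years) if age_years >= 1 else age_years
        for e in self.entries:
            if e.sex == sex and e.age_min <= completed < e.age_max:
                return e.pri_mg_day
        raise ScheduleError(f"no PRI covers sex={sex!r}, age={age_years} y")

    def pri_series(self, sex: pd.Series, age_years: pd.Series) -> pd.Series:
        """Vectorized lookup aligned on the input index."""
        return pd.Series(
            [self.pri_for(s, a) for s, a in zip(sex, age_years)],
            index=sex.index,
            dtype=float,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sex": e.sex,
                    "age_min_years": e.age_min,
                    "age_max_years": e.age_max,
                    "pri_mg_day": e.pri_mg_day,
                }
                for e in self.entries
            ]
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PriSchedule":
        return cls(
            [
                PriEntry(
                    sex=row["sex"],
                    age_min=float(row["age_min_years"]),
                    age_max=float(row["age_max_years"]),
                    pri_mg_day=float(row["pri_mg_day"]),
                )
                for _, row in frame.iterrows()
            ]
        )

    @classmethod
    def from_csv(cls, path) -> "PriSchedule":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def default(
        cls,
        female_11_14_split_age: float = 12.0,
        female_30_59_split_age: float = 50.0,
    ) -> "PriSchedule":
        """The Italian iron PRI schedule (mg/day) used throughout the package.

        Infants <1 year: 11; children 1-3: 8; 4-6: 11; 7-10: 13.
        Males 11-14: 10; 15-17: 13; adults/older >=18: 10.
        Females 11-14: 10 before the first split age, 18 after; 15-29: 18;
        30-59: 18 before the second split age, 10 after; >=60: 10.
        The two split ages are assumptions (the source ranges are printed as
        "10/18" and "18/10" without a switch age) and are configurable.
        """
        s1 = float(female_11_14_split_age)
        s2 = float(female_30_59_split_age)
        if not 11.0 <= s1 <= 15.0:
            raise ScheduleError("female_11_14_split_age must lie in [11, 15]")
        if not 30.0 <= s2 <= 60.0:
            raise ScheduleError("female_30_59_split_age must lie in [30, 60]")
        shared = [(0.0, 1.0, 11.0), (1.0, 4.0, 8.0), (4.0, 7.0, 11.0), (7.0, 11.0, 13.0)]
        male = shared + [(11.0, 15.0, 10.0), (15.0, 18.0, 13.0), (18.0, AGE_COVERAGE_MAX, 10.0)]
        female = shared + [
            (11.0, s1, 10.0),
            (s1, 15.0, 18.0),
            (15.0, 18.0, 18.0),
            (18.0, 30.0, 18.0),
            (30.0, s2, 18.0),
            (s2, 60.0, 10.0),
            (60.0, AGE_COVERAGE_MAX, 10.0),
        ]
        entries = [PriEntry(MALE, lo, hi, p) for lo, hi, p in male]
        entries += [PriEntry(FEMALE, lo, hi, p) for lo, hi, p in female if lo < hi]
        return cls(entries)


def pri_for(sex: str, age_years: float, schedule: PriSchedule) -> float:
    """Functional form of :meth:`PriSchedule.pri_for`."""
    return schedule.pri_for(sex, age_years)


def adequacy_gap(iron_mg_day: float, sex: str, age_years: float, schedule: PriSchedule) -> float:
    """Iron intake minus the applicable PRI (mg/day); negative = inadequate."""
    return iron_mg_day - schedule.pri_for(sex, age_years)


def add_gaps(intakes: pd.DataFrame, schedule: PriSchedule) -> pd.DataFrame:
    """Attach ``pri_mg_day`` and ``gap_mg_day`` columns to an intake frame."""
    out = intakes.copy()
    out["pri_mg_day"] = schedule.pri_series(out["sex"], out["age_years"])
    out["gap_mg_day"] = out["iron_mg_day"] - out["pri_mg_day"]
    return out


def group_adequacy(gaps: np.ndarray | pd.Series, group: tuple) -> AdequacyResult:
    """Summarize per-individual adequacy gaps for one group.

    Gaps are computed per individual before summarizing, so groups whose
    members fall under different PRIs (split schedules, mixed ages) average
    the correct member-level references.
    """
    gaps = np.asarray(gaps, dtype=float)
    if gaps.size == 0:
        raise ValueError(f"group {group!r} is empty")
    return AdequacyResult(
        group=group,
        n=int(gaps.size),
        mean_gap=float(np.mean(gaps)),
        median_gap=float(np.median(gaps)),
        p5_gap=float(np.percentile(gaps, 5)),
        p95_gap=float(np.percentile(gaps, 95)),
        share_below_pri=float(np.mean(gaps < 0)),
    )
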