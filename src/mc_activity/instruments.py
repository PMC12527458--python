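"""Raw instrument handling: MCSQ diary aggregation, Hjortswang activity
classification, and IBDQ-32 / Short Health Scale scoring.

The MCSQ is a 7-day daily symptom diary for microscopic colitis recording
total stools, nocturnal stools (disrupting sleep), Bristol-6 (mushy) and
Bristol-7 (watery) stools, solid stools, urgency, fecal leakage, and
abdominal pain.  This module turns raw diaries into weekly summaries, applies
the Hjortswang disease-activity rule (mean >=3 stools/day or mean >=1 watery
stool/day), and scores the two health-related quality-of-life instruments
used as external anchors.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StoolDiaryDay",
    "StoolDiary",
    "WeeklySymptomSummary",
    "DiseaseActivity",
    "ActivityRule",
    "IBDQScores",
    "SHSScores",
    "IBDQ_DOMAIN_MAP",
    "IncompleteDiaryError",
    "DiaryValidationError",
    "MissingItemError",
    "summarize_diary",
    "hjortswang_classify",
    "score_ibdq",
    "score_shs",
    "validate_cohort_table",
    "read_diary_csv",
    "read_questionnaire_csv",
    "diaries_from_frame",
]

# Minimum number of recorded diary days accepted for a weekly summary.
# Partial diaries down to 4/7 days are averaged over recorded days;
# day-count items (urgency, leakage) are rescaled to a 7-day week.
MIN_DIARY_DAYS = 4

# Standard 32-item IBDQ domain partition (10/5/5/12 items); item numbers are
# 1-based.  Configurable via the ``domain_map`` argument of :func:`score_ibdq`
# to accommodate licensed item orderings.
IBDQ_DOMAIN_MAP: Mapping[str, tuple[int, ...]] = {
    "bowel": (1, 5, 9, 13, 17, 20, 22, 24, 26, 29),
    "systemic": (2, 6, 10, 14, 18),
    "social": (4, 8, 12, 16, 28),
    "emotional": (3, 7, 11, 15, 19, 21, 23, 25, 27, 30, 31, 32),
}

IBDQ_DOMAIN_RANGES = {
    "bowel": (10, 70),
    "systemic": (5, 35),
    "social": (5, 35),
    "emotional": (12, 84),
}


class IncompleteDiaryError(ValueError):
    """Raised when a diary has fewer recorded days than the completeness rule allows."""


class DiaryValidationError(ValueError):
    """Raised when diary entries violate basic count constraints."""


class MissingItemError(ValueError):
    """Raised when a questionnaire response set is incomplete."""


@dataclass(frozen=True)
class StoolDiaryDay:
    """One day of MCSQ diary entries.

    Counts are stools per day; ``urgency`` and ``leakage`` are daily
    occurrence indicators, ``pain`` is a daily 0-3 ordinal severity rating.
    """

    day_index: int
    n_total_stools: int
    n_nocturnal: int
    n_bristol6: int
    n_bristol7: int
    n_solid: int
    urgency: bool
    leakage: bool
    pain: int

    def __post_init__(self) -> None:
        if not 1 <= self.day_index <= 7:
            raise DiaryValidationError(f"day_index {self.day_index} outside 1-7")
        for name in ("n_total_stools", "n_nocturnal", "n_bristol6", "n_bristol7", "n_solid"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise DiaryValidationError(f"{name}={v} must be a non-negative integer")
        if self.n_bristol6 + self.n_bristol7 + self.n_solid > self.n_total_stools:
            raise DiaryValidationError(
                "typed stools (Bristol 6 + Bristol 7 + solid) exceed total stools"
            )
        if self.n_nocturnal > self.n_total_stools:
            raise DiaryValidationError("nocturnal stools exceed total stools")
        if not 0 <= self.pain <= 3:
            raise DiaryValidationError(f"pain={self.pain} outside 0-3")


@dataclass(frozen=True)
class StoolDiary:
    """A patient-timepoint MCSQ diary: up to 7 :class:`StoolDiaryDay` records."""

    patient_id: str
    timepoint: str
    days: tuple[StoolDiaryDay, ...]

    def __post_init__(self) -> None:
        if self.timepoint not in ("baseline", "followup"):
            raise DiaryValidationError(f"unknown timepoint {self.timepoint!r}")
        idx = [d.day_index for d in self.days]
        if len(set(idx)) != len(idx):
            raise DiaryValidationError("duplicate day_index values in diary")
        if len(self.days) > 7:
            raise DiaryValidationError("diary has more than 7 days")

    @property
    def partial(self) -> bool:
        return len(self.days) < 7


@dataclass(frozen=True)
class WeeklySymptomSummary:
    """Per-item weekly aggregates of one diary.

    Stool items are daily means over recorded days; ``urgency_days`` and
    ``leakage_days`` are days/week (rescaled to 7 for partial diaries);
    ``mean_pain`` is the mean daily 0-3 pain rating.
    """

    mean_total: float
    mean_nocturnal: float
    mean_b6: float
    mean_b7: float
    mean_loose: float
    mean_solid: float
    urgency_days: float
    leakage_days: float
    mean_pain: float
    n_days: int = 7

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_total": self.mean_total,
            "mean_nocturnal": self.mean_nocturnal,
            "mean_b6": self.mean_b6,
            "mean_b7": self.mean_b7,
            "mean_loose": self.mean_loose,
            "mean_solid": self.mean_solid,
            "urgency_days": self.urgency_days,
            "leakage_days": self.leakage_days,
            "mean_pain": self.mean_pain,
        }


class ActivityRule(str, Enum):
    STOOL_FREQUENCY = "stool_frequency"
    WATERY = "watery"
    BOTH = "both"
    NONE = "none"


@dataclass(frozen=True)
class DiseaseActivity:
    active: bool
    rule_fired: ActivityRule


@dataclass(frozen=True)
class IBDQScores:
    """IBDQ-32 total and domain scores; higher scores mean better HRQoL."""

    total: int
    bowel: int
    systemic: int
    social: int
    emotional: int

    def __post_init__(self) -> None:
        assert self.total == self.bowel + self.systemic + self.social + self.emotional


@dataclass(frozen=True)
class SHSScores:
    """Short Health Scale: four single-item dimensions, 1 (best) to 6 (worst)."""

    symptoms: int
    function: int
    worry: int
    wellbeing: int


def summarize_diary(diary: StoolDiary) -> WeeklySymptomSummary:
    """Aggregate a diary to its weekly summary.

    Means are taken over recorded days; urgency/leakage day-counts are scaled
    to a 7-day week when fewer than 7 days were recorded.  Diaries with fewer
    than 4 recorded days are rejected as incomplete.
    """
    n = len(diary.days)
    if n < MIN_DIARY_DAYS:
        raise IncompleteDiaryError(
            f"diary {diary.patient_id}/{diary.timepoint} has {n} days; >= {MIN_DIARY_DAYS} required"
        )
    total = np.array([d.n_total_stools for d in diary.days], dtype=float)
    noct = np.array([d.n_nocturnal for d in diary.days], dtype=float)
    b6 = np.array([d.n_bristol6 for d in diary.days], dtype=float)
    b7 = np.array([d.n_bristol7 for d in diary.days], dtype=float)
    solid = np.array([d.n_solid for d in diary.days], dtype=float)
    urg = sum(bool(d.urgency) for d in diary.days)
    leak = sum(bool(d.leakage) for d in diary.days)
    pain = np.array([d.pain for d in diary.days], dtype=float)
    return WeeklySymptomSummary(
        mean_total=total.mean(),
        mean_nocturnal=noct.mean(),
        mean_b6=b6.mean(),
        mean_b7=b7.mean(),
        mean_loose=(b6 + b7).mean(),
        mean_solid=solid.mean(),
        urgency_days=urg * 7.0 / n,
        leakage_days=leak * 7.0 / n,
        mean_pain=pain.mean(),
        n_days=n,
    )


def hjortswang_classify(summary: WeeklySymptomSummary) -> DiseaseActivity:
    """Apply the Hjortswang disease-activity criteria.

    Active disease is a mean of >=3 stools/day or >=1 watery (Bristol 7)
    stool/day over the diary week.  Comparisons are exact; weekly means are
    not rounded first.
    """
    freq = summary.mean_total >= 3.0
    watery = summary.mean_b7 >= 1.0
    if freq and watery:
        rule = ActivityRule.BOTH
    elif freq:
        rule = ActivityRule.STOOL_FREQUENCY
    elif watery:
        rule = ActivityRule.WATERY
    else:
        rule = ActivityRule.NONE
    return DiseaseActivity(active=rule is not ActivityRule.NONE, rule_fired=rule)


def score_ibdq(
    responses: Mapping[int, int] | Sequence[int],
    domain_map: Mapping[str, tuple[int, ...]] = IBDQ_DOMAIN_MAP,
) -> IBDQScores:
    """Score the 32-item IBDQ.

    ``responses`` is either a mapping from 1-based item number to the 1-7
    Likert response, or a length-32 sequence in item order.  The total is the
    plain item sum (range 32-224); domain scores sum the items of the
    10/5/5/12 partition given by ``domain_map``.  Missing items raise
    :class:`MissingItemError` -- no imputation happens here.
    """
    if not isinstance(responses, Mapping):
        responses = {i + 1: v for i, v in enumerate(responses)}
    all_items = sorted(i for items in domain_map.values() for i in items)
    if all_items != list(range(1, 33)):
        raise ValueError("domain_map must partition items 1-32")
    missing = [i for i in all_items if i not in responses or pd.isna(responses[i])]
    if missing:
        raise MissingItemError(f"missing IBDQ items: {missing}")
    for i in all_items:
        v = responses[i]
        if not 1 <= v <= 7 or int(v) != v:
            raise ValueError(f"IBDQ item {i} response {v} outside 1-7")
    domains = {
        name: int(sum(responses[i] for i in items)) for name, items in domain_map.items()
    }
    return IBDQScores(total=sum(domains.values()), **domains)


def score_shs(responses: Sequence[int]) -> SHSScores:
    """Score the Short Health Scale: four 1-6 responses reported separately
    (symptoms, social function, worry, well-being); no summation."""
    if len(responses) != 4:
        raise MissingItemError(f"SHS needs 4 responses, got {len(responses)}")
    for v in responses:
        if pd.isna(v) or not 1 <= v <= 6 or int(v) != v:
            raise ValueError(f"SHS response {v} outside 1-6")
    s, f, w, b = (int(v) for v in responses)
    return SHSScores(symptoms=s, function=f, worry=w, wellbeing=b)


# ---------------------------------------------------------------------------
# Cohort-table plumbing
# ---------------------------------------------------------------------------

_RANGE_RULES: dict[str, tuple[float, float]] = {
    **{f"ibdq_{i:02d}": (1, 7) for i in range(1, 33)},
    "shs_symptoms": (1, 6),
    "shs_function": (1, 6),
    "shs_worry": (1, 6),
    "shs_wellbeing": (1, 6),
    "patient_symptom_rating": (0, 3),
    "ibs": (0, 1),
    "mean_pain": (0, 3),
    "urgency_days": (0, 7),
    "leakage_days": (0, 7),
}


def validate_cohort_table(table: pd.DataFrame) -> dict:
    """Audit a wide patient x variable cohort table.

    Reports (does not raise): out-of-range values for known columns,
    duplicated patient-timepoint rows, and per-row/per-column missingness
    fractions.
    """
    violations: list[dict] = []
    for col, (lo, hi) in _RANGE_RULES.items():
        if col not in table.columns:
            continue
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[(vals < lo) | (vals > hi)]
        for idx in bad:
            violations.append(
                {"row": idx, "column": col, "value": table.loc[idx, col], "range": (lo, hi)}
            )
    duplicates: list = []
    key = [c for c in ("patient_id", "timepoint") if c in table.columns]
    if key:
        dup_mask = table.duplicated(subset=key, keep=False)
        if dup_mask.any():
            duplicates = (
                table.loc[dup_mask, key].drop_duplicates().to_records(index=False).tolist()
            )
    numeric = table.drop(columns=[c for c in ("patient_id", "timepoint") if c in table.columns])
    return {
        "range_violations": violations,
        "duplicates": duplicates,
        "row_missingness": numeric.isna().mean(axis=1),
        "column_missingness": numeric.isna().mean(axis=0),
        "n_rows": len(table),
    }


_DIARY_COLUMNS = [
    "patient_id", "timepoint", "day_index", "total", "nocturnal",
    "bristol6", "bristol7", "solid", "urgency", "leakage", "pain",
]


def read_diary_csv(path) -> pd.DataFrame:
    """Read a long-format diary CSV (one row per patient-day) and report
    per-column missingness on ``DataFrame.attrs['missingness']``."""
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    missing_cols = [c for c in _DIARY_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"diary CSV lacks columns: {missing_cols}")
    df.attrs["missingness"] = df.isna().mean(axis=0)
    return df


def diaries_from_frame(df: pd.DataFrame) -> list[StoolDiary]:
    """Build :class:`StoolDiary` objects from a long diary frame, dropping
    unrecorded days (rows with any missing count)."""
    diaries = []
    for (pid, tp), grp in df.groupby(["patient_id", "timepoint"], sort=True):
        days = []
        for _, row in grp.iterrows():
            if row[["total", "nocturnal", "bristol6", "bristol7", "solid"]].isna().any():
                continue
            days.append(
                StoolDiaryDay(
                    day_index=int(row["day_index"]),
                    n_total_stools=int(row["total"]),
                    n_nocturnal=int(row["nocturnal"]),
                    n_bristol6=int(row["bristol6"]),
                    n_bristol7=int(row["bristol7"]),
                    n_solid=int(row["solid"]),
                    urgency=bool(row["urgency"]),
                    leakage=bool(row["leakage"]),
                    pain=int(row["pain"]),
                )
            )
        diaries.append(StoolDiary(patient_id=str(pid), timepoint=str(tp), days=tuple(days)))
    return diaries


def read_questionnaire_csv(path) -> pd.DataFrame:
    """Read a wide questionnaire CSV (one row per patient-timepoint); empty
    cells are missing values; missingness reported on ``attrs``."""
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    df.attrs["missingness"] = df.isna().mean(axis=0)
    return df
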