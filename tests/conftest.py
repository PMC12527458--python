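import numpy as np
import pytest

from mc_activity.instruments import StoolDiary, StoolDiaryDay, WeeklySymptomSummary
from mc_activity.mcs import ScoreTable, ScoreTableEntry
from mc_activity.synthetic_cohort import GeneratorConfig, generate_cohort


def make_day(day_index=1, total=0, nocturnal=0, b6=0, b7=0, solid=0,
             urgency=False, leakage=False, pain=0):
    return StoolDiaryDay(
        day_index=day_index, n_total_stools=total, n_nocturnal=nocturnal,
        n_bristol6=b6, n_bristol7=b7, n_solid=solid,
        urgency=urgency, leakage=leakage, pain=pain,
    )


def make_diary(days, patient_id="P001", timepoint="baseline"):
    return StoolDiary(patient_id=patient_id, timepoint=timepoint, days=tuple(days))


def make_summary(**kwargs):
    """Weekly summary with all-zero defaults; loose is kept consistent with
    b6 + b7 unless given explicitly."""
    base = dict(mean_total=0.0, mean_nocturnal=0.0, mean_b6=0.0, mean_b7=0.0,
                mean_loose=0.0, mean_solid=0.0, urgency_days=0.0,
                leakage_days=0.0, mean_pain=0.0)
    base.update(kwargs)
    if "mean_loose" not in kwargs:
        base["mean_loose"] = base["mean_b6"] + base["mean_b7"]
    return WeeklySymptomSummary(**base)


@pytest.fixture(scope="session")
def unit_table():
    """A simple table: every item scores 0-3 at thresholds (1, 2, 3)."""
    return ScoreTable(entries=tuple(
        ScoreTableEntry(item=item, thresholds=(1.0, 2.0, 3.0), points=(0, 1, 2, 3))
        for item in ("mean_loose", "mean_nocturnal", "urgency_days",
                     "leakage_days", "mean_pain")
    ))


@pytest.fixture(scope="session")
def reference_cohort():
    """One default synthetic cohort shared across tests (seed 0)."""
    return generate_cohort(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def clean_cohort():
    """Cohort without missingness, for analyses needing complete data."""
    return generate_cohort(GeneratorConfig(seed=1, missing_rate=0.0))
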