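"""Synthetic two-timepoint microscopic-colitis cohorts.

Patient-level microscopic-colitis cohorts of the kind used to develop
severity scores (on the order of 131 patients, roughly 1:1
remission:active, assessed at baseline and a 2-4-week follow-up) are not
publicly shareable, so this module generates cohorts with the statistical
structure the analysis pipeline assumes:

* five severity strata (remission, partial remission, mild, moderate,
  severe), each a distinct symptom profile: a stratum-typical vector of true
  point categories (0-3 per scoring item, occasionally flipped one step),
  whose sum is the patient's true MCS;
* daily diary draws consistent with those categories -- negative-binomial
  stool counts, Bernoulli urgency/leakage days, ordinal pain -- through
  category-specific intensity bands, with the watery (Bristol 7) share of
  loose stools rising with severity;
* HRQoL anchored to the true score through the linear relation
  IBDQ-32 total = 202.3 - 6.0 * MCS + noise (the cohort's fitted
  univariate regression), with item responses allocated to realize the
  target total; SHS dimensions and the patient's own 0-3 symptom rating are
  monotone noisy maps of the true score;
* treatment response at follow-up (active patients move down two severity
  strata), retest stability for untreated patients, and MCAR missingness.

The per-patient ground truth (stratum, item categories, true MCS) is
returned alongside so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .instruments import (
    IBDQ_DOMAIN_MAP,
    StoolDiary,
    StoolDiaryDay,
    score_ibdq,
    summarize_diary,
    hjortswang_classify,
)

__all__ = [
    "STRATA",
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_diary",
    "generate_hrqol",
    "apply_missingness",
    "generate_retest_data",
    "generate_anchor_data",
]

STRATA = ("remission", "partial remission", "mild", "moderate", "severe")

# stratum-typical item point categories (loose, nocturnal, urgency, leakage,
# pain) -- the severity groups are distinct symptom profiles, not slices of a
# featureless continuum; each item flips one category up/down with a small
# probability per patient-occasion
_CATEGORY_PATTERN = {
    "remission": (0, 0, 0, 0, 0),
    "partial remission": (1, 0, 1, 0, 1),
    "mild": (2, 1, 1, 1, 1),
    "moderate": (2, 2, 2, 1, 2),
    "severe": (3, 3, 3, 2, 3),
}
_CATEGORY_FLIP_P = 0.04  # per-item probability of a one-step category flip

# category -> weekly-mean intensity band per item (uniform draw within band)
_LOOSE_BANDS = ((0.0, 0.5), (1.5, 2.3), (3.6, 4.8), (6.5, 8.5))
_NOCT_BANDS = ((0.0, 0.12), (0.55, 0.95), (1.4, 1.9), (2.7, 3.6))
_PAIN_LEVELS = (0.15, 1.0, 1.85, 2.7)
_URGENCY_P = (0.02, 0.32, 0.66, 0.97)
_LEAKAGE_P = (0.01, 0.30, 0.64, 0.95)

# watery (Bristol 7) share of loose stools rises with severity
_B7_SHARE = {"remission": 0.15, "partial remission": 0.25, "mild": 0.45,
             "moderate": 0.70, "severe": 0.85}
_SOLID_MEAN = {"remission": 0.9, "partial remission": 0.6, "mild": 0.9,
               "moderate": 0.6, "severe": 0.4}

_NB_DISPERSION = 10.0  # negative-binomial size; variance = mu + mu^2/size


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the development-cohort design: 131 patients, ~49%
    active at baseline (Hjortswang), IBDQ anchored at
    202.3 - 6.0 * MCS with residual SD 20 (which reproduces the reported
    adjusted R^2 of ~0.6), retest reliability target ICC 0.88, IBS
    comorbidity prevalence 15%, and a low residual MCAR missingness rate.
    """

    n_patients: int = 131
    prop_active: float = 0.49
    severity_strata: tuple[float, float, float, float, float] = (0.31, 0.25, 0.15, 0.15, 0.14)
    ibdq_intercept: float = 202.3
    ibdq_slope_per_mcs: float = -6.0
    ibdq_noise_sd: float = 20.0
    retest_reliability_target: float = 0.88
    treatment_strata_shift: int = 2
    category_flip_p: float = _CATEGORY_FLIP_P
    missing_rate: float = 0.03
    ibs_prevalence: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.severity_strata), 1.0):
            raise ValueError("severity_strata weights must sum to 1")
        if self.ibdq_noise_sd <= 0:
            raise ValueError("ibdq_noise_sd must be > 0")
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must be in [0, 0.5)")


@dataclass
class SyntheticCohort:
    """Generated cohort: long diary frame, wide per-patient-timepoint cohort
    table (summaries + questionnaire scores + demographics), and the ground
    truth used for recovery tests (kept separate, never merged into the
    exported cohort unless asked for)."""

    diary: pd.DataFrame
    cohort: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig


def _draw_categories(
    stratum: str, rng: np.random.Generator, flip_p: float = _CATEGORY_FLIP_P
) -> np.ndarray:
    base = np.array(_CATEGORY_PATTERN[stratum])
    flips = rng.random(5) < flip_p
    signs = np.where(rng.random(5) < 0.5, -1, 1)
    return np.clip(base + flips * signs, 0, 3).astype(int)


def _nb_counts(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=int)
    p = _NB_DISPERSION / (_NB_DISPERSION + mean)
    return rng.negative_binomial(_NB_DISPERSION, p, size=size)


def generate_diary(
    stratum: str,
    categories: np.ndarray,
    patient_id: str,
    timepoint: str,
    rng: np.random.Generator,
) -> StoolDiary:
    """Draw a 7-day diary consistent with the five item categories
    (loose, nocturnal, urgency, leakage, pain in that order)."""
    c_loose, c_noct, c_urg, c_leak, c_pain = (int(c) for c in categories)
    loose_mu = rng.uniform(*_LOOSE_BANDS[c_loose])
    noct_mu = rng.uniform(*_NOCT_BANDS[c_noct])
    solid_mu = _SOLID_MEAN[stratum]
    b7_share = _B7_SHARE[stratum]

    loose = _nb_counts(rng, loose_mu, 7)
    solid = _nb_counts(rng, solid_mu, 7)
    total = loose + solid
    b7 = rng.binomial(loose, b7_share)
    b6 = loose - b7
    noct = np.minimum(rng.poisson(noct_mu, size=7), total)
    urg = rng.random(7) < _URGENCY_P[c_urg]
    leak = rng.random(7) < _LEAKAGE_P[c_leak]
    pain = np.clip(np.rint(rng.normal(_PAIN_LEVELS[c_pain], 0.6, size=7)), 0, 3).astype(int)

    days = tuple(
        StoolDiaryDay(
            day_index=d + 1,
            n_total_stools=int(total[d]),
            n_nocturnal=int(noct[d]),
            n_bristol6=int(b6[d]),
            n_bristol7=int(b7[d]),
            n_solid=int(solid[d]),
            urgency=bool(urg[d]),
            leakage=bool(leak[d]),
            pain=int(pain[d]),
        )
        for d in range(7)
    )
    return StoolDiary(patient_id=patient_id, timepoint=timepoint, days=days)


_DOMAIN_ORDER = ("bowel", "systemic", "social", "emotional")


def _allocate_ibdq_items(
    target_total: float, rng: np.random.Generator | None = None, share_jitter: float = 0.12
) -> dict[int, int]:
    """Allocate 32 item responses (1-7) realizing the target total exactly.

    Extra points beyond the floor of 32 are split across domains by
    largest-remainder proportional allocation (domain shares receive a small
    multiplicative jitter, since real domain scores track the total only
    approximately), then spread evenly within each domain.  Deterministic
    when ``rng`` is None."""
    t = int(np.clip(np.rint(target_total), 32, 224))
    extra = t - 32
    caps = {d: 6 * len(IBDQ_DOMAIN_MAP[d]) for d in _DOMAIN_ORDER}
    total_cap = sum(caps.values())
    weights = {d: float(caps[d]) for d in _DOMAIN_ORDER}
    if rng is not None and share_jitter > 0:
        weights = {d: caps[d] * max(0.1, 1.0 + rng.normal(0.0, share_jitter))
                   for d in _DOMAIN_ORDER}
    wsum = sum(weights.values())
    shares = {d: min(float(caps[d]), extra * weights[d] / wsum) for d in _DOMAIN_ORDER}
    deficit = extra - sum(shares.values())
    if deficit > 0:  # jittered shares hit a domain cap; spill over evenly
        open_caps = {d: caps[d] - shares[d] for d in _DOMAIN_ORDER}
        spill = sum(open_caps.values())
        shares = {d: shares[d] + deficit * open_caps[d] / spill for d in _DOMAIN_ORDER}
    alloc = {d: int(np.floor(shares[d])) for d in _DOMAIN_ORDER}
    remainder = extra - sum(alloc.values())
    for d in sorted(_DOMAIN_ORDER, key=lambda d: shares[d] - alloc[d], reverse=True):
        if remainder == 0:
            break
        if alloc[d] < caps[d]:
            alloc[d] += 1
            remainder -= 1
    responses: dict[int, int] = {}
    for d in _DOMAIN_ORDER:
        items = IBDQ_DOMAIN_MAP[d]
        base, rem = divmod(alloc[d], len(items))
        for j, item in enumerate(sorted(items)):
            responses[item] = 1 + base + (1 if j < rem else 0)
    return responses


def generate_hrqol(
    true_mcs: float, config: GeneratorConfig, rng: np.random.Generator
) -> dict:
    """IBDQ-32 item responses, SHS dimensions, and patient symptom rating for
    one patient-timepoint, anchored to the latent score."""
    target = (
        config.ibdq_intercept
        + config.ibdq_slope_per_mcs * true_mcs
        + rng.normal(0.0, config.ibdq_noise_sd)
    )
    ibdq_items = _allocate_ibdq_items(target, rng=rng)
    shs = {
        "shs_symptoms": int(np.clip(np.rint(1 + 5 * true_mcs / 15 + rng.normal(0, 0.4)), 1, 6)),
        "shs_function": int(np.clip(np.rint(1 + 5 * true_mcs / 15 + rng.normal(0, 0.45)), 1, 6)),
        "shs_worry": int(np.clip(np.rint(1 + 5 * true_mcs / 15 + rng.normal(0, 0.55)), 1, 6)),
        "shs_wellbeing": int(np.clip(np.rint(1 + 5 * true_mcs / 15 + rng.normal(0, 0.55)), 1, 6)),
    }
    rating = int(np.clip(np.rint(3 * true_mcs / 15 + rng.normal(0, 0.35)), 0, 3))
    return {"ibdq_items": ibdq_items, "shs": shs, "patient_symptom_rating": rating}


def _diary_to_rows(diary: StoolDiary) -> list[dict]:
    return [
        {
            "patient_id": diary.patient_id,
            "timepoint": diary.timepoint,
            "day_index": d.day_index,
            "total": d.n_total_stools,
            "nocturnal": d.n_nocturnal,
            "bristol6": d.n_bristol6,
            "bristol7": d.n_bristol7,
            "solid": d.n_solid,
            "urgency": int(d.urgency),
            "leakage": int(d.leakage),
            "pain": d.pain,
        }
        for d in diary.days
    ]


_ACTIVE_STRATA = frozenset({"mild", "moderate", "severe"})


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate a two-timepoint cohort under the configured study conditions.

    Patients in an active stratum at baseline are treated and move down
    ``treatment_strata_shift`` strata at follow-up; remission and partial-
    remission patients are retested with only occasion noise on their latent
    trait.  Missingness is applied to the cohort table (MCAR); the diary
    frame is left complete so diary handling can be tested separately.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    diary_rows: list[dict] = []
    cohort_rows: list[dict] = []
    truth_rows: list[dict] = []

    strata_idx = rng.choice(len(STRATA), size=config.n_patients, p=config.severity_strata)
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        s_bl = STRATA[strata_idx[i]]
        treated = s_bl in _ACTIVE_STRATA
        s_fu = (
            STRATA[max(0, strata_idx[i] - config.treatment_strata_shift)]
            if treated else s_bl
        )

        age = int(np.clip(rng.normal(64, 12), 22, 92))
        sex = "F" if rng.random() < 0.82 else "M"
        duration = float(np.round(np.clip(rng.gamma(1.5, 2.5), 0.1, 30), 1))
        ibs = int(rng.random() < config.ibs_prevalence)

        for timepoint, stratum in (("baseline", s_bl), ("followup", s_fu)):
            cats = _draw_categories(stratum, rng, config.category_flip_p)
            true_mcs = int(cats.sum())
            diary = generate_diary(stratum, cats, pid, timepoint, rng)
            summary = summarize_diary(diary)
            activity = hjortswang_classify(summary)
            hrqol = generate_hrqol(true_mcs, config, rng)
            ibdq = score_ibdq(hrqol["ibdq_items"])
            diary_rows.extend(_diary_to_rows(diary))
            row = {
                "patient_id": pid,
                "timepoint": timepoint,
                **summary.as_dict(),
                **{f"ibdq_{k:02d}": v for k, v in sorted(hrqol["ibdq_items"].items())},
                "ibdq_total": ibdq.total,
                "ibdq_bowel": ibdq.bowel,
                "ibdq_systemic": ibdq.systemic,
                "ibdq_social": ibdq.social,
                "ibdq_emotional": ibdq.emotional,
                **hrqol["shs"],
                "patient_symptom_rating": hrqol["patient_symptom_rating"],
                "hjortswang_active": int(activity.active),
                "treated": int(treated),
                "age": age,
                "sex": sex,
                "disease_duration": duration,
                "ibs": ibs,
            }
            cohort_rows.append(row)
            truth_rows.append(
                {
                    "patient_id": pid,
                    "timepoint": timepoint,
                    "stratum": stratum,
                    "latent_severity": float(true_mcs),
                    "true_mcs": true_mcs,
                    "cat_loose": cats[0],
                    "cat_nocturnal": cats[1],
                    "cat_urgency": cats[2],
                    "cat_leakage": cats[3],
                    "cat_pain": cats[4],
                    "treated": int(treated),
                }
            )

    diary_df = pd.DataFrame(diary_rows)
    cohort_df = pd.DataFrame(cohort_rows)
    truth_df = pd.DataFrame(truth_rows)
    if config.missing_rate > 0:
        cohort_df, _ = apply_missingness(
            cohort_df, config.missing_rate, seed=int(rng.integers(2**31))
        )
    return SyntheticCohort(diary=diary_df, cohort=cohort_df, truth=truth_df, config=config)


# never masked: identifiers and the derived activity label (computed from the
# diary, which is exported complete)
_ID_COLUMNS = ("patient_id", "timepoint", "hjortswang_active", "treated")


def apply_missingness(
    cohort: pd.DataFrame,
    missing_rate: float,
    mechanism: str = "MCAR",
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Punch missing-completely-at-random holes into the feature columns.

    Returns the masked copy and the boolean mask (True = masked) so recovery
    can be scored on the held-out truth.
    """
    if not 0 <= missing_rate < 0.5:
        raise ValueError("missing_rate must be in [0, 0.5)")
    if mechanism != "MCAR":
        raise ValueError(f"unsupported missingness mechanism {mechanism!r}")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    feature_cols = [c for c in cohort.columns if c not in _ID_COLUMNS]
    mask = pd.DataFrame(
        rng.random((len(cohort), len(feature_cols))) < missing_rate,
        index=cohort.index,
        columns=feature_cols,
    )
    for c in feature_cols:
        out[c] = out[c].mask(mask[c])
    return out, mask


def generate_retest_data(
    n_subjects: int,
    icc_target: float = 0.88,
    k_occasions: int = 2,
    between_sd: float = 3.0,
    seed: int | None = None,
) -> np.ndarray:
    """Subject x occasion scores with a known population ICC(2,k).

    With subject variance sigma_b^2 and occasion-error variance sigma_e^2,
    ICC(2,k) = sigma_b^2 / (sigma_b^2 + sigma_e^2 / k); the error variance is
    solved in closed form from the target.
    """
    if not 0 < icc_target < 1:
        raise ValueError("icc_target must be in (0, 1)")
    rng = np.random.default_rng(seed)
    sigma_b2 = between_sd**2
    sigma_e2 = k_occasions * sigma_b2 * (1.0 - icc_target) / icc_target
    subj = rng.normal(0.0, between_sd, size=n_subjects)
    err = rng.normal(0.0, np.sqrt(sigma_e2), size=(n_subjects, k_occasions))
    return subj[:, None] + err


def generate_anchor_data(
    n: int,
    gap: float = 17.5,
    intercept: float = 202.3,
    noise_sd: float = 15.0,
    n_categories: int = 4,
    level_jitter: float = 0.15,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Item values with planted categories and IBDQ totals dropping ``gap``
    points per category -- the calibration module's recovery benchmark.

    Item values sit at the integer unit levels 0..n_categories-1 with a small
    measurement jitter, so the generating category boundaries are the unit
    mid-points (0.5, 1.5, ...).  Returns (item_values, ibdq_totals,
    true_categories).
    """
    rng = np.random.default_rng(seed)
    cats = rng.integers(0, n_categories, size=n)
    values = np.clip(cats + rng.normal(0.0, level_jitter, size=n), 0.0, None)
    ibdq = intercept - gap * cats + rng.normal(0.0, noise_sd, size=n)
    return values, ibdq, cats
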