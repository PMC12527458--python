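"""End-to-end orchestration: simulate -> score -> calibrate -> validate ->
cluster -> ROC, with seeded reproducibility and a run manifest.

Every stochastic stage receives a seed derived deterministically from the
master seed, so a manifest (config hash + seeds) suffices to reproduce every
numeric output bit-identically.  Artifacts are CSV (UTF-8, '.' decimal) and
JSON; the report is written both machine-readable (JSON) and as a short
markdown summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration, psychometrics, roc_validation, severity_clustering
from .instruments import diaries_from_frame, hjortswang_classify, summarize_diary
from .mcs import ScoreTable, compute_mcs, default_score_table, dump_score_table, load_score_table
from .synthetic_cohort import GeneratorConfig, generate_cohort

__all__ = ["RunConfig", "ValidationReport", "run_pipeline", "score_cohort", "stage_seed"]

log = logging.getLogger("mc_activity")

MCSQ_ITEMS = [
    "mean_total", "mean_nocturnal", "mean_b6", "mean_b7", "mean_loose",
    "mean_solid", "urgency_days", "leakage_days", "mean_pain",
]

# items entering correlation-based analyses (factorability, EFA, alpha):
# mean_loose and mean_total are exact sums of other items and would make the
# correlation matrix singular
MCSQ_NONDERIVED_ITEMS = [
    "mean_nocturnal", "mean_b6", "mean_b7", "mean_solid",
    "urgency_days", "leakage_days", "mean_pain",
]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, derived from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    master_seed: int = 0
    out_dir: str | Path = "mc_activity_run"
    generator: GeneratorConfig | None = None
    score_table_path: str | Path | None = None  # None -> calibrate on this cohort
    run_calibrate: bool = True
    run_validate: bool = True
    run_cluster: bool = True
    run_roc: bool = True
    correlation_threshold: float = 0.4
    jackstraw_perms: int = 200
    n_trees: int = 100


@dataclass
class ValidationReport:
    sections: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"manifest": self.manifest, "sections": self.sections},
                          indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def score_cohort(diary_df: pd.DataFrame, table: ScoreTable) -> pd.DataFrame:
    """Score every patient-timepoint diary: weekly summary, Hjortswang
    activity, item points, MCS, and severity class."""
    rows = []
    for diary in diaries_from_frame(diary_df):
        summary = summarize_diary(diary)
        activity = hjortswang_classify(summary)
        res = compute_mcs(summary, table)
        rows.append(
            {
                "patient_id": diary.patient_id,
                "timepoint": diary.timepoint,
                **summary.as_dict(),
                **{f"points_{k}": v for k, v in res.item_points.items()},
                "mcs": res.mcs,
                "severity": res.severity,
                "hjortswang_active": int(activity.active),
                "hjortswang_rule": activity.rule_fired.value,
            }
        )
    return pd.DataFrame(rows)


def _config_hash(config: RunConfig) -> str:
    gen = asdict(config.generator) if config.generator else None
    # out_dir identifies where artifacts land, not what was computed
    payload = json.dumps(
        {**{k: v for k, v in asdict(config).items()
            if k not in ("generator", "out_dir")},
         "generator": gen},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> ValidationReport:
    """Execute the configured stages on a (simulated) cohort and write all
    artifacts under ``config.out_dir``.  Stage failures propagate with the
    stage name in the exception message."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = ValidationReport()
    gen_cfg = config.generator or GeneratorConfig(seed=stage_seed(config.master_seed, "simulate"))

    stage = "simulate"
    try:
        cohort = generate_cohort(gen_cfg)
        cohort.diary.to_csv(out / "diary.csv", index=False)
        cohort.cohort.to_csv(out / "cohort.csv", index=False)
        cohort.truth.to_csv(out / "truth.csv", index=False)
        log.info("simulate: %d patients, %d diary rows", gen_cfg.n_patients, len(cohort.diary))

        stage = "calibrate"
        if config.score_table_path is not None:
            table = load_score_table(Path(config.score_table_path))
            selection = None
        elif config.run_calibrate:
            baseline = cohort.cohort[cohort.cohort["timepoint"] == "baseline"]
            table, selection = calibration.calibrate_score_table(baseline)
            (out / "model_comparison.csv").write_text(selection.comparison.to_csv(index=False))
        else:
            table = default_score_table()
            selection = None
        dump_score_table(table, out / "mcs_table.cfg")
        if selection is not None:
            report.sections["calibration"] = {
                "chosen_diarrhea_item": selection.chosen,
                "multivariate_gain": selection.multivariate_gain,
                "meaningful_gain": selection.meaningful_gain,
            }

        stage = "score"
        scores = score_cohort(cohort.diary, table)
        scores.to_csv(out / "scores.csv", index=False)
        merged = scores.merge(
            cohort.cohort.drop(columns=[c for c in MCSQ_ITEMS + ["hjortswang_active"]
                                        if c in cohort.cohort.columns]),
            on=["patient_id", "timepoint"],
        )
        report.sections["score"] = {
            "n_scored": len(scores),
            "severity_counts": scores[scores.timepoint == "baseline"]["severity"]
            .value_counts().to_dict(),
        }

        if config.run_validate:
            stage = "validate"
            report.sections["validation"] = _validate_stage(merged, config, out)

        cluster_labels = None
        if config.run_cluster:
            stage = "cluster"
            result, meta = severity_clustering.cluster_cohort(
                cohort.cohort,
                seed=stage_seed(config.master_seed, "cluster"),
                jackstraw_perms=config.jackstraw_perms,
                n_trees=config.n_trees,
            )
            labels_df = cohort.cohort.loc[meta["index"], ["patient_id", "timepoint"]].copy()
            labels_df["cluster"] = result.labels
            labels_df["annotation"] = [result.annotation[c] for c in result.labels]
            labels_df.to_csv(out / "clusters.csv", index=False)
            cluster_labels = labels_df
            report.sections["clustering"] = {
                "n_clusters": result.n_clusters,
                "quality": result.quality,
                "n_significant_dims": meta["n_significant_dims"],
                "removed_rows": len(meta["removal_log"]["removed_rows"]),
                "removed_columns": meta["removal_log"]["removed_columns"],
            }

        if config.run_roc and cluster_labels is not None:
            stage = "roc"
            roc_df = scores.merge(cluster_labels, on=["patient_id", "timepoint"])
            contrasts = roc_validation.evaluate_severity_contrasts(
                roc_df["mcs"], roc_df["hjortswang_active"], roc_df["annotation"]
            )
            report.sections["roc"] = {
                name: {"auc": r.auc, "cutoff": r.chosen_cutoff,
                       "sensitivity": r.sensitivity, "specificity": r.specificity}
                for name, r in contrasts.items()
            }
            pd.DataFrame(
                [
                    {"contrast": name, "threshold": t, "fpr": f, "tpr": s}
                    for name, r in contrasts.items()
                    for t, f, s in zip(r.thresholds, r.fpr, r.tpr)
                ]
            ).to_csv(out / "roc_curves.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report.manifest = {
        "master_seed": config.master_seed,
        "config_hash": _config_hash(config),
        "stage_seeds": {s: stage_seed(config.master_seed, s)
                        for s in ("simulate", "cluster")},
        "n_patients": gen_cfg.n_patients,
    }
    (out / "report.json").write_text(report.to_json())
    (out / "report.md").write_text(_markdown_summary(report))
    return report


def _validate_stage(merged: pd.DataFrame, config: RunConfig, out: Path) -> dict:
    baseline = merged[merged.timepoint == "baseline"].set_index("patient_id")
    followup = merged[merged.timepoint == "followup"].set_index("patient_id")
    items = [c for c in MCSQ_NONDERIVED_ITEMS if baseline[c].std() > 0]
    x = baseline[items].dropna()

    r = np.corrcoef(x.to_numpy(float), rowvar=False)
    chi2, df, bart_p = psychometrics.bartlett_sphericity(r, len(x))
    overall_kmo, _ = psychometrics.kmo(r)
    alpha = psychometrics.cronbach_alpha(x)
    n_factors = psychometrics.parallel_analysis(
        x.to_numpy(float), seed=stage_seed(config.master_seed, "parallel"))
    model = psychometrics.efa(x, n_factors=max(1, n_factors), rotation="promax")
    model.loadings.to_csv(out / "factor_loadings.csv")

    # test-retest on untreated patients (stable between administrations);
    # responsiveness on the treated arm
    if "treated" in baseline.columns:
        untreated = baseline.index[baseline["treated"] == 0]
    else:
        untreated = baseline.index[baseline["severity"] == "remission"]
    both = untreated.intersection(followup.index)
    retest = pd.DataFrame(
        {"baseline": baseline.loc[both, "mcs"], "followup": followup.loc[both, "mcs"]}
    )
    icc = psychometrics.icc2k(retest) if len(both) >= 5 else None

    treated = baseline.index.difference(untreated).intersection(followup.index)
    resp = psychometrics.responsiveness_battery(
        baseline.loc[treated, items + ["mcs"]], followup.loc[treated, items + ["mcs"]]
    )
    resp.table.to_csv(out / "responsiveness.csv")

    hyps = [
        psychometrics.CorrelationHypothesis("mcs", "ibdq_total", -1, "pearson",
                                            config.correlation_threshold),
        psychometrics.CorrelationHypothesis("mcs", "ibdq_bowel", -1, "pearson",
                                            config.correlation_threshold),
        psychometrics.CorrelationHypothesis("mcs", "shs_symptoms", +1, "spearman",
                                            config.correlation_threshold),
        psychometrics.CorrelationHypothesis("mcs", "patient_symptom_rating", +1, "spearman",
                                            config.correlation_threshold),
    ]
    validity = psychometrics.validity_correlations(baseline.reset_index(), hyps)
    validity.to_csv(out / "validity.csv", index=False)

    anchor = calibration.fit_anchor_regression(baseline["mcs"], baseline["ibdq_total"])
    return {
        "bartlett": {"chi2": chi2, "df": df, "p": bart_p},
        "kmo": overall_kmo,
        "cronbach_alpha": alpha,
        "parallel_analysis_factors": n_factors,
        "efa_n_factors": model.n_factors,
        "efa_rmsr": model.rmsr,
        "icc2k": None if icc is None else
        {"icc": icc.icc, "ci": [icc.ci_low, icc.ci_high], "n": icc.n_subjects},
        "responsiveness_all_significant": bool((resp.table["p_adjusted"] < 0.05).all()),
        "validity_met": {f"{r.x}~{r.y}": bool(r.met) for r in validity.itertuples()},
        "anchor_regression": {"slope": anchor.slope, "intercept": anchor.intercept,
                              "adjusted_r2": anchor.adjusted_r2,
                              "ci": [anchor.ci_low, anchor.ci_high]},
    }


def _markdown_summary(report: ValidationReport) -> str:
    lines = ["# MC activity pipeline report", ""]
    lines.append(f"master seed: {report.manifest.get('master_seed')}  ")
    lines.append(f"config hash: {report.manifest.get('config_hash')}")
    for name, section in report.sections.items():
        lines.append(f"\n## {name}\n")
        lines.append("```json")
        lines.append(json.dumps(section, indent=2, sort_keys=True, default=_jsonable))
        lines.append("```")
    return "\n".join(lines) + "\n"
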