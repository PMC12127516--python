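"""Cohort table I/O, pipeline configuration, and the end-to-end run.

One tabular dialect only: comma-separated, header row, UTF-8, "." decimal,
empty cell = missing.  Decimal-comma files are rejected with a clear
message rather than silently misparsed.  All pipeline randomness flows from
a single seed; artifacts are schema-versioned and byte-stable for a fixed
configuration.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarkers import BiomarkerThresholds, biological_diagnosis, concordance
from .norms import derive_norms_from_reference_cohort, flag_cohort, \
    flag_cognitive_deficits, flag_regional_atrophy
from .profiling import profile_cohort
from .risk import RiskModelConfig, cross_validate_risk, feature_columns, \
    predict_risk, train_risk_model
from .schema import (COHORT_COLUMNS, META_FIELDS, NUMERIC_FIELDS, SCHEMA_VERSION,
                     StagingError, SubjectRecord, ValidationError)
from .staging import stage_cohort
from .stats import ConfusionCounts, cohens_kappa, diagnostic_metrics, roc_auc_delong
from .synthetic import build_published_group_spec, generate_cohort

log = logging.getLogger("memclinic")

__all__ = ["read_cohort", "write_cohort", "PipelineConfig", "run_pipeline",
           "SubjectReport"]

_BOOL_COLS = ["pet_assessed"]
_STRING_COLS = [c for c in META_FIELDS if c not in _BOOL_COLS]


def write_cohort(cohort: pd.DataFrame, path) -> None:
    df = cohort.copy()
    df.to_csv(path, index=False, na_rep="", encoding="utf-8")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort table in the canonical dialect; strict about locale."""
    df = pd.read_csv(path, dtype={c: "string" for c in _STRING_COLS},
                     encoding="utf-8")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort file missing columns {missing[:6]}")
    for col in NUMERIC_FIELDS:
        if df[col].dtype == object or str(df[col].dtype) == "string":
            offending = df[col].astype(str).str.match(r"^-?\d+,\d+$", na=False)
            if offending.any():
                line = int(offending.idxmax()) + 2  # header + 1-based
                raise ValidationError(
                    f"column {col!r} line {line}: decimal comma detected; "
                    "this reader accepts '.' decimals only")
        try:
            df[col] = pd.to_numeric(df[col])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"column {col!r} not numeric: {exc}") from exc
    if df["pet_assessed"].dtype == object:
        df["pet_assessed"] = df["pet_assessed"].astype(bool)
    df["pet_positive_for"] = df["pet_positive_for"].fillna("")
    if df["subject_id"].duplicated().any():
        raise ValidationError("duplicate subject_id values")
    # unit sanity (warn-level): hippocampal volumes beyond plausible mL range
    hippo = df["hippocampus_total"].dropna()
    if len(hippo) and (hippo > 50).any():
        log.warning("hippocampus_total above 50 mL for %d subjects — check units",
                    int((hippo > 50).sum()))
    return df


@dataclass(frozen=True)
class SubjectReport:
    """Per-subject end-to-end report; every field traces to a pipeline stage."""

    subject_id: str
    n_cognitive_impairments: int
    n_functional_impairments: int
    memory_impaired: bool
    atrophy_patterns: dict
    stage: str
    syndrome: str | None
    hypothesis_pre: str | None
    hypothesis: str | None
    risk_class: str | None
    vote_fraction: float | None
    biological_diagnosis: str | None
    schema_version: str = SCHEMA_VERSION
    package_version: str = __version__
    seed: int | None = None


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "pipeline_out"
    n_per_group: dict = field(default_factory=lambda: {"LOW_RISK": 200, "HIGH_RISK": 200})
    n_reference: int = 200
    reference_group: str = "LOW_RISK"
    label_noise: float = 0.15
    feature_blocks: tuple = ("volumetric", "cognitive")
    risk: RiskModelConfig = field(default_factory=RiskModelConfig)
    thresholds: BiomarkerThresholds = field(default_factory=BiomarkerThresholds)
    cv_splits: int = 5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        risk = RiskModelConfig(**doc.pop("risk", {}))
        thr = BiomarkerThresholds(**doc.pop("thresholds", {}))
        if "feature_blocks" in doc:
            doc["feature_blocks"] = tuple(doc["feature_blocks"])
        return cls(risk=risk, thresholds=thr, **doc)


def run_pipeline(config: PipelineConfig) -> dict:
    """simulate → flags → stage → risk → profile → adjudicate → evaluate.

    Writes the artifact set (cohort, flags, stages, profiles, adjudication,
    metrics report, per-subject reports) under ``config.out_dir`` and
    returns the in-memory artifacts.  Deterministic for a fixed config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = build_published_group_spec()
    log.info("pipeline start: seed=%d groups=%s", config.seed, config.n_per_group)

    cohort = generate_cohort(spec, config.n_per_group, seed=config.seed,
                             label_noise=config.label_noise)
    write_cohort(cohort, out / "cohort.csv")
    reference = generate_cohort(spec, {config.reference_group: config.n_reference},
                                seed=config.seed + 1)
    artifacts: dict = {"cohort": cohort, "reference": reference}
    metrics_report: dict = {"seed": config.seed, "package_version": __version__,
                            "schema_version": SCHEMA_VERSION,
                            "n_subjects": int(len(cohort))}

    if cohort.empty:
        for name in ("flags", "stages", "profiles", "adjudication"):
            pd.DataFrame().to_csv(out / f"{name}.csv", index=False)
        (out / "metrics.json").write_text(json.dumps(metrics_report, indent=2))
        (out / "reports.jsonl").write_text("")
        return {**artifacts, "metrics": metrics_report}

    norms = derive_norms_from_reference_cohort(reference)
    norms.to_yaml(out / "norms.yaml")
    flags = flag_cohort(cohort, norms)
    flags.to_csv(out / "flags.csv", index=False)
    stages = stage_cohort(flags, cohort["mmse"])
    stages.to_csv(out / "stages.csv", index=False)

    # conversion-risk model on the risk groups, cross-validated then refit
    risk_mask = cohort["diagnosis_24mo"].notna()
    risk_rows = cohort[risk_mask]
    features = feature_columns(config.feature_blocks)
    risk_class = pd.Series(pd.NA, index=cohort.index, dtype="object")
    votes = pd.Series(np.nan, index=cohort.index, dtype=float)
    if len(risk_rows) and risk_rows["diagnosis_24mo"].nunique() == 2:
        y = (risk_rows["diagnosis_24mo"] == "cMCI").astype(int).to_numpy()
        cv = cross_validate_risk(risk_rows, y, config.risk, seed=config.seed,
                                 n_splits=config.cv_splits, features=features)
        model = train_risk_model(risk_rows, y, config.risk, seed=config.seed,
                                 features=features)
        labels, v = predict_risk(model, cohort)
        risk_class[:] = labels
        votes[:] = v
        # generalization metrics from the pooled held-out CV votes
        cv_truth = cv["truth"].astype(bool)
        cv_pred = cv["votes"] >= config.risk.vote_threshold
        counts = ConfusionCounts(tp=int((cv_pred & cv_truth).sum()),
                                 fp=int((cv_pred & ~cv_truth).sum()),
                                 tn=int((~cv_pred & ~cv_truth).sum()),
                                 fn=int((~cv_pred & cv_truth).sum()))
        metrics_report["progression"] = {
            "cv_accuracy": cv["accuracy"],
            "cv_fold_accuracies": cv["fold_accuracies"],
            **{k: {"estimate": m.estimate, "percent": m.percent,
                   "ci": [m.ci_low, m.ci_high], "counts": [m.numerator, m.denominator]}
               for k, m in diagnostic_metrics(counts).items()},
        }
        auc = roc_auc_delong(cv["votes"], cv["truth"])
        metrics_report["progression"]["roc_auc"] = {
            "estimate": auc.estimate, "ci": [auc.ci_low, auc.ci_high]}

    # syndrome profiling + hypothesis with risk-based reclassification
    profiles = []
    for _, row in cohort.iterrows():
        d = flag_cognitive_deficits(row, norms)
        a = flag_regional_atrophy(row, norms)
        profiles.append((row["subject_id"], d, a))
    risk_map = {sid: rc for sid, rc in zip(cohort["subject_id"], risk_class)
                if pd.notna(rc)}
    prof_table, flow = profile_cohort(profiles, risk_map)
    prof_table.to_csv(out / "profiles.csv", index=False)
    metrics_report["profiling_flow"] = flow

    # biomarker adjudication against the causal hypothesis
    adj_rows = []
    for (_, row), (_, prow) in zip(cohort.iterrows(), prof_table.iterrows()):
        rec = SubjectRecord.from_row(row)
        value = None
        if prow["syndrome"] is not None and not prow["error"]:
            try:
                value = biological_diagnosis(rec.csf, rec.pet, prow["syndrome"],
                                             config.thresholds).value
            except Exception as exc:  # per-subject, recorded not fatal
                log.debug("adjudication failed for %s: %s", rec.subject_id, exc)
        adj_rows.append({"subject_id": row["subject_id"], "biodx": value})
    adjudication = pd.DataFrame(adj_rows)
    adjudication.to_csv(out / "adjudication.csv", index=False)
    ok = prof_table["hypothesis"].notna() & adjudication["biodx"].notna()
    if ok.any():
        table = concordance(prof_table.loc[ok, "hypothesis"].tolist(),
                            adjudication.loc[ok, "biodx"].tolist())
        metrics_report["concordance"] = {
            k: {"percent": m.percent, "counts": [m.numerator, m.denominator],
                "ci_percent": list(m.ci_percent)}
            for k, m in table.metrics().items()}

    # staging agreement against the clinician baseline where present
    staged = cohort["clinician_stage_baseline"].notna()
    if staged.any():
        kap = cohens_kappa(stages.loc[staged.to_numpy(), "stage"],
                           cohort.loc[staged, "clinician_stage_baseline"])
        metrics_report["staging_kappa"] = {"estimate": kap.estimate,
                                           "ci": [kap.ci_low, kap.ci_high]}

    reports = []
    for (_, f), (_, s), (_, p), (_, adj), rc, vf in zip(
            flags.iterrows(), stages.iterrows(), prof_table.iterrows(),
            adjudication.iterrows(), risk_class, votes):
        reports.append(SubjectReport(
            subject_id=f["subject_id"],
            n_cognitive_impairments=int(f["n_cognitive_impairments"]),
            n_functional_impairments=int(f["n_functional_impairments"]),
            memory_impaired=bool(f["memory_impaired"]),
            atrophy_patterns={k: bool(f[k]) for k in (
                "medial_temporal_atrophy", "parieto_occipital_atrophy",
                "dominant_hemisphere_focal_atrophy", "frontotemporal_atrophy",
                "mri_inconsistent")},
            stage=s["stage"], syndrome=p["syndrome"],
            hypothesis_pre=p["hypothesis_pre"], hypothesis=p["hypothesis"],
            risk_class=None if pd.isna(rc) else str(rc),
            vote_fraction=None if np.isnan(vf) else float(vf),
            biological_diagnosis=adj["biodx"],
            seed=config.seed))
    with open(out / "reports.jsonl", "w") as fh:
        for r in reports:
            fh.write(json.dumps(dataclasses.asdict(r), default=str) + "\n")
    (out / "metrics.json").write_text(
        json.dumps(metrics_report, indent=2, default=float))
    log.info("pipeline done: %d subjects, artifacts in %s", len(cohort), out)
    return {**artifacts, "flags": flags, "stages": stages, "profiles": prof_table,
            "adjudication": adjudication, "metrics": metrics_report,
            "reports": reports}
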