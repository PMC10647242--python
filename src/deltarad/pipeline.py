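"""End-to-end pipeline: simulate (or load) a paired-scan cohort, preprocess,
extract the 593-feature catalog, ICC-filter, compute the five delta methods,
run staged selection, fit Cox risk models, evaluate on the holdout, and
stratify by the training Youden threshold.

One pipeline seed fans out to per-stage child seeds as ``seed * 1000 + k``
(k = stage index), so every stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import (
    DAYS_PER_MONTH,
    HORIZON_MONTHS,
    EvaluationReport,
    bootstrap_compare,
    evaluate_model,
    km_logrank,
    youden_threshold,
)
from .features import extract_all
from .images import ImageVolume, RoiMask, read_nifti_mask, read_nifti_volume
from .preprocessing import resample_isotropic, wavelet_bank, znormalize
from .reliability import DELTA_METHODS, delta_features, icc_filter, jitter_mask
from .selection import (
    SelectionResult,
    encode_clinical,
    impute_missing_forest,
    select_clinical,
    select_radiomic,
)
from .survival import RiskModel, fit_coxph, split_holdout
from .synthetic import (
    CohortConfig,
    SyntheticSubject,
    apply_missingness,
    cohort_outcomes,
    generate_cohort,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "extract_cohort_features",
    "read_cohort",
]


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    wavelet: str = "haar"
    normalization_scope: str = "whole_image"
    n_gray_levels: int = 32
    icc_threshold: float = 0.80
    icc_subset: int = 30
    delta_methods: tuple[str, ...] = DELTA_METHODS
    p_uni_clinical: float = 0.1
    p_multi_clinical: float = 0.1
    p_uni_radiomic: float = 0.05
    vif_threshold: float = 5.0
    top_k: int = 5
    p_final: float = 0.1
    train_fraction: float = 0.7
    combined_mode: str = "joint"  # 'joint' refit or 'average' of the two risk scores
    horizons_months: tuple[float, ...] = HORIZON_MONTHS
    youden_horizon_days: float | None = None  # default: median training PFS
    n_bootstrap: int = 100
    seed: int = 0

    def child_seed(self, k: int) -> int:
        return (self.seed * 1000 + k) % (2**31 - 1)

    @property
    def horizons_days(self) -> list[float]:
        return [m * DAYS_PER_MONTH for m in self.horizons_months]


@dataclass
class PipelineResult:
    config: PipelineConfig
    feature_table: pd.DataFrame
    icc_retained: list[str]
    clinical_selection: SelectionResult
    radiomic_selections: dict[str, SelectionResult]
    method_reports: dict[str, EvaluationReport]
    combined_report: EvaluationReport | None
    clinical_report: EvaluationReport | None
    comparison_pvalues: dict
    stratification: dict
    train_ids: list
    test_ids: list
    models: dict[str, RiskModel]

    def report_dict(self) -> dict:
        return {
            "methods": {m: r.to_dict() for m, r in self.method_reports.items()},
            "clinical": self.clinical_report.to_dict() if self.clinical_report else None,
            "combined": self.combined_report.to_dict() if self.combined_report else None,
            "comparison_pvalues": {
                f"{a}_vs_{b}": {str(h): p for h, p in pv.items()}
                for (a, b), pv in self.comparison_pvalues.items()
            },
            "stratification": {
                k: v for k, v in self.stratification.items() if k != "km_curves"
            },
            "icc_retained": len(self.icc_retained),
            "n_train": len(self.train_ids),
            "n_test": len(self.test_ids),
        }


def preprocess_and_extract(
    volume: ImageVolume,
    mask: RoiMask,
    config: PipelineConfig,
) -> dict[str, float]:
    """Resample -> Z-normalize -> wavelet bank -> full catalog for one scan."""
    vol, msk = resample_isotropic(volume, mask, config.target_spacing)
    vol = znormalize(vol, msk, scope=config.normalization_scope)
    bank = wavelet_bank(vol, config.wavelet)
    return extract_all(bank, msk, config.n_gray_levels)


def extract_cohort_features(
    cohort: list[SyntheticSubject], config: PipelineConfig
) -> pd.DataFrame:
    """Feature table indexed (subject_id, timepoint in {pretreat, follow})."""
    rows = {}
    for s in cohort:
        rows[(s.subject_id, "pretreat")] = preprocess_and_extract(s.pre_volume, s.pre_mask, config)
        rows[(s.subject_id, "follow")] = preprocess_and_extract(s.post_volume, s.post_mask, config)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index, names=["subject_id", "timepoint"])
    return table


def retest_tables(
    cohort: list[SyntheticSubject], config: PipelineConfig, feature_table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-reader emulation: reader 1 = pipeline masks, reader 2 = jittered masks."""
    subset = cohort[: min(config.icc_subset, len(cohort))]
    ids = [s.subject_id for s in subset]
    r1 = feature_table.xs("pretreat", level="timepoint").loc[ids]
    rows = {}
    for k, s in enumerate(subset):
        jmask = jitter_mask(s.pre_mask, seed=config.child_seed(100 + k))
        rows[s.subject_id] = preprocess_and_extract(s.pre_volume, jmask, config)
    r2 = pd.DataFrame.from_dict(rows, orient="index").loc[ids]
    return r1, r2


def read_cohort(data_dir: str) -> tuple[list[SyntheticSubject], int]:
    """Load a cohort written by :func:`deltarad.synthetic.write_cohort`.

    Subjects missing a scan or mask are excluded with a logged reason; returns
    (cohort, n_excluded).  Schema violations (shape mismatch, non-positive
    survival time) raise.
    """
    from .synthetic import SurvivalOutcome

    clinical = pd.read_csv(os.path.join(data_dir, "clinical.csv"))
    cohort = []
    excluded = 0
    for _, row in clinical.iterrows():
        sid = row["subject_id"]
        paths = {
            kind: os.path.join(data_dir, f"{sid}_{kind}.nii.gz")
            for kind in ("pre", "post", "pre_mask", "post_mask")
        }
        if not all(os.path.exists(p) for p in paths.values()):
            logger.warning("subject %s missing a scan/mask file; excluded", sid)
            excluded += 1
            continue
        pre = read_nifti_volume(paths["pre"])
        post = read_nifti_volume(paths["post"])
        pre_mask = read_nifti_mask(paths["pre_mask"])
        post_mask = read_nifti_mask(paths["post_mask"])
        pre_mask.require_aligned(pre)
        post_mask.require_aligned(post)
        if float(row["time_days"]) <= 0:
            raise ValueError(f"subject {sid}: non-positive survival time")
        interval = (
            pd.Timestamp(row["scan_date_follow"]) - pd.Timestamp(row["scan_date_pre"])
        ).days
        clin = {
            k: row[k]
            for k in row.index
            if k not in ("subject_id", "time_days", "event", "scan_date_pre", "scan_date_follow")
        }
        cohort.append(
            SyntheticSubject(
                subject_id=sid,
                pre_volume=pre,
                post_volume=post,
                pre_mask=pre_mask,
                post_mask=post_mask,
                scan_interval_days=float(interval),
                clinical=clin,
                outcome=SurvivalOutcome(float(row["time_days"]), int(row["event"])),
                true_risk=float("nan"),
                texture_shift=float("nan"),
            )
        )
    return cohort, excluded


def run_pipeline(
    config: PipelineConfig,
    cohort: list[SyntheticSubject] | None = None,
    out_dir: str | None = None,
) -> PipelineResult:
    """Execute the full workflow and optionally persist every intermediate."""
    if cohort is None:
        cohort = generate_cohort(dataclasses.replace(config.cohort, seed=config.child_seed(0)))
    outcomes = cohort_outcomes(cohort)
    ids = outcomes.index

    logger.info("extracting features for %d subjects", len(cohort))
    table = extract_cohort_features(cohort, config)

    r1, r2 = retest_tables(cohort, config, table)
    retained = icc_filter(r1, r2, config.icc_threshold)
    logger.info("ICC filter retained %d features", len(retained))

    interval = pd.Series(
        {s.subject_id: s.scan_interval_days for s in cohort}, name="interval_days"
    )

    # clinical branch: missingness -> forest imputation -> dummy encoding
    clin_raw = pd.DataFrame({s.subject_id: s.clinical for s in cohort}).T
    clin_raw.index.name = "subject_id"
    clin_missing = apply_missingness(clin_raw, config.cohort.missing_rate, config.child_seed(1))
    numeric = clin_missing.copy()
    numeric["gender"] = (numeric["gender"] == "female").astype(float)
    numeric = numeric.astype(float)
    imputed = impute_missing_forest(numeric, seed=config.child_seed(2))
    imputed["gender"] = np.where(imputed["gender"] > 0.5, "female", "male")
    encoded = encode_clinical(imputed)

    train_ids, test_ids = split_holdout(
        ids, outcomes["event"], config.train_fraction, config.child_seed(3)
    )

    clinical_sel = select_clinical(
        encoded.loc[train_ids],
        outcomes.loc[train_ids],
        config.p_uni_clinical,
        config.p_multi_clinical,
    )

    radiomic_sels: dict[str, SelectionResult] = {}
    method_reports: dict[str, EvaluationReport] = {}
    models: dict[str, RiskModel] = {}
    test_risks: dict[str, np.ndarray] = {}
    delta_tables: dict[str, pd.DataFrame] = {}
    for i, method in enumerate(config.delta_methods):
        dtab = delta_features(table[retained], method, interval)
        delta_tables[method] = dtab
        sel = select_radiomic(
            dtab.loc[train_ids],
            outcomes.loc[train_ids],
            config.p_uni_radiomic,
            config.vif_threshold,
            config.top_k,
            config.p_final,
        )
        radiomic_sels[method] = sel
        if not sel.final_features:
            logger.warning("method %s: no features selected; skipped", method)
            continue
        filled = dtab[sel.final_features].apply(lambda c: c.fillna(c.median()))
        model = fit_coxph(filled.loc[train_ids], outcomes.loc[train_ids])
        models[method] = model
        risk = model.predict_risk(filled.loc[test_ids]).to_numpy()
        test_risks[method] = risk
        method_reports[method] = evaluate_model(
            risk,
            outcomes.loc[test_ids],
            config.horizons_days,
            train_outcomes=outcomes.loc[train_ids],
            n_bootstrap=config.n_bootstrap,
            seed=config.child_seed(10 + i),
        )

    comparison_pvalues: dict = {}
    if "delta_time" in test_risks and len(test_risks) > 1:
        # horizon definedness depends on the test outcomes only
        defined_horizons = []
        out_te = outcomes.loc[test_ids]
        for h in config.horizons_days:
            ev = out_te["event"].astype(bool) & (out_te["time_days"] <= h)
            if ev.any() and (out_te["time_days"] > h).any():
                defined_horizons.append(h)
        boot = bootstrap_compare(
            test_risks,
            outcomes.loc[test_ids],
            defined_horizons,
            B=config.n_bootstrap,
            seed=config.child_seed(20),
            reference="delta_time",
        )
        comparison_pvalues = boot["p_values"]

    # clinical-only and combined (joint refit) models
    clinical_report = None
    combined_report = None
    stratification: dict = {}
    risk_cols = clinical_sel.final_features
    if risk_cols:
        clin_model = fit_coxph(encoded.loc[train_ids, risk_cols], outcomes.loc[train_ids])
        models["clinical"] = clin_model
        clin_risk = clin_model.predict_risk(encoded.loc[test_ids, risk_cols]).to_numpy()
        clinical_report = evaluate_model(
            clin_risk,
            outcomes.loc[test_ids],
            config.horizons_days,
            train_outcomes=outcomes.loc[train_ids],
            n_bootstrap=config.n_bootstrap,
            seed=config.child_seed(30),
        )

    best_method = "delta_time" if "delta_time" in radiomic_sels else None
    if best_method and risk_cols and radiomic_sels[best_method].final_features:
        rad_cols = radiomic_sels[best_method].final_features
        dtab = delta_tables[best_method][rad_cols].apply(lambda c: c.fillna(c.median()))
        if config.combined_mode == "joint":
            joint = encoded[risk_cols].join(dtab)
            comb_model = fit_coxph(joint.loc[train_ids], outcomes.loc[train_ids])
            models["combined"] = comb_model
            comb_risk_test = comb_model.predict_risk(joint.loc[test_ids]).to_numpy()
            comb_risk_train = comb_model.predict_risk(joint.loc[train_ids]).to_numpy()
        elif config.combined_mode == "average":
            # standardized mean of the clinical and radiomic risk scores
            rad_model = models[best_method]

            def _avg(ids):
                a = models["clinical"].predict_risk(encoded.loc[ids, risk_cols]).to_numpy()
                b = rad_model.predict_risk(dtab.loc[ids]).to_numpy()
                za = (a - a.mean()) / (a.std() or 1.0)
                zb = (b - b.mean()) / (b.std() or 1.0)
                return 0.5 * (za + zb)

            comb_risk_train = _avg(train_ids)
            comb_risk_test = _avg(test_ids)
        else:
            raise ValueError(f"unknown combined_mode {config.combined_mode!r}")
        combined_report = evaluate_model(
            comb_risk_test,
            outcomes.loc[test_ids],
            config.horizons_days,
            train_outcomes=outcomes.loc[train_ids],
            n_bootstrap=config.n_bootstrap,
            seed=config.child_seed(31),
        )

        horizon = config.youden_horizon_days
        if horizon is None:
            horizon = float(outcomes.loc[train_ids, "time_days"].median())
        thr = youden_threshold(comb_risk_train, outcomes.loc[train_ids], horizon)
        group = pd.Series(
            np.where(comb_risk_test >= thr, "high", "low"), index=pd.Index(test_ids)
        )
        if group.nunique() == 2:
            strat = km_logrank(group, outcomes.loc[test_ids])
        else:
            logger.warning("Youden threshold put every test subject in one group")
            strat = {"km_curves": {}, "logrank_stat": np.nan, "logrank_p": np.nan,
                     "hazard_ratio": np.nan, "power": np.nan, "n_events": int(outcomes.loc[test_ids, "event"].sum())}
        stratification = {"threshold": thr, "youden_horizon_days": horizon, **strat}

    result = PipelineResult(
        config=config,
        feature_table=table,
        icc_retained=retained,
        clinical_selection=clinical_sel,
        radiomic_selections=radiomic_sels,
        method_reports=method_reports,
        combined_report=combined_report,
        clinical_report=clinical_report,
        comparison_pvalues=comparison_pvalues,
        stratification=stratification,
        train_ids=list(train_ids),
        test_ids=list(test_ids),
        models=models,
    )
    if out_dir:
        _persist(result, out_dir)
    return result


def _persist(result: PipelineResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    result.feature_table.to_csv(os.path.join(out_dir, "features.csv"))
    with open(os.path.join(out_dir, "report.json"), "w") as f:
        json.dump(result.report_dict(), f, indent=1, default=float)
    stage_logs = {
        "clinical": result.clinical_selection.stage_log,
        **{m: s.stage_log for m, s in result.radiomic_selections.items()},
    }
    with open(os.path.join(out_dir, "selection_log.json"), "w") as f:
        json.dump(stage_logs, f, indent=1, default=float)
    for name, model in result.models.items():
        model.to_json(os.path.join(out_dir, f"model_{name}.json"))
    km = result.stratification.get("km_curves") or {}
    for lab, df in km.items():
        df.to_csv(os.path.join(out_dir, f"km_{lab}.csv"))
    prov = {
        "seed": result.config.seed,
        "n_subjects": result.config.cohort.n_subjects,
        "config": {
            k: v for k, v in dataclasses.asdict(result.config).items() if k != "cohort"
        },
        "cohort_config": dataclasses.asdict(result.config.cohort),
    }
    with open(os.path.join(out_dir, "provenance.json"), "w") as f:
        json.dump(prov, f, indent=1, default=str)
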