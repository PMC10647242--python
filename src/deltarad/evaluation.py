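"""Survival-model evaluation: Harrell C-index, IPCW time-dependent AUC at
fixed horizons, bootstrap model comparison, Youden-index risk stratification,
Kaplan-Meier curves, the two-group log-rank test and its Schoenfeld power.

Horizons are stored in days; months convert at 30.44 days/month.  The
time-dependent AUC is the cumulative/dynamic (Uno) estimator with inverse
probability-of-censoring weights from the Kaplan-Meier censoring distribution
of the training outcomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DAYS_PER_MONTH",
    "HORIZON_MONTHS",
    "UndefinedMetricError",
    "concordance_index",
    "time_dependent_auc",
    "bootstrap_compare",
    "youden_threshold",
    "km_logrank",
    "schoenfeld_power",
    "evaluate_model",
    "EvaluationReport",
    "RiskStratification",
]

DAYS_PER_MONTH = 30.44
HORIZON_MONTHS = (6, 9, 12, 15)


class UndefinedMetricError(ValueError):
    """The requested metric is undefined on the given data."""


@dataclass
class EvaluationReport:
    c_index: float
    c_index_ci: tuple[float, float]
    auc_by_horizon: dict[float, tuple[float, float, float]]  # point, lo, hi
    n_bootstrap: int
    comparisons: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "c_index": self.c_index,
            "c_index_ci": list(self.c_index_ci),
            "auc_by_horizon": {
                str(h): list(v) for h, v in self.auc_by_horizon.items()
            },
            "n_bootstrap": self.n_bootstrap,
            "comparisons": self.comparisons,
        }


@dataclass
class RiskStratification:
    threshold: float
    group: pd.Series  # 'high' / 'low'
    km_curves: dict[str, pd.DataFrame]
    logrank_stat: float
    logrank_p: float
    hazard_ratio: float
    power: float


def concordance_index(risk, outcomes: pd.DataFrame) -> float:
    """Harrell's C over usable pairs; risk ties count 1/2."""
    from lifelines.utils import concordance_index as _ci

    risk = np.asarray(risk, dtype=float)
    time = outcomes["time_days"].to_numpy()
    event = outcomes["event"].to_numpy()
    if event.sum() == 0 or len(time) < 2:
        raise UndefinedMetricError("no comparable pairs")
    # lifelines' convention scores predicted *survival* times, so negate risk
    return float(_ci(time, -risk, event))


def _km_censoring(outcomes: pd.DataFrame):
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(outcomes["time_days"], 1 - outcomes["event"])
    return km


def time_dependent_auc(
    risk,
    outcomes: pd.DataFrame,
    horizon_days: float,
    train_outcomes: pd.DataFrame | None = None,
) -> float:
    """Cumulative/dynamic AUC at a horizon with IPCW censoring weights.

    Cases: event by the horizon.  Controls: still at risk past the horizon.
    Weights come from the training censoring Kaplan-Meier (the evaluation
    outcomes themselves when no separate training set is given).
    """
    risk = np.asarray(risk, dtype=float)
    time = outcomes["time_days"].to_numpy()
    event = outcomes["event"].to_numpy().astype(bool)
    cases = event & (time <= horizon_days)
    controls = time > horizon_days
    if not cases.any() or not controls.any():
        raise UndefinedMetricError(
            f"no cases or no controls at horizon {horizon_days:.0f} days"
        )
    km = _km_censoring(train_outcomes if train_outcomes is not None else outcomes)
    g_cases = np.atleast_1d(np.asarray(km.predict(time[cases]), dtype=float))
    g_horizon = float(km.predict(horizon_days))
    g_cases = np.clip(g_cases, 1e-8, None)
    g_horizon = max(g_horizon, 1e-8)
    w_cases = 1.0 / g_cases
    w_controls = np.full(int(controls.sum()), 1.0 / g_horizon)

    r_cases = risk[cases]
    r_controls = risk[controls]
    # weighted Mann-Whitney: P(risk_case > risk_control), ties at 1/2
    order = np.argsort(r_controls, kind="mergesort")
    rc_sorted = r_controls[order]
    wc_sorted = w_controls[order]
    cum_w = np.concatenate(([0.0], np.cumsum(wc_sorted)))
    lo = np.searchsorted(rc_sorted, r_cases, side="left")
    hi = np.searchsorted(rc_sorted, r_cases, side="right")
    wins = cum_w[lo] + 0.5 * (cum_w[hi] - cum_w[lo])
    num = float(np.sum(w_cases * wins))
    den = float(np.sum(w_cases) * np.sum(w_controls))
    return num / den


def bootstrap_compare(
    risks: dict[str, np.ndarray],
    outcomes: pd.DataFrame,
    horizons_days,
    B: int = 100,
    seed: int = 0,
    reference: str | None = None,
) -> dict:
    """Resample subjects B times; paired t-tests of per-replicate AUCs.

    ``risks`` maps model name -> per-subject risk scores on the same subjects.
    Degenerate replicates (metric undefined) are redrawn, up to 10*B attempts.
    Returns per-replicate metric frames and, when ``reference`` is given,
    two-sided paired-t p-values of every other model against it per horizon.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    n = len(outcomes)
    names = list(risks)
    rep_metrics = {name: {h: [] for h in horizons_days} for name in names}
    rep_cindex = {name: [] for name in names}
    redrawn = 0
    attempts = 0
    done = 0
    while done < B:
        attempts += 1
        if attempts > 10 * B:
            raise RuntimeError("too many degenerate bootstrap replicates")
        idx = rng.integers(0, n, size=n)
        out_b = outcomes.iloc[idx]
        try:
            vals = {}
            cvals = {}
            for name in names:
                r_b = np.asarray(risks[name])[idx]
                cvals[name] = concordance_index(r_b, out_b)
                vals[name] = {
                    h: time_dependent_auc(r_b, out_b, h) for h in horizons_days
                }
        except UndefinedMetricError:
            redrawn += 1
            continue
        for name in names:
            rep_cindex[name].append(cvals[name])
            for h in horizons_days:
                rep_metrics[name][h].append(vals[name][h])
        done += 1
    if redrawn:
        logger.info("redrew %d degenerate bootstrap replicates", redrawn)

    result = {
        "replicate_auc": {
            name: pd.DataFrame(rep_metrics[name]) for name in names
        },
        "replicate_c_index": pd.DataFrame(rep_cindex),
        "n_redrawn": redrawn,
        "p_values": {},
    }
    if reference is not None:
        for name in names:
            if name == reference:
                continue
            pvs = {}
            for h in horizons_days:
                a = np.asarray(rep_metrics[reference][h])
                b = np.asarray(rep_metrics[name][h])
                if np.allclose(a, b):
                    pvs[h] = 1.0
                else:
                    pvs[h] = float(stats.ttest_rel(a, b).pvalue)
            result["p_values"][(name, reference)] = pvs
    return result


def youden_threshold(
    risk_train,
    outcomes_train: pd.DataFrame,
    horizon_days: float,
) -> float:
    """Risk cut maximizing sensitivity + specificity - 1 on the training ROC.

    IPCW-weighted cases/controls at the horizon; candidate thresholds are the
    observed risk values (classify risk >= threshold as high risk); ties in J
    break toward the lower threshold.
    """
    risk = np.asarray(risk_train, dtype=float)
    time = outcomes_train["time_days"].to_numpy()
    event = outcomes_train["event"].to_numpy().astype(bool)
    cases = event & (time <= horizon_days)
    controls = time > horizon_days
    if not cases.any() or not controls.any():
        raise UndefinedMetricError("ROC undefined: need cases and controls at horizon")
    km = _km_censoring(outcomes_train)
    w = np.zeros(len(risk))
    w[cases] = 1.0 / np.clip(
        np.atleast_1d(np.asarray(km.predict(time[cases]), dtype=float)), 1e-8, None
    )
    w[controls] = 1.0 / max(float(km.predict(horizon_days)), 1e-8)

    total_case_w = w[cases].sum()
    total_ctrl_w = w[controls].sum()
    candidates = np.unique(risk)
    best_thr, best_j = candidates[0], -np.inf
    for thr in candidates:  # ascending: first maximizer is the lowest threshold
        positive = risk >= thr
        sens = w[cases & positive].sum() / total_case_w
        spec = w[controls & ~positive].sum() / total_ctrl_w
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_thr = j, thr
    return float(best_thr)


def schoenfeld_power(
    hazard_ratio: float, n_events: int, p_group1: float = 0.5, alpha: float = 0.05
) -> float:
    """Two-sided power of the log-rank test (Schoenfeld's approximation).

    power = Phi(|log HR| sqrt(d p (1-p)) - z_{1-a/2}) + Phi(-|log HR| sqrt(...) - z_{1-a/2});
    at HR = 1 this equals alpha.
    """
    if hazard_ratio <= 0 or not 0 < p_group1 < 1:
        raise ValueError("need hazard_ratio > 0 and p_group1 in (0, 1)")
    z = stats.norm.ppf(1 - alpha / 2)
    delta = abs(np.log(hazard_ratio)) * np.sqrt(n_events * p_group1 * (1 - p_group1))
    return float(stats.norm.cdf(delta - z) + stats.norm.cdf(-delta - z))


def km_logrank(group: pd.Series, outcomes: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Two-group Kaplan-Meier with Greenwood bands, log-rank test and power.

    ``group`` labels each subject 'high' or 'low'.  With no events the curves
    are flat at 1 and the log-rank test is flagged undefined (NaN).
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    labels = sorted(group.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two nonempty groups, got {labels}")
    curves = {}
    for lab in labels:
        sel = group == lab
        km = KaplanMeierFitter()
        km.fit(outcomes.loc[sel, "time_days"], outcomes.loc[sel, "event"], label=str(lab))
        df = km.survival_function_.copy()
        ci = km.confidence_interval_
        df["lower95"] = ci.iloc[:, 0].to_numpy()
        df["upper95"] = ci.iloc[:, 1].to_numpy()
        df.columns = ["survival", "lower95", "upper95"]
        curves[str(lab)] = df

    total_events = int(outcomes["event"].sum())
    if total_events == 0:
        logger.warning("no events: log-rank test undefined")
        return {
            "km_curves": curves,
            "logrank_stat": np.nan,
            "logrank_p": np.nan,
            "hazard_ratio": np.nan,
            "power": np.nan,
            "n_events": 0,
        }

    g1 = group == labels[1]
    res = logrank_test(
        outcomes.loc[g1, "time_days"],
        outcomes.loc[~g1, "time_days"],
        outcomes.loc[g1, "event"],
        outcomes.loc[~g1, "event"],
    )
    # HR estimate for the power formula: single-covariate Cox on group label
    from lifelines import CoxPHFitter

    df = outcomes[["time_days", "event"]].copy()
    df["g"] = g1.astype(float).to_numpy()
    if df.groupby("g")["event"].sum().min() >= 1 and res.test_statistic > 1e-12:
        try:
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time_days", event_col="event")
            hr = float(np.exp(cph.params_["g"]))
        except Exception:
            hr = 1.0
    else:
        hr = 1.0
    p1 = float(g1.mean())
    return {
        "km_curves": curves,
        "logrank_stat": float(res.test_statistic),
        "logrank_p": float(res.p_value),
        "hazard_ratio": hr,
        "power": schoenfeld_power(hr, total_events, p1, alpha),
        "n_events": total_events,
    }


def evaluate_model(
    risk,
    outcomes: pd.DataFrame,
    horizons_days=None,
    train_outcomes: pd.DataFrame | None = None,
    n_bootstrap: int = 100,
    seed: int = 0,
) -> EvaluationReport:
    """C-index and horizon AUCs with bootstrap percentile 95% CIs."""
    if horizons_days is None:
        horizons_days = [m * DAYS_PER_MONTH for m in HORIZON_MONTHS]
    risk = np.asarray(risk, dtype=float)
    c_point = concordance_index(risk, outcomes)
    auc_points = {}
    for h in horizons_days:
        try:
            auc_points[h] = time_dependent_auc(risk, outcomes, h, train_outcomes)
        except UndefinedMetricError:
            logger.warning("AUC undefined at horizon %.0f days; reported as NaN", h)
            auc_points[h] = np.nan
    defined = [h for h in horizons_days if np.isfinite(auc_points[h])]
    boot = bootstrap_compare({"model": risk}, outcomes, defined, B=n_bootstrap, seed=seed)
    c_reps = boot["replicate_c_index"]["model"].to_numpy()
    c_ci = (float(np.percentile(c_reps, 2.5)), float(np.percentile(c_reps, 97.5)))
    auc = {}
    for h in horizons_days:
        if h in defined:
            reps = boot["replicate_auc"]["model"][h].to_numpy()
            auc[h] = (
                auc_points[h],
                float(np.percentile(reps, 2.5)),
                float(np.percentile(reps, 97.5)),
            )
        else:
            auc[h] = (np.nan, np.nan, np.nan)
    return EvaluationReport(c_point, c_ci, auc, n_bootstrap)
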