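"""Missing-data imputation and the staged feature-selection procedures.

Clinical variables go through a two-stage screen: dummy-encoded covariates are
tested one at a time in univariate proportional-hazards fits (keep p < 0.1),
survivors enter one multivariate fit (keep p < 0.1).  Radiomic delta features
go through three stages: univariate screen at p < 0.05, iterative pruning of
variance-inflation factors above 5 (recomputed after every removal), then a
multivariate fit whose top five features by absolute standardized coefficient
are kept and refit (retain p < 0.1).

Laboratory missingness is filled by an iterative random-forest imputer in the
missForest style: initialise with column medians/modes, then repeatedly
regress each incomplete column on all the others until the imputed values stop
changing (or 10 sweeps).  Observed cells are never altered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionResult",
    "impute_missing_forest",
    "encode_clinical",
    "univariate_cox_pvalues",
    "vif",
    "vif_prune",
    "select_clinical",
    "select_radiomic",
    "benchmark_selectors",
    "SELECTOR_NAMES",
    "LEARNER_NAMES",
]

SELECTOR_NAMES = ("Kbest", "Lasso", "Ridge", "ElasticNet")
LEARNER_NAMES = (
    "CoxPH",
    "SurvivalTree",
    "RandomSurvivalForest",
    "FastSVM",
    "GradientBoosting",
)


@dataclass
class SelectionResult:
    stage_log: list[dict] = field(default_factory=list)
    final_features: list[str] = field(default_factory=list)
    coefficients: dict[str, float] = field(default_factory=dict)
    summary: pd.DataFrame | None = None

    def log_stage(self, stage: str, criterion: str, features_in, features_out) -> None:
        self.stage_log.append(
            {
                "stage": stage,
                "criterion": criterion,
                "n_in": len(features_in),
                "n_out": len(features_out),
                "features_out": list(features_out),
            }
        )


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_missing_forest(
    table: pd.DataFrame,
    seed: int = 0,
    categorical: tuple[str, ...] = (),
    max_iter: int = 10,
    n_estimators: int = 50,
) -> pd.DataFrame:
    """Iterative random-forest imputation (missForest scheme).

    Columns in ``categorical`` use a classification forest and mode
    initialisation; all other columns use a regression forest and median
    initialisation.  Stops when the normalised change in imputed values rises
    (missForest's criterion) or after ``max_iter`` sweeps.
    """
    out = table.copy()
    na = out.isna()
    incomplete = [c for c in out.columns if na[c].any()]
    if not incomplete:
        return out
    for col in incomplete:
        if not (~na[col]).any():
            raise ValueError(f"column {col!r} has no observed values")

    for col in out.columns:
        if col in categorical:
            out[col] = out[col].fillna(out[col].mode().iloc[0])
        else:
            out[col] = out[col].fillna(out[col].median())

    # sweep columns in increasing missingness, as missForest does
    incomplete.sort(key=lambda c: na[c].sum())
    rng = np.random.default_rng(seed)
    prev_change = np.inf
    prev_state = out.copy()
    for _ in range(max_iter):
        change_num = 0.0
        change_den = 0.0
        for col in incomplete:
            miss = na[col]
            X_obs = out.loc[~miss].drop(columns=[col])
            X_mis = out.loc[miss].drop(columns=[col])
            y_obs = out.loc[~miss, col]
            seed_i = int(rng.integers(2**31 - 1))
            if col in categorical:
                model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed_i)
            else:
                model = RandomForestRegressor(n_estimators=n_estimators, random_state=seed_i)
            model.fit(X_obs, y_obs)
            pred = model.predict(X_mis)
            old = out.loc[miss, col].to_numpy()
            if col not in categorical:
                change_num += float(np.sum((pred - old) ** 2))
                change_den += float(np.sum(np.asarray(pred, dtype=float) ** 2))
            else:
                change_num += float(np.sum(pred != old))
                change_den += float(len(pred))
            out.loc[miss, col] = pred
        change = change_num / change_den if change_den > 0 else 0.0
        if change >= prev_change:
            return prev_state  # criterion rose: previous sweep was the best
        prev_change = change
        prev_state = out.copy()
        if change == 0.0:
            break
    return out


# ---------------------------------------------------------------------------
# encoding and Cox screens
# ---------------------------------------------------------------------------

DEFAULT_CATEGORICAL = ("gender", "ECOG", "N_stage", "histology", "TKI")


def encode_clinical(frame: pd.DataFrame, categorical=DEFAULT_CATEGORICAL) -> pd.DataFrame:
    """Dummy-encode categorical covariates, dropping one reference level each.

    M stage is kept ordinal (a single column), matching how the model treats
    metastatic burden as a graded covariate.
    """
    cats = [c for c in categorical if c in frame.columns]
    out = pd.get_dummies(frame, columns=cats, drop_first=True, dtype=float)
    return out.astype(float)


def _fit_cox(df: pd.DataFrame, duration_col: str, event_col: str, penalizer: float = 0.0) -> CoxPHFitter:
    cph = CoxPHFitter(penalizer=penalizer)
    cph.fit(df, duration_col=duration_col, event_col=event_col)
    return cph


def univariate_cox_pvalues(
    X: pd.DataFrame, outcomes: pd.DataFrame
) -> pd.Series:
    """Wald p-value of each covariate in its own proportional-hazards fit.

    Non-convergent covariates get p = NaN (flagged, excluded downstream).
    """
    pvals = {}
    base = outcomes[["time_days", "event"]]
    for col in X.columns:
        df = base.join(X[[col]]).dropna()
        if df[col].nunique() < 2:
            pvals[col] = np.nan
            continue
        try:
            cph = _fit_cox(df, "time_days", "event")
            pvals[col] = float(cph.summary.loc[col, "p"])
        except (ConvergenceError, ValueError, np.linalg.LinAlgError):
            logger.warning("univariate Cox failed for %s; excluded", col)
            pvals[col] = np.nan
    return pd.Series(pvals)


# ---------------------------------------------------------------------------
# VIF
# ---------------------------------------------------------------------------

def vif(matrix: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1-R²) per column; exact collinearity -> inf."""
    if matrix.shape[1] < 2:
        raise ValueError("VIF needs at least 2 features")
    if matrix.shape[0] <= matrix.shape[1]:
        raise ValueError("VIF needs more rows than features")
    X = matrix.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    out = {}
    for j, name in enumerate(matrix.columns):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        tss = float(y @ y)
        if tss == 0:
            out[name] = np.inf
            continue
        coef, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        r2 = 1.0 - float(resid @ resid) / tss
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_prune(matrix: pd.DataFrame, threshold: float = 5.0) -> list[str]:
    """Iteratively drop the largest-VIF column while any VIF exceeds threshold."""
    cols = list(matrix.columns)
    while len(cols) >= 2:
        v = vif(matrix[cols])
        worst = v.idxmax()
        if v[worst] <= threshold:
            break
        cols.remove(worst)
    return cols


# ---------------------------------------------------------------------------
# staged selection
# ---------------------------------------------------------------------------

def _multivariate_fit(
    X: pd.DataFrame, outcomes: pd.DataFrame, penalizer: float = 0.0
) -> CoxPHFitter:
    df = outcomes[["time_days", "event"]].join(X)
    try:
        return _fit_cox(df, "time_days", "event", penalizer)
    except (ConvergenceError, ValueError, np.linalg.LinAlgError):
        logger.warning("multivariate Cox non-convergent; refitting with ridge penalty 0.1")
        return _fit_cox(df, "time_days", "event", penalizer=0.1)


def select_clinical(
    records: pd.DataFrame,
    outcomes: pd.DataFrame,
    p_univariate: float = 0.1,
    p_multivariate: float = 0.1,
) -> SelectionResult:
    """Two-stage clinical screen: univariate p < 0.1, then multivariate p < 0.1."""
    if int(outcomes["event"].sum()) < 10:
        raise ValueError("need at least 10 events for clinical selection")
    result = SelectionResult()
    X = records.copy()
    pvals = univariate_cox_pvalues(X, outcomes)
    stage1 = pvals[pvals < p_univariate].index.tolist()
    result.log_stage("univariate", f"p<{p_univariate}", list(X.columns), stage1)
    if not stage1:
        return result
    cph = _multivariate_fit(X[stage1], outcomes)
    summ = cph.summary
    final = summ[summ["p"] < p_multivariate].index.tolist()
    result.log_stage("multivariate", f"p<{p_multivariate}", stage1, final)
    result.final_features = final
    if final:
        refit = _multivariate_fit(X[final], outcomes)
        result.coefficients = refit.params_.to_dict()
        result.summary = refit.summary
    return result


def select_radiomic(
    delta_table: pd.DataFrame,
    outcomes: pd.DataFrame,
    p_univariate: float = 0.05,
    vif_threshold: float = 5.0,
    top_k: int = 5,
    p_final: float = 0.1,
) -> SelectionResult:
    """Three-stage radiomic screen: univariate, VIF pruning, top-k coefficients.

    Features are standardized to unit variance before the multivariate fit, so
    'largest coefficient' means largest absolute per-SD log hazard ratio; ties
    at rank ``top_k`` break by feature-name lexicographic order.
    """
    if int(outcomes["event"].sum()) < 10:
        raise ValueError("need at least 10 events for radiomic selection")
    result = SelectionResult()
    X = delta_table.dropna(axis=1, how="all")
    # undefined delta cells -> column median; constant columns out
    X = X.apply(lambda c: c.fillna(c.median()))
    keep = [c for c in X.columns if X[c].notna().all() and X[c].nunique() > 1]
    X = X[keep]
    sd = X.std(ddof=0)
    X = (X - X.mean()) / sd

    pvals = univariate_cox_pvalues(X, outcomes)
    stage1 = pvals[pvals < p_univariate].index.tolist()
    result.log_stage("univariate", f"p<{p_univariate}", list(X.columns), stage1)
    if not stage1:
        return result

    if len(stage1) >= 2 and len(stage1) < len(X):
        stage2 = vif_prune(X[stage1], vif_threshold)
    else:
        stage2 = stage1
    result.log_stage("vif", f"VIF<={vif_threshold}", stage1, stage2)
    if not stage2:
        return result

    cph = _multivariate_fit(X[stage2], outcomes, penalizer=0.0 if len(stage2) < len(X) // 2 else 0.01)
    coefs = cph.params_.abs().sort_values(ascending=False)
    # deterministic tie-break: by (-|coef|, name)
    ranked = sorted(coefs.index, key=lambda n: (-coefs[n], n))
    stage3 = sorted(ranked[:top_k])
    result.log_stage("top_k", f"top {top_k} |standardized coef|", stage2, stage3)
    if len(stage2) < top_k:
        logger.info("only %d features survived to the top-%d stage; keeping all", len(stage2), top_k)

    refit = _multivariate_fit(X[stage3], outcomes)
    summ = refit.summary
    final = summ[summ["p"] < p_final].index.tolist()
    result.log_stage("final_p", f"p<{p_final}", stage3, final)
    result.final_features = final if final else stage3
    fit2 = _multivariate_fit(X[result.final_features], outcomes)
    result.coefficients = fit2.params_.to_dict()
    result.summary = fit2.summary
    return result


# ---------------------------------------------------------------------------
# selector x learner benchmark
# ---------------------------------------------------------------------------

def _surv_y(outcomes: pd.DataFrame):
    from sksurv.util import Surv

    return Surv.from_arrays(outcomes["event"].astype(bool), outcomes["time_days"])


def make_learner(name: str, seed: int = 0):
    from sksurv.ensemble import GradientBoostingSurvivalAnalysis, RandomSurvivalForest
    from sksurv.linear_model import CoxPHSurvivalAnalysis
    from sksurv.svm import FastSurvivalSVM
    from sksurv.tree import SurvivalTree

    if name == "CoxPH":
        return CoxPHSurvivalAnalysis(alpha=0.01)
    if name == "SurvivalTree":
        return SurvivalTree(max_depth=3, min_samples_leaf=10, random_state=seed)
    if name == "RandomSurvivalForest":
        return RandomSurvivalForest(
            n_estimators=50, max_depth=4, min_samples_leaf=10, random_state=seed
        )
    if name == "FastSVM":
        return FastSurvivalSVM(max_iter=50, random_state=seed)
    if name == "GradientBoosting":
        return GradientBoostingSurvivalAnalysis(
            n_estimators=50, max_depth=2, random_state=seed
        )
    raise ValueError(f"unknown learner {name!r}")


def select_features_by(
    name: str, X: pd.DataFrame, outcomes: pd.DataFrame, n_features: int = 5, seed: int = 0
) -> list[str]:
    """Restrict to ``n_features`` columns by one of the four selector criteria."""
    from sksurv.linear_model import CoxnetSurvivalAnalysis, CoxPHSurvivalAnalysis

    y = _surv_y(outcomes)
    Xs = (X - X.mean()) / X.std(ddof=0).replace(0.0, 1.0)
    if name == "Kbest":
        pv = univariate_cox_pvalues(Xs, outcomes)
        ranked = sorted(pv.index, key=lambda n: (pv[n] if np.isfinite(pv[n]) else 2.0, n))
        return sorted(ranked[:n_features])
    if name in ("Lasso", "ElasticNet"):
        l1 = 1.0 if name == "Lasso" else 0.5
        model = CoxnetSurvivalAnalysis(l1_ratio=l1, alpha_min_ratio=0.01, n_alphas=50)
        model.fit(Xs.to_numpy(), y)
        coefs = model.coef_  # (p, n_alphas), alphas decreasing
        nnz = (coefs != 0).sum(axis=0)
        cand = np.flatnonzero(nnz >= n_features)
        col = cand[0] if cand.size else coefs.shape[1] - 1
        mags = pd.Series(np.abs(coefs[:, col]), index=Xs.columns)
    elif name == "Ridge":
        model = CoxPHSurvivalAnalysis(alpha=1.0)
        model.fit(Xs.to_numpy(), y)
        mags = pd.Series(np.abs(model.coef_), index=Xs.columns)
    else:
        raise ValueError(f"unknown selector {name!r}")
    ranked = sorted(mags.index, key=lambda n: (-mags[n], n))
    return sorted(ranked[:n_features])


def benchmark_selectors(
    delta_table: pd.DataFrame,
    outcomes: pd.DataFrame,
    horizon_days: float,
    selectors=SELECTOR_NAMES,
    learners=LEARNER_NAMES,
    n_features: int = 5,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated horizon AUC for every (selector, learner) pair.

    Selection and fitting happen inside each training fold only.  Returns a
    long-format frame (selector, learner, mean_auc, sd_auc, n_folds_used).
    """
    from sklearn.model_selection import StratifiedKFold

    from .evaluation import time_dependent_auc

    X = delta_table.dropna(axis=1, how="all").apply(lambda c: c.fillna(c.median()))
    X = X[[c for c in X.columns if X[c].notna().all() and X[c].nunique() > 1]]
    ev = outcomes["event"].to_numpy()

    fold_sets = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        fold_sets.extend(skf.split(np.zeros(len(X)), ev))

    records = []
    for sel in selectors:
        # cache the per-fold selection: it does not depend on the learner
        chosen_per_fold = []
        for tr, te in fold_sets:
            chosen_per_fold.append(
                select_features_by(sel, X.iloc[tr], outcomes.iloc[tr], n_features, seed)
            )
        for lrn in learners:
            aucs = []
            skipped = 0
            for (tr, te), chosen in zip(fold_sets, chosen_per_fold):
                try:
                    Xtr, Xte = X.iloc[tr][chosen], X.iloc[te][chosen]
                    mu, sdv = Xtr.mean(), Xtr.std(ddof=0).replace(0.0, 1.0)
                    model = make_learner(lrn, seed)
                    model.fit(((Xtr - mu) / sdv).to_numpy(), _surv_y(outcomes.iloc[tr]))
                    risk = model.predict(((Xte - mu) / sdv).to_numpy())
                    aucs.append(
                        time_dependent_auc(
                            risk, outcomes.iloc[te], horizon_days, train_outcomes=outcomes.iloc[tr]
                        )
                    )
                except Exception as exc:
                    skipped += 1
                    logger.warning("fold skipped for (%s, %s): %s", sel, lrn, exc)
            if skipped > 0.2 * len(fold_sets):
                logger.warning("(%s, %s): %d/%d folds skipped", sel, lrn, skipped, len(fold_sets))
            records.append(
                {
                    "selector": sel,
                    "learner": lrn,
                    "mean_auc": float(np.mean(aucs)) if aucs else np.nan,
                    "sd_auc": float(np.std(aucs)) if aucs else np.nan,
                    "n_folds_used": len(aucs),
                }
            )
    return pd.DataFrame(records)
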