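"""Proportional-hazards risk modelling: Cox fits, holdout splits, repeated CV.

The fitted :class:`RiskModel` standardizes its inputs internally (parameters
stored at fit time and reused at prediction), predicts a linear log-hazard
risk score (higher = earlier expected progression), and reports per-covariate
hazard ratios with 95% confidence intervals.  Ties are handled with the Efron
approximation (lifelines' default).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

logger = logging.getLogger(__name__)

__all__ = ["RiskModel", "fit_coxph", "split_holdout", "cross_validate"]


@dataclass
class RiskModel:
    kind: str
    feature_names: list[str]
    coefficients: dict[str, float]
    standardization: dict[str, tuple[float, float]]
    summary: pd.DataFrame | None = None

    def predict_risk(self, X: pd.DataFrame) -> pd.Series:
        """Linear predictor (log relative hazard) per row."""
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise ValueError(f"missing model covariates: {missing}")
        risk = pd.Series(0.0, index=X.index)
        for name in self.feature_names:
            mu, sd = self.standardization[name]
            risk = risk + self.coefficients[name] * (X[name] - mu) / sd
        return risk

    def hazard_ratios(self) -> pd.DataFrame:
        """HR = exp(coef) with 95% CI, on the standardized (per-SD) scale."""
        if self.summary is None:
            raise ValueError("model carries no fit summary")
        out = pd.DataFrame(
            {
                "coef": self.summary["coef"],
                "HR": np.exp(self.summary["coef"]),
                "HR_lower95": np.exp(self.summary["coef lower 95%"]),
                "HR_upper95": np.exp(self.summary["coef upper 95%"]),
                "se": self.summary["se(coef)"],
                "p": self.summary["p"],
            }
        )
        return out

    def to_json(self, path: str) -> None:
        payload = {
            "kind": self.kind,
            "feature_names": self.feature_names,
            "coefficients": self.coefficients,
            "standardization": {k: list(v) for k, v in self.standardization.items()},
        }
        with open(path, "w") as f:
            json.dump(payload, f, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "RiskModel":
        with open(path) as f:
            payload = json.load(f)
        payload["standardization"] = {
            k: tuple(v) for k, v in payload["standardization"].items()
        }
        return cls(summary=None, **payload)


class CoxConvergenceError(RuntimeError):
    pass


def fit_coxph(X: pd.DataFrame, outcomes: pd.DataFrame, penalizer: float = 0.0) -> RiskModel:
    """Maximum-partial-likelihood Cox fit (Efron ties) with internal standardization."""
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more subjects than covariates")
    if int(outcomes["event"].sum()) < 1:
        raise ValueError("need at least one event")
    mu = X.mean()
    sd = X.std(ddof=0).replace(0.0, 1.0)
    Xs = (X - mu) / sd
    df = outcomes[["time_days", "event"]].join(Xs)
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        cph.fit(df, duration_col="time_days", event_col="event")
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        raise CoxConvergenceError(f"Cox fit failed to converge: {exc}") from exc
    return RiskModel(
        kind="CoxPH",
        feature_names=list(X.columns),
        coefficients=cph.params_.to_dict(),
        standardization={c: (float(mu[c]), float(sd[c])) for c in X.columns},
        summary=cph.summary,
    )


def split_holdout(
    index: pd.Index | list, events: pd.Series, fraction: float = 0.7, seed: int = 0
) -> tuple[list, list]:
    """Event-stratified train/test split (default 70/30), seed-reproducible."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    index = list(index)
    ev = np.asarray(events, dtype=int)
    rng = np.random.default_rng(seed)
    if ev.sum() < 2 or (len(ev) - ev.sum()) < 2:
        logger.warning("too few events to stratify; falling back to a plain random split")
        perm = rng.permutation(len(index))
        n_train = int(round(fraction * len(index)))
        train = [index[i] for i in perm[:n_train]]
        test = [index[i] for i in perm[n_train:]]
        return train, test
    train, test = [], []
    for value in (0, 1):
        ids = [i for i, e in zip(index, ev) if e == value]
        perm = rng.permutation(len(ids))
        n_train = int(round(fraction * len(ids)))
        train.extend(ids[i] for i in perm[:n_train])
        test.extend(ids[i] for i in perm[n_train:])
    return train, test


def cross_validate(
    X: pd.DataFrame,
    outcomes: pd.DataFrame,
    learner_factory,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
    horizon_days: float | None = None,
) -> pd.DataFrame:
    """k-fold CV repeated ``repeats`` times; fitting happens inside folds only.

    ``learner_factory(X_train, outcomes_train)`` must return an object with
    ``predict_risk(X_test)``.  Returns one record per fold with the C-index
    and, when a horizon is given, the IPCW AUC at that horizon.
    """
    from sklearn.model_selection import StratifiedKFold

    from .evaluation import concordance_index, time_dependent_auc

    ev = outcomes["event"].to_numpy()

    def folds_for(rep_seed):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
        return list(skf.split(np.zeros(len(X)), ev))

    records = []
    for rep in range(repeats):
        folds = folds_for(seed + rep)
        if any(ev[te].sum() == 0 or ev[tr].sum() == 0 for tr, te in folds):
            # one reshuffle before giving up
            folds = folds_for(seed + rep + 10_000)
        for fold, (tr, te) in enumerate(folds):
            out_tr, out_te = outcomes.iloc[tr], outcomes.iloc[te]
            if out_te["event"].sum() == 0 or out_tr["event"].sum() == 0:
                raise RuntimeError("fold without events; reduce k or enlarge the cohort")
            model = learner_factory(X.iloc[tr], out_tr)
            risk = np.asarray(model.predict_risk(X.iloc[te]))
            rec = {
                "repeat": rep,
                "fold": fold,
                "c_index": concordance_index(risk, out_te),
            }
            if horizon_days is not None:
                rec["auc"] = time_dependent_auc(
                    risk, out_te, horizon_days, train_outcomes=out_tr
                )
            records.append(rec)
    return pd.DataFrame(records)
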