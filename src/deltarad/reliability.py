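"""Test-retest reliability filtering (ICC) and the delta-radiomics transforms.

ICC uses the two-way random-effects, absolute-agreement, single-measure form
ICC(2,1): with n subjects and k raters,

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

where MSR, MSC, MSE are the rows (subjects), columns (raters) and residual
mean squares of the two-way ANOVA.

The delta transforms turn a per-subject pair of feature values (pretreat p,
follow-up f, inter-scan interval dt in days) into:

    delta           (f - p) / p
    delta_time      (1/dt) * (f - p) / p
    delta_log_time  (1/dt) * (log f - log p)

plus the pass-throughs ``pretreat_only`` and ``follow_only``.  Cells whose
transform is undefined (p = 0, or non-positive inputs to the log form) become
missing values; the count is reported, the run does not abort.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import RoiMask

logger = logging.getLogger(__name__)

__all__ = [
    "DELTA_METHODS",
    "icc_2_1",
    "icc_filter",
    "delta_features",
    "jitter_mask",
]

DELTA_METHODS = ("pretreat_only", "follow_only", "delta", "delta_time", "delta_log_time")


def icc_2_1(ratings: np.ndarray) -> float:
    """ICC(2,1) for an (n subjects x k raters) matrix of one feature."""
    ratings = np.asarray(ratings, dtype=np.float64)
    n, k = ratings.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((ratings - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        return np.nan
    return float((msr - mse) / denom)


def icc_filter(
    features_rater1: pd.DataFrame,
    features_rater2: pd.DataFrame,
    threshold: float = 0.80,
) -> list[str]:
    """Feature names whose test-retest ICC(2,1) exceeds ``threshold``.

    Zero-variance features have undefined ICC and are dropped with a warning.
    """
    if not features_rater1.index.equals(features_rater2.index):
        raise ValueError("retest tables must cover the same subjects")
    common = [c for c in features_rater1.columns if c in features_rater2.columns]
    if len(common) != features_rater1.shape[1] or len(common) != features_rater2.shape[1]:
        raise ValueError("retest tables must share feature names")
    kept = []
    dropped_undefined = 0
    for name in common:
        mat = np.column_stack([features_rater1[name].to_numpy(), features_rater2[name].to_numpy()])
        if np.ptp(mat) == 0 or not np.all(np.isfinite(mat)):
            dropped_undefined += 1
            continue
        if icc_2_1(mat) > threshold:
            kept.append(name)
    if dropped_undefined:
        warnings.warn(
            f"{dropped_undefined} features had undefined ICC (zero variance or non-finite) and were dropped"
        )
    return kept


def jitter_mask(mask: RoiMask, seed: int, p_flip: float = 0.3) -> RoiMask:
    """Morphological jitter emulating a second reader's segmentation.

    Boundary voxels are randomly dilated/eroded; the ROI interior is untouched,
    so the perturbed mask stays a plausible re-segmentation of the same lesion.
    """
    rng = np.random.default_rng(seed)
    m = mask.voxels
    dilated = ndimage.binary_dilation(m)
    eroded = ndimage.binary_erosion(m)
    outer_rim = dilated & ~m
    inner_rim = m & ~eroded
    out = m.copy()
    out[outer_rim] = rng.random(int(outer_rim.sum())) < p_flip
    out[inner_rim & (rng.random(m.shape) < p_flip)] = False
    if not out.any():
        out = m.copy()
    return RoiMask(out, mask.spacing_mm)


def delta_features(
    table: pd.DataFrame,
    method: str,
    interval_days: pd.Series | None = None,
) -> pd.DataFrame:
    """Collapse a (subject, timepoint)-indexed feature table to one row per subject.

    ``table`` must carry a 2-level index (subject_id, timepoint) with timepoints
    'pretreat' and 'follow' both present for every subject.  ``interval_days``
    (per subject) is required for the time-adjusted methods.
    """
    if method not in DELTA_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {DELTA_METHODS}")
    pre = table.xs("pretreat", level="timepoint")
    fol = table.xs("follow", level="timepoint")
    if not pre.index.equals(fol.index):
        missing = set(pre.index).symmetric_difference(fol.index)
        raise ValueError(f"subjects missing a timepoint: {sorted(missing)[:5]}")

    if method == "pretreat_only":
        return pre.copy()
    if method == "follow_only":
        return fol.copy()

    with np.errstate(divide="ignore", invalid="ignore"):
        if method in ("delta", "delta_time"):
            out = (fol - pre) / pre
            out = out.where(pre != 0)
        else:  # delta_log_time
            valid = (pre > 0) & (fol > 0)
            out = (np.log(fol.where(valid)) - np.log(pre.where(valid)))
    out = out.replace([np.inf, -np.inf], np.nan)

    if method in ("delta_time", "delta_log_time"):
        if interval_days is None:
            raise ValueError(f"method {method!r} requires interval_days")
        dt = interval_days.reindex(out.index)
        if (dt <= 0).any() or dt.isna().any():
            raise ValueError("interval_days must be positive for every subject")
        out = out.div(dt, axis=0)

    n_missing = int(out.isna().sum().sum())
    if n_missing:
        logger.info("delta method %s produced %d undefined cells", method, n_missing)
    return out
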