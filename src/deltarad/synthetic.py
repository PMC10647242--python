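"""Synthetic paired-CT cohort generator with a planted survival signal.

Each subject gets an ellipsoidal primary tumor filled with a smoothed Gaussian
texture field on a noisy background, imaged at two timepoints 6-16 weeks
apart.  The follow-up scan reuses the same per-subject field with its contrast
multiplied by ``exp(shift)``, where the per-subject shift is the planted
texture-change signal: it enters the latent log-hazard with coefficient
``texture_effect_size``, so delta features that track ROI contrast carry real
prognostic information while single-timepoint features carry much less.

Clinical covariates mirror the schema of an advanced-NSCLC EGFR-TKI cohort
(N/M staging, ECOG, gender, smoking, age, laboratory platelet/AST/total
protein); categorical marginals follow the demographic reference table shipped
with the package, laboratory values are log-normal around their published
medians/IQRs.  Survival is Weibull proportional hazards (default shape 1 =
exponential) with the baseline scale set so median time at zero risk is 383
days; censoring is uniform on [0, c] with c calibrated by bisection to the
requested censoring fraction; laboratory values are masked missing completely
at random.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import ImageVolume, RoiMask

__all__ = [
    "CohortConfig",
    "SyntheticSubject",
    "generate_cohort",
    "planted_signal_report",
    "cohort_clinical_frame",
    "cohort_outcomes",
    "write_cohort",
]

LAB_COLUMNS = ("platelet", "AST", "total_protein")
MEDIAN_PFS_DAYS = 383.0

# Categorical marginals for the generator (training-group proportions of the
# demographic reference table); laboratory distributions from published
# median/IQR summaries.
N_STAGE_P = (45 / 157, 13 / 157, 40 / 157, 59 / 157)
M_STAGE_P = (6 / 158, 47 / 158, 24 / 158, 81 / 158)
ECOG_P = (49 / 158, 91 / 158, 11 / 158, 7 / 158)
P_FEMALE = 99 / 158
P_SMOKER = 35 / 158


class ConfigurationError(ValueError):
    pass


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_subjects: int = 226
    image_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_radius_range_mm: tuple[float, float] = (5.0, 9.0)
    texture_effect_size: float = 1.0
    clinical_effect_sizes: dict[str, float] = field(
        default_factory=lambda: {
            "N_stage": 0.30,
            "M_stage": 0.28,
            "platelet": 0.31,
            "AST": 0.27,
            "total_protein": -0.17,
        }
    )
    censor_rate_target: float = 0.3
    interval_weeks_range: tuple[float, float] = (6.0, 16.0)
    missing_rate: float = 0.3
    weibull_shape: float = 1.0
    background_noise_sd: float = 0.2
    tumor_mean_shift: float = 2.0
    texture_shift_sd: float = 0.4
    baseline_contrast_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if any(n <= 0 for n in self.image_shape):
            raise ConfigurationError(f"non-positive image shape {self.image_shape}")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ConfigurationError(f"non-positive spacing {self.voxel_spacing_mm}")
        lo, hi = self.interval_weeks_range
        if not (6.0 <= lo <= hi <= 16.0):
            raise ConfigurationError("interval range must lie inside [6, 16] weeks")
        if not 0.0 <= self.censor_rate_target < 1.0:
            raise ConfigurationError("censor_rate_target must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")


@dataclass
class SurvivalOutcome:
    """Right-censored progression-free-survival endpoint."""

    time: float  # days
    event: int  # 1 = progression/death observed

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be positive")
        self.event = int(self.event)


@dataclass
class SyntheticSubject:
    subject_id: str
    pre_volume: ImageVolume
    post_volume: ImageVolume
    pre_mask: RoiMask
    post_mask: RoiMask
    scan_interval_days: float
    clinical: dict[str, object]
    outcome: SurvivalOutcome
    true_risk: float
    texture_shift: float
    censor_time: float = float("inf")


def _ellipsoid_mask(shape, spacing, radii_mm, rng) -> np.ndarray:
    center = [(n - 1) / 2 + rng.uniform(-1, 1) for n in shape]
    grids = np.indices(shape).astype(np.float64)
    q = np.zeros(shape)
    for g, c, s, r in zip(grids, center, spacing, radii_mm):
        q += ((g - c) * s / r) ** 2
    return q <= 1.0


def _texture_field(shape, width, rng) -> np.ndarray:
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=width)
    sd = field.std()
    return field / sd if sd > 0 else field


def _draw_clinical(rng) -> dict[str, object]:
    return {
        "age": float(rng.normal(62.0, 11.0)),
        "gender": "female" if rng.random() < P_FEMALE else "male",
        "smoking": int(rng.random() < P_SMOKER),
        "ECOG": int(rng.choice(4, p=ECOG_P)),
        "N_stage": int(rng.choice(4, p=N_STAGE_P)),
        "M_stage": int(rng.choice(4, p=M_STAGE_P)),
        "platelet": float(np.exp(rng.normal(np.log(269_000.0), 0.21))),
        "AST": float(np.exp(rng.normal(np.log(23.0), 0.30))),
        "total_protein": float(rng.normal(7.1, 0.45)),
    }


# theoretical (population) standardisation of the effect covariates, so planted
# effect sizes are per-SD log hazard ratios
_STANDARDIZERS = {
    "N_stage": (
        float(np.dot(range(4), N_STAGE_P)),
        float(np.sqrt(np.dot(np.arange(4) ** 2, N_STAGE_P) - np.dot(range(4), N_STAGE_P) ** 2)),
    ),
    "M_stage": (
        float(np.dot(range(4), M_STAGE_P)),
        float(np.sqrt(np.dot(np.arange(4) ** 2, M_STAGE_P) - np.dot(range(4), M_STAGE_P) ** 2)),
    ),
    "platelet": (np.log(269_000.0), 0.21),
    "AST": (np.log(23.0), 0.30),
    "total_protein": (7.1, 0.45),
}


def standardized_covariate(name: str, value: float) -> float:
    mu, sd = _STANDARDIZERS[name]
    if name in ("platelet", "AST"):
        value = math.log(value)
    return (value - mu) / sd


def _calibrate_censor_bound(times: np.ndarray, target: float) -> float:
    """Bisect the uniform-censoring upper bound c so E[frac censored] ~ target.

    With C ~ U(0, c), P(censor subject i) = P(C < T_i) = min(T_i, c)/c,
    which decreases in c.
    """

    def frac(c):
        return float(np.mean(np.minimum(times, c) / c))

    lo, hi = float(times.min()) * 1e-3, float(times.max()) * 100
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(config: CohortConfig) -> list[SyntheticSubject]:
    """Deterministically generate a paired-scan cohort from a config + seed."""
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.image_shape)
    spacing = tuple(config.voxel_spacing_mm)
    n = config.n_subjects

    subjects_raw = []
    etas = np.empty(n)
    for idx in range(n):
        radii = rng.uniform(*config.tumor_radius_range_mm, size=3)
        mask = _ellipsoid_mask(shape, spacing, radii, rng)
        width = rng.uniform(0.8, 2.0)
        tex = _texture_field(shape, width, rng)
        shift = rng.normal(0.0, config.texture_shift_sd)
        # per-subject baseline contrast: single-timepoint features see
        # c_pre (noise), delta features see exp(shift) (the planted signal)
        c_pre = math.exp(rng.normal(0.0, config.baseline_contrast_sd))

        noise_pre = rng.normal(0.0, config.background_noise_sd, size=shape)
        noise_post = rng.normal(0.0, config.background_noise_sd, size=shape)
        pre = noise_pre + mask * (config.tumor_mean_shift + tex * c_pre)
        post = noise_post + mask * (config.tumor_mean_shift + tex * c_pre * math.exp(shift))

        clinical = _draw_clinical(rng)
        eta = config.texture_effect_size * (shift / config.texture_shift_sd)
        for name, beta in config.clinical_effect_sizes.items():
            eta += beta * standardized_covariate(name, clinical[name])
        etas[idx] = eta
        interval = rng.uniform(*config.interval_weeks_range) * 7.0
        subjects_raw.append((mask, pre, post, clinical, shift, interval))

    # Weibull PH: S(t) = exp(-(t/lam)^k * e^eta); baseline median = 383 days
    k = config.weibull_shape
    lam = MEDIAN_PFS_DAYS / math.log(2.0) ** (1.0 / k)
    u = rng.uniform(size=n)
    times = lam * (-np.log(u) * np.exp(-etas)) ** (1.0 / k)
    times = np.maximum(times, 0.5)

    if config.censor_rate_target > 0:
        c_max = _calibrate_censor_bound(times, config.censor_rate_target)
        censor = rng.uniform(0.0, c_max, size=n)
    else:
        censor = np.full(n, np.inf)
    observed = np.minimum(times, censor)
    events = (times <= censor).astype(int)
    observed = np.maximum(observed, 0.5)

    cohort = []
    for idx, (mask, pre, post, clinical, shift, interval) in enumerate(subjects_raw):
        roi = RoiMask(mask, spacing)
        cohort.append(
            SyntheticSubject(
                subject_id=f"S{idx:04d}",
                pre_volume=ImageVolume(pre, spacing),
                post_volume=ImageVolume(post, spacing),
                pre_mask=roi,
                post_mask=RoiMask(mask.copy(), spacing),
                scan_interval_days=float(interval),
                clinical=clinical,
                outcome=SurvivalOutcome(float(observed[idx]), int(events[idx])),
                true_risk=float(etas[idx]),
                texture_shift=float(shift),
                censor_time=float(censor[idx]),
            )
        )
    return cohort


def planted_signal_report(cohort: list[SyntheticSubject], config: CohortConfig) -> dict:
    """Ground-truth coefficients and per-subject latent risks, for recovery tests."""
    return {
        "texture_effect_size": config.texture_effect_size,
        "clinical_effect_sizes": dict(config.clinical_effect_sizes),
        "true_risk": {s.subject_id: s.true_risk for s in cohort},
        "texture_shift": {s.subject_id: s.texture_shift for s in cohort},
        "standardized_texture_shift": {
            s.subject_id: s.texture_shift / config.texture_shift_sd for s in cohort
        },
    }


def cohort_clinical_frame(cohort: list[SyntheticSubject]) -> pd.DataFrame:
    """Clinical covariates + outcome, one row per subject."""
    rows = []
    for s in cohort:
        row = {"subject_id": s.subject_id, **s.clinical}
        row["time_days"] = s.outcome.time
        row["event"] = s.outcome.event
        row["scan_interval_days"] = s.scan_interval_days
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def cohort_outcomes(cohort: list[SyntheticSubject]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_days": [s.outcome.time for s in cohort],
            "event": [s.outcome.event for s in cohort],
        },
        index=pd.Index([s.subject_id for s in cohort], name="subject_id"),
    )


def apply_missingness(
    frame: pd.DataFrame, missing_rate: float, seed: int, columns=LAB_COLUMNS
) -> pd.DataFrame:
    """Mask laboratory columns missing completely at random."""
    rng = np.random.default_rng(seed)
    out = frame.copy()
    for col in columns:
        if col in out.columns:
            mask = rng.random(len(out)) < missing_rate
            out.loc[mask, col] = np.nan
    return out


def write_cohort(cohort: list[SyntheticSubject], config: CohortConfig, out_dir: str) -> None:
    """Persist NIfTI volume/mask pairs, the clinical CSV, and a ground-truth JSON."""
    os.makedirs(out_dir, exist_ok=True)
    base_date = pd.Timestamp("2018-06-01")
    rows = []
    for i, s in enumerate(cohort):
        s.pre_volume.to_nifti(os.path.join(out_dir, f"{s.subject_id}_pre.nii.gz"))
        s.post_volume.to_nifti(os.path.join(out_dir, f"{s.subject_id}_post.nii.gz"))
        s.pre_mask.to_nifti(os.path.join(out_dir, f"{s.subject_id}_pre_mask.nii.gz"))
        s.post_mask.to_nifti(os.path.join(out_dir, f"{s.subject_id}_post_mask.nii.gz"))
        pre_date = base_date + pd.Timedelta(days=i)
        row = {
            "subject_id": s.subject_id,
            "time_days": s.outcome.time,
            "event": s.outcome.event,
            "scan_date_pre": pre_date.date().isoformat(),
            "scan_date_follow": (pre_date + pd.Timedelta(days=round(s.scan_interval_days))).date().isoformat(),
            **s.clinical,
        }
        rows.append(row)
    clinical = pd.DataFrame(rows)
    lab = apply_missingness(clinical, config.missing_rate, config.seed + 1)
    lab.to_csv(os.path.join(out_dir, "clinical.csv"), index=False)
    truth = planted_signal_report(cohort, config)
    with open(os.path.join(out_dir, "ground_truth.json"), "w") as f:
        json.dump(truth, f, indent=1)
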