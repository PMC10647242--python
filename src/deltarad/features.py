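"""Radiomic feature catalog: first-order histogram, 3D GLCM and GLRLM texture,
slice-wise LBP, and mask geometry.

Per image band the catalog holds 14 first-order + 22 GLCM + 16 GLRLM + 13 LBP
= 65 features; over the original image and its 8 wavelet sub-bands that is
585, plus 8 shape features computed once from the mask geometry: 593 named
features per ROI.  Texture matrices use 13 unique 3D directions at voxel
distance 1 (26-connectivity modulo sign) and are aggregated by averaging the
per-direction feature values, which makes them invariant to axis-aligned 90
degree rotations.  Feature definitions follow the IBSI reference formulations.

Feature names are ``<band>_<feature>`` (e.g. ``LHL_Run_Length_Nonuniformity``)
and ``Shape_<feature>`` for geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure
from skimage.feature import local_binary_pattern

from .images import DegenerateRoiError, ImageVolume, RoiMask
from .preprocessing import ALL_BAND_LABELS, WaveletBank

__all__ = [
    "DIRECTIONS_3D",
    "FIRST_ORDER_NAMES",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "LBP_NAMES",
    "SHAPE_NAMES",
    "catalog_feature_names",
    "DiscretizedRoi",
    "discretize",
    "first_order_features",
    "glcm_features",
    "glrlm_features",
    "lbp_features",
    "shape_features",
    "extract_all",
]

N_LEVELS_DEFAULT = 32

# 13 unique voxel offsets: 26-neighbourhood modulo sign (first nonzero positive).
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(DIRECTIONS_3D) == 13

FIRST_ORDER_NAMES = (
    "Mean", "Variance", "Skewness", "Kurtosis", "Median", "Minimum", "Maximum",
    "Range", "Energy", "Entropy", "Uniformity", "P10", "P90", "IQR",
)
GLCM_NAMES = (
    "Autocorrelation", "Joint_Average", "Cluster_Prominence", "Cluster_Shade",
    "Cluster_Tendency", "Contrast", "Correlation", "Difference_Average",
    "Difference_Entropy", "Difference_Variance", "Joint_Energy", "Joint_Entropy",
    "Joint_Variance", "Homogeneity", "Inverse_Difference_Moment", "IMC1", "IMC2",
    "Inverse_Variance", "Maximum_Probability", "Sum_Average", "Sum_Entropy",
    "Sum_Variance",
)
GLRLM_NAMES = (
    "Short_Run_Emphasis", "Long_Run_Emphasis", "Gray_Level_Nonuniformity",
    "Gray_Level_Nonuniformity_Normalized", "Run_Length_Nonuniformity",
    "Run_Length_Nonuniformity_Normalized", "Run_Percentage",
    "Low_Gray_Level_Run_Emphasis", "High_Gray_Level_Run_Emphasis",
    "Short_Run_Low_Gray_Level_Emphasis", "Short_Run_High_Gray_Level_Emphasis",
    "Long_Run_Low_Gray_Level_Emphasis", "Long_Run_High_Gray_Level_Emphasis",
    "Gray_Level_Variance", "Run_Length_Variance", "Run_Entropy",
)
LBP_NAMES = tuple(f"LBP_Bin_{k}" for k in range(10)) + (
    "LBP_Mean", "LBP_Variance", "LBP_Entropy",
)
SHAPE_NAMES = (
    "Shape_Volume", "Shape_Surface_Area", "Shape_Surface_To_Volume",
    "Shape_Sphericity", "Shape_Compactness", "Shape_Max_Diameter",
    "Shape_Elongation", "Shape_Flatness",
)

BAND_FEATURE_NAMES = FIRST_ORDER_NAMES + GLCM_NAMES + GLRLM_NAMES + LBP_NAMES


def catalog_feature_names() -> list[str]:
    """The full 593-entry feature-name catalog, in extraction order."""
    names = [
        f"{band}_{feat}" for band in ALL_BAND_LABELS for feat in BAND_FEATURE_NAMES
    ]
    names.extend(SHAPE_NAMES)
    return names


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

@dataclass
class DiscretizedRoi:
    """ROI intensities quantised into integer gray levels 1..n_levels.

    ``gray_levels`` is a full-size 3D grid, 0 outside the ROI.  A constant ROI
    collapses to a single level and is flagged, not rejected.
    """

    gray_levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    bin_edges: np.ndarray
    single_level: bool = False


def discretize(volume: ImageVolume, mask: RoiMask, n_levels: int = N_LEVELS_DEFAULT) -> DiscretizedRoi:
    """Equal-width binning of ROI intensities into ``n_levels`` levels."""
    mask.require_aligned(volume)
    mask.require_nonempty()
    m = mask.voxels
    vals = volume.intensities[m]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(volume.shape, dtype=np.int32)
    if hi == lo:
        levels[m] = 1
        edges = np.array([lo, lo])
        return DiscretizedRoi(levels, m, n_levels, edges, single_level=True)
    edges = np.linspace(lo, hi, n_levels + 1)
    idx = np.minimum(((vals - lo) / (hi - lo) * n_levels).astype(np.int32), n_levels - 1)
    levels[m] = idx + 1
    return DiscretizedRoi(levels, m, n_levels, edges)


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

def first_order_features(
    volume: ImageVolume, mask: RoiMask, d: DiscretizedRoi | None = None
) -> dict[str, float]:
    """14 histogram statistics of ROI intensities.

    Entropy and Uniformity are computed on the discretized histogram (the same
    binning the texture matrices use); the rest on the raw intensities.
    Population (n) moment conventions; Kurtosis is the non-excess form.
    """
    mask.require_aligned(volume)
    mask.require_nonempty()
    vals = volume.intensities[mask.voxels]
    n = vals.size
    mean = float(vals.mean())
    var = float(vals.var())
    if var > 0:
        z = (vals - mean) / np.sqrt(var)
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))
    else:
        skew, kurt = 0.0, 0.0
    if d is None:
        d = discretize(volume, mask)
    counts = np.bincount(d.gray_levels[d.mask], minlength=d.n_levels + 1)[1:]
    p = counts / counts.sum()
    nz = p[p > 0]
    q = np.percentile(vals, [10, 25, 50, 75, 90])
    return {
        "Mean": mean,
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Median": float(q[2]),
        "Minimum": float(vals.min()),
        "Maximum": float(vals.max()),
        "Range": float(vals.max() - vals.min()),
        "Energy": float(np.sum(vals**2)),
        "Entropy": float(-np.sum(nz * np.log2(nz))),
        "Uniformity": float(np.sum(p**2)),
        "P10": float(q[0]),
        "P90": float(q[4]),
        "IQR": float(q[3] - q[1]),
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def _paired_slices(offset: tuple[int, int, int], shape: tuple[int, int, int]):
    src, dst = [], []
    for d, n in zip(offset, shape):
        if d == 0:
            src.append(slice(0, n))
            dst.append(slice(0, n))
        elif d > 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    return tuple(src), tuple(dst)


def glcm_matrices(d: DiscretizedRoi) -> list[np.ndarray]:
    """Symmetrised, normalised co-occurrence matrix per direction (distance 1).

    Directions with no valid in-ROI pair are omitted.
    """
    n = d.n_levels
    lv = d.gray_levels
    m = d.mask
    out = []
    for off in DIRECTIONS_3D:
        s, t = _paired_slices(off, lv.shape)
        valid = m[s] & m[t]
        if not valid.any():
            continue
        i = lv[s][valid] - 1
        j = lv[t][valid] - 1
        mat = np.bincount(i * n + j, minlength=n * n).reshape(n, n).astype(np.float64)
        mat = mat + mat.T
        out.append(mat / mat.sum())
    return out


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    n = p.shape[0]
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py by symmetry
    mu = float(np.sum(i * px))
    sigma2 = float(np.sum((i - mu) ** 2 * px))

    diff = np.abs(ii - jj)
    p_diff = np.bincount(diff.ravel(), weights=p.ravel(), minlength=n)
    k_diff = np.arange(n)
    da = float(np.sum(k_diff * p_diff))
    p_sum = np.bincount((ii + jj).ravel(), weights=p.ravel(), minlength=2 * n + 1)[2:]
    k_sum = np.arange(2, 2 * n + 1)
    sa = float(np.sum(k_sum * p_sum))

    def ent(q):
        q = q[q > 0]
        return float(-np.sum(q * np.log2(q)))

    hxy = ent(p.ravel())
    hx = ent(px)
    pxy_outer = np.outer(px, px)
    both = (p > 0) | (pxy_outer > 0)
    with np.errstate(divide="ignore"):
        log_outer = np.where(pxy_outer > 0, np.log2(np.where(pxy_outer > 0, pxy_outer, 1.0)), 0.0)
    hxy1 = float(-np.sum(p[both] * log_outer[both]))
    hxy2 = float(-np.sum(pxy_outer[both] * log_outer[both]))
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * max(hxy2 - hxy, 0.0))
    imc2 = float(np.sqrt(max(arg, 0.0)))

    autoc = float(np.sum(ii * jj * p))
    corr = (autoc - mu * mu) / sigma2 if sigma2 > 0 else 1.0

    off = diff > 0
    inv_var = float(np.sum(p[off] / (ii - jj)[off] ** 2)) if off.any() else 0.0

    return {
        "Autocorrelation": autoc,
        "Joint_Average": mu,
        "Cluster_Prominence": float(np.sum((ii + jj - 2 * mu) ** 4 * p)),
        "Cluster_Shade": float(np.sum((ii + jj - 2 * mu) ** 3 * p)),
        "Cluster_Tendency": float(np.sum((ii + jj - 2 * mu) ** 2 * p)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": corr,
        "Difference_Average": da,
        "Difference_Entropy": ent(p_diff),
        "Difference_Variance": float(np.sum((k_diff - da) ** 2 * p_diff)),
        "Joint_Energy": float(np.sum(p**2)),
        "Joint_Entropy": hxy,
        "Joint_Variance": float(np.sum((ii - mu) ** 2 * p)),
        "Homogeneity": float(np.sum(p / (1.0 + diff))),
        "Inverse_Difference_Moment": float(np.sum(p / (1.0 + diff**2))),
        "IMC1": imc1,
        "IMC2": imc2,
        "Inverse_Variance": inv_var,
        "Maximum_Probability": float(p.max()),
        "Sum_Average": sa,
        "Sum_Entropy": ent(p_sum),
        "Sum_Variance": float(np.sum((k_sum - sa) ** 2 * p_sum)),
    }


def glcm_features(d: DiscretizedRoi) -> dict[str, float]:
    """22 co-occurrence features, averaged over the 13 directions."""
    if d.mask.sum() < 2:
        raise DegenerateRoiError("GLCM needs at least 2 ROI voxels")
    mats = glcm_matrices(d)
    if not mats:
        raise DegenerateRoiError("no in-ROI voxel pairs at distance 1")
    accum = {k: 0.0 for k in GLCM_NAMES}
    for mat in mats:
        for k, v in _glcm_features_single(mat).items():
            accum[k] += v
    return {k: v / len(mats) for k, v in accum.items()}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def glrlm_matrix(d: DiscretizedRoi, offset: tuple[int, int, int]) -> np.ndarray:
    """Run-length matrix R[level-1, length-1] along one direction.

    A run is a maximal sequence of in-ROI voxels of equal gray level along the
    direction; voxels outside the ROI break runs.
    """
    coords = np.argwhere(d.mask)
    levels = d.gray_levels[d.mask]
    off = np.asarray(offset)
    # Parameterise each line by t (steps along the offset) and a line id
    # (the coordinate projected back to t=0); sorting by (line id, t) puts
    # voxels of one line consecutively in traversal order.
    axis = int(np.nonzero(off)[0][0])
    t = coords[:, axis] * np.sign(off[axis])
    line_id = coords - np.outer(t, off)
    order = np.lexsort((t, line_id[:, 2], line_id[:, 1], line_id[:, 0]))
    t_s = t[order]
    lid_s = line_id[order]
    lev_s = levels[order]

    same_line = np.all(lid_s[1:] == lid_s[:-1], axis=1)
    contiguous = t_s[1:] == t_s[:-1] + 1
    same_level = lev_s[1:] == lev_s[:-1]
    joined = same_line & contiguous & same_level
    # run starts where the chain with the previous voxel is broken
    starts = np.flatnonzero(np.concatenate(([True], ~joined)))
    run_len = np.diff(np.concatenate((starts, [len(lev_s)])))
    run_lev = lev_s[starts]

    max_len = int(run_len.max()) if run_len.size else 1
    mat = np.zeros((d.n_levels, max_len), dtype=np.float64)
    np.add.at(mat, (run_lev - 1, run_len - 1), 1.0)
    return mat


def _glrlm_features_single(r: np.ndarray, n_voxels: int) -> dict[str, float]:
    n_runs = r.sum()
    gi = np.arange(1, r.shape[0] + 1, dtype=np.float64)
    lj = np.arange(1, r.shape[1] + 1, dtype=np.float64)
    rg = r.sum(axis=1)  # per gray level
    rl = r.sum(axis=0)  # per run length
    p = r / n_runs
    pg = rg / n_runs
    pl = rl / n_runs
    mu_g = float(np.sum(gi * pg))
    mu_l = float(np.sum(lj * pl))
    nz = p[p > 0]
    return {
        "Short_Run_Emphasis": float(np.sum(rl / lj**2) / n_runs),
        "Long_Run_Emphasis": float(np.sum(rl * lj**2) / n_runs),
        "Gray_Level_Nonuniformity": float(np.sum(rg**2) / n_runs),
        "Gray_Level_Nonuniformity_Normalized": float(np.sum(rg**2) / n_runs**2),
        "Run_Length_Nonuniformity": float(np.sum(rl**2) / n_runs),
        "Run_Length_Nonuniformity_Normalized": float(np.sum(rl**2) / n_runs**2),
        "Run_Percentage": float(n_runs / n_voxels),
        "Low_Gray_Level_Run_Emphasis": float(np.sum(rg / gi**2) / n_runs),
        "High_Gray_Level_Run_Emphasis": float(np.sum(rg * gi**2) / n_runs),
        "Short_Run_Low_Gray_Level_Emphasis": float(np.sum(r / np.outer(gi**2, lj**2)) / n_runs),
        "Short_Run_High_Gray_Level_Emphasis": float(np.sum(r * np.outer(gi**2, 1.0 / lj**2)) / n_runs),
        "Long_Run_Low_Gray_Level_Emphasis": float(np.sum(r * np.outer(1.0 / gi**2, lj**2)) / n_runs),
        "Long_Run_High_Gray_Level_Emphasis": float(np.sum(r * np.outer(gi**2, lj**2)) / n_runs),
        "Gray_Level_Variance": float(np.sum((gi - mu_g) ** 2 * pg)),
        "Run_Length_Variance": float(np.sum((lj - mu_l) ** 2 * pl)),
        "Run_Entropy": float(-np.sum(nz * np.log2(nz))),
    }


def glrlm_features(d: DiscretizedRoi) -> dict[str, float]:
    """16 run-length features, averaged over the 13 directions."""
    if not d.mask.any():
        raise DegenerateRoiError("GLRLM needs a nonempty ROI")
    n_voxels = int(d.mask.sum())
    accum = {k: 0.0 for k in GLRLM_NAMES}
    for off in DIRECTIONS_3D:
        mat = glrlm_matrix(d, off)
        for k, v in _glrlm_features_single(mat, n_voxels).items():
            accum[k] += v
    nd = len(DIRECTIONS_3D)
    return {k: v / nd for k, v in accum.items()}


# ---------------------------------------------------------------------------
# LBP
# ---------------------------------------------------------------------------

def quantize_slice(plane: np.ndarray) -> np.ndarray:
    """Quantise one 2D slice to integer gray levels 0..255 (equal width)."""
    lo, hi = float(plane.min()), float(plane.max())
    if hi == lo:
        return np.zeros_like(plane, dtype=np.int64)
    return np.minimum(((plane - lo) / (hi - lo) * 256).astype(np.int64), 255)


def lbp_features(volume: ImageVolume, mask: RoiMask) -> dict[str, float]:
    """Rotation-invariant uniform LBP (P=8, R=1) per axial slice.

    Axial slices are planes of constant z (last axis).  Each slice is first
    quantised to 256 equal-width gray levels (the 8-bit setting LBP was
    designed for; it also makes the diagonal bilinear samples exact on
    constant regions).  Codes of in-ROI pixels are pooled over all slices
    into one 10-bin histogram (codes 0..8 uniform, 9 = non-uniform),
    summarised by its mean, variance and entropy.
    """
    mask.require_aligned(volume)
    mask.require_nonempty()
    counts = np.zeros(10, dtype=np.float64)
    for k in range(volume.shape[2]):
        sl_mask = mask.voxels[:, :, k]
        if not sl_mask.any():
            continue
        codes = local_binary_pattern(quantize_slice(volume.intensities[:, :, k]), P=8, R=1, method="uniform")
        roi_codes = codes[sl_mask].astype(np.int64)
        counts += np.bincount(roi_codes, minlength=10)[:10]
    if counts.sum() == 0:
        raise DegenerateRoiError("ROI has no pixels on any axial slice")
    p = counts / counts.sum()
    k_idx = np.arange(10, dtype=np.float64)
    mean = float(np.sum(k_idx * p))
    var = float(np.sum((k_idx - mean) ** 2 * p))
    nz = p[p > 0]
    feats = {f"LBP_Bin_{k}": float(p[k]) for k in range(10)}
    feats["LBP_Mean"] = mean
    feats["LBP_Variance"] = var
    feats["LBP_Entropy"] = float(-np.sum(nz * np.log2(nz)))
    return feats


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def shape_features(mask: RoiMask) -> dict[str, float]:
    """8 geometry features from the binary mask and its voxel spacing."""
    mask.require_nonempty()
    m = mask.voxels
    sp = np.asarray(mask.spacing_mm)
    voxel_vol = float(np.prod(sp))
    n = int(m.sum())
    volume = n * voxel_vol

    # Gaussian pre-smoothing (sigma 0.8 voxels) before meshing suppresses the
    # staircase overestimate of the marching-cubes surface on binary masks.
    padded = np.pad(m.astype(np.float64), 2)
    smoothed = ndimage.gaussian_filter(padded, sigma=0.8)
    level_field = smoothed if smoothed.max() > 0.5 else padded
    verts, faces, _, _ = measure.marching_cubes(level_field, level=0.5, spacing=tuple(sp))
    area = float(measure.mesh_surface_area(verts, faces))

    coords = np.argwhere(m) * sp
    if len(coords) > 1:
        pts = coords
        if len(pts) > 400:
            try:
                pts = pts[ConvexHull(pts).vertices]
            except Exception:  # degenerate (coplanar) point sets
                pass
        max_diam = float(pdist(pts).max())
        cov = np.cov(coords.T, bias=True)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
        elong = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
        flat = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0
    else:
        max_diam, elong, flat = 0.0, 1.0, 1.0

    sphericity = float(np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area)
    compactness = float(36 * np.pi * volume**2 / area**3)
    return {
        "Shape_Volume": volume,
        "Shape_Surface_Area": area,
        "Shape_Surface_To_Volume": area / volume,
        "Shape_Sphericity": sphericity,
        "Shape_Compactness": compactness,
        "Shape_Max_Diameter": max_diam,
        "Shape_Elongation": elong,
        "Shape_Flatness": flat,
    }


# ---------------------------------------------------------------------------
# full catalog
# ---------------------------------------------------------------------------

def extract_all(
    bank: WaveletBank, mask: RoiMask, n_levels: int = N_LEVELS_DEFAULT
) -> dict[str, float]:
    """Extract the full 593-feature catalog from a wavelet bank and its ROI."""
    mask.require_aligned(bank["original"])
    mask.require_nonempty()
    out: dict[str, float] = {}
    for band, vol in bank:
        try:
            d = discretize(vol, mask, n_levels)
            fo = first_order_features(vol, mask, d)
            gl = glcm_features(d)
            rl = glrlm_features(d)
            lb = lbp_features(vol, mask)
        except Exception as exc:
            raise type(exc)(f"band {band}: {exc}") from exc
        for feats in (fo, gl, rl, lb):
            for k, v in feats.items():
                out[f"{band}_{k}"] = v
    out.update(shape_features(mask))
    return out
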