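"""Per-family feature formulas.

Texture features follow the Haralick (GLCM), Galloway + extensions (GLRLM),
Thibault (GLSZM) and Amadasun-King (NGTDM) definitions in their
IBSI-consistent form. Per-direction matrices are reduced by averaging the
feature values over directions (matrices are not merged). Logarithms are
base 2 with the 0*log(0)=0 convention.

Degenerate-case conventions: skewness and kurtosis of constant input are 0;
GLCM correlation of a zero-variance matrix is 1; NGTDM coarseness is capped
at 1e6 when its denominator falls below 1e-6.
"""

from __future__ import annotations

import numpy as np

from . import matrices as tm
from .registry import (
    FIRST_ORDER_FEATURES,
    GLCM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGTDM_FEATURES,
)

COARSENESS_CAP = 1e6
_EPS = 1e-12


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def roi_size(mask: np.ndarray, spacing) -> float:
    """Volume in mm^3 (3D mask) or area in mm^2 (2D mask)."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("roi_size: empty mask")
    return n * float(np.prod(spacing))


def first_order_features(intensities: np.ndarray, levels: np.ndarray, n_levels: int) -> dict[str, float]:
    """8 first-order statistics of the in-mask urine-normalized intensities.

    ``intensities`` and ``levels`` are 1D arrays over in-mask voxels.
    Energy is the mean of squared intensities (size-invariant); Entropy and
    Uniformity are computed on the quantized-level histogram.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("first_order_features: no in-mask values")
    mean = float(x.mean())
    sd = float(x.std())  # population SD
    if sd > 0:
        z = (x - mean) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4) - 3.0)  # excess kurtosis
    else:
        skew = 0.0
        kurt = 0.0
    hist = np.bincount(np.asarray(levels) - 1, minlength=n_levels).astype(float)
    p = hist / hist.sum()
    vals = {
        "Int_Mean": mean,
        "Int_Median": float(np.median(x)),
        "Int_StdDev": sd,
        "Int_Skewness": skew,
        "Int_Kurtosis": kurt,
        "Int_Energy": float(np.mean(x**2)),
        "Int_Entropy": float(-_xlog2(p).sum()),
        "Int_Uniformity": float((p**2).sum()),
    }
    assert tuple(vals) == FIRST_ORDER_FEATURES
    return vals


# ---------------------------------------------------------------------------
# GLCM


def _glcm_single(P: np.ndarray) -> dict[str, float]:
    n = P.shape[0]
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu_x = float((i * px).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    # symmetric matrix: marginals coincide
    if sd_x > _EPS:
        corr = float((((ii - mu_x) * (jj - mu_x) * P).sum()) / (sd_x * sd_x))
    else:
        corr = 1.0
    # p_{x+y}(k), k = 2..2n ; p_{x-y}(k), k = 0..n-1
    p_sum = np.zeros(2 * n + 1)
    np.add.at(p_sum, (ii + jj).ravel(), P.ravel())
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), P.ravel())
    k_sum = np.arange(2 * n + 1)
    k_diff = np.arange(n)
    sum_avg = float((k_sum * p_sum).sum())
    diff_avg = float((k_diff * p_diff).sum())
    return {
        "GLCM_Energy": float((P**2).sum()),
        "GLCM_Contrast": float(((ii - jj) ** 2 * P).sum()),
        "GLCM_Correlation": corr,
        "GLCM_SumAverage": sum_avg,
        "GLCM_SumVariance": float(((k_sum - sum_avg) ** 2 * p_sum).sum()),
        "GLCM_SumEntropy": float(-_xlog2(p_sum).sum()),
        "GLCM_Entropy": float(-_xlog2(P).sum()),
        "GLCM_DifferenceVariance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "GLCM_DifferenceEntropy": float(-_xlog2(p_diff).sum()),
        "GLCM_InverseDifferenceMoment": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "GLCM_Autocorrelation": float((ii * jj * P).sum()),
        "GLCM_ClusterShade": float(((ii + jj - 2 * mu_x) ** 3 * P).sum()),
        "GLCM_ClusterProminence": float(((ii + jj - 2 * mu_x) ** 4 * P).sum()),
        "GLCM_Dissimilarity": float((np.abs(ii - jj) * P).sum()),
        "GLCM_MaximumProbability": float(P.max()),
    }


def glcm_features(levels, mask, n_levels: int) -> dict[str, float]:
    """15 Haralick features, averaged over the per-direction GLCMs."""
    mats = tm.glcm_matrices(levels, mask, n_levels)
    per_dir = [_glcm_single(P) for P in mats]
    vals = {k: float(np.mean([d[k] for d in per_dir])) for k in GLCM_FEATURES}
    return vals


# ---------------------------------------------------------------------------
# GLRLM / GLSZM share the weighted-matrix feature structure


def _rl_zone_features(R: np.ndarray, n_voxels: int, prefix: str, names) -> dict[str, float]:
    """Features over a (level x size) count matrix with total count Ns.

    Low/high-gray weights are 1/i^2 and i^2; short/small and long/large
    weights are 1/s^2 and s^2.
    """
    n_levels, max_s = R.shape
    i = np.arange(1, n_levels + 1)[:, None].astype(float)
    s = np.arange(1, max_s + 1)[None, :].astype(float)
    Ns = R.sum()
    if Ns == 0:
        raise ValueError(f"{prefix}: empty matrix")
    p = R / Ns
    r_i = R.sum(axis=1)
    r_s = R.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_s = float((p * s).sum())
    vals = [
        float((R / s**2).sum() / Ns),            # SRE / SAE
        float((R * s**2).sum() / Ns),            # LRE / LAE
        float((r_i**2).sum() / Ns),              # GLN
        float((r_s**2).sum() / Ns),              # RLN / ZSN
        float(Ns / n_voxels),                    # Run/Zone percentage
        float((R / i**2).sum() / Ns),            # LGLRE / LGLZE
        float((R * i**2).sum() / Ns),            # HGLRE / HGLZE
        float((R / (i**2 * s**2)).sum() / Ns),   # SRLGLE / SALGLE
        float((R * i**2 / s**2).sum() / Ns),     # SRHGLE / SAHGLE
        float((R * s**2 / i**2).sum() / Ns),     # LRLGLE / LZLGLE
        float((R * i**2 * s**2).sum() / Ns),     # LRHGLE / LZHGLE
        float((p * (i - mu_i) ** 2).sum()),      # GrayLevelVariance
        float((p * (s - mu_s) ** 2).sum()),      # RunLength/ZoneSize variance
    ]
    return dict(zip(names, vals))


def glrlm_features(levels, mask, n_levels: int) -> dict[str, float]:
    """13 run-length features, averaged over directions."""
    n_vox = int(np.asarray(mask, dtype=bool).sum())
    if n_vox == 0:
        raise ValueError("glrlm_features: empty ROI")
    mats = tm.glrlm_matrices(levels, mask, n_levels)
    per_dir = [_rl_zone_features(R, n_vox, "GLRLM", GLRLM_FEATURES) for R in mats]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLRLM_FEATURES}


def glszm_features(levels, mask, n_levels: int) -> dict[str, float]:
    """13 size-zone features (single matrix; zones have no direction)."""
    n_vox = int(np.asarray(mask, dtype=bool).sum())
    if n_vox == 0:
        raise ValueError("glszm_features: empty ROI")
    Z = tm.glszm_matrix(levels, mask, n_levels)
    return _rl_zone_features(Z, n_vox, "GLSZM", GLSZM_FEATURES)


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_features(levels, mask, n_levels: int) -> dict[str, float]:
    """5 Amadasun-King features from the neighbor gray tone table."""
    n_i, p_i, s_i = tm.ngtdm_table(levels, mask, n_levels)
    nvp = n_i.sum()
    nz = p_i > 0
    ngp = int(nz.sum())
    pi_nz = p_i[nz]
    si_nz = s_i[nz]
    lev_nz = np.arange(1, n_levels + 1, dtype=float)[nz]

    denom_coarse = float((p_i * s_i).sum())
    coarseness = COARSENESS_CAP if denom_coarse < 1e-6 else min(1.0 / denom_coarse, COARSENESS_CAP)

    if ngp > 1:
        di = lev_nz[:, None] - lev_nz[None, :]
        pp = pi_nz[:, None] * pi_nz[None, :]
        contrast = float((pp * di**2).sum() / (ngp * (ngp - 1)) * (s_i.sum() / nvp))
        busy_denom = float(np.abs(lev_nz[:, None] * pi_nz[:, None] - lev_nz[None, :] * pi_nz[None, :]).sum())
        busyness = float((p_i * s_i).sum() / busy_denom) if busy_denom > _EPS else 0.0
        psum = pi_nz[:, None] + pi_nz[None, :]
        pss = pi_nz[:, None] * si_nz[:, None] + pi_nz[None, :] * si_nz[None, :]
        complexity = float((np.abs(di) * pss / psum).sum() / nvp)
        s_total = float(s_i.sum())
        strength = float((psum * di**2).sum() / s_total) if s_total > _EPS else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    vals = {
        "NGTDM_Coarseness": coarseness,
        "NGTDM_Contrast": contrast,
        "NGTDM_Busyness": busyness,
        "NGTDM_Complexity": complexity,
        "NGTDM_Strength": strength,
    }
    assert tuple(vals) == NGTDM_FEATURES
    return vals
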