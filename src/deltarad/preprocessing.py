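"""Intensity normalization, resampling and gray-level quantization.

Fixed pipeline order: Collewet clip -> urine normalize -> isotropic
resample -> quantize. Intensities are resampled before quantization so that
interpolation never acts on discrete level labels. Provenance flags on
:class:`NormalizedVolume` make the normalization steps no-ops on re-entry,
so re-running the pipeline on its own output changes nothing.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi

from .types import ImageVolume, NormalizedVolume, QuantizedROI

logger = logging.getLogger(__name__)

__all__ = [
    "collewet_normalize",
    "urine_normalize",
    "resample_isotropic_3d",
    "select_largest_slice_2d",
    "quantize",
    "preprocess",
]

DEFAULT_LEVELS = 64


def _as_normalized(volume: ImageVolume) -> NormalizedVolume:
    if isinstance(volume, NormalizedVolume):
        return volume
    return NormalizedVolume(volume.data, volume.spacing)


def collewet_normalize(
    volume: ImageVolume,
    tumor_mask: np.ndarray,
    n_sigma: float = 3.0,
) -> NormalizedVolume:
    """Clip in-mask intensities to [mu - 3 sigma, mu + 3 sigma].

    mu and sigma (sample SD) are computed from the tumor ROI only; voxels
    outside the mask are untouched. Zero in-mask variance returns the input
    unchanged with a logged note. Idempotent via the ``collewet_applied``
    provenance flag.
    """
    vol = _as_normalized(volume)
    if vol.collewet_applied:
        return vol
    mask = np.asarray(tumor_mask, dtype=bool)
    if not mask.any():
        raise ValueError("collewet_normalize: empty tumor mask")
    inside = vol.data[mask]
    mu = inside.mean()
    sigma = inside.std(ddof=1) if inside.size > 1 else 0.0
    if sigma == 0:
        logger.info("collewet_normalize: zero in-mask variance; returning input unchanged")
        return vol.with_data(vol.data.copy(), collewet_applied=True)
    data = vol.data.copy()
    data[mask] = np.clip(inside, mu - n_sigma * sigma, mu + n_sigma * sigma)
    return vol.with_data(data, collewet_applied=True)


def urine_normalize(volume: ImageVolume, bladder_mask: np.ndarray) -> NormalizedVolume:
    """Divide every voxel by the mean bladder-urine intensity.

    The bladder mean becomes exactly 1. Idempotent via the
    ``urine_applied`` flag.
    """
    vol = _as_normalized(volume)
    if vol.urine_applied:
        return vol
    mask = np.asarray(bladder_mask, dtype=bool)
    if not mask.any():
        raise ValueError("urine_normalize: empty bladder mask")
    ref = vol.data[mask].mean()
    if ref <= 0:
        raise ValueError(f"urine_normalize: non-positive bladder mean ({ref:g}); degenerate input")
    return vol.with_data(vol.data / ref, urine_applied=True)


def resample_isotropic_3d(
    volume: ImageVolume,
    masks: dict[str, np.ndarray],
    target_mm: float = 1.0,
):
    """Resample to an isotropic ``target_mm`` grid: trilinear for
    intensities, nearest-neighbor for masks. Physical extent is preserved
    within one voxel. Returns ``(volume', masks')``.
    """
    factors = tuple(s / target_mm for s in volume.spacing)
    if np.allclose(factors, 1.0):
        out_vol = _as_normalized(volume).with_data(volume.data.copy())
        out_masks = {k: np.asarray(m, dtype=bool).copy() for k, m in masks.items()}
    else:
        data = ndi.zoom(volume.data, factors, order=1, mode="nearest", grid_mode=True)
        vol = _as_normalized(volume)
        out_vol = NormalizedVolume(
            data,
            (target_mm,) * 3,
            collewet_applied=vol.collewet_applied,
            urine_applied=vol.urine_applied,
        )
        out_masks = {}
        for name, m in masks.items():
            rm = ndi.zoom(
                np.asarray(m, dtype=np.uint8), factors, order=0, mode="nearest", grid_mode=True
            ).astype(bool)
            if rm.shape != data.shape:
                raise RuntimeError("mask/volume shape mismatch after resampling")
            out_masks[name] = rm
    for name, m in out_masks.items():
        if not m.any():
            raise ValueError(f"resample_isotropic_3d: mask '{name}' empty after resampling")
    out_vol = out_vol.with_data(out_vol.data)
    out_vol.spacing = (target_mm,) * 3
    return out_vol, out_masks


def select_largest_slice_2d(
    mask3d: np.ndarray,
    volume: ImageVolume,
    target_mm: float = 1.0,
):
    """Pick the axial (z) slice with the largest in-plane mask area and
    resample it in-plane to ``target_mm`` pixels.

    Ties are broken by the lowest slice index. Returns
    ``(slice_index, intensities2d, mask2d)`` with the 2D arrays on the
    isotropic in-plane grid.
    """
    mask3d = np.asarray(mask3d, dtype=bool)
    if not mask3d.any():
        raise ValueError("select_largest_slice_2d: empty mask")
    areas = mask3d.sum(axis=(1, 2))  # same pixel area per slice -> counts suffice
    z = int(np.argmax(areas))  # argmax returns the first (lowest) maximum
    img2d = volume.data[z]
    m2d = mask3d[z]
    factors = (volume.spacing[1] / target_mm, volume.spacing[2] / target_mm)
    if not np.allclose(factors, 1.0):
        img2d = ndi.zoom(img2d, factors, order=1, mode="nearest", grid_mode=True)
        m2d = ndi.zoom(m2d.astype(np.uint8), factors, order=0, mode="nearest", grid_mode=True).astype(bool)
    if not m2d.any():
        raise ValueError("select_largest_slice_2d: mask empty after in-plane resampling")
    return z, img2d, m2d


def quantize(
    volume: NormalizedVolume | np.ndarray,
    mask: np.ndarray,
    levels: int = DEFAULT_LEVELS,
    dimensionality: str = "3D",
    spacing=None,
) -> QuantizedROI:
    """Quantize urine-normalized intensities into ``levels`` gray levels.

    level(v) = clamp(ceil(levels * v), 1, levels): the urine mean (v = 1)
    maps exactly to the highest level, v <= 0 maps to level 1, v > 1 is
    clamped to the top level.
    """
    if levels < 2:
        raise ValueError(f"quantize: need at least 2 levels, got {levels}")
    if isinstance(volume, NormalizedVolume):
        if not volume.urine_applied:
            logger.warning("quantize: volume not flagged urine-normalized; levels assume v=1 at urine mean")
        data = volume.data
        if spacing is None:
            spacing = volume.spacing
    else:
        data = np.asarray(volume, dtype=float)
        if spacing is None:
            spacing = (1.0,) * data.ndim
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("quantize: empty mask")
    lev = np.ceil(levels * data).astype(np.int64)
    lev = np.clip(lev, 1, levels)
    lev[~mask] = 0
    return QuantizedROI(
        levels=lev,
        mask=mask,
        n_levels=levels,
        spacing=tuple(spacing),
        dimensionality=dimensionality,
        intensities=np.asarray(data, dtype=float),
    )


def preprocess(
    volume: ImageVolume,
    tumor_mask: np.ndarray,
    bladder_mask: np.ndarray,
    levels: int = DEFAULT_LEVELS,
    collewet: bool = True,
):
    """Run the full fixed-order pipeline for one timepoint.

    Returns ``{"3D": QuantizedROI, "2D": QuantizedROI, "slice_index": int}``
    where the 3D ROI lives on the 1 mm isotropic grid and the 2D ROI on the
    largest axial slice at 1 mm in-plane.
    """
    vol = _as_normalized(volume)
    if collewet:
        vol = collewet_normalize(vol, tumor_mask)
    vol = urine_normalize(vol, bladder_mask)

    vol3, masks3 = resample_isotropic_3d(vol, {"tumor": tumor_mask, "bladder": bladder_mask})
    q3 = quantize(vol3, masks3["tumor"], levels=levels, dimensionality="3D")

    z, img2d, m2d = select_largest_slice_2d(tumor_mask, vol)
    q2 = quantize(img2d, m2d, levels=levels, dimensionality="2D", spacing=(1.0, 1.0))
    return {"3D": q3, "2D": q2, "slice_index": z}
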