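"""Full 55-feature extraction from a quantized ROI."""

from __future__ import annotations

import numpy as np

from ..types import FeatureVector, QuantizedROI
from . import families
from .registry import ALL_FEATURES, N_FEATURES

__all__ = ["extract_all"]


def extract_all(
    q: QuantizedROI,
    patient_id: str = "",
    timepoint: str = "",
) -> FeatureVector:
    """Extract all 55 registry features from a quantized ROI.

    Concatenates size (1) + first-order (8) + GLCM (15) + GLRLM (13) +
    GLSZM (13) + NGTDM (5) in registry order. Family errors are re-raised
    with the family named.

    Parameters
    ----------
    q : QuantizedROI
        Quantized levels + mask + urine-normalized intensities on an
        isotropic grid ("3D") or single axial slice ("2D").
    """
    if q.n_voxels == 0:
        raise ValueError("extract_all: empty mask")
    if q.intensities is None:
        raise ValueError("extract_all: QuantizedROI carries no intensities")
    # crop to the mask bounding box: texture features see in-mask content only
    bbox = tuple(
        slice(idx.min(), idx.max() + 1) for idx in np.nonzero(q.mask)
    )
    mask = q.mask[bbox]
    levels = np.asarray(q.levels)[bbox]
    in_mask_int = np.asarray(q.intensities)[bbox][mask]
    in_mask_lev = levels[mask]

    values: dict[str, float] = {"Volume": families.roi_size(mask, q.spacing)}
    stages = [
        ("first_order", lambda: families.first_order_features(in_mask_int, in_mask_lev, q.n_levels)),
        ("glcm", lambda: families.glcm_features(levels, mask, q.n_levels)),
        ("glrlm", lambda: families.glrlm_features(levels, mask, q.n_levels)),
        ("glszm", lambda: families.glszm_features(levels, mask, q.n_levels)),
        ("ngtdm", lambda: families.ngtdm_features(levels, mask, q.n_levels)),
    ]
    for family, fn in stages:
        try:
            values.update(fn())
        except ValueError as exc:
            raise ValueError(f"feature family '{family}' failed: {exc}") from exc

    assert tuple(values) == ALL_FEATURES and len(values) == N_FEATURES
    return FeatureVector(
        values=values,
        dimensionality=q.dimensionality,
        timepoint=timepoint,
        patient_id=patient_id,
    )
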