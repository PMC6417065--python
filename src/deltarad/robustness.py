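"""Delta features and the translation-based ICC robustness filter.

Eight translated ROIs emulate inter-observer contouring variability: all
in-plane (y, x) voxel shifts in {-1, 0, 1}^2 except (0, 0), on the 1 mm
isotropic grid (so +/-1 voxel = +/-1 mm). The translation is applied to the
mask only; the image stays fixed. A feature is robust when its one-way
random single-measure ICC(1,1) over {original + 8 translations} exceeds the
threshold in all four tables: {2D, 3D} x {before, after}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import ALL_FEATURES, extract_all
from .preprocessing import quantize
from .types import DeltaFeatureVector, FeatureVector, QuantizedROI

__all__ = [
    "delta_features",
    "translated_rois",
    "icc_one_way",
    "robustness_filter",
    "ICCReport",
]

SHIFTS_2D = tuple(
    (dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)
)


def delta_features(after: FeatureVector, before: FeatureVector) -> DeltaFeatureVector:
    """Elementwise after - before."""
    if after.dimensionality != before.dimensionality:
        raise ValueError("delta_features: dimensionality mismatch")
    if after.patient_id and before.patient_id and after.patient_id != before.patient_id:
        raise ValueError("delta_features: patient mismatch")
    missing = set(after.values) ^ set(before.values)
    if missing:
        raise ValueError(f"delta_features: mismatched feature names: {sorted(missing)}")
    values = {k: after.values[k] - before.values[k] for k in after.values}
    return DeltaFeatureVector(
        values=values,
        dimensionality=after.dimensionality,
        patient_id=after.patient_id or before.patient_id,
    )


def _shift_mask(mask: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Rigid in-plane voxel shift; errors if the mask would exit the grid."""
    dy, dx = shift
    axes = (mask.ndim - 2, mask.ndim - 1)
    for d, ax in ((dy, axes[0]), (dx, axes[1])):
        if d == 0:
            continue
        edge = [slice(None)] * mask.ndim
        edge[ax] = -1 if d > 0 else 0
        if mask[tuple(edge)].any():
            raise ValueError(
                f"translated_rois: shift {shift} exits grid bounds along axis {ax}; pad the grid"
            )
    out = np.roll(mask, (dy, dx), axis=axes)
    return out


def translated_rois(mask: np.ndarray, shifts=SHIFTS_2D) -> list[np.ndarray]:
    """The 8 in-plane +/-1 voxel translations of ``mask`` (2D or 3D array).

    Each output mask has the same voxel count as the input.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("translated_rois: empty mask")
    return [_shift_mask(mask, s) for s in shifts]


def icc_one_way(measurements: np.ndarray) -> float:
    """One-way random, single-measure ICC(1,1).

    ``measurements`` is subjects x k repeated values. Returns NaN when the
    ANOVA denominator is zero (all values identical everywhere); callers
    treat NaN as non-robust.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("icc_one_way: need >= 2 subjects and >= 2 repeats")
    n, k = x.shape
    row_means = x.mean(axis=1)
    grand = x.mean()
    msb = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msw = ((x - row_means[:, None]) ** 2).sum() / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0:
        return float("nan")
    return float((msb - msw) / denom)


@dataclass
class ICCReport:
    """Per-table ICC values and the conjunctive robust set."""

    tables: dict[tuple[str, str], dict[str, float]]  # (dims, timepoint) -> name -> ICC
    robust_set: list[str] = field(default_factory=list)
    threshold: float = 0.9

    def pass_set(self, dims: str, timepoint: str) -> set[str]:
        table = self.tables[(dims, timepoint)]
        return {name for name, v in table.items() if np.isfinite(v) and v > self.threshold}


def _perturbed_vectors(q: QuantizedROI, patient_id: str, timepoint: str) -> np.ndarray:
    """Feature matrix (9 x 55) for the original + 8 translated masks."""
    masks = [q.mask] + translated_rois(q.mask)
    # re-derive levels from the full intensity grid: translated masks cover
    # voxels outside the original mask, where q.levels is zeroed
    lev_full = np.clip(np.ceil(q.n_levels * np.asarray(q.intensities)).astype(np.int64), 1, q.n_levels)
    rows = []
    for m in masks:
        qm = QuantizedROI(
            levels=np.where(m, lev_full, 0),
            mask=m,
            n_levels=q.n_levels,
            spacing=q.spacing,
            dimensionality=q.dimensionality,
            intensities=q.intensities,
        )
        try:
            fv = extract_all(qm, patient_id=patient_id, timepoint=timepoint)
        except ValueError as exc:
            raise ValueError(
                f"robustness_filter: extraction failed for patient {patient_id}, "
                f"timepoint {timepoint}: {exc}"
            ) from exc
        rows.append(fv.as_array(ALL_FEATURES))
    return np.vstack(rows)


def robustness_filter(preprocessed: dict, threshold: float = 0.9) -> ICCReport:
    """ICC robustness filter over a preprocessed cohort.

    ``preprocessed`` maps patient_id -> {("3D"|"2D", "before"|"after"):
    QuantizedROI}. For every patient, timepoint and dimensionality the 55
    features are extracted from the original and 8 translated masks (k = 9
    repeats); ICC(1,1) is computed per feature per table and the robust set
    is the intersection of the four per-table pass sets.
    """
    pids = sorted(preprocessed)
    if len(pids) < 2:
        raise ValueError("robustness_filter: need >= 2 patients")
    tables: dict[tuple[str, str], dict[str, float]] = {}
    for dims in ("3D", "2D"):
        for tp in ("before", "after"):
            stack = np.stack(
                [_perturbed_vectors(preprocessed[pid][(dims, tp)], pid, tp) for pid in pids]
            )  # patients x 9 x 55
            tables[(dims, tp)] = {
                name: icc_one_way(stack[:, :, j])
                for j, name in enumerate(ALL_FEATURES)
            }
    report = ICCReport(tables=tables, threshold=threshold)
    passing = None
    for key in tables:
        ps = report.pass_set(*key)
        passing = ps if passing is None else (passing & ps)
    report.robust_set = [n for n in ALL_FEATURES if n in passing]
    return report
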