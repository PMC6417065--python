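"""Readers/writers for NIfTI volumes, feature/outcome CSV and signature JSON.

Arrays are stored in the package-wide ``(z, y, x)`` order; the NIfTI affine
is the diagonal of the spacings in that order, making the header zooms the
single source of truth for millimetres. Masks are written as uint8 {0, 1}.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .features import ALL_FEATURES
from .signature import RadSignature
from .types import ImageVolume, NormalizedVolume

__all__ = [
    "write_nifti",
    "read_nifti",
    "write_mask",
    "read_mask",
    "write_features_csv",
    "read_features_csv",
    "write_outcomes_csv",
    "read_outcomes_csv",
    "write_signature_json",
    "read_signature_json",
]

OUTCOME_COLUMNS = ["patient_id", "endpoint", "time", "event"]


def write_nifti(volume: ImageVolume, path) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.data.astype(np.float32), affine)
    nib.save(img, str(path))


def read_nifti(path) -> NormalizedVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return NormalizedVolume(data, spacing)


def write_mask(mask: np.ndarray, spacing, path) -> None:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    nib.save(img, str(path))


def read_mask(path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data.astype(bool), spacing


def write_features_csv(rows: pd.DataFrame, path) -> None:
    """Feature table with columns patient_id, timepoint, dims, then the 55
    registry names in order."""
    cols = ["patient_id", "timepoint", "dims", *ALL_FEATURES]
    missing = [c for c in cols if c not in rows.columns]
    if missing:
        raise ValueError(f"write_features_csv: missing columns {missing}")
    rows[cols].to_csv(path, index=False)


def read_features_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("patient_id", "timepoint", "dims", *ALL_FEATURES) if c not in df.columns]
    if missing:
        raise ValueError(f"read_features_csv: missing columns {missing}")
    return df


def write_outcomes_csv(outcomes: pd.DataFrame, path) -> None:
    missing = [c for c in OUTCOME_COLUMNS if c not in outcomes.columns]
    if missing:
        raise ValueError(f"write_outcomes_csv: missing columns {missing}")
    outcomes[OUTCOME_COLUMNS].to_csv(path, index=False)


def read_outcomes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in OUTCOME_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"read_outcomes_csv: missing columns {missing}")
    bad = set(df["event"].unique()) - {0, 1}
    if bad:
        raise ValueError(f"read_outcomes_csv: event values must be 0/1, got {sorted(bad)}")
    if (df["time"] <= 0).any():
        raise ValueError("read_outcomes_csv: times must be positive")
    return df


def write_signature_json(sig: RadSignature, path) -> None:
    payload = {
        "endpoint": sig.endpoint,
        "dims": sig.dimensionality,
        "coefficients": sig.coefficients,
        "cutoff": sig.cutoff,
        "provenance": sig.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_signature_json(path) -> RadSignature:
    payload = json.loads(Path(path).read_text())
    for key in ("endpoint", "dims", "coefficients"):
        if key not in payload:
            raise ValueError(f"read_signature_json: missing field {key!r}")
    return RadSignature(
        endpoint=payload["endpoint"],
        dimensionality=payload["dims"],
        coefficients={str(k): float(v) for k, v in payload["coefficients"].items()},
        cutoff=payload.get("cutoff"),
        provenance=payload.get("provenance", "fitted"),
    )
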