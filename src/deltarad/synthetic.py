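"""Synthetic paired-MRI cohort generator.

Emulates T2-weighted-like volumes on an anisotropic native grid: a textured
ellipsoidal tumor whose size and texture change between timepoints as a
function of a latent response in [0, 1], a bright ~1 cm^3 spherical
bladder-urine reference, and proportional-hazards outcomes driven by the
latent response.

Texture model: Gaussian white noise convolved with an isotropic Gaussian
kernel (sigma = correlation_length, mm) then offset to a positive mean.
The latent response r acts on three knobs (all configurable):

* tumor semi-axes scale by ``1 - tumor_shrink * r`` (default 0.5),
* texture correlation length scales by ``1 + r``,
* texture intensity SD scales by ``1 - 0.5 * r``.

Everything is deterministic given (config, seed): patient ``i`` draws from
``default_rng([seed, i])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .types import ImageVolume, ROISet

__all__ = [
    "CohortConfig",
    "PatientCase",
    "generate_patient",
    "generate_cohort",
    "simulate_survival",
    "cohort_outcomes",
    "split_cohort",
]

ENDPOINTS = ("LR", "DM", "DFS")

#: Radius (mm) of a 1 cm^3 sphere.
_BLADDER_RADIUS_MM = (3.0 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    ``hazard_coefficients`` maps latent quantities ("latent_response",
    "delta_volume") to log-hazard weights; ``baseline_hazard`` maps endpoint
    name to events/month (a float applies to all three endpoints).
    """

    n_patients: int = 30
    grid_shape: tuple[int, int, int] = (16, 48, 48)
    voxel_spacing: tuple[float, float, float] = (4.0, 1.0, 1.0)
    tumor_radius_range: tuple[float, float] = (6.0, 10.0)
    correlation_length: float = 2.0
    intensity_sd: float = 0.12
    tumor_mean: float = 0.35
    background_mean: float = 0.15
    background_sd: float = 0.02
    bladder_intensity: float = 1.0
    bladder_sd: float = 0.004
    axis_jitter: float = 0.05
    tumor_shrink: float = 0.5
    response_alpha: float = 2.0
    response_beta: float = 2.0
    hazard_coefficients: dict = field(default_factory=lambda: {"latent_response": -3.0})
    baseline_hazard: dict | float = field(
        default_factory=lambda: {"LR": 0.004, "DM": 0.008, "DFS": 0.012}
    )
    censor_horizon: float = 60.0
    censor_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacings must be positive")

    def hazard_for(self, endpoint: str) -> float:
        if isinstance(self.baseline_hazard, dict):
            return float(self.baseline_hazard[endpoint])
        return float(self.baseline_hazard)


@dataclass
class PatientCase:
    patient_id: str
    before: ImageVolume
    after: ImageVolume
    rois_before: ROISet
    rois_after: ROISet
    latent_response: float

    def __post_init__(self) -> None:
        if not self.rois_before.tumor.any() or not self.rois_after.tumor.any():
            raise ValueError("tumor masks must be non-empty")
        if self.latent_response > 0:
            vb = self.rois_before.tumor.sum()
            va = self.rois_after.tumor.sum()
            if va > vb:
                raise ValueError("after-tumor volume exceeds before-tumor volume under response > 0")


def _ellipsoid_mask(shape, spacing, center_mm, semi_axes_mm) -> np.ndarray:
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    cz, cy, cx = center_mm
    az, ay, ax = semi_axes_mm
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _correlated_field(rng: np.random.Generator, shape, spacing, corr_length_mm: float) -> np.ndarray:
    """Smoothed unit-variance Gaussian random field (sigma in mm)."""
    white = rng.standard_normal(shape)
    sigma_vox = [corr_length_mm / s for s in spacing]
    smooth = ndi.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generate_patient(
    config: CohortConfig,
    index: int,
    rng: np.random.Generator | None = None,
    response_override: float | None = None,
) -> PatientCase:
    """Generate one paired pre/post case, deterministic in (config.seed, index).

    ``response_override`` replaces the Beta-drawn latent response (the
    random draw still occurs, so geometry and noise are unchanged)."""
    if index >= config.n_patients:
        raise ValueError(f"index {index} out of range for n_patients={config.n_patients}")
    if rng is None:
        rng = np.random.default_rng([config.seed, index])
    shape = tuple(config.grid_shape)
    spacing = tuple(config.voxel_spacing)
    extent = [n * s for n, s in zip(shape, spacing)]

    radius = rng.uniform(*config.tumor_radius_range)
    jit = rng.uniform(1.0 - config.axis_jitter, 1.0 + config.axis_jitter, size=3)
    semi_axes = radius * jit
    # margin: tumor + 1 mm translation padding + resampling slack
    margin = 3.0
    for ax_name, ext, sa in zip("zyx", extent, semi_axes):
        if 2 * (sa + margin) > ext:
            raise ValueError(
                f"tumor radius {radius:.1f} mm too large for grid along {ax_name} "
                f"(extent {ext:.1f} mm)"
            )
    center = [ext / 2.0 for ext in extent]
    # jitter the center a little, keeping the margin
    center = [
        c + rng.uniform(-1.0, 1.0) for c in center
    ]
    r = float(rng.beta(config.response_alpha, config.response_beta))
    if response_override is not None:
        if not 0.0 <= response_override <= 1.0:
            raise ValueError("response_override must lie in [0, 1]")
        r = float(response_override)

    tumor_before = _ellipsoid_mask(shape, spacing, center, semi_axes)
    after_axes = semi_axes * (1.0 - config.tumor_shrink * r)
    tumor_after = _ellipsoid_mask(shape, spacing, center, after_axes)

    # bladder: ~1 cm^3 sphere tucked in a corner, away from the tumor
    bl_center = [
        min(2.0 + _BLADDER_RADIUS_MM, ext) for ext in extent
    ]
    bl_center[0] = extent[0] / 2.0  # keep it mid-stack so 2D slices see context
    bladder = _ellipsoid_mask(shape, spacing, bl_center, (_BLADDER_RADIUS_MM,) * 3)
    if (bladder & (tumor_before | tumor_after)).any():
        raise ValueError("bladder and tumor masks overlap; enlarge the grid")

    # shared noise draws so latent_response = 0 gives identical timepoints
    noise_seed = rng.integers(0, 2**63 - 1)
    bg = config.background_mean + config.background_sd * _correlated_field(
        np.random.default_rng([noise_seed, 0]), shape, spacing, 1.0
    )
    field_rng_state = [noise_seed, 1]
    tex_rng = np.random.default_rng(field_rng_state)
    white_state = tex_rng.bit_generator.state

    def textured(corr_len: float, sd: float) -> np.ndarray:
        trng = np.random.default_rng(field_rng_state)
        trng.bit_generator.state = white_state
        return config.tumor_mean + sd * _correlated_field(trng, shape, spacing, corr_len)

    bl_noise = config.bladder_sd * np.random.default_rng([noise_seed, 2]).standard_normal(shape)

    def compose(tumor_mask: np.ndarray, corr_len: float, sd: float) -> np.ndarray:
        img = bg.copy()
        tex = textured(corr_len, sd)
        img[tumor_mask] = tex[tumor_mask]
        img[bladder] = config.bladder_intensity + bl_noise[bladder]
        return np.clip(img, 1e-4, None)

    img_before = compose(tumor_before, config.correlation_length, config.intensity_sd)
    img_after = compose(
        tumor_after,
        config.correlation_length * (1.0 + r),
        config.intensity_sd * (1.0 - 0.5 * r),
    )

    pid = f"P{index:04d}"
    return PatientCase(
        patient_id=pid,
        before=ImageVolume(img_before, spacing),
        after=ImageVolume(img_after, spacing),
        rois_before=ROISet(tumor_before, bladder),
        rois_after=ROISet(tumor_after, bladder),
        latent_response=r,
    )


def generate_cohort(config: CohortConfig) -> list[PatientCase]:
    return [generate_patient(config, i) for i in range(config.n_patients)]


def simulate_survival(
    scores,
    baseline_hazard: float,
    censor_horizon: float,
    rng: np.random.Generator,
    censor_rate: float = 0.0,
    endpoint: str = "DFS",
    patient_ids=None,
) -> pd.DataFrame:
    """Proportional-hazards outcome simulation for one endpoint.

    Event times are exponential with rate ``baseline_hazard * exp(score)``;
    censoring time is ``min(Exp(censor_rate), censor_horizon)`` (pure
    administrative censoring when ``censor_rate == 0``). ``event = 1`` iff
    the event time does not exceed the censoring time.

    Returns a tidy frame with columns patient_id, endpoint, time, event.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("simulate_survival: scores must be finite")
    if baseline_hazard <= 0:
        raise ValueError("simulate_survival: baseline_hazard must be positive")
    n = scores.size
    if patient_ids is None:
        patient_ids = [f"P{i:04d}" for i in range(n)]
    rate = baseline_hazard * np.exp(scores)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        t_cens = np.minimum(rng.exponential(1.0 / censor_rate, size=n), censor_horizon)
    else:
        t_cens = np.full(n, censor_horizon)
    event = (t_event <= t_cens).astype(int)
    time = np.minimum(t_event, t_cens)
    time = np.maximum(time, 1e-6)
    return pd.DataFrame(
        {"patient_id": patient_ids, "endpoint": endpoint, "time": time, "event": event}
    )


def latent_scores(config: CohortConfig, cases: list[PatientCase]) -> np.ndarray:
    """Linear predictor per patient from configured latent quantities.

    Supported keys: ``latent_response`` (centered at its Beta mean) and
    ``delta_volume`` (after - before tumor volume, cm^3).
    """
    coeffs = config.hazard_coefficients
    r = np.array([c.latent_response for c in cases])
    score = np.zeros(len(cases))
    if "latent_response" in coeffs:
        r_mean = config.response_alpha / (config.response_alpha + config.response_beta)
        score += coeffs["latent_response"] * (r - r_mean)
    if "delta_volume" in coeffs:
        vv = float(np.prod(config.voxel_spacing)) / 1000.0  # cm^3 per voxel
        dv = np.array(
            [
                (c.rois_after.tumor.sum() - c.rois_before.tumor.sum()) * vv
                for c in cases
            ]
        )
        score += coeffs["delta_volume"] * dv
    return score


def cohort_outcomes(config: CohortConfig, cases: list[PatientCase], rng=None) -> pd.DataFrame:
    """One (time, event) row per patient per endpoint (LR, DM, DFS), all
    driven by the same latent score with endpoint-specific baseline hazards
    so DFS events dominate."""
    if rng is None:
        rng = np.random.default_rng([config.seed, 10**6])
    scores = latent_scores(config, cases)
    ids = [c.patient_id for c in cases]
    frames = [
        simulate_survival(
            scores,
            config.hazard_for(ep),
            config.censor_horizon,
            rng,
            censor_rate=config.censor_rate,
            endpoint=ep,
            patient_ids=ids,
        )
        for ep in ENDPOINTS
    ]
    return pd.concat(frames, ignore_index=True)


def split_cohort(patient_ids, ratio=(2, 1), rng=None):
    """Random disjoint, exhaustive split with sizes in the rounded a:b ratio.

    101 ids at 2:1 give 67 training / 34 validation ids.
    """
    ids = list(patient_ids)
    if len(ids) < 2:
        raise ValueError("split_cohort: need at least 2 patients")
    a, b = ratio
    if a <= 0 or b <= 0 or a != int(a) or b != int(b):
        raise ValueError("split_cohort: ratio must be positive integers")
    if rng is None:
        rng = np.random.default_rng(0)
    n_train = int(round(len(ids) * a / (a + b)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    perm = rng.permutation(len(ids))
    train = [ids[i] for i in sorted(perm[:n_train])]
    valid = [ids[i] for i in sorted(perm[n_train:])]
    return train, valid
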