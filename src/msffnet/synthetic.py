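"""Multimodal brain-tumor phantom generator.

Emulates the structure of a BRATS 2015 case without requiring any download:
an ellipsoidal "brain" inside a zero background, optionally containing a
nested tumor whose shells follow the label taxonomy —

    edema (2)  >  core = { enhancing rim (4) > non-enhancing (3) > necrosis (1) }

All shells are level sets of a single perturbed ellipsoidal distance field,
so the nesting enhancing < core < complete holds by construction.  Modality
intensities mimic clinical contrast (T1c-bright enhancing rim, FLAIR-bright
edema, T1-dark necrosis) with additive Gaussian noise inside the brain; the
background is exactly zero, as in skull-stripped BRATS volumes.  Tumors are
small relative to the volume, which reproduces the severe background/
foreground class imbalance the losses are designed for.

Limitations by design: no realistic anatomy, no bias field, single focal
tumor, Gaussian (not Rician) noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_brats import write_labelmap, write_volume
from .types import MODALITIES, CaseSample, LabelVolume, ModalityVolume

# Mean intensity per (modality, tissue).  Arbitrary units, fixed; chosen for
# clinical-like contrast and comfortable separability at the default noise.
DEFAULT_INTENSITY_TABLE: dict[str, dict[str, float]] = {
    "T1":    {"brain": 100.0, "necrosis": 40.0, "edema": 80.0, "nonenh": 70.0, "enh": 90.0},
    "T1c":   {"brain": 100.0, "necrosis": 45.0, "edema": 90.0, "nonenh": 80.0, "enh": 160.0},
    "T2":    {"brain": 100.0, "necrosis": 130.0, "edema": 140.0, "nonenh": 115.0, "enh": 110.0},
    "FLAIR": {"brain": 100.0, "necrosis": 70.0, "edema": 160.0, "nonenh": 120.0, "enh": 115.0},
}

_TISSUE_OF_LABEL = {1: "necrosis", 2: "edema", 3: "nonenh", 4: "enh"}


@dataclass
class PhantomParams:
    """Geometry, contrast and noise settings of the phantom cohort."""

    volume_shape: tuple[int, int, int] = (64, 64, 32)
    #: Semi-axis of the brain ellipsoid as a fraction of each half-dimension.
    brain_axes: tuple[float, float, float] = (0.84, 0.88, 0.86)
    #: Probability that a case carries a tumor (BRATS cases always do).
    tumor_probability: float = 1.0
    #: Edema semi-axis range, fraction of each half-dimension.
    edema_radius_range: tuple[float, float] = (0.30, 0.42)
    #: Core boundary as a fraction of the edema radius (edema > core).
    core_fraction_range: tuple[float, float] = (0.55, 0.70)
    #: Necrotic center as a fraction of the core radius.
    necrosis_fraction: float = 0.45
    #: Inner edge of the enhancing rim as a fraction of the core radius
    #: (necrosis < non-enhancing < enhancing rim).
    enhancing_inner_fraction: float = 0.80
    #: Amplitude of the smooth boundary perturbation (distance-field units).
    boundary_roughness: float = 0.08
    noise_sd: float = 10.0
    intensity_table: dict[str, dict[str, float]] = field(
        default_factory=lambda: {m: dict(v) for m, v in DEFAULT_INTENSITY_TABLE.items()}
    )

    def __post_init__(self) -> None:
        if len(self.volume_shape) != 3 or min(self.volume_shape) < 8:
            raise ValueError("volume_shape must be three dimensions, each >= 8")
        if not 0.0 <= self.tumor_probability <= 1.0:
            raise ValueError("tumor_probability must be in [0, 1]")
        if not 0.0 < self.necrosis_fraction < self.enhancing_inner_fraction < 1.0:
            raise ValueError(
                "need 0 < necrosis_fraction < enhancing_inner_fraction < 1 "
                "(nesting necrosis < non-enhancing < enhancing rim)"
            )
        lo, hi = self.core_fraction_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("core_fraction_range must lie in (0, 1): core < edema")
        lo, hi = self.edema_radius_range
        if not 0.0 < lo <= hi <= 0.5 + 1e-9:
            # cap so the edema stays inside the brain half-dimension
            raise ValueError("edema_radius_range must lie in (0, 0.5]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _ellipsoid_rho(
    shape: tuple[int, int, int],
    center: np.ndarray,
    semi_axes: np.ndarray,
) -> np.ndarray:
    """Normalized ellipsoidal distance (<= 1 inside) on the voxel grid."""
    grids = np.meshgrid(*(np.arange(n, dtype=np.float64) for n in shape), indexing="ij")
    rho2 = np.zeros(shape, np.float64)
    for g, c, a in zip(grids, center, semi_axes):
        rho2 += ((g - c) / a) ** 2
    return np.sqrt(rho2)


def generate_case(
    params: PhantomParams, seed: int, case_id: Optional[str] = None
) -> CaseSample:
    """Generate one phantom case with labels; bitwise deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    shape = params.volume_shape
    half = np.array(shape, np.float64) / 2.0

    # Brain ellipsoid, slightly jittered around the volume center.
    brain_center = half + rng.uniform(-0.02, 0.02, 3) * np.array(shape)
    brain_axes = np.array(params.brain_axes) * half
    brain = _ellipsoid_rho(shape, brain_center, brain_axes) <= 1.0

    labels = np.zeros(shape, np.uint8)
    has_tumor = rng.random() < params.tumor_probability
    if has_tumor:
        # Tumor center well inside the brain so the nested shells fit.
        offset = rng.uniform(-0.25, 0.25, 3) * brain_axes
        center = brain_center + offset
        edema_axes = rng.uniform(*params.edema_radius_range) * half
        core_frac = rng.uniform(*params.core_fraction_range)

        # One smooth low-frequency field perturbs every shell identically, so
        # thresholding it at increasing radii preserves the nesting exactly.
        rough = gaussian_filter(rng.normal(size=shape), sigma=min(shape) / 6.0)
        sd = rough.std()
        if sd > 0:
            rough = rough / sd * params.boundary_roughness
        rho = _ellipsoid_rho(shape, center, edema_axes) + rough

        core_r = core_frac
        necro_r = params.necrosis_fraction * core_frac
        enh_inner_r = params.enhancing_inner_fraction * core_frac
        labels[rho <= 1.0] = 2                # edema shell
        labels[rho <= core_r] = 4             # enhancing rim (outer core)
        labels[rho <= enh_inner_r] = 3        # non-enhancing tumor
        labels[rho <= necro_r] = 1            # necrotic center
        labels[~brain] = 0                    # tumor clipped at the brain mask

    volumes: dict[str, ModalityVolume] = {}
    for m in MODALITIES:
        table = params.intensity_table[m]
        img = np.zeros(shape, np.float64)
        img[brain] = table["brain"]
        for lab, tissue in _TISSUE_OF_LABEL.items():
            img[labels == lab] = table[tissue]
        if params.noise_sd > 0:
            img[brain] += rng.normal(0.0, params.noise_sd, size=int(brain.sum()))
        volumes[m] = ModalityVolume(data=img.astype(np.float32), modality=m)

    cid = case_id or f"phantom_{seed:06d}"
    return CaseSample(case_id=cid, volumes=volumes, labels=LabelVolume(data=labels))


def generate_cohort(
    n_cases: int, params: Optional[PhantomParams] = None, seed: int = 0
) -> list[CaseSample]:
    """Generate ``n_cases`` in-memory phantoms with independent per-case seeds."""
    params = params or PhantomParams()
    child_seeds = np.random.SeedSequence(seed).generate_state(n_cases) % (2**31)
    return [
        generate_case(params, int(s), case_id=f"phantom_{i:03d}")
        for i, s in enumerate(child_seeds)
    ]


def generate_dataset(
    n_cases: int,
    params: Optional[PhantomParams] = None,
    seed: int = 0,
    out_dir: Union[str, Path] = "phantoms",
    format: str = "mha",
) -> Path:
    """Write a BRATS-layout phantom dataset readable by ``io_brats.index_dataset``.

    One folder per case, one file per modality plus an ``_OT`` ground truth.
    """
    ext = {"mha": ".mha", "nifti": ".nii"}.get(format)
    if ext is None:
        raise ValueError(f"unknown format {format!r}; expected 'mha' or 'nifti'")
    out_dir = Path(out_dir)
    for case in generate_cohort(n_cases, params, seed):
        case_dir = out_dir / case.case_id
        for m in MODALITIES:
            write_volume(case.volumes[m], case_dir / f"{case.case_id}_{m}{ext}")
        if case.labels is not None:
            write_labelmap(case.labels, case_dir / f"{case.case_id}_OT{ext}")
    return out_dir
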