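"""Cropping, z-score normalization, axial slicing and augmentation.

The pipeline mirrors the minimal pre-processing used for BRATS 2015 volumes:
a centered in-plane crop from 240x240 to 176x176 that removes only the empty
border while keeping the whole brain, then per-modality per-case zero-mean /
unit-variance normalization over all voxels of the cropped volume.  No bias
field correction, histogram matching or elastic deformation is applied.

Augmentation is restricted to flips and 90-degree rotation multiples: both
are label-exact (no interpolation) and apply the identical spatial map to the
image and the annotation.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Union

import numpy as np

from .types import MODALITIES, CaseSample, LabelVolume, ModalityVolume, SliceSample

logger = logging.getLogger(__name__)

DEFAULT_CROP_SIZE = 176


def _crop_offsets(shape: tuple[int, ...], crop_size: int) -> tuple[int, int]:
    """Centered in-plane crop offsets; (32, 32) for 240 -> 176."""
    ox = (shape[0] - crop_size) // 2
    oy = (shape[1] - crop_size) // 2
    return ox, oy


def crop_volume(data: np.ndarray, crop_size: int = DEFAULT_CROP_SIZE) -> np.ndarray:
    if data.shape[0] < crop_size or data.shape[1] < crop_size:
        raise ValueError(
            f"in-plane dimensions {data.shape[:2]} smaller than crop size {crop_size}"
        )
    ox, oy = _crop_offsets(data.shape, crop_size)
    return data[ox : ox + crop_size, oy : oy + crop_size, :]


def crop_case(case: CaseSample, crop_size: int = DEFAULT_CROP_SIZE) -> CaseSample:
    """Center-crop every modality (and the labels) to crop_size x crop_size in-plane.

    The crop window is identical across modalities and labels; Z is unchanged.
    """
    volumes = {
        m: ModalityVolume(
            data=crop_volume(case.volumes[m].data, crop_size),
            modality=m,
            spacing=case.volumes[m].spacing,
        )
        for m in MODALITIES
    }
    labels = None
    if case.labels is not None:
        labels = LabelVolume(
            data=crop_volume(case.labels.data, crop_size), spacing=case.labels.spacing
        )
    return CaseSample(case_id=case.case_id, volumes=volumes, labels=labels)


def zscore_normalize(volume: ModalityVolume) -> ModalityVolume:
    """Normalize a volume to zero mean and unit variance over all voxels.

    A constant volume has no scale to normalize by; it maps to all zeros and
    a warning is logged.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    mean = data.mean()
    sd = data.std()
    if sd == 0.0:
        logger.warning("constant volume (%s): z-scoring returns all zeros", volume.modality)
        out = np.zeros_like(data, dtype=np.float32)
    else:
        out = ((data - mean) / sd).astype(np.float32)
    return ModalityVolume(data=out, modality=volume.modality, spacing=volume.spacing)


def normalize_case(case: CaseSample) -> CaseSample:
    """Z-score every modality independently (per modality, per case)."""
    volumes = {m: zscore_normalize(case.volumes[m]) for m in MODALITIES}
    return CaseSample(case_id=case.case_id, volumes=volumes, labels=case.labels)


def _slice_is_empty(image: np.ndarray) -> bool:
    # Brain-content filter: a slice is "empty" when every pixel equals the
    # per-channel background value, taken from the (0, 0) corner.  This works
    # both before normalization (background exactly 0) and after (background
    # maps to a common constant).
    corner = image[0, 0, :]
    return bool(np.all(image == corner[None, None, :]))


def extract_slices(case: CaseSample, keep_empty: bool = True) -> list[SliceSample]:
    """Decompose a case into axial slices, channel order T1, T1c, T2, FLAIR.

    With ``keep_empty=False``, slices without brain content (all pixels equal
    to the background value) are dropped; prediction paths always keep all
    slices so volumes reassemble exactly.
    """
    stack = np.stack([case.volumes[m].data for m in MODALITIES], axis=-1)  # (X, Y, Z, 4)
    out: list[SliceSample] = []
    for z in range(stack.shape[2]):
        image = stack[:, :, z, :]
        if not keep_empty and _slice_is_empty(image):
            continue
        labels = case.labels.data[:, :, z] if case.labels is not None else None
        out.append(SliceSample(image=image, labels=labels, case_id=case.case_id, slice_index=z))
    return out


def assemble_volume(slices: Sequence[SliceSample]) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Restack slices (sorted by slice_index) into (X, Y, Z, 4) and (X, Y, Z)."""
    ordered = sorted(slices, key=lambda s: s.slice_index)
    image = np.stack([s.image for s in ordered], axis=2)
    labels = None
    if all(s.labels is not None for s in ordered):
        labels = np.stack([s.labels for s in ordered], axis=2)
    return image, labels


def apply_flip_rotation(
    s: SliceSample, flip_h: bool = False, flip_v: bool = False, k90: int = 0
) -> SliceSample:
    """Apply an identical flip/90-degree-rotation map to image and labels."""
    image = s.image
    labels = s.labels
    if flip_h:
        image = image[:, ::-1, :]
        labels = labels[:, ::-1] if labels is not None else None
    if flip_v:
        image = image[::-1, :, :]
        labels = labels[::-1, :] if labels is not None else None
    k90 %= 4
    if k90:
        image = np.rot90(image, k=k90, axes=(0, 1))
        labels = np.rot90(labels, k=k90, axes=(0, 1)) if labels is not None else None
    return SliceSample(
        image=np.ascontiguousarray(image),
        labels=np.ascontiguousarray(labels) if labels is not None else None,
        case_id=s.case_id,
        slice_index=s.slice_index,
    )


def augment(
    s: SliceSample,
    seed: Union[int, np.random.Generator],
    flips: bool = True,
    rotations: bool = True,
) -> SliceSample:
    """Random flip + 90-degree-multiple rotation; deterministic given ``seed``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flip_h = flips and bool(rng.integers(0, 2))
    flip_v = flips and bool(rng.integers(0, 2))
    k90 = int(rng.integers(0, 4)) if rotations else 0
    return apply_flip_rotation(s, flip_h=flip_h, flip_v=flip_v, k90=k90)
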