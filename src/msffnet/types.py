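"""Core domain containers for multimodal brain-MRI segmentation.

The canonical axis order everywhere in the package is (X, Y, Z) with axial
slices taken along Z.  The label taxonomy is the BRATS 2015 one:
0 background (everything that is not tumor), 1 necrosis, 2 edema,
3 non-enhancing tumor, 4 enhancing tumor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Fixed modality order used for channel stacking throughout the package.
MODALITIES: tuple[str, ...] = ("T1", "T1c", "T2", "FLAIR")

#: Allowed label values.
LABEL_SET: frozenset[int] = frozenset({0, 1, 2, 3, 4})

#: Number of segmentation classes (background + four tumor tissues).
NUM_CLASSES: int = 5


def validate_labels(data: np.ndarray) -> None:
    """Raise ``ValueError`` naming the first offending value outside {0..4}."""
    bad = np.setdiff1d(np.unique(data), np.array(sorted(LABEL_SET)))
    if bad.size:
        raise ValueError(
            f"label volume contains invalid value {int(bad[0])}; allowed values are 0..4"
        )


@dataclass
class ModalityVolume:
    """One 3-D intensity array for one MRI sequence of one case."""

    data: np.ndarray
    modality: str = "T1"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must have 3 axes, got {self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("all volume dimensions must be >= 1")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three strictly positive values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class LabelVolume:
    """3-D integer annotation volume with values in {0..4}."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    label_set: frozenset[int] = field(default=LABEL_SET, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must have 3 axes, got {self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise ValueError("label volume must hold integers")
            self.data = rounded.astype(np.uint8)
        validate_labels(self.data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class CaseSample:
    """Four co-registered modality volumes plus an optional label volume."""

    case_id: str
    volumes: dict[str, ModalityVolume]
    labels: Optional[LabelVolume] = None

    def __post_init__(self) -> None:
        missing = [m for m in MODALITIES if m not in self.volumes]
        if missing:
            raise ValueError(f"case {self.case_id!r} is missing modalities: {missing}")
        shapes = {m: self.volumes[m].shape for m in MODALITIES}
        ref = shapes[MODALITIES[0]]
        if any(s != ref for s in shapes.values()):
            raise ValueError(f"case {self.case_id!r} has mismatched volume shapes: {shapes}")
        if self.labels is not None and self.labels.shape != ref:
            raise ValueError(
                f"case {self.case_id!r}: label shape {self.labels.shape} != volume shape {ref}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes[MODALITIES[0]].shape

    def modality_array(self, modality: str) -> np.ndarray:
        return self.volumes[modality].data


@dataclass
class SliceSample:
    """One axial slice: (H, W, 4) image in modality order T1, T1c, T2, FLAIR."""

    image: np.ndarray
    labels: Optional[np.ndarray]
    case_id: str = ""
    slice_index: int = 0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 3 or self.image.shape[2] != len(MODALITIES):
            raise ValueError(f"slice image must be (H, W, 4), got {self.image.shape}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != self.image.shape[:2]:
                raise ValueError("slice labels must match image in-plane shape")
            validate_labels(self.labels)
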