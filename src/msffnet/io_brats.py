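"""Read/write BRATS-style multimodal cases in MHA and NIfTI, and index a dataset tree.

Dataset layout (one folder per case, one file per modality, BRATS-like):

    root/
      case_0001/
        case_0001_T1.mha
        case_0001_T1c.mha
        case_0001_T2.mha
        case_0001_Flair.mha
        case_0001_OT.mha        # optional ground truth

A modality file is recognised by an exact token match (split on non-alphanumeric
characters) against T1 / T1c / T2 / Flair, case-insensitively, so the real BRATS
names like ``VSD.Brain.XX.O.MR_T1c.54513.mha`` parse as well.  Ground-truth
files are recognised by the tokens OT / seg / label(s) / truth.

On disk, images follow the usual ITK convention; in memory the package uses
(X, Y, Z) axis order with Z as the axial slice axis, and axis order is never
reordered beyond that fixed transpose (reading back a written volume returns
the identical array).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import SimpleITK as sitk

from .types import MODALITIES, CaseSample, LabelVolume, ModalityVolume, validate_labels

logger = logging.getLogger(__name__)

_LABEL_TOKENS = {"ot", "seg", "segmentation", "label", "labels", "truth", "gt"}
_SUFFIXES = (".mha", ".mhd", ".nii", ".nii.gz")


def _tokens(name: str) -> list[str]:
    return [t for t in re.split(r"[^A-Za-z0-9]+", name) if t]


def _matches_modality(filename: str, modality: str) -> bool:
    toks = {t.lower() for t in _tokens(Path(filename).name)}
    return modality.lower() in toks


def _is_label_file(filename: str) -> bool:
    toks = {t.lower() for t in _tokens(Path(filename).name)}
    return bool(toks & _LABEL_TOKENS)


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _SUFFIXES):
        raise ValueError(f"unsupported volume format: {path.name} (expected one of {_SUFFIXES})")


def read_volume(
    path: Union[str, Path], kind: str = "intensity", modality: str = "T1"
) -> Union[ModalityVolume, LabelVolume]:
    """Read an MHA or NIfTI volume as (X, Y, Z).

    ``kind`` is ``"intensity"`` or ``"label"``; label reads reject any voxel
    value outside {0..4}.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    _check_suffix(path)
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (Z, Y, X)
    arr = np.ascontiguousarray(arr.transpose(2, 1, 0))  # -> (X, Y, Z)
    spacing = tuple(float(s) for s in img.GetSpacing())  # already (X, Y, Z)
    if kind == "label":
        validate_labels(arr)
        return LabelVolume(data=arr.astype(np.uint8), spacing=spacing)  # type: ignore[arg-type]
    if kind != "intensity":
        raise ValueError(f"kind must be 'intensity' or 'label', got {kind!r}")
    return ModalityVolume(data=arr, modality=modality, spacing=spacing)  # type: ignore[arg-type]


def _write_array(data: np.ndarray, spacing: tuple[float, float, float], path: Path) -> None:
    _check_suffix(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    path.parent.mkdir(parents=True, exist_ok=True)
    sitk.WriteImage(img, str(path))


def write_volume(volume: ModalityVolume, path: Union[str, Path]) -> Path:
    """Write an intensity volume; the format follows the file suffix."""
    path = Path(path)
    _write_array(np.asarray(volume.data, dtype=np.float32), volume.spacing, path)
    return path


def write_labelmap(labels: LabelVolume, path: Union[str, Path], format: Optional[str] = None) -> Path:
    """Write a label volume as uint8; ``format`` ('mha'|'nifti') overrides the suffix."""
    path = Path(path)
    if format is not None:
        ext = {"mha": ".mha", "nifti": ".nii", "nii": ".nii"}.get(format)
        if ext is None:
            raise ValueError(f"unknown format {format!r}; expected 'mha' or 'nifti'")
        if not path.name.lower().endswith(ext):
            path = path.with_suffix(ext)
    _write_array(labels.data.astype(np.uint8), labels.spacing, path)
    return path


@dataclass
class CaseFiles:
    """Descriptor of one on-disk case: paths per modality + optional truth."""

    case_id: str
    modality_paths: dict[str, Path]
    label_path: Optional[Path] = None


@dataclass
class DatasetIndex:
    """Complete cases plus a report of incomplete (skipped) ones."""

    cases: list[CaseFiles] = field(default_factory=list)
    skipped: list[tuple[str, list[str]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cases)


def index_dataset(root: Union[str, Path]) -> DatasetIndex:
    """Index per-case subdirectories of ``root``.

    A case is complete when all four modality files are present; incomplete
    cases are reported in ``skipped`` (case id + missing modalities), never
    silently dropped.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root is not a directory: {root}")
    index = DatasetIndex()
    case_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not case_dirs:
        logger.warning("dataset root %s contains no case directories", root)
        return index
    for case_dir in case_dirs:
        files = sorted(
            f for f in case_dir.iterdir()
            if f.is_file() and any(f.name.lower().endswith(s) for s in _SUFFIXES)
        )
        modality_paths: dict[str, Path] = {}
        label_path: Optional[Path] = None
        for f in files:
            if _is_label_file(f.name):
                label_path = f
                continue
            for m in MODALITIES:
                if m not in modality_paths and _matches_modality(f.name, m):
                    modality_paths[m] = f
                    break
        missing = [m for m in MODALITIES if m not in modality_paths]
        if missing:
            logger.warning("case %s skipped: missing modalities %s", case_dir.name, missing)
            index.skipped.append((case_dir.name, missing))
        else:
            index.cases.append(CaseFiles(case_dir.name, modality_paths, label_path))
    return index


def load_case(descriptor: CaseFiles) -> CaseSample:
    """Load all volumes of an indexed case into a :class:`CaseSample`."""
    volumes = {
        m: read_volume(descriptor.modality_paths[m], kind="intensity", modality=m)
        for m in MODALITIES
    }
    labels = None
    if descriptor.label_path is not None:
        labels = read_volume(descriptor.label_path, kind="label")
    return CaseSample(case_id=descriptor.case_id, volumes=volumes, labels=labels)  # type: ignore[arg-type]


def load_dataset(root: Union[str, Path]) -> list[CaseSample]:
    """Index ``root`` and load every complete case."""
    return [load_case(d) for d in index_dataset(root).cases]
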