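"""Label algebra: one-hot encoding and the composite evaluation regions.

The three overlapping evaluation regions used by the BRATS scoring protocol
are defined over the raw labels:

* complete tumor  = labels {1, 2, 3, 4}
* tumor core      = labels {1, 3, 4}
* enhancing tumor = label  {4}

Channel index k always equals the raw label value (channel 0 = background,
channel 4 = enhancing), so the subscripts of every probability expression
match the label taxonomy one-to-one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import NUM_CLASSES, validate_labels


@dataclass(frozen=True)
class RegionSpec:
    """A named evaluation region: a subset of label values."""

    name: str
    member_labels: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.member_labels:
            raise ValueError("region must have at least one member label")
        if any(l not in range(NUM_CLASSES) for l in self.member_labels):
            raise ValueError(f"region {self.name!r} has labels outside 0..4")


REGIONS: dict[str, RegionSpec] = {
    "background": RegionSpec("background", (0,)),
    "complete": RegionSpec("complete", (1, 2, 3, 4)),
    "core": RegionSpec("core", (1, 3, 4)),
    "enhancing": RegionSpec("enhancing", (4,)),
}

#: The three tumor regions scored by the evaluation protocol, in report order.
EVAL_REGIONS: tuple[str, ...] = ("complete", "core", "enhancing")


def resolve_region(region: "str | RegionSpec") -> RegionSpec:
    if isinstance(region, RegionSpec):
        return region
    try:
        return REGIONS[region]
    except KeyError:
        raise ValueError(
            f"unknown region {region!r}; expected one of {sorted(REGIONS)}"
        ) from None


def one_hot(labels: np.ndarray, num_classes: int = NUM_CLASSES) -> np.ndarray:
    """Encode an integer label array as a (..., K) one-hot float array.

    Raises ``ValueError`` for labels outside ``0..num_classes-1``.
    """
    labels = np.asarray(labels)
    if labels.size and (labels.min() < 0 or labels.max() >= num_classes):
        bad = labels[(labels < 0) | (labels >= num_classes)].flat[0]
        raise ValueError(f"label {int(bad)} outside 0..{num_classes - 1}")
    out = np.zeros(labels.shape + (num_classes,), dtype=np.float32)
    np.put_along_axis(out, labels[..., None].astype(np.int64), 1.0, axis=-1)
    return out


def region_soft(probs: np.ndarray, region: "str | RegionSpec") -> np.ndarray:
    """Per-pixel sum of the member-label probability channels.

    ``probs`` is (..., K); the result drops the channel axis.  On a one-hot
    map this equals the hard region mask of the argmax labels.
    """
    spec = resolve_region(region)
    probs = np.asarray(probs)
    if probs.shape[-1] != NUM_CLASSES:
        raise ValueError(f"probability map must have {NUM_CLASSES} channels")
    return probs[..., list(spec.member_labels)].sum(axis=-1)


def region_hard(labels: np.ndarray, region: "str | RegionSpec") -> np.ndarray:
    """Binary mask: 1 where the label belongs to the region, 0 elsewhere."""
    spec = resolve_region(region)
    labels = np.asarray(labels)
    validate_labels(labels)
    return np.isin(labels, spec.member_labels)
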