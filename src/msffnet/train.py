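"""Training with cyclical learning rates, slice-wise prediction and ensembling.

Training follows the published recipe: Adam with a triangular cyclical
learning-rate schedule between 1e-6 and 1e-3, batch size 40, flip/rotation
augmentation, loss selectable among {ce, sliced_dice, combined_dice, hl1,
hl2}, and best-checkpoint selection on the validation loss.  Dataset splits
are always by case, never by slice, so no patient leaks across partitions.

Prediction runs the model slice by slice over all axial indices of a case
and restacks the per-pixel argmax into a label volume; an ensemble averages
the softmax probability maps of its members before the argmax.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import preprocess
from .losses import DEFAULT_WEIGHTS, LOSS_REGISTRY, LossWeights
from .metrics import dsc
from .model import _Network, load_checkpoint
from .regions import EVAL_REGIONS, one_hot, region_hard
from .nn import Adam, F32
from .types import MODALITIES, CaseSample, LabelVolume

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the published recipe."""

    batch_size: int = 40
    lr_min: float = 1e-6
    lr_max: float = 1e-3
    #: Iterations per half-cycle of the triangular schedule.
    cycle_length: int = 400
    epochs: int = 10
    loss: str = "hl2"
    loss_weights: Optional[LossWeights] = None
    augment: bool = True
    keep_empty_slices: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.lr_min < self.lr_max:
            raise ValueError("need 0 < lr_min < lr_max")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.cycle_length < 1:
            raise ValueError("cycle_length must be >= 1")
        if self.loss not in LOSS_REGISTRY:
            raise ValueError(f"unknown loss {self.loss!r}; choose from {sorted(LOSS_REGISTRY)}")


@dataclass
class SplitSpec:
    """Case-level train/validation split."""

    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")


def cyclical_lr(iteration: int, cfg: TrainConfig) -> float:
    """Triangular cyclical learning rate.

    Rises linearly from ``lr_min`` at iteration 0 to ``lr_max`` after
    ``cycle_length`` iterations, falls back linearly, and repeats with
    period ``2 * cycle_length``.
    """
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    L = cfg.cycle_length
    pos = iteration % (2 * L)
    frac = pos / L if pos <= L else (2 * L - pos) / L
    return cfg.lr_min + (cfg.lr_max - cfg.lr_min) * frac


def split_dataset(
    cases: Sequence[CaseSample], spec: Optional[SplitSpec] = None
) -> tuple[list[CaseSample], list[CaseSample]]:
    """Disjoint, exhaustive, reproducible case-level split."""
    spec = spec or SplitSpec()
    n = len(cases)
    if n < 2:
        raise ValueError("need at least 2 cases to split")
    n_val = int(round(spec.validation_fraction * n))
    n_val = min(max(n_val, 1), n - 1)
    order = np.random.default_rng(spec.seed).permutation(n)
    val_idx = set(order[:n_val].tolist())
    train = [cases[i] for i in range(n) if i not in val_idx]
    val = [cases[i] for i in range(n) if i in val_idx]
    return train, val


def _prepare_case(case: CaseSample, input_size: int) -> CaseSample:
    """Center-crop to the model's input size (if larger) and z-score normalize."""
    if case.shape[0] != input_size or case.shape[1] != input_size:
        case = preprocess.crop_case(case, crop_size=input_size)
    return preprocess.normalize_case(case)


def _cases_to_arrays(
    cases: Sequence[CaseSample], input_size: int, keep_empty: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Stack preprocessed axial slices: (N, H, W, 4) images + (N, H, W) labels."""
    images, labels = [], []
    for case in cases:
        if case.labels is None:
            raise ValueError(f"case {case.case_id!r} has no labels; cannot train on it")
        prepared = _prepare_case(case, input_size)
        for s in preprocess.extract_slices(prepared, keep_empty=keep_empty):
            images.append(s.image)
            labels.append(s.labels)
    if not images:
        raise ValueError("no slices extracted from the given cases")
    return (
        np.stack(images).astype(F32),
        np.stack(labels).astype(np.uint8),
    )


def _augment_batch(
    xb: np.ndarray, yb: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Random per-sample flip + 90-degree rotation (image and labels together)."""
    xb = xb.copy()
    yb = yb.copy()
    flips_h = rng.integers(0, 2, len(xb))
    flips_v = rng.integers(0, 2, len(xb))
    rots = rng.integers(0, 4, len(xb))
    for i in range(len(xb)):
        xi, yi = xb[i], yb[i]
        if flips_h[i]:
            xi, yi = xi[:, ::-1], yi[:, ::-1]
        if flips_v[i]:
            xi, yi = xi[::-1], yi[::-1]
        if rots[i]:
            xi = np.rot90(xi, k=int(rots[i]), axes=(0, 1))
            yi = np.rot90(yi, k=int(rots[i]), axes=(0, 1))
        xb[i], yb[i] = xi, yi
    return xb, yb


def _forward_in_batches(model: _Network, X: np.ndarray, batch_size: int) -> np.ndarray:
    out = []
    for i in range(0, len(X), batch_size):
        out.append(model.forward(X[i : i + batch_size], training=False))
    return np.concatenate(out, axis=0)


@dataclass
class TrainResult:
    """History, the best (lowest validation loss) weights, and the live model."""

    history: pd.DataFrame
    best_state: list[np.ndarray]
    best_epoch: int
    best_val_loss: float
    model: _Network = field(repr=False)

    def restore_best(self) -> _Network:
        self.model.restore(self.best_state)
        return self.model


def train(
    model: _Network,
    train_cases: Sequence[CaseSample],
    val_cases: Sequence[CaseSample],
    cfg: Optional[TrainConfig] = None,
) -> TrainResult:
    """Optimize ``model`` on slice batches; select weights on validation loss.

    Records per-epoch mean training loss, validation loss and validation
    region DSC (computed on pooled validation slices).  Aborts with a
    diagnostic if the loss turns non-finite.
    """
    cfg = cfg or TrainConfig()
    if not train_cases:
        raise ValueError("training set is empty")
    if not val_cases:
        raise ValueError("validation set is empty")
    input_size = model.cfg.input_size
    Xtr, Ytr = _cases_to_arrays(train_cases, input_size, cfg.keep_empty_slices)
    Xva, Yva = _cases_to_arrays(val_cases, input_size, keep_empty=True)

    loss_fn = LOSS_REGISTRY[cfg.loss]
    weights = cfg.loss_weights or DEFAULT_WEIGHTS.get(cfg.loss)
    rng = np.random.default_rng(cfg.seed)
    model.reseed_dropout(cfg.seed + 1)
    optimizer = Adam(model.params())

    history_rows = []
    best_state: Optional[list[np.ndarray]] = None
    best_val = np.inf
    best_epoch = -1
    iteration = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(Xtr))
        epoch_losses = []
        for b0 in range(0, len(order), cfg.batch_size):
            idx = order[b0 : b0 + cfg.batch_size]
            xb, yb = Xtr[idx], Ytr[idx]
            if cfg.augment:
                xb, yb = _augment_batch(xb, yb, rng)
            P = model.forward(xb, training=True)
            G = one_hot(yb)
            value, dP = loss_fn(P, G, weights)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged: loss={value} at epoch {epoch}, iteration {iteration} "
                    f"(loss={cfg.loss!r}, lr={cyclical_lr(iteration, cfg):.2e})"
                )
            optimizer.zero_grad()
            model.backward(dP.astype(F32))
            optimizer.step(cyclical_lr(iteration, cfg))
            epoch_losses.append(value)
            iteration += 1

        Pva = _forward_in_batches(model, Xva, cfg.batch_size)
        val_loss, _ = loss_fn(Pva, one_hot(Yva), weights)
        pred_va = np.argmax(Pva, axis=-1).astype(np.uint8)
        row = {
            "epoch": epoch,
            "train_loss": float(np.mean(epoch_losses)),
            "val_loss": float(val_loss),
            "lr_last": cyclical_lr(iteration - 1, cfg),
        }
        for region in EVAL_REGIONS:
            row[f"val_dsc_{region}"] = dsc(
                region_hard(pred_va, region), region_hard(Yva, region)
            )
        if val_loss < best_val:
            best_val = float(val_loss)
            best_state = model.snapshot()
            best_epoch = epoch
        row["best_val_loss"] = best_val
        history_rows.append(row)
        logger.info(
            "epoch %d: train %.4f, val %.4f, complete DSC %.3f",
            epoch, row["train_loss"], row["val_loss"], row["val_dsc_complete"],
        )

    assert best_state is not None
    return TrainResult(
        history=pd.DataFrame(history_rows),
        best_state=best_state,
        best_epoch=best_epoch,
        best_val_loss=best_val,
        model=model,
    )


class Ensemble:
    """Averages member softmax maps before the argmax (or majority-votes)."""

    def __init__(self, models: Sequence[_Network], fusion: str = "mean"):
        if not models:
            raise ValueError("ensemble needs at least one member")
        if fusion not in ("mean", "vote"):
            raise ValueError("fusion must be 'mean' or 'vote'")
        self.models = list(models)
        self.fusion = fusion

    @property
    def cfg(self):
        return self.models[0].cfg

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if self.fusion == "mean":
            acc = self.models[0].forward(x, training=False)
            for m in self.models[1:]:
                acc = acc + m.forward(x, training=False)
            return acc / len(self.models)
        # majority vote: one-hot each member's argmax, then average
        counts = None
        for m in self.models:
            p = m.forward(x, training=False)
            votes = one_hot(np.argmax(p, axis=-1))
            counts = votes if counts is None else counts + votes
        return counts / len(self.models)


def build_ensemble(
    checkpoints: Sequence[Union[str, Path]], fusion: str = "mean"
) -> Ensemble:
    """Load checkpoint files into an ensemble predictor."""
    return Ensemble([load_checkpoint(p) for p in checkpoints], fusion=fusion)


def predict_case(
    model: Union[_Network, Ensemble], case: CaseSample, batch_size: int = 16
) -> LabelVolume:
    """Segment one case: per-slice forward pass, per-pixel argmax, restack.

    The case is preprocessed identically to training (center crop to the
    model input size, per-modality z-scoring); all axial slices are processed
    so the output Z extent equals the case's.
    """
    input_size = model.cfg.input_size
    prepared = _prepare_case(case, input_size)
    stack = np.stack(
        [prepared.volumes[m].data for m in MODALITIES], axis=-1
    )  # (X, Y, Z, 4)
    X = np.ascontiguousarray(stack.transpose(2, 0, 1, 3)).astype(F32)  # (Z, H, W, 4)
    probs = _forward_in_batches(model, X, batch_size)
    pred = np.argmax(probs, axis=-1).astype(np.uint8)  # (Z, H, W)
    return LabelVolume(data=np.ascontiguousarray(pred.transpose(1, 2, 0)))
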