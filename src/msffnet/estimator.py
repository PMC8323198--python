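"""Scikit-learn-style estimator wrapping model building, training and prediction."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .losses import LossWeights
from .metrics import evaluate_cohort
from .model import MSFFNet, NetConfig
from .train import SplitSpec, TrainConfig, predict_case, split_dataset, train
from .types import CaseSample, LabelVolume


class MultiScaleSegmenter(BaseEstimator):
    """Multi-scale feature-fusion brain-tumor segmenter.

    ``fit`` takes a list of :class:`CaseSample` with labels (an internal
    case-level split provides the validation set for best-checkpoint
    selection), ``predict`` returns one :class:`LabelVolume` per case, and
    ``score`` is the mean complete-tumor DSC.  All constructor arguments are
    sklearn-style hyper-parameters, so the estimator composes with ``clone``
    and model selection.

    Parameters follow the package defaults: input size 176, stage channels
    (16, 32, 64, 128, 256) with (4, 2, 2, 2, 2) conv units, fusing width 64,
    HL2 loss, Adam with a triangular cyclical learning rate in [1e-6, 1e-3],
    batch size 40, flip/90-degree-rotation augmentation.
    """

    def __init__(
        self,
        input_size: int = 176,
        stage_channels: tuple[int, ...] = (16, 32, 64, 128, 256),
        stage_units: tuple[int, ...] = (4, 2, 2, 2, 2),
        fusing_channels: int = 64,
        dropout_rate: float = 0.2,
        loss: str = "hl2",
        loss_weights: Optional[LossWeights] = None,
        batch_size: int = 40,
        epochs: int = 10,
        lr_min: float = 1e-6,
        lr_max: float = 1e-3,
        cycle_length: int = 400,
        validation_fraction: float = 0.2,
        augment: bool = True,
        keep_empty_slices: bool = False,
        random_state: int = 0,
    ):
        self.input_size = input_size
        self.stage_channels = stage_channels
        self.stage_units = stage_units
        self.fusing_channels = fusing_channels
        self.dropout_rate = dropout_rate
        self.loss = loss
        self.loss_weights = loss_weights
        self.batch_size = batch_size
        self.epochs = epochs
        self.lr_min = lr_min
        self.lr_max = lr_max
        self.cycle_length = cycle_length
        self.validation_fraction = validation_fraction
        self.augment = augment
        self.keep_empty_slices = keep_empty_slices
        self.random_state = random_state

    def _net_config(self) -> NetConfig:
        return NetConfig(
            input_size=self.input_size,
            stage_channels=tuple(self.stage_channels),
            stage_units=tuple(self.stage_units),
            fusing_channels=self.fusing_channels,
            dropout_rate=self.dropout_rate,
            seed=self.random_state,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            batch_size=self.batch_size,
            lr_min=self.lr_min,
            lr_max=self.lr_max,
            cycle_length=self.cycle_length,
            epochs=self.epochs,
            loss=self.loss,
            loss_weights=self.loss_weights,
            augment=self.augment,
            keep_empty_slices=self.keep_empty_slices,
            seed=self.random_state,
        )

    def fit(self, X: Sequence[CaseSample], y=None) -> "MultiScaleSegmenter":
        """Train on labeled cases; the validation split selects the best weights."""
        cases = list(X)
        tr, va = split_dataset(
            cases, SplitSpec(self.validation_fraction, seed=self.random_state)
        )
        model = MSFFNet(self._net_config())
        result = train(model, tr, va, self._train_config())
        result.restore_best()
        self.model_ = model
        self.history_ = result.history
        self.best_epoch_ = result.best_epoch
        self.best_val_loss_ = result.best_val_loss
        self.classes_ = np.arange(model.cfg.num_classes)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit() first")

    def predict(self, X: Sequence[CaseSample]) -> list[LabelVolume]:
        self._check_fitted()
        return [predict_case(self.model_, case, batch_size=self.batch_size) for case in X]

    def score(self, X: Sequence[CaseSample], y=None) -> float:
        """Mean complete-tumor DSC over labeled cases."""
        self._check_fitted()
        preds = self.predict(X)
        pairs = []
        for case, pred in zip(X, preds):
            if case.labels is None:
                raise ValueError(f"case {case.case_id!r} has no labels to score against")
            truth = case.labels
            if truth.shape != pred.shape:
                from .preprocess import crop_case

                truth = crop_case(case, self.input_size).labels
            pairs.append((pred, truth))
        mean_report, _ = evaluate_cohort(pairs)
        return float(mean_report["complete"].dsc)
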