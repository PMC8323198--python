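"""Region-wise segmentation scoring: DSC, PPV and Sensitivity.

Replicates the shape of the BRATS online scoring: for each of the three
overlapping evaluation regions (complete, core, enhancing) the prediction and
the ground truth are binarized on the whole 3-D volume of a case and

* DSC         = 2|P n G| / (|P| + |G|)
* PPV         = |P n G| / |P|        (precision)
* Sensitivity = |P n G| / |G|        (recall)

Degenerate masks follow the convention that a correct all-negative prediction
is perfect: both masks empty -> 1; exactly one empty -> 0.  (The online
system's own rule for empty masks is undocumented; this choice never
penalizes a correct absence call.)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .regions import EVAL_REGIONS, region_hard
from .types import LabelVolume

METRICS = ("dsc", "ppv", "sensitivity")


def _binary(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def _check_shapes(P: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    P, G = _binary(P), _binary(G)
    if P.shape != G.shape:
        raise ValueError(f"mask shape mismatch: {P.shape} vs {G.shape}")
    return P, G


def dsc(P: np.ndarray, G: np.ndarray) -> float:
    """Dice similarity coefficient of two binary masks."""
    P, G = _check_shapes(P, G)
    np_, ng = int(P.sum()), int(G.sum())
    if np_ + ng == 0:
        return 1.0
    return 2.0 * int((P & G).sum()) / (np_ + ng)


def ppv(P: np.ndarray, G: np.ndarray) -> float:
    """Positive predictive value (precision) of P against G."""
    P, G = _check_shapes(P, G)
    np_ = int(P.sum())
    if np_ == 0:
        return 1.0 if int(G.sum()) == 0 else 0.0
    return int((P & G).sum()) / np_


def sensitivity(P: np.ndarray, G: np.ndarray) -> float:
    """Sensitivity (recall) of P against G."""
    P, G = _check_shapes(P, G)
    ng = int(G.sum())
    if ng == 0:
        return 1.0 if int(P.sum()) == 0 else 0.0
    return int((P & G).sum()) / ng


@dataclass
class RegionScores:
    """Metrics and raw counts for one evaluation region."""

    dsc: float
    ppv: float
    sensitivity: float
    n_pred: int
    n_truth: int
    n_overlap: int


@dataclass
class RegionReport:
    """DSC/PPV/Sensitivity for the three evaluation regions of one case or cohort."""

    scores: dict[str, RegionScores]

    def __getitem__(self, region: str) -> RegionScores:
        return self.scores[region]

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {
            r: {m: getattr(s, m) for m in METRICS} for r, s in self.scores.items()
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"region": r, **{m: getattr(s, m) for m in METRICS},
                 "n_pred": s.n_pred, "n_truth": s.n_truth, "n_overlap": s.n_overlap}
                for r, s in self.scores.items()
            ]
        )


def _labels_array(vol: Union[LabelVolume, np.ndarray]) -> np.ndarray:
    return vol.data if isinstance(vol, LabelVolume) else np.asarray(vol)


def evaluate_case(
    pred: Union[LabelVolume, np.ndarray], truth: Union[LabelVolume, np.ndarray]
) -> RegionReport:
    """Score one case: all three metrics for all three regions on 3-D masks."""
    p = _labels_array(pred)
    g = _labels_array(truth)
    if p.shape != g.shape:
        raise ValueError(f"prediction shape {p.shape} != truth shape {g.shape}")
    scores: dict[str, RegionScores] = {}
    for region in EVAL_REGIONS:
        pm = region_hard(p, region)
        gm = region_hard(g, region)
        scores[region] = RegionScores(
            dsc=dsc(pm, gm),
            ppv=ppv(pm, gm),
            sensitivity=sensitivity(pm, gm),
            n_pred=int(pm.sum()),
            n_truth=int(gm.sum()),
            n_overlap=int((pm & gm).sum()),
        )
    return RegionReport(scores)


def evaluate_cohort(
    cases: Sequence[tuple[Union[LabelVolume, np.ndarray], Union[LabelVolume, np.ndarray]]],
    case_ids: Sequence[str] | None = None,
) -> tuple[RegionReport, pd.DataFrame]:
    """Unweighted mean report over cases plus a per-case table.

    Returns ``(mean_report, per_case_frame)``; the frame has one row per case
    with columns ``<region>_<metric>``.
    """
    if not cases:
        raise ValueError("cohort is empty")
    ids = list(case_ids) if case_ids is not None else [f"case_{i:03d}" for i in range(len(cases))]
    rows = []
    for cid, (pred, truth) in zip(ids, cases):
        rep = evaluate_case(pred, truth)
        row: dict[str, Union[str, float]] = {"case_id": cid}
        for r in EVAL_REGIONS:
            for m in METRICS:
                row[f"{r}_{m}"] = getattr(rep[r], m)
        rows.append(row)
    frame = pd.DataFrame(rows)
    mean_scores: dict[str, RegionScores] = {}
    for r in EVAL_REGIONS:
        mean_scores[r] = RegionScores(
            dsc=float(frame[f"{r}_dsc"].mean()),
            ppv=float(frame[f"{r}_ppv"].mean()),
            sensitivity=float(frame[f"{r}_sensitivity"].mean()),
            n_pred=-1,
            n_truth=-1,
            n_overlap=-1,
        )
    return RegionReport(mean_scores), frame


def write_report_csv(frame: pd.DataFrame, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path
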