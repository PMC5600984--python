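"""Voxelwise detection metrics against a ground-truth lesion mask.

A feature map is swept over evenly spaced thresholds between its in-mask
minimum and maximum; at each threshold voxels are classified positive
according to the feature's polarity (``high_is_positive``: value > T;
``low_is_positive``: value < T) and compared with the truth mask, yielding
TP/TN/FP/FN and the derived TPR, FPR, precision, recall and F-score.

Two conventions, fixed here because the literature leaves them open:
feature values below a feature's ``background_rule`` are excluded from all
four counts, and 0/0 ratios (empty precision or F denominators) evaluate
to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ContractError, GeometryError
from .features import FeatureMap
from .volume import Volume


@dataclass
class EvalCurve:
    """Per-threshold confusion counts and derived metrics."""

    thresholds: np.ndarray
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f_score: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds, "tp": self.tp, "tn": self.tn,
            "fp": self.fp, "fn": self.fn, "tpr": self.tpr, "fpr": self.fpr,
            "precision": self.precision, "recall": self.recall,
            "f_score": self.f_score,
        })


def _valid_mask(feature: FeatureMap, eval_mask: Volume) -> np.ndarray:
    data = np.asarray(feature.data.data, dtype=float)
    m = np.asarray(eval_mask.data, dtype=bool)
    if data.shape != m.shape:
        raise GeometryError("feature and eval mask shapes differ")
    if feature.background_rule is not None:
        m = m & (data >= feature.background_rule)
    return m


def confusion_at(feature: FeatureMap, truth: Volume, t: float,
                 eval_mask: Volume) -> tuple[int, int, int, int]:
    """(tp, tn, fp, fn) at threshold ``t`` over the evaluation mask.

    Positivity follows the feature polarity; background-excluded voxels
    enter none of the four counts.
    """
    data = np.asarray(feature.data.data, dtype=float)
    tr = np.asarray(truth.data, dtype=bool)
    if data.shape != tr.shape:
        raise GeometryError("feature and truth shapes differ")
    m = _valid_mask(feature, eval_mask)
    if not np.asarray(eval_mask.data, dtype=bool).any():
        raise ContractError("empty evaluation mask")
    pos = (data > t) if feature.polarity == "high_is_positive" else (data < t)
    tp = int(np.count_nonzero(m & pos & tr))
    fp = int(np.count_nonzero(m & pos & ~tr))
    fn = int(np.count_nonzero(m & ~pos & tr))
    tn = int(np.count_nonzero(m & ~pos & ~tr))
    return tp, tn, fp, fn


def sweep(feature: FeatureMap, truth: Volume, eval_mask: Volume,
          n_thresholds: int = 256) -> EvalCurve:
    """Threshold sweep from the in-mask minimum to maximum feature value."""
    if n_thresholds < 2:
        raise ContractError("need at least 2 thresholds")
    if not np.asarray(eval_mask.data, dtype=bool).any():
        raise ContractError("empty evaluation mask")
    data = np.asarray(feature.data.data, dtype=float)
    m = _valid_mask(feature, eval_mask)
    vals = data[m]
    if vals.size == 0:
        raise ContractError("background rule excluded every in-mask voxel")
    ts = np.linspace(float(vals.min()), float(vals.max()), int(n_thresholds))
    counts = np.array([confusion_at(feature, truth, t, eval_mask) for t in ts])
    tp, tn, fp, fn = counts.T.astype(float)

    def safe(num, den):
        out = np.zeros_like(num)
        nz = den > 0
        out[nz] = num[nz] / den[nz]
        return out

    tpr = safe(tp, tp + fn)
    fpr = safe(fp, fp + tn)
    precision = safe(tp, tp + fp)
    recall = tpr
    f_score = safe(2 * precision * recall, precision + recall)
    return EvalCurve(ts, counts[:, 0], counts[:, 1], counts[:, 2], counts[:, 3],
                     tpr, fpr, precision, recall, f_score)


def best_f_score(curve: EvalCurve) -> tuple[float, float]:
    """(threshold, F) maximizing the F-score; ties go to the smallest threshold."""
    if curve.thresholds.size == 0:
        raise ContractError("empty curve")
    i = int(np.argmax(curve.f_score))  # first maximum = smallest threshold
    return float(curve.thresholds[i]), float(curve.f_score[i])


def lesion_slice_mask(truth: Volume, n_slices: int, seed: int = 0,
                      axis: int = 2) -> Volume:
    """Evaluation mask of randomly chosen lesion-containing slices.

    Mirrors slice-based evaluation protocols: pick ``n_slices`` distinct
    slices along ``axis`` that contain lesion voxels, seeded for
    reproducibility.
    """
    tr = np.asarray(truth.data, dtype=bool)
    has = [i for i in range(tr.shape[axis])
           if np.take(tr, i, axis=axis).any()]
    if not has:
        raise ContractError("truth mask contains no lesion voxels")
    rng = np.random.default_rng(int(seed))
    chosen = rng.choice(has, size=min(n_slices, len(has)), replace=False)
    mask = np.zeros(tr.shape, dtype=np.uint8)
    sl = [slice(None)] * 3
    for i in sorted(int(c) for c in chosen):
        sl[axis] = i
        mask[tuple(sl)] = 1
    return Volume(mask, truth.spacing, truth.affine.copy(), "mask")
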