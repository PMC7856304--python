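"""Evaluation metrics: Dice overlap, precision/recall, volumes, Pearson
correlation of volume estimates, and leave-one-out threshold tuning."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr

#: lesion-load strata boundaries in ml: (0, 2], (2, 10], (10, inf)
LOAD_BINS_ML = (0.0, 2.0, 10.0, np.inf)

UNDEFINED = float("nan")  # empty-denominator marker, excluded from aggregates


def dice(X: np.ndarray, Y: np.ndarray) -> float:
    """Dice overlap 2|X∩Y| / (|X|+|Y|); two empty masks score 1.0."""
    X = np.asarray(X, bool)
    Y = np.asarray(Y, bool)
    if X.shape != Y.shape:
        raise ValueError("mask shapes differ")
    total = X.sum() + Y.sum()
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(X, Y).sum() / total)


def precision_recall(pred: np.ndarray, ref: np.ndarray) -> tuple[float, float]:
    """(TP/(TP+FP), TP/(TP+FN)); empty denominators yield NaN markers."""
    pred = np.asarray(pred, bool)
    ref = np.asarray(ref, bool)
    if pred.shape != ref.shape:
        raise ValueError("mask shapes differ")
    tp = np.logical_and(pred, ref).sum()
    fp = np.logical_and(pred, ~ref).sum()
    fn = np.logical_and(~pred, ref).sum()
    precision = tp / (tp + fp) if (tp + fp) > 0 else UNDEFINED
    recall = tp / (tp + fn) if (tp + fn) > 0 else UNDEFINED
    return float(precision), float(recall)


def mask_volume(mask: np.ndarray, voxel_size) -> float:
    """Mask volume in mm^d: voxel count times voxel volume."""
    return float(np.asarray(mask, bool).sum() * np.prod(voxel_size))


def pearson_volumes(a, b) -> float:
    """Pearson correlation between two lists of volume estimates."""
    return float(pearsonr(np.asarray(a, float), np.asarray(b, float))[0])


def tune_threshold_loo(posteriors: list[np.ndarray], refs: list[np.ndarray],
                       gamma_grid) -> np.ndarray:
    """Leave-one-out threshold tuning.

    For each held-out subject, returns the gamma maximizing the *mean* Dice
    of thresholded posteriors against references over the remaining
    subjects; ties go to the smallest gamma.
    """
    n = len(posteriors)
    if n < 2:
        raise ValueError("at least 2 subjects required")
    if len(refs) != n:
        raise ValueError("one reference per posterior required")
    gamma_grid = np.asarray(gamma_grid, float)
    table = np.empty((n, gamma_grid.size))
    for s in range(n):
        for gi, g in enumerate(gamma_grid):
            table[s, gi] = dice(posteriors[s] > g, refs[s])
    out = np.empty(n)
    for s in range(n):
        others = np.delete(table, s, axis=0).mean(axis=0)
        out[s] = gamma_grid[int(np.argmax(others))]  # argmax: first/smallest
    return out


def lesion_load_stratum(volume_ml: float) -> int:
    """Index of the lesion-load bin (0, 2], (2, 10], (10, inf) ml."""
    for i in range(len(LOAD_BINS_ML) - 1):
        if LOAD_BINS_ML[i] < volume_ml <= LOAD_BINS_ML[i + 1]:
            return i
    return 0  # zero-load subjects fall in the lowest stratum


@dataclass
class EvalReport:
    """Per-subject lesion evaluation with load-stratified aggregates."""

    dice: list = field(default_factory=list)
    precision: list = field(default_factory=list)
    recall: list = field(default_factory=list)
    volume_mm3: list = field(default_factory=list)
    ref_volume_mm3: list = field(default_factory=list)
    tuned_gamma: list = field(default_factory=list)
    stratum: list = field(default_factory=list)

    def add_subject(self, pred, ref, voxel_size, gamma=None):
        self.dice.append(dice(pred, ref))
        p, r = precision_recall(pred, ref)
        self.precision.append(p)
        self.recall.append(r)
        vol = mask_volume(pred, voxel_size)
        ref_vol = mask_volume(ref, voxel_size)
        self.volume_mm3.append(vol)
        self.ref_volume_mm3.append(ref_vol)
        self.tuned_gamma.append(gamma)
        self.stratum.append(lesion_load_stratum(ref_vol / 1000.0))

    def aggregates(self) -> dict:
        def stats(xs):
            xs = np.asarray([x for x in xs if x is not None], float)
            xs = xs[np.isfinite(xs)]
            if xs.size == 0:
                return {"mean": UNDEFINED, "sd": UNDEFINED}
            return {"mean": float(xs.mean()), "sd": float(xs.std(ddof=0))}
        return {"dice": stats(self.dice),
                "precision": stats(self.precision),
                "recall": stats(self.recall),
                "volume_mm3": stats(self.volume_mm3)}
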