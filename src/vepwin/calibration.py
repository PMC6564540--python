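"""Automatic selection of the minimum window and certainty threshold.

The minimum classification window ``n_y_min`` and the threshold ``beta``
are chosen per user from the training data alone.  Leave-one-block-out
cross-validation classifies every held-out trial truncated to each window
of the grid ``n_y = 30, 60, ..., 3*n_c`` samples (no threshold gate), which
yields an accuracy curve ``p(n_y)`` and, via the Wolpaw information
transfer rate with the gaze-shift period included in the selection time,
an ITR curve.  The window maximizing the ITR becomes ``n_y_min``; ``beta``
is the smallest per-class margin (trial-averaged target correlation minus
best non-target correlation) observed at that window, floored at zero.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .decoder import _band_correlations, _projected_references
from .spatial import TemplateBank, subband_filter, train_bank
from .synth import TrialSet

__all__ = [
    "itr",
    "selection_time",
    "loo_curves",
    "select_parameters",
    "calibrate",
    "CalibrationResult",
]


def itr(K: int, p: float, t: float) -> float:
    """Wolpaw information transfer rate in bits per minute.

    ``[log2 K + p log2 p + (1-p) log2((1-p)/(K-1))] / (t/60)`` with the
    ``x log2 x -> 0`` limits at p in {0, 1}; below-chance rates (p < 1/K)
    would be negative-divergent and are clamped to 0.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if t <= 0:
        raise ValueError("t must be positive")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    bits = math.log2(K)
    if 0.0 < p < 1.0:
        bits += p * math.log2(p) + (1.0 - p) * math.log2((1.0 - p) / (K - 1))
    elif p == 0.0:
        bits += math.log2(1.0 / (K - 1))
    rate = bits / (t / 60.0)
    return max(rate, 0.0)


def selection_time(n_y: int, sampling_rate: float, gaze_shift_s: float = 1.0) -> float:
    """Average time per selection: the classification window plus the
    gaze-shifting pause (default 1 s)."""
    if n_y <= 0:
        raise ValueError("n_y must be positive")
    return n_y / sampling_rate + gaze_shift_s


@dataclass
class CalibrationResult:
    """Leave-one-out calibration curves and the chosen parameters."""

    window_grid: np.ndarray
    accuracy_curve: np.ndarray
    itr_curve: np.ndarray
    margins: np.ndarray  # (K, n_windows) trial-averaged class margins
    sampling_rate: float
    gaze_shift_s: float
    classes: np.ndarray
    chosen_n_y_min: int | None = None
    chosen_beta: float | None = None
    margin_table: np.ndarray | None = None  # per-class margins at chosen window
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "window_grid": self.window_grid.tolist(),
            "accuracy_curve": self.accuracy_curve.tolist(),
            "itr_curve": self.itr_curve.tolist(),
            "margins": self.margins.tolist(),
            "sampling_rate": self.sampling_rate,
            "gaze_shift_s": self.gaze_shift_s,
            "classes": self.classes.tolist(),
            "chosen_n_y_min": self.chosen_n_y_min,
            "chosen_beta": self.chosen_beta,
            "margin_table": None if self.margin_table is None else self.margin_table.tolist(),
            "meta": self.meta,
        }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResult":
        return cls(
            window_grid=np.asarray(d["window_grid"], dtype=int),
            accuracy_curve=np.asarray(d["accuracy_curve"], dtype=float),
            itr_curve=np.asarray(d["itr_curve"], dtype=float),
            margins=np.asarray(d["margins"], dtype=float),
            sampling_rate=d["sampling_rate"],
            gaze_shift_s=d["gaze_shift_s"],
            classes=np.asarray(d["classes"], dtype=int),
            chosen_n_y_min=d.get("chosen_n_y_min"),
            chosen_beta=d.get("chosen_beta"),
            margin_table=(
                None if d.get("margin_table") is None else np.asarray(d["margin_table"])
            ),
            meta=d.get("meta", {}),
        )

    @classmethod
    def from_json(cls, path) -> "CalibrationResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _fold_ids(trainset: TrialSet, mode: str):
    if mode == "block":
        for b in trainset.block_ids:
            yield trainset.blocks == b
    elif mode == "trial":
        for i in range(trainset.n_trials):
            mask = np.zeros(trainset.n_trials, dtype=bool)
            mask[i] = True
            yield mask
    else:
        raise ValueError("mode must be 'block' or 'trial'")


def loo_curves(
    trainset: TrialSet,
    M: int = 1,
    grid: np.ndarray | None = None,
    grid_step: int = 30,
    gaze_shift_s: float = 1.0,
    mode: str = "block",
    bank_builder=train_bank,
) -> CalibrationResult:
    """Leave-one-out accuracy and ITR curves over the window grid.

    For every fold a template bank is trained on the remaining blocks and
    every held-out trial, truncated to each grid window, is classified
    without a threshold gate.  Accuracy is pooled over folds; the ITR uses
    ``t = n_y / f_s + gaze_shift_s``.
    """
    if not trainset.is_balanced():
        raise ValueError("training blocks must be balanced")
    if trainset.block_ids.size < 2:
        raise ValueError("need at least two blocks for leave-one-out")
    if grid is None:
        grid = np.arange(grid_step, trainset.n_samples + 1, grid_step)
    grid = np.asarray(grid, dtype=int)
    classes = trainset.classes
    K = classes.size
    class_pos = {int(c): i for i, c in enumerate(classes)}
    n_w = grid.size

    correct = np.zeros(n_w)
    total = 0
    margin_sum = np.zeros((K, n_w))
    margin_cnt = np.zeros(K)
    for held in _fold_ids(trainset, mode):
        bank = bank_builder(trainset.subset(~held), M)
        ref_cache: dict = {}
        for ti in np.flatnonzero(held):
            trial = trainset.trials[ti]
            true_pos = class_pos[int(trainset.labels[ti])]
            lam_all = np.zeros((n_w, K))
            for wi, w in enumerate(grid):
                Yw = trial[:, :w]
                proj = _projected_references(bank, int(w), cache=ref_cache)
                lam = np.zeros(K)
                for b, band in enumerate(bank.bands):
                    Yb = subband_filter(Yw, band, bank.sampling_rate)
                    lam += bank.a[b] * _band_correlations(Yb, proj[b], bank.weights[b])
                lam_all[wi] = lam
            pred = np.argmax(lam_all, axis=1)
            correct += pred == true_pos
            nontarget = lam_all.copy()
            nontarget[:, true_pos] = -np.inf
            margin_sum[true_pos] += lam_all[:, true_pos] - nontarget.max(axis=1)
            margin_cnt[true_pos] += 1
            total += 1
    accuracy = correct / total
    itr_curve = np.array(
        [
            itr(K, p, selection_time(int(w), trainset.sampling_rate, gaze_shift_s))
            for p, w in zip(accuracy, grid)
        ]
    )
    margins = margin_sum / margin_cnt[:, None]
    return CalibrationResult(
        window_grid=grid,
        accuracy_curve=accuracy,
        itr_curve=itr_curve,
        margins=margins,
        sampling_rate=trainset.sampling_rate,
        gaze_shift_s=gaze_shift_s,
        classes=classes,
        meta={"M": M, "mode": mode},
    )


def select_parameters(curves: CalibrationResult) -> tuple[int, float]:
    """Pick ``(n_y_min, beta)`` from calibration curves: the grid window
    maximizing the ITR (ties -> smallest window) and the minimum per-class
    margin at that window, floored at 0 (a warning is issued when classes
    overlap so heavily that margins go negative)."""
    if curves.window_grid.size == 0:
        raise ValueError("empty calibration curves")
    j = int(np.argmax(curves.itr_curve))
    n_y_min = int(curves.window_grid[j])
    margin_table = curves.margins[:, j]
    beta = float(margin_table.min())
    if beta < 0:
        warnings.warn(
            "negative class margin at the selected window; threshold floored at 0",
            stacklevel=2,
        )
        beta = 0.0
    curves.chosen_n_y_min = n_y_min
    curves.chosen_beta = beta
    curves.margin_table = margin_table
    return n_y_min, beta


def calibrate(
    trainset: TrialSet,
    M: int = 1,
    grid: np.ndarray | None = None,
    grid_step: int = 30,
    gaze_shift_s: float = 1.0,
    mode: str = "block",
) -> CalibrationResult:
    """Convenience wrapper: LOO curves plus parameter selection."""
    curves = loo_curves(
        trainset, M=M, grid=grid, grid_step=grid_step, gaze_shift_s=gaze_shift_s, mode=mode
    )
    select_parameters(curves)
    return curves
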