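"""Threshold and window-size calibration by pooled F1 maximisation.

Reproduces the calibration procedure behind the default method constants:
decision thresholds are the pooled-F1 maximisers on a labelled dataset, and
the RSA window length is chosen by grid search over odd windows, scoring
each window by the best F1 it can reach (Fmax).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .caid_eval import f1_curve
from .disorder_scores import windowed_mean
from .errors import DegenerateInputError, InputError
from .structure_io import UNKNOWN


@dataclass
class CalibrationResult:
    """Outcome of a threshold or window search.

    ``metric_by_threshold`` / ``metric_by_window`` record the full curves so
    plateaus are visible, not just the argmax.
    """

    best_metric: float
    best_threshold: float | None = None
    metric_by_threshold: list[tuple[float, float]] = field(default_factory=list)
    best_window: int | None = None
    metric_by_window: list[tuple[int, float]] = field(default_factory=list)
    threshold_by_window: dict[int, float] = field(default_factory=dict)


def _clean_pool(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=int).ravel()
    if scores.shape != labels.shape:
        raise InputError("scores and labels must have equal length")
    keep = labels != UNKNOWN
    return scores[keep], labels[keep]


def optimize_threshold(scores, labels,
                       grid: Sequence[float] | None = None,
                       step: float | None = None) -> CalibrationResult:
    """Threshold maximising pooled F1 under the >= call rule.

    ``grid`` defaults to all distinct score values plus {0, 1} (the exact
    optimum); pass ``step`` (e.g. 0.001) for a fixed-step grid instead, for
    parity with assessments that discretise.  Ties go to the smallest
    threshold.  Unknown labels (-1) are dropped before pooling.
    """
    scores, labels = _clean_pool(scores, labels)
    if grid is None and step is not None:
        grid = np.arange(0.0, 1.0 + step / 2, step)
    pos = int((labels == 1).sum())
    if pos == 0 or pos == labels.size:
        raise DegenerateInputError(
            "threshold calibration needs both positive and negative labels")
    thresholds, f1s, _, _ = f1_curve(scores, labels, grid=grid)
    best = int(np.argmax(f1s))      # first occurrence = smallest threshold
    return CalibrationResult(
        best_metric=float(f1s[best]),
        best_threshold=float(thresholds[best]),
        metric_by_threshold=list(zip(thresholds.tolist(), f1s.tolist())),
    )


def window_grid_search(profiles: Sequence[np.ndarray],
                       labels: Sequence[np.ndarray],
                       window_range: Sequence[int] = range(1, 51),
                       mirror: str = "reflect") -> CalibrationResult:
    """Grid-search the RSA smoothing window by pooled Fmax.

    For each odd window the per-target profiles are re-smoothed, residues
    pooled across targets, and the best attainable F1 recorded.  Even window
    values are skipped with a warning (a centred +/-h window is odd by
    construction).  Ties go to the smallest window.
    """
    windows = sorted(set(int(w) for w in window_range))
    if not windows:
        raise InputError("window_range is empty")
    if len(profiles) != len(labels):
        raise InputError("profiles and labels must pair up")
    even = [w for w in windows if w % 2 == 0]
    if even:
        warnings.warn(f"skipping even window sizes {even}: centred windows "
                      "are odd", stacklevel=2)
        windows = [w for w in windows if w % 2 == 1]
    if not windows:
        raise InputError("window_range contains no odd window")

    label_pool = np.concatenate([np.asarray(l, dtype=int).ravel()
                                 for l in labels])
    curve: list[tuple[int, float]] = []
    thr_by_window: dict[int, float] = {}
    for w in windows:
        smoothed = np.concatenate([windowed_mean(p, w, mirror=mirror)
                                   for p in profiles])
        res = optimize_threshold(smoothed, label_pool)
        curve.append((w, res.best_metric))
        thr_by_window[w] = res.best_threshold
    best_w, best_f1 = max(curve, key=lambda wf: (wf[1], -wf[0]))
    return CalibrationResult(
        best_metric=float(best_f1),
        best_window=int(best_w),
        best_threshold=thr_by_window[best_w],
        metric_by_window=curve,
        threshold_by_window=thr_by_window,
    )
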