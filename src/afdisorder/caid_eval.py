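"""CAID-style evaluation of per-residue binary predictions.

Residues from all matched targets are pooled into one confusion matrix (the
CAID headline convention); residues with unknown reference labels are
excluded.  Metrics: precision/recall/F1 at a threshold, Fmax over all
thresholds, ROC AUC, target coverage, and a fully-disordered-protein call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import (
    ConsistencyError,
    DegenerateInputError,
    EmptyEvaluationError,
    InputError,
)
from .structure_io import UNKNOWN, PredictionTrack, ReferenceTrack


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvalResult:
    """Pooled evaluation of one score variant against one reference set."""

    fmax: float
    fmax_threshold: float
    auc: float
    pr_curve: list[tuple[float, float, float]]   # (threshold, precision, recall)
    roc_curve: list[tuple[float, float]]         # (fpr, tpr)
    coverage: float
    n_targets: int
    n_residues: int
    variant: str = ""
    dataset: str = ""
    per_target_f1: dict[str, float] = field(default_factory=dict)


def _as_mapping(tracks) -> dict[str, object]:
    if isinstance(tracks, Mapping):
        return dict(tracks)
    if hasattr(tracks, "target_id"):
        tracks = [tracks]
    return {t.target_id: t for t in tracks}


def pool(preds, refs) -> tuple[np.ndarray, np.ndarray]:
    """Pool matched targets into (scores, labels), dropping unknown labels.

    Raises ConsistencyError on per-target length mismatch and
    EmptyEvaluationError when no target id is shared.
    """
    pred_map, ref_map = _as_mapping(preds), _as_mapping(refs)
    matched = [tid for tid in ref_map if tid in pred_map]
    if not matched:
        raise EmptyEvaluationError(
            "no overlap between prediction and reference target ids")
    scores, labels = [], []
    for tid in matched:
        p, r = pred_map[tid], ref_map[tid]
        if len(p.scores) != len(r.labels):
            raise ConsistencyError(
                f"{tid}: {len(p.scores)} predictions vs "
                f"{len(r.labels)} reference labels")
        keep = r.labels != UNKNOWN
        scores.append(np.asarray(p.scores)[keep])
        labels.append(np.asarray(r.labels)[keep])
    scores = np.concatenate(scores)
    labels = np.concatenate(labels).astype(int)
    if scores.size == 0:
        raise EmptyEvaluationError("all matched residues have unknown labels")
    return scores, labels


def confusion(preds, refs, threshold: float) -> ConfusionCounts:
    """Pooled confusion counts at a threshold with the >= call rule."""
    scores, labels = pool(preds, refs)
    calls = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(calls & pos)),
        fp=int(np.sum(calls & ~pos)),
        tn=int(np.sum(~calls & ~pos)),
        fn=int(np.sum(~calls & pos)),
    )


def precision(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0


def recall(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0


def f1(c: ConfusionCounts) -> float:
    """Harmonic mean of precision and recall; 0 by convention when both
    denominators vanish."""
    p, r = precision(c), recall(c)
    return 2 * p * r / (p + r) if p + r else 0.0


def f1_curve(scores: np.ndarray, labels: np.ndarray,
             grid: Sequence[float] | None = None
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(thresholds, F1, precision, recall) at every candidate cut.

    Default grid: all distinct score values plus 0 and 1 (the exact optimum
    lies on a distinct score under the >= rule).  Vectorised via sorting.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    if n_pos == 0 or n_pos == labels.size:
        raise DegenerateInputError(
            "need at least one positive and one negative label")
    if grid is None:
        thresholds = np.unique(np.concatenate([scores, [0.0, 1.0]]))
    else:
        thresholds = np.unique(np.asarray(grid, dtype=float))
    order = np.argsort(scores, kind="stable")
    sorted_scores = scores[order]
    pos_prefix = np.concatenate([[0], np.cumsum(labels[order] == 1)])
    idx = np.searchsorted(sorted_scores, thresholds, side="left")
    tp = n_pos - pos_prefix[idx]
    pred_pos = scores.size - idx
    fp = pred_pos - tp
    fn = n_pos - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(pred_pos > 0, tp / np.maximum(pred_pos, 1), 0.0)
        rec = tp / n_pos
        denom = 2 * tp + fp + fn
        f1s = np.where(denom > 0, 2 * tp / np.maximum(denom, 1), 0.0)
    return thresholds, f1s, prec, rec


def fmax(preds, refs) -> tuple[float, float, list[tuple[float, float, float]]]:
    """Maximum pooled F1 over all distinct score cuts.

    Returns (fmax, threshold at the maximum -- ties toward the smallest
    threshold -- and the (threshold, precision, recall) curve).
    """
    scores, labels = pool(preds, refs)
    if not np.any(labels == 1):
        raise EmptyEvaluationError("reference contains no positive residues")
    thresholds, f1s, prec, rec = f1_curve(scores, labels)
    best = int(np.argmax(f1s))          # argmax returns the first (smallest)
    curve = list(zip(thresholds.tolist(), prec.tolist(), rec.tolist()))
    return float(f1s[best]), float(thresholds[best]), curve


def roc_auc(preds, refs) -> tuple[float, list[tuple[float, float]]]:
    """Pooled ROC AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores, labels = pool(preds, refs)
    if len(np.unique(labels)) < 2:
        raise DegenerateInputError("AUC undefined for single-class labels")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def coverage(pred_ids: Iterable[str], ref_ids: Iterable[str]) -> float:
    """Fraction of reference targets with a prediction (full precision;
    report rounded to 2 decimals, as in 489/645 -> 0.76)."""
    pred_ids, ref_ids = set(pred_ids), set(ref_ids)
    if not ref_ids:
        raise EmptyEvaluationError("empty reference target set")
    return len(pred_ids & ref_ids) / len(ref_ids)


def fully_disordered(track: PredictionTrack,
                     fraction_threshold: float = 0.95) -> bool:
    """Call a protein fully disordered when the positively-called residue
    fraction is >= fraction_threshold (a dialect; the criterion varies
    between assessments)."""
    if len(track) == 0:
        raise InputError(f"{track.target_id}: empty prediction track")
    return bool(np.mean(track.calls) >= fraction_threshold)


def evaluate(preds, refs, variant: str = "", dataset: str = "") -> EvalResult:
    """Full pooled evaluation: Fmax, AUC, coverage and per-target F1."""
    pred_map = _as_mapping(preds)
    ref_map = _as_mapping(refs)
    fm, fm_thr, pr = fmax(pred_map, ref_map)
    auc, roc = roc_auc(pred_map, ref_map)
    cov = coverage(pred_map, ref_map)
    n_res = pool(pred_map, ref_map)[0].size
    per_target = {}
    for tid in ref_map:
        if tid not in pred_map:
            continue
        try:
            per_target[tid] = f1(confusion({tid: pred_map[tid]},
                                           {tid: ref_map[tid]},
                                           fm_thr))
        except EmptyEvaluationError:
            continue
    return EvalResult(fmax=fm, fmax_threshold=fm_thr, auc=auc,
                      pr_curve=pr, roc_curve=roc, coverage=cov,
                      n_targets=len(set(pred_map) & set(ref_map)),
                      n_residues=int(n_res), variant=variant, dataset=dataset,
                      per_target_f1=per_target)


def format_report(result: EvalResult) -> str:
    """One-line TSV summary, Fmax/AUC to 3 decimals, coverage to 2."""
    return "\t".join([
        result.variant or "-", result.dataset or "-",
        f"{result.fmax:.3f}", f"{result.fmax_threshold:.3f}",
        f"{result.auc:.3f}", f"{result.coverage:.2f}",
        str(result.n_targets), str(result.n_residues),
    ])


REPORT_HEADER = "\t".join(["variant", "dataset", "fmax", "fmax_threshold",
                           "auc", "coverage", "n_targets", "n_residues"])
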