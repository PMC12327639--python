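"""Evaluation metrics for multi-label GO-term prediction.

Three metrics, all operating on a proteins × terms score matrix and the
matching binary label matrix:

* **Fmax** — the maximum, over decision thresholds t, of the F1 combining
  pooled precision and recall of the predicted term sets: every
  (protein, term) cell with score ≥ t counts as one predicted annotation
  and the sums in precision/recall run over proteins and terms jointly.
  A per-protein-averaged (CAFA-style) variant is available behind the
  ``per_protein`` flag for comparability with protein-centric tooling.
* **AUPR (micro)** — every cell of the label matrix is one binary
  decision; the precision–recall curve is swept from high to low
  threshold and integrated as a step sum Σ_t (rc(t) − rc(t−1))·pr(t).
* **AUC** — per-term ROC area via the rank (Mann–Whitney) formulation
  with ties counted 1/2, macro-averaged over terms that have both classes
  (default), or micro over the flattened matrix.

The threshold sweep uses the 0.01-step grid {0.00, …, 1.00} united with
the exact set of observed score values, which makes the "all possible
thresholds" maximisation exact regardless of grid resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .graph_io import DataError, ShapeMismatchError

logger = logging.getLogger("contactgo")

#: Default decision-threshold grid, step 0.01. The degenerate t = 0
#: point (every term predicted for every protein) is excluded; a score
#: of exactly 0 means "never predicted".
THRESHOLD_GRID = np.round(np.linspace(0.01, 1.0, 100), 2)


class UndefinedMetricError(DataError):
    """The metric is undefined for this input (e.g. no positive labels)."""


def _check_batch(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    S = np.asarray(scores, dtype=np.float64)
    Y = np.asarray(labels)
    if S.shape != Y.shape or S.ndim != 2:
        raise ShapeMismatchError(
            f"scores {S.shape} and labels {Y.shape} must be equal-shape 2-D matrices"
        )
    if not np.isin(Y, (0, 1)).all():
        raise DataError("labels must be binary")
    if S.min() < 0.0 or S.max() > 1.0:
        raise DataError("scores must lie in [0, 1]")
    return S, Y.astype(np.int8)


def _sweep_thresholds(scores: np.ndarray, grid: np.ndarray | None) -> np.ndarray:
    base = THRESHOLD_GRID if grid is None else np.asarray(grid, dtype=np.float64)
    merged = np.unique(np.concatenate([base, np.unique(scores)]))
    return merged[merged > 0.0]


@dataclass
class MetricReport:
    """Bundle of the three metrics plus the precision/recall curves."""

    fmax: float
    fmax_threshold: float
    aupr: float
    auc: float
    auc_micro: float
    curves: pd.DataFrame

    def as_dict(self) -> dict:
        return {
            "fmax": self.fmax,
            "fmax_threshold": self.fmax_threshold,
            "aupr": self.aupr,
            "auc": self.auc,
            "auc_micro": self.auc_micro,
        }


def fmax(
    scores: np.ndarray,
    labels: np.ndarray,
    grid: np.ndarray | None = None,
    per_protein: bool = False,
) -> tuple[float, float, pd.DataFrame]:
    """Maximum F1 over thresholds, with the pooled precision/recall sums.

    Returns ``(fmax, best_threshold, curves)`` where ``curves`` tabulates
    pr(t) and rc(t) per threshold. Thresholds at which nothing is
    predicted have undefined precision and are skipped. With
    ``per_protein`` precision is averaged over proteins that predict at
    least one term and recall over all proteins (CAFA convention) instead
    of the pooled sums.
    """
    S, Y = _check_batch(scores, labels)
    total_pos = int(Y.sum())
    if total_pos == 0:
        raise UndefinedMetricError("Fmax undefined: label matrix has no positives")
    thresholds = _sweep_thresholds(S, grid)
    rows = []
    best_f, best_t = 0.0, float(thresholds[0])
    for t in thresholds:
        pred = S >= t
        n_pred = int(pred.sum())
        if per_protein:
            prot_pred = pred.sum(axis=1)
            covered = prot_pred > 0
            if not covered.any():
                continue
            tp_per = (pred & (Y == 1)).sum(axis=1)
            pr = float((tp_per[covered] / prot_pred[covered]).mean())
            pos_per = Y.sum(axis=1)
            with np.errstate(invalid="ignore"):
                rc_terms = np.where(pos_per > 0, tp_per / np.maximum(pos_per, 1), 0.0)
            rc = float(rc_terms.mean())
        else:
            if n_pred == 0:
                continue
            tp = int((pred & (Y == 1)).sum())
            pr = tp / n_pred
            rc = tp / total_pos
        f1 = 0.0 if pr + rc == 0 else 2.0 * pr * rc / (pr + rc)
        rows.append((float(t), pr, rc, f1))
        if f1 > best_f:
            best_f, best_t = f1, float(t)
    curves = pd.DataFrame(rows, columns=["threshold", "precision", "recall", "f1"])
    return best_f, best_t, curves


def aupr(scores: np.ndarray, labels: np.ndarray, grid: np.ndarray | None = None) -> float:
    """Micro-averaged area under the precision–recall curve (step sum).

    Flattens the matrices, sweeps thresholds from high to low (recall is
    then non-decreasing, starting from 0) and accumulates
    Σ (rc(t) − rc(t_prev))·pr(t); empty-prediction thresholds are skipped.
    """
    S, Y = _check_batch(np.atleast_2d(scores), np.atleast_2d(labels))
    s, y = S.ravel(), Y.ravel()
    total_pos = int(y.sum())
    if total_pos == 0:
        raise UndefinedMetricError("AUPR undefined: no positive labels")
    thresholds = _sweep_thresholds(s, grid)[::-1]  # high → low
    area, prev_rc = 0.0, 0.0
    for t in thresholds:
        pred = s >= t
        n_pred = int(pred.sum())
        if n_pred == 0:
            continue
        tp = int((pred & (y == 1)).sum())
        pr = tp / n_pred
        rc = tp / total_pos
        area += (rc - prev_rc) * pr
        prev_rc = rc
    return area


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC area via the Mann–Whitney U statistic, ties counted 1/2."""
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc(scores: np.ndarray, labels: np.ndarray, averaging: str = "macro") -> float:
    """ROC AUC over the batch.

    ``macro`` (default) averages the per-term areas over label columns
    that contain both classes (columns lacking one class are excluded,
    with a logged count); ``micro`` ranks the flattened matrix.
    """
    if averaging not in ("macro", "micro"):
        raise DataError(f"averaging must be 'macro' or 'micro', got {averaging!r}")
    S, Y = _check_batch(np.atleast_2d(scores), np.atleast_2d(labels))
    if averaging == "micro":
        y = Y.ravel()
        if y.sum() == 0 or y.sum() == y.size:
            raise UndefinedMetricError("micro AUC undefined: one class absent")
        return _rank_auc(S.ravel(), y)
    areas = []
    skipped = 0
    for f in range(Y.shape[1]):
        col = Y[:, f]
        if col.sum() == 0 or col.sum() == col.size:
            skipped += 1
            continue
        areas.append(_rank_auc(S[:, f], col))
    if skipped:
        logger.debug("AUC: excluded %d single-class term column(s)", skipped)
    if not areas:
        raise UndefinedMetricError("macro AUC undefined: no term has both classes")
    return float(np.mean(areas))


def evaluate(scores: np.ndarray, labels: np.ndarray, grid: np.ndarray | None = None) -> MetricReport:
    """Compute all three metrics on one batch."""
    f, t, curves = fmax(scores, labels, grid=grid)
    return MetricReport(
        fmax=f,
        fmax_threshold=t,
        aupr=aupr(scores, labels, grid=grid),
        auc=auc(scores, labels, averaging="macro"),
        auc_micro=auc(scores, labels, averaging="micro"),
        curves=curves,
    )
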