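"""Evaluation metrics: Ftot, Pearson correlation, range-normalized RMSE,
and activity-/participant-level aggregation of per-subtrial predictions.

The headline quantity is the total shoulder-joint reaction force
``Ftot = sqrt(Fx² + Fy² + Fz²)`` per sample.  Predicted and ground-truth
Ftot series are compared with Pearson's correlation coefficient (PCC) and
the relative RMSE (rRMSE), i.e. the RMSE normalized by the range of the
ground-truth Ftot, in percent.  For evaluation, subtrial predictions are
concatenated back to the original eight activities:

* activity level — per (participant, activity): PCC/rRMSE computed per
  iteration on the concatenated activity, then averaged over iterations;
* participant level — per (participant, iteration): all activities of one
  iteration concatenated into one "complete iteration" and scored once.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from shoulderload.synthetic import ACTIVITIES

__all__ = [
    "PredictionSet",
    "compute_ftot",
    "pearson",
    "rrmse",
    "concatenate_to_activities",
    "activity_level_metrics",
    "participant_level_metrics",
]

logger = logging.getLogger(__name__)

Key = tuple[int, str, int]


def compute_ftot(series: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of the three force components."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[1] != 3:
        raise ValueError("expected an (n, 3) force array")
    if not np.all(np.isfinite(series)):
        raise ValueError("force series contains non-finite values")
    return np.sqrt((series**2).sum(axis=1))


def pearson(pred: np.ndarray, truth: np.ndarray) -> float:
    """Sample Pearson product-moment correlation; NaN (with a warning) for
    constant inputs, where the coefficient is undefined."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1 or len(pred) < 2:
        raise ValueError("pred and truth must be equal-length 1D series of length >= 2")
    sp, st = pred.std(), truth.std()
    if sp == 0 or st == 0:
        warnings.warn("Pearson correlation undefined for constant input; returning NaN", stacklevel=2)
        return float("nan")
    p = pred - pred.mean()
    t = truth - truth.mean()
    # (n-1) cancels between covariance and SDs
    return float((p @ t) / np.sqrt((p @ p) * (t @ t)))


def rrmse(pred: np.ndarray, truth: np.ndarray) -> float:
    """RMSE normalized by the range of the ground truth, in percent."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValueError("pred and truth must be equal-length 1D series")
    rng = truth.max() - truth.min()
    if rng <= 0:
        raise ValueError("ground-truth range is zero; rRMSE undefined")
    rmse = np.sqrt(np.mean((pred - truth) ** 2))
    return float(100.0 * rmse / rng)


@dataclass
class PredictionSet:
    """Per-subtrial predictions for one experiment configuration.

    ``entries`` maps ``(participant, activity, subtrial, iteration)`` to an
    ``(pred, truth)`` pair of (n, 3) force arrays in newtons.
    """

    entries: dict[tuple[int, str, int, int], tuple[np.ndarray, np.ndarray]]

    def add(self, key: Key, iteration: int, pred: np.ndarray, truth: np.ndarray) -> None:
        self.entries[(*key, iteration)] = (np.asarray(pred), np.asarray(truth))

    def iterations(self) -> list[int]:
        return sorted({it for (_, _, _, it) in self.entries})

    def participants(self) -> list[int]:
        return sorted({p for (p, _, _, _) in self.entries})


def concatenate_to_activities(predictions: PredictionSet, participant_id: int,
                              iteration: int) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Concatenate subtrial predictions back to whole activities.

    Subtrials are concatenated in subtrial-index (recording) order.  An
    activity whose expected subtrials are not all present (e.g. excluded
    from the cohort) is dropped with a log entry rather than imputed.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    present: dict[str, dict[int, tuple[np.ndarray, np.ndarray]]] = {}
    for (pid, act, sub, it), pair in predictions.entries.items():
        if pid == participant_id and it == iteration:
            present.setdefault(act, {})[sub] = pair
    for act, subs in present.items():
        expected = ACTIVITIES[act][0] if act in ACTIVITIES else max(subs) + 1
        if len(subs) < expected:
            logger.info(
                "participant %d iteration %d: activity %s incomplete (%d/%d subtrials); skipped",
                participant_id, iteration, act, len(subs), expected,
            )
            continue
        order = sorted(subs)
        pred = np.vstack([subs[k][0] for k in order])
        truth = np.vstack([subs[k][1] for k in order])
        out[act] = (pred, truth)
    return out


def activity_level_metrics(predictions: PredictionSet,
                           require_complete: bool = True) -> pd.DataFrame:
    """Per (participant, activity): PCC/rRMSE on Ftot per iteration, then
    averaged over iterations.  Returns a tidy frame with one row per record.

    With ``require_complete=False``, activities with missing subtrials are
    scored on the subtrials present instead of being dropped.
    """
    rows = []
    for pid in predictions.participants():
        per_iter: dict[str, list[tuple[float, float]]] = {}
        for it in predictions.iterations():
            acts = concatenate_to_activities(predictions, pid, it)
            if not require_complete:
                acts = _concatenate_partial(predictions, pid, it)
            for act, (pred, truth) in acts.items():
                f_pred, f_truth = compute_ftot(pred), compute_ftot(truth)
                per_iter.setdefault(act, []).append((pearson(f_pred, f_truth), rrmse(f_pred, f_truth)))
        for act, vals in per_iter.items():
            pccs, errs = zip(*vals)
            rows.append({
                "scope": "activity", "participant_id": pid, "activity": act,
                "pcc": float(np.nanmean(pccs)), "rrmse": float(np.nanmean(errs)),
                "n_iterations": len(vals),
            })
    return pd.DataFrame(rows)


def _concatenate_partial(predictions: PredictionSet, participant_id: int,
                         iteration: int) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    present: dict[str, dict[int, tuple[np.ndarray, np.ndarray]]] = {}
    for (pid, act, sub, it), pair in predictions.entries.items():
        if pid == participant_id and it == iteration:
            present.setdefault(act, {})[sub] = pair
    return {
        act: (
            np.vstack([subs[k][0] for k in sorted(subs)]),
            np.vstack([subs[k][1] for k in sorted(subs)]),
        )
        for act, subs in present.items()
    }


def participant_level_metrics(predictions: PredictionSet) -> pd.DataFrame:
    """Per (participant, iteration): concatenate all activities into one
    complete iteration and score PCC and rRMSE on Ftot."""
    rows = []
    for pid in predictions.participants():
        for it in predictions.iterations():
            acts = _concatenate_partial(predictions, pid, it)
            if not acts:
                continue
            order = sorted(acts)  # stable concatenation order
            pred = np.vstack([acts[a][0] for a in order])
            truth = np.vstack([acts[a][1] for a in order])
            f_pred, f_truth = compute_ftot(pred), compute_ftot(truth)
            rows.append({
                "scope": "participant", "participant_id": pid, "iteration": it,
                "pcc": pearson(f_pred, f_truth), "rrmse": rrmse(f_pred, f_truth),
                "n_samples": len(f_truth),
            })
    return pd.DataFrame(rows)
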