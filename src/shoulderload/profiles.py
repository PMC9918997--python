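"""Shoulder-load profiles and the Swain–Ballard histogram intersection.

A shoulder-load profile summarizes exposure magnitude over a period as a
histogram of Ftot with a fixed 25 N bin width, bins anchored at 0 N
(half-open ``[a, b)``, final bin closed).  The similarity between a
predicted profile (counts ŷ) and the ground-truth profile (counts y) over
shared edges is the Swain–Ballard intersection

    I(y, ŷ) = Σᵢ min(yᵢ, ŷᵢ) / Σᵢ yᵢ ,

which is 1 for identical histograms and 0 for disjoint ones.  Because both
series share the 25 Hz time base, both histograms bin the same number of
samples and I lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from shoulderload.metrics import PredictionSet, _concatenate_partial, compute_ftot

__all__ = [
    "DEFAULT_BIN_WIDTH_N",
    "LoadProfile",
    "build_profile",
    "shared_edges",
    "histogram_intersection",
    "profile_report",
]

DEFAULT_BIN_WIDTH_N = 25.0


@dataclass(frozen=True)
class LoadProfile:
    """Histogram of Ftot at fixed bin width with uniform edges."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        edges, counts = self.bin_edges, self.counts
        if len(edges) != len(counts) + 1:
            raise ValueError("need exactly one more edge than bins")
        widths = np.diff(edges)
        if np.any(widths <= 0) or not np.allclose(widths, widths[0]):
            raise ValueError("bin edges must be strictly increasing and uniform")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())


def shared_edges(*series: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH_N) -> np.ndarray:
    """Uniform edges anchored at 0, covering the union of all series."""
    top = max(float(np.max(s)) for s in series)
    n_bins = max(1, int(np.floor(top / bin_width)) + 1)
    return bin_width * np.arange(n_bins + 1)


def build_profile(ftot: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH_N,
                  edges: np.ndarray | None = None) -> LoadProfile:
    """Bin an Ftot series into a load profile.

    Bins are half-open ``[a, b)`` with the final bin closed (numpy's
    convention), anchored at 0 since Ftot is a norm.  ``edges`` may be
    supplied to share a grid between the profiles being compared.
    """
    ftot = np.asarray(ftot, dtype=float)
    if ftot.size == 0:
        raise ValueError("cannot build a load profile from an empty series")
    if np.any(ftot < 0):
        raise ValueError("Ftot is a norm and must be non-negative")
    if edges is None:
        edges = shared_edges(ftot, bin_width=bin_width)
    counts, _ = np.histogram(ftot, bins=edges)
    return LoadProfile(bin_edges=np.asarray(edges, dtype=float), counts=counts)


def histogram_intersection(truth: LoadProfile, pred: LoadProfile) -> float:
    """Swain–Ballard intersection: Σ min(yᵢ, ŷᵢ) / Σ yᵢ with y = truth."""
    if truth.n_bins != pred.n_bins or not np.allclose(truth.bin_edges, pred.bin_edges):
        raise ValueError("profiles must share identical bin edges")
    denom = truth.counts.sum()
    if denom <= 0:
        raise ValueError("ground-truth profile is empty")
    return float(np.minimum(truth.counts, pred.counts).sum() / denom)


def _intersection_for(pred: np.ndarray, truth: np.ndarray, bin_width: float) -> float:
    f_pred, f_truth = compute_ftot(pred), compute_ftot(truth)
    edges = shared_edges(f_pred, f_truth, bin_width=bin_width)
    return histogram_intersection(
        build_profile(f_truth, edges=edges), build_profile(f_pred, edges=edges)
    )


def profile_report(predictions: PredictionSet, scope: str = "participants",
                   bin_width: float = DEFAULT_BIN_WIDTH_N,
                   participant_id: int | None = None) -> pd.DataFrame:
    """Mean (SD) intersection table.

    ``scope="participants"``: one row per participant, intersection of the
    all-activities profile per iteration, mean ± SD over iterations, plus a
    ``mean`` row.  ``scope="activities"``: one row per activity for a single
    participant (default: the first), same aggregation.
    """
    if scope not in ("participants", "activities"):
        raise ValueError("scope must be 'participants' or 'activities'")
    rows = []
    if scope == "participants":
        for pid in predictions.participants():
            vals = []
            for it in predictions.iterations():
                acts = _concatenate_partial(predictions, pid, it)
                if not acts:
                    continue
                order = sorted(acts)
                pred = np.vstack([acts[a][0] for a in order])
                truth = np.vstack([acts[a][1] for a in order])
                vals.append(_intersection_for(pred, truth, bin_width))
            rows.append({"key": pid, "intersection_mean": float(np.mean(vals)),
                         "intersection_sd": float(np.std(vals))})
    else:
        pid = participant_id if participant_id is not None else predictions.participants()[0]
        per_act: dict[str, list[float]] = {}
        for it in predictions.iterations():
            acts = _concatenate_partial(predictions, pid, it)
            for act, (pred, truth) in acts.items():
                per_act.setdefault(act, []).append(_intersection_for(pred, truth, bin_width))
        for act in sorted(per_act):
            vals = per_act[act]
            rows.append({"key": act, "intersection_mean": float(np.mean(vals)),
                         "intersection_sd": float(np.std(vals))})
    df = pd.DataFrame(rows)
    mean_row = {"key": "mean",
                "intersection_mean": float(df["intersection_mean"].mean()),
                "intersection_sd": float(df["intersection_mean"].std(ddof=0))}
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
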