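"""Stepwise model-selection experiment and reporting.

The selection procedure fixes one factor per step, carrying each step's
winner forward:

1. cross-validation strategy (LOTO vs LOSO) with the complete sensor setup
   and the biLSTM model,
2. sensor setup (complete vs sparse) with the winning strategy,
3. architecture (biLSTM vs feedforward) with the winning strategy and setup.

The winner of a step is the configuration with the higher mean
participant-level PCC, ties broken by lower mean rRMSE.  The orchestrator
also provides the unseen-activity probe: for a participant whose data
retain only a single weight-relief subtrial, the subject-specific LOTO fold
that tests this subtrial has no similar data in its training set, while the
generalizable LOSO model has seen weight-relief lifts from other
participants — so the LOTO prediction of the orphaned subtrial is expected
to be poor relative to both the participant's other folds and the LOSO
prediction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from shoulderload.datasets import (
    SplitPlan,
    SubtrialSample,
    build_sample,
    fit_standardizer,
    get_setup,
    make_loso_folds,
    make_loto_folds,
)
from shoulderload.metrics import (
    PredictionSet,
    activity_level_metrics,
    compute_ftot,
    participant_level_metrics,
    pearson,
)
from shoulderload.models import ModelConfig, predict, train_model
from shoulderload.preprocessing import AlignedTrial, preprocess_cohort
from shoulderload.profiles import profile_report
from shoulderload.synthetic import Cohort, generate_cohort

__all__ = [
    "ExperimentConfig",
    "StepResult",
    "scaled_model_config",
    "build_setup_samples",
    "run_configuration",
    "run_step",
    "run_stepwise_experiment",
    "unseen_activity_probe",
    "final_report",
]

logger = logging.getLogger(__name__)

Key = tuple[int, str, int]


def scaled_model_config(architecture: str = "bilstm", seed: int = 0) -> ModelConfig:
    """Desk-scale model configuration used by the scaled-down runs: same
    layer structure as the full models but 32 units per direction and a
    50-epoch cap."""
    return ModelConfig(architecture=architecture, bilstm_units=32, max_epochs=50, seed=seed)


@dataclass
class ExperimentConfig:
    """Cohort, model and protocol parameters for one stepwise experiment."""

    n_iterations: int = 10
    seed: int = 0
    val_fraction: float = 0.15
    model: ModelConfig = field(default_factory=ModelConfig)
    strategies: tuple[str, str] = ("LOTO", "LOSO")
    setups: tuple[str, str] = ("complete", "sparse")
    architectures: tuple[str, str] = ("bilstm", "linear")
    #: subsample folds (every k-th) to bound compute in reduced runs
    fold_stride: int = 1


@dataclass
class StepResult:
    step: str
    summaries: dict[str, dict[str, float]]  # configuration label -> mean metrics
    winner: str
    participant_tables: dict[str, pd.DataFrame]
    activity_tables: dict[str, pd.DataFrame]
    predictions: dict[str, PredictionSet]


def build_setup_samples(aligned: dict[Key, AlignedTrial], setup_name: str) -> dict[Key, SubtrialSample]:
    setup = get_setup(setup_name)
    return {key: build_sample(trial, setup) for key, trial in aligned.items()}


def _make_folds(manifest: pd.DataFrame, strategy: str, val_fraction: float, seed: int) -> list[SplitPlan]:
    if strategy == "LOSO":
        return make_loso_folds(manifest, val_fraction=val_fraction, seed=seed)
    if strategy == "LOTO":
        folds: list[SplitPlan] = []
        for pid in sorted(int(p) for p in manifest.loc[manifest["valid"], "participant_id"].unique()):
            folds.extend(make_loto_folds(manifest, pid, val_fraction=val_fraction, seed=seed))
        return folds
    raise ValueError(f"unknown strategy {strategy!r}")


def run_configuration(
    samples: dict[Key, SubtrialSample],
    manifest: pd.DataFrame,
    strategy: str,
    model_config: ModelConfig,
    n_iterations: int = 1,
    val_fraction: float = 0.15,
    seed: int = 0,
    fold_stride: int = 1,
) -> PredictionSet:
    """Train all folds × iterations of one configuration and collect
    per-subtrial test predictions in force units."""
    folds = _make_folds(manifest, strategy, val_fraction, seed)[::fold_stride]
    predictions = PredictionSet(entries={})
    for fold in folds:
        train = [samples[k] for k in fold.train]
        val = [samples[k] for k in fold.validation]
        standardizer = fit_standardizer(train)
        for it in range(n_iterations):
            config = replace(model_config, seed=model_config.seed + 1000 * it + fold.fold_id)
            trained = train_model(train, val, standardizer, config)
            logger.info(
                "%s fold %d iter %d: %d epochs, best %d, val %.4f",
                strategy, fold.fold_id, it, trained.n_epochs, trained.best_epoch,
                min(trained.val_loss),
            )
            for key in fold.test:
                sample = samples[key]
                predictions.add(key, it, predict(trained, sample), sample.Y)
    return predictions


def _summarize(predictions: PredictionSet) -> dict[str, float]:
    table = participant_level_metrics(predictions)
    return {
        "pcc": float(table["pcc"].mean()),
        "rrmse": float(table["rrmse"].mean()),
    }


def _pick_winner(summaries: dict[str, dict[str, float]]) -> str:
    labels = list(summaries)
    return max(labels, key=lambda l: (summaries[l]["pcc"], -summaries[l]["rrmse"]))


def run_step(
    step: str,
    configurations: dict[str, tuple[str, str, str]],
    aligned: dict[Key, AlignedTrial],
    manifest: pd.DataFrame,
    config: ExperimentConfig,
) -> StepResult:
    """Run every configuration of one step (label -> (strategy, setup, arch))
    and declare the winner by mean participant-level PCC."""
    summaries, part_tables, act_tables, preds = {}, {}, {}, {}
    for label, (strategy, setup_name, arch) in configurations.items():
        samples = build_setup_samples(aligned, setup_name)
        model_config = replace(config.model, architecture=arch)
        p = run_configuration(
            samples, manifest, strategy, model_config,
            n_iterations=config.n_iterations, val_fraction=config.val_fraction,
            seed=config.seed, fold_stride=config.fold_stride,
        )
        preds[label] = p
        part_tables[label] = participant_level_metrics(p)
        act_tables[label] = activity_level_metrics(p, require_complete=False)
        summaries[label] = _summarize(p)
    winner = _pick_winner(summaries)
    logger.info("step %s winner: %s (%s)", step, winner, summaries[winner])
    return StepResult(step, summaries, winner, part_tables, act_tables, preds)


def run_stepwise_experiment(
    aligned: dict[Key, AlignedTrial],
    manifest: pd.DataFrame,
    config: ExperimentConfig,
) -> dict[str, StepResult]:
    """Three-step selection: strategy → setup → architecture."""
    s1 = run_step(
        "strategy",
        {s: (s, config.setups[0], config.architectures[0]) for s in config.strategies},
        aligned, manifest, config,
    )
    strategy = s1.winner
    s2 = run_step(
        "setup",
        {s: (strategy, s, config.architectures[0]) for s in config.setups},
        aligned, manifest, config,
    )
    setup = s2.winner
    s3 = run_step(
        "architecture",
        {a: (strategy, setup, a) for a in config.architectures},
        aligned, manifest, config,
    )
    return {"strategy": s1, "setup": s2, "architecture": s3}


# ---------------------------------------------------------------------------
# unseen-activity probe


def unseen_activity_probe(
    aligned: dict[Key, AlignedTrial],
    manifest: pd.DataFrame,
    model_config: ModelConfig,
    setup_name: str = "sparse",
    val_fraction: float = 0.15,
    seed: int = 0,
    other_fold_stride: int = 1,
) -> dict | None:
    """Compare LOTO vs LOSO on an orphaned weight-relief subtrial.

    Requires a participant with exactly one valid weight-relief subtrial;
    returns None (with a log message) when no orphan exists.
    ``other_fold_stride`` subsamples the participant's non-orphan folds (the
    orphan fold itself always runs) to bound compute in scaled-down runs.
    """
    valid = manifest[manifest["valid"]]
    wr = valid[valid["activity"] == "weight_relief_lift"].groupby("participant_id").size()
    orphans = [int(p) for p, n in wr.items() if n == 1]
    if not orphans:
        logger.info("unseen-activity probe skipped: no participant with an orphaned weight-relief subtrial")
        return None
    pid = orphans[0]
    samples = build_setup_samples(aligned, setup_name)
    orphan_key = next(
        k for k in samples if k[0] == pid and k[1] == "weight_relief_lift"
    )

    folds = make_loto_folds(manifest, pid, val_fraction=val_fraction, seed=seed)
    orphan_folds = [f for f in folds if f.test[0] == orphan_key]
    other_folds = [f for f in folds if f.test[0] != orphan_key][::other_fold_stride]
    fold_pcc: dict[Key, float] = {}
    for fold in orphan_folds + other_folds:
        train = [samples[k] for k in fold.train]
        val = [samples[k] for k in fold.validation]
        trained = train_model(train, val, fit_standardizer(train), model_config)
        key = fold.test[0]
        sample = samples[key]
        fold_pcc[key] = pearson(compute_ftot(predict(trained, sample)), compute_ftot(sample.Y))

    loso_fold = next(
        f for f in make_loso_folds(manifest, val_fraction=val_fraction, seed=seed)
        if f.test and f.test[0][0] == pid
    )
    train = [samples[k] for k in loso_fold.train]
    val = [samples[k] for k in loso_fold.validation]
    trained = train_model(train, val, fit_standardizer(train), model_config)
    sample = samples[orphan_key]
    loso_pcc = pearson(compute_ftot(predict(trained, sample)), compute_ftot(sample.Y))

    others = [v for k, v in fold_pcc.items() if k != orphan_key]
    return {
        "participant_id": pid,
        "orphan_key": orphan_key,
        "loto_orphan_pcc": fold_pcc[orphan_key],
        "loto_median_other_pcc": float(np.median(others)),
        "loso_orphan_pcc": loso_pcc,
    }


# ---------------------------------------------------------------------------
# reporting


def final_report(results: dict[str, StepResult], out_dir: str | Path,
                 make_plots: bool = True) -> dict:
    """Persist metric tables, load-profile tables and overlay plots for the
    final (winning) configuration; returns the report summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    final = {
        "strategy": results["strategy"].winner,
        "setup": results["setup"].winner,
        "architecture": results["architecture"].winner,
    }
    preds = results["architecture"].predictions[final["architecture"]]
    for name, step in results.items():
        for label, table in step.participant_tables.items():
            table.to_csv(out / f"metrics_participant_{name}_{label}.csv", index=False)
        for label, table in step.activity_tables.items():
            table.to_csv(out / f"metrics_activity_{name}_{label}.csv", index=False)
    table1 = profile_report(preds, scope="participants")
    table2 = profile_report(preds, scope="activities")
    table1.to_csv(out / "load_profile_participants.csv", index=False)
    table2.to_csv(out / "load_profile_activities.csv", index=False)
    summary = {
        "final_configuration": final,
        "step_summaries": {name: step.summaries for name, step in results.items()},
        "mean_intersection": float(table1.loc[table1["key"] == "mean", "intersection_mean"].iloc[0]),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    if make_plots:
        _overlay_plots(preds, out)
    return summary


def _overlay_plots(predictions: PredictionSet, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from shoulderload.metrics import _concatenate_partial

    it = predictions.iterations()[0]
    for pid in predictions.participants():
        acts = _concatenate_partial(predictions, pid, it)
        if not acts:
            continue
        order = sorted(acts)
        pred = np.vstack([acts[a][0] for a in order])
        truth = np.vstack([acts[a][1] for a in order])
        t = np.arange(len(pred)) / 25.0
        fig, ax = plt.subplots(figsize=(10, 3))
        ax.plot(t, compute_ftot(truth), label="ground truth", lw=0.8)
        ax.plot(t, compute_ftot(pred), label="predicted", lw=0.8, alpha=0.8)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("Ftot (N)")
        ax.set_title(f"participant {pid}, complete iteration {it}")
        ax.legend(loc="upper right")
        fig.tight_layout()
        fig.savefig(out / f"ftot_overlay_P{pid:02d}.png", dpi=110)
        plt.close(fig)


# ---------------------------------------------------------------------------
# scaled-down study runs (documented problem sizes; see docs/methods.md)


def parameter_recovery_run(seed: int = 1, n_participants: int = 3,
                           duration_scale: float = 0.35, noise_sd: float = 0.02,
                           n_iterations: int = 1) -> dict:
    """Scaled-down parameter-recovery study: LOTO + sparse + biLSTM on a
    small low-noise cohort; reports mean participant-level PCC and rRMSE and
    the mean load-profile intersection over participants."""
    cohort = generate_cohort(
        n_participants=n_participants, heterogeneity=0.3, noise_sd=noise_sd,
        n_exclusions=0, seed=seed, duration_scale=duration_scale,
    )
    aligned = preprocess_cohort(cohort)
    samples = build_setup_samples(aligned, "sparse")
    preds = run_configuration(
        samples, cohort.manifest, "LOTO", scaled_model_config("bilstm", seed=seed),
        n_iterations=n_iterations, seed=seed,
    )
    table = participant_level_metrics(preds)
    profiles = profile_report(preds, scope="participants")
    return {
        "participant_pcc": float(table["pcc"].mean()),
        "participant_rrmse": float(table["rrmse"].mean()),
        "mean_intersection": float(
            profiles.loc[profiles["key"] == "mean", "intersection_mean"].iloc[0]
        ),
        "n_subtrials": len(samples),
        "n_samples": int(sum(s.n_samples for s in samples.values())),
        "predictions": preds,
    }


def architecture_separation_run(seeds: tuple[int, ...] = (1, 2, 3),
                                duration_scale: float = 0.35,
                                noise_sd: float = 0.2) -> dict:
    """Scaled-down biLSTM-vs-feedforward comparison: single-participant LOTO
    with the sparse setup on a fold subset (every third fold, spanning the
    activities), repeated over several seeds; the nonlinear latent→force
    mapping should favour the recurrent model."""
    per_arch: dict[str, list[float]] = {"bilstm": [], "linear": []}
    for seed in seeds:
        cohort = generate_cohort(
            n_participants=1, heterogeneity=0.3, noise_sd=noise_sd,
            n_exclusions=0, seed=seed, duration_scale=duration_scale,
        )
        aligned = preprocess_cohort(cohort)
        samples = build_setup_samples(aligned, "sparse")
        folds = make_loto_folds(cohort.manifest, 1, seed=seed)[::3]
        for arch in ("bilstm", "linear"):
            # few training sequences per fold: batches of 2 whole sequences
            # give both architectures enough optimizer steps per epoch
            config = replace(scaled_model_config(arch, seed=seed), batch_size=2)
            pccs = []
            for fold in folds:
                train = [samples[k] for k in fold.train]
                val = [samples[k] for k in fold.validation]
                trained = train_model(train, val, fit_standardizer(train), config)
                sample = samples[fold.test[0]]
                pccs.append(pearson(compute_ftot(predict(trained, sample)),
                                    compute_ftot(sample.Y)))
            per_arch[arch].append(float(np.mean(pccs)))
    return {
        "bilstm_pcc": per_arch["bilstm"],
        "linear_pcc": per_arch["linear"],
        "bilstm_mean_pcc": float(np.mean(per_arch["bilstm"])),
        "linear_mean_pcc": float(np.mean(per_arch["linear"])),
    }


def orphan_probe_run(seeds: tuple[int, ...] = (1, 2, 3), n_participants: int = 3,
                     duration_scale: float = 0.35, noise_sd: float = 0.05) -> dict:
    """Scaled-down unseen-activity probe on cohorts with a forced orphaned
    weight-relief subtrial, repeated over several seeds.

    Per seed: the orphan LOTO fold, every third non-orphan LOTO fold of the
    same participant, and the LOSO fold holding that participant out, all
    with the scaled biLSTM at batch size 2 (few sequences per fold; see
    :func:`architecture_separation_run`)."""
    per_seed = []
    for seed in seeds:
        cohort = generate_cohort(
            n_participants=n_participants, heterogeneity=0.15, noise_sd=noise_sd,
            n_exclusions=1, seed=seed, duration_scale=duration_scale,
            force_orphan_weight_relief=True,
        )
        aligned = preprocess_cohort(cohort)
        config = replace(scaled_model_config("bilstm", seed=seed), batch_size=2)
        probe = unseen_activity_probe(
            aligned, cohort.manifest, config, seed=seed, other_fold_stride=3,
        )
        assert probe is not None
        per_seed.append(probe)
    return {
        "per_seed": per_seed,
        "loto_orphan_pcc": float(np.mean([p["loto_orphan_pcc"] for p in per_seed])),
        "loto_median_other_pcc": float(np.mean([p["loto_median_other_pcc"] for p in per_seed])),
        "loso_orphan_pcc": float(np.mean([p["loso_orphan_pcc"] for p in per_seed])),
    }


# ---------------------------------------------------------------------------
# convenience entry point used by the CLI and the acceptance pipeline


def smoke_experiment(
    n_participants: int = 2,
    duration_scale: float = 0.3,
    noise_sd: float = 0.05,
    heterogeneity: float = 0.3,
    n_iterations: int = 1,
    seed: int = 0,
    fold_stride: int = 4,
    model: ModelConfig | None = None,
) -> tuple[dict[str, StepResult], Cohort]:
    """End-to-end reduced run of the full stepwise procedure."""
    cohort = generate_cohort(
        n_participants=n_participants, heterogeneity=heterogeneity, noise_sd=noise_sd,
        n_exclusions=0, seed=seed, duration_scale=duration_scale,
    )
    aligned = preprocess_cohort(cohort)
    config = ExperimentConfig(
        n_iterations=n_iterations, seed=seed,
        model=model if model is not None else scaled_model_config(seed=seed),
        fold_stride=fold_stride,
    )
    results = run_stepwise_experiment(aligned, cohort.manifest, config)
    return results, cohort
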