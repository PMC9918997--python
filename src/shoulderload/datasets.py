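"""Model-ready matrices, sensor setups, cross-validation splits, scaling.

Two sensor setups are supported: the *complete* setup (all 5 IMUs + 2 EMG
channels, 32 input columns) and the *sparse* setup (upper-arm IMU, the two
wheelchair IMUs and both EMG channels, 20 columns).  Cross-validation
follows two designs:

* LOTO (leave-one-trial-out, subject-specific): folds within one
  participant; each valid subtrial is the test set exactly once, the
  remaining subtrials of the same participant are split into train and a
  small validation hold-out used for early stopping.
* LOSO (leave-one-subject-out, generalizable): one fold per participant;
  the held-out participant's subtrials form the test set and all other
  participants supply train/validation.

Standardization (zero mean, unit variance per column, population SD) is
fitted on training subtrials only and applied unchanged to validation and
test data, so no test statistics leak into the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from shoulderload.preprocessing import AlignedTrial, imu_column_names
from shoulderload.synthetic import EMG_CHANNELS

__all__ = [
    "SensorSetup",
    "SubtrialSample",
    "SplitPlan",
    "Standardizer",
    "get_setup",
    "build_sample",
    "make_loto_folds",
    "make_loso_folds",
    "fit_standardizer",
]

Key = tuple[int, str, int]

SPARSE_STREAMS = ("upper_arm", "wc_frame", "wc_wheel")


@dataclass(frozen=True)
class SensorSetup:
    name: str
    included_streams: tuple[str, ...]

    def column_names(self) -> list[str]:
        imu_cols = [c for c in imu_column_names()
                    if any(c.startswith(s + "_") for s in self.included_streams)]
        return imu_cols + [f"emg_{n}" for n in EMG_CHANNELS]

    @property
    def n_columns(self) -> int:
        return len(self.column_names())


_SETUPS = {
    "complete": SensorSetup("complete", ("lower_arm", "upper_arm", "thorax", "wc_frame", "wc_wheel")),
    "sparse": SensorSetup("sparse", SPARSE_STREAMS),
}


def get_setup(name: str) -> SensorSetup:
    try:
        return _SETUPS[name]
    except KeyError:
        raise ValueError(f"unknown sensor setup {name!r}; expected one of {sorted(_SETUPS)}") from None


@dataclass
class SubtrialSample:
    """One subtrial's input matrix X (n, C) and target Y (n, 3)."""

    participant_id: int
    activity: str
    subtrial_index: int
    X: np.ndarray
    Y: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        if self.X.ndim != 2 or self.Y.ndim != 2 or self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y must be 2D with equal row counts")
        if self.Y.shape[1] != 3:
            raise ValueError("Y must have exactly 3 columns (Fx, Fy, Fz)")
        if np.any(~np.isfinite(self.X)) or np.any(~np.isfinite(self.Y)):
            raise ValueError("sample contains non-finite values")

    @property
    def key(self) -> Key:
        return (self.participant_id, self.activity, self.subtrial_index)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


def build_sample(trial: AlignedTrial, setup: SensorSetup) -> SubtrialSample:
    """Select the setup's channels from an aligned trial, in fixed order."""
    all_imu = imu_column_names()
    idx = [all_imu.index(c) for c in setup.column_names() if not c.startswith("emg_")]
    X = np.hstack([trial.imu[:, idx], trial.emg])
    return SubtrialSample(
        participant_id=trial.participant_id,
        activity=trial.activity,
        subtrial_index=trial.subtrial_index,
        X=X,
        Y=trial.sjrf.copy(),
        columns=setup.column_names(),
    )


# ---------------------------------------------------------------------------
# cross-validation splits


@dataclass
class SplitPlan:
    strategy: str  # "LOTO" | "LOSO"
    fold_id: int
    train: list[Key]
    validation: list[Key]
    test: list[Key]

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.validation), set(self.test)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("train/validation/test sets must be pairwise disjoint")
        if not self.train or not self.test:
            raise ValueError("train and test sets must be non-empty")

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "fold_id": self.fold_id,
            "train": [list(k) for k in self.train],
            "validation": [list(k) for k in self.validation],
            "test": [list(k) for k in self.test],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplitPlan":
        as_keys = lambda ks: [(int(p), str(a), int(s)) for p, a, s in ks]
        return cls(d["strategy"], int(d["fold_id"]), as_keys(d["train"]),
                   as_keys(d["validation"]), as_keys(d["test"]))


def _validation_holdout(pool: list[Key], val_fraction: float, rng: np.random.Generator) -> tuple[list[Key], list[Key]]:
    """Split a training pool into train and validation at subtrial
    granularity, roughly stratified by activity."""
    n_val = max(1, int(round(val_fraction * len(pool))))
    by_activity: dict[str, list[Key]] = {}
    for k in pool:
        by_activity.setdefault(k[1], []).append(k)
    validation: list[Key] = []
    activities = sorted(by_activity)
    order = rng.permutation(len(activities))
    # round-robin over activities so the hold-out is spread across them
    while len(validation) < n_val:
        progressed = False
        for i in order:
            act_pool = by_activity[activities[i]]
            if len(act_pool) > 1:  # keep at least one subtrial per activity in train
                j = int(rng.integers(len(act_pool)))
                validation.append(act_pool.pop(j))
                progressed = True
                if len(validation) >= n_val:
                    break
        if not progressed:
            break
    train = [k for k in pool if k not in set(validation)]
    return train, validation


def _valid_keys(manifest, participant_id: int | None = None) -> list[Key]:
    df = manifest[manifest["valid"]]
    if participant_id is not None:
        df = df[df["participant_id"] == participant_id]
    return [(int(r.participant_id), str(r.activity), int(r.subtrial_index)) for r in df.itertuples()]


def make_loto_folds(manifest, participant_id: int, val_fraction: float = 0.15,
                    seed: int = 0) -> list[SplitPlan]:
    """Leave-one-trial-out folds for one participant: one fold per valid
    subtrial, validation carved from the remaining subtrials."""
    keys = _valid_keys(manifest, participant_id)
    if len(keys) < 3:
        raise ValueError(
            f"participant {participant_id} has {len(keys)} valid subtrials; LOTO needs at least 3"
        )
    folds = []
    for fold_id, test_key in enumerate(keys):
        rng = np.random.default_rng([seed, participant_id, fold_id, 505])
        pool = [k for k in keys if k != test_key]
        train, validation = _validation_holdout(pool, val_fraction, rng)
        folds.append(SplitPlan("LOTO", fold_id, train, validation, [test_key]))
    return folds


def make_loso_folds(manifest, val_fraction: float = 0.15, seed: int = 0) -> list[SplitPlan]:
    """Leave-one-subject-out folds: one per participant."""
    participants = sorted(int(p) for p in manifest.loc[manifest["valid"], "participant_id"].unique())
    if len(participants) < 2:
        raise ValueError("LOSO needs at least 2 participants")
    folds = []
    for fold_id, pid in enumerate(participants):
        rng = np.random.default_rng([seed, pid, 606])
        test = _valid_keys(manifest, pid)
        pool = [k for k in _valid_keys(manifest) if k[0] != pid]
        train, validation = _validation_holdout(pool, val_fraction, rng)
        folds.append(SplitPlan("LOSO", fold_id, train, validation, test))
    return folds


# ---------------------------------------------------------------------------
# standardization


@dataclass
class Standardizer:
    """Per-column mean/SD for X and Y, fitted on training subtrials only."""

    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    columns: list[str] = field(default_factory=list)

    def transform_x(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) / self.x_std

    def transform_y(self, Y: np.ndarray) -> np.ndarray:
        return (Y - self.y_mean) / self.y_std

    def inverse_y(self, Yz: np.ndarray) -> np.ndarray:
        return Yz * self.y_std + self.y_mean


def fit_standardizer(train_samples: list[SubtrialSample]) -> Standardizer:
    """Pool all training rows and fit per-column mean and population SD.

    A constant column is an error: it carries no information and would make
    the transform non-invertible.
    """
    if not train_samples:
        raise ValueError("cannot fit a standardizer on an empty training set")
    X = np.vstack([s.X for s in train_samples])
    Y = np.vstack([s.Y for s in train_samples])
    columns = train_samples[0].columns
    x_std = X.std(axis=0)
    y_std = Y.std(axis=0)
    bad = np.flatnonzero(x_std == 0)
    if bad.size:
        names = [columns[i] for i in bad]
        raise ValueError(f"constant input column(s): {names}")
    if np.any(y_std == 0):
        raise ValueError("constant target column")
    return Standardizer(X.mean(axis=0), x_std, Y.mean(axis=0), y_std, list(columns))
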