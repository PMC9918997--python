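"""Signal preprocessing: filtering, EMG envelopes, synchronization, alignment.

Raw multi-rate streams are transformed into one aligned 25 Hz trial:

* IMU channels: zero-phase 4th-order Butterworth low-pass at 10 Hz, then
  resampled to 25 Hz,
* EMG channels: high-pass 20 Hz → offset correction (mean subtraction) →
  full-wave rectification → low-pass 3 Hz → division by the submaximal
  static-posture reference → clipped at 0 → resampled to 25 Hz,
* SJRF target: low-pass 4 Hz, resampled to 25 Hz,
* inter-stream clock offsets estimated by normalized cross-correlation on a
  fiducial burst against a designated reference stream (upper-arm IMU) and
  removed before resampling.

All filters are applied zero-phase (forward–backward) by default, the
biomechanics convention, which squares the single-pass magnitude response
(−3 dB at the cutoff becomes a factor 0.5) and keeps inputs and targets
delay-free relative to each other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, lfilter

from shoulderload.synthetic import (
    EMG_CHANNELS,
    EMG_FS,
    IMU_CHANNEL_NAMES,
    IMU_FS,
    IMU_STREAMS,
    REFERENCE_STREAM,
    SJRF_FS,
    Cohort,
    SensorRecording,
)

__all__ = [
    "TARGET_FS",
    "FilterSpec",
    "EmgNormalizationReference",
    "AlignedTrial",
    "butterworth_filter",
    "process_imu",
    "process_emg",
    "process_sjrf",
    "compute_emg_reference",
    "synchronize_streams",
    "align_trial",
    "preprocess_cohort",
    "imu_column_names",
]

TARGET_FS = 25.0  # Hz, shared grid of the aligned trial

#: default filter specifications
IMU_FILTER_CUTOFF_HZ = 10.0
EMG_HIGHPASS_CUTOFF_HZ = 20.0
EMG_ENVELOPE_CUTOFF_HZ = 3.0
SJRF_FILTER_CUTOFF_HZ = 4.0
FILTER_ORDER = 4


class ConfigurationError(ValueError):
    """Raised for invalid filter configuration (e.g. cutoff above Nyquist)."""


@dataclass(frozen=True)
class FilterSpec:
    kind: str  # "low-pass" | "high-pass"
    cutoff_hz: float
    order: int = FILTER_ORDER
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("low-pass", "high-pass"):
            raise ConfigurationError(f"unknown filter kind {self.kind!r}")
        if self.order < 1:
            raise ConfigurationError("filter order must be >= 1")


@dataclass(frozen=True)
class EmgNormalizationReference:
    """Submaximal-contraction normalization reference for one muscle."""

    muscle: str
    reference_value: float
    source_window_s: tuple[float, float]

    def __post_init__(self) -> None:
        if self.reference_value <= 0:
            raise ValueError(f"reference_value must be > 0 for {self.muscle}")


def butterworth_filter(signal: np.ndarray, fs: float, spec: FilterSpec,
                       channel: str = "signal") -> np.ndarray:
    """Apply a Butterworth filter along the first axis.

    Zero-phase application runs the filter forward and backward
    (``filtfilt``) with reflect padding of length ``3 × order``, so the
    effective magnitude response is the squared single-pass response and the
    group delay is zero.
    """
    signal = np.asarray(signal, dtype=float)
    nyquist = fs / 2.0
    if not (0 < spec.cutoff_hz < nyquist):
        raise ConfigurationError(
            f"cutoff {spec.cutoff_hz} Hz out of (0, {nyquist}) Hz for channel {channel!r}"
        )
    btype = "lowpass" if spec.kind == "low-pass" else "highpass"
    b, a = butter(spec.order, spec.cutoff_hz / nyquist, btype=btype)
    padlen = 3 * spec.order
    if signal.shape[0] <= padlen:
        raise ValueError(f"signal too short ({signal.shape[0]} samples) for filter warm-up on {channel!r}")
    if spec.zero_phase:
        return filtfilt(b, a, signal, axis=0, padtype="even", padlen=padlen)
    return lfilter(b, a, signal, axis=0)


def _target_grid(t_start: float, duration_s: float, fs: float = TARGET_FS) -> np.ndarray:
    n = int(np.floor(duration_s * fs))
    return t_start + np.arange(n) / fs


def _resample(t_src: np.ndarray, x: np.ndarray, t_target: np.ndarray) -> np.ndarray:
    """Linear interpolation onto the target grid (column-wise for 2D)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return np.interp(t_target, t_src, x)
    return np.column_stack([np.interp(t_target, t_src, x[:, j]) for j in range(x.shape[1])])


def process_imu(t: np.ndarray, data: np.ndarray, fs: float = IMU_FS,
                t_target: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Low-pass (10 Hz, zero-phase) an IMU stream and resample it to 25 Hz."""
    spec = FilterSpec("low-pass", IMU_FILTER_CUTOFF_HZ)
    filtered = butterworth_filter(data, fs, spec, channel="imu")
    if t_target is None:
        t_target = _target_grid(float(t[0]), float(t[-1] - t[0]))
    return t_target, _resample(t, filtered, t_target)


def process_sjrf(t: np.ndarray, data: np.ndarray, fs: float = SJRF_FS,
                 t_target: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Low-pass (4 Hz, zero-phase) the force series and resample it to 25 Hz."""
    if not np.all(np.isfinite(data)):
        raise ValueError("SJRF series contains non-finite values")
    spec = FilterSpec("low-pass", SJRF_FILTER_CUTOFF_HZ)
    filtered = butterworth_filter(data, fs, spec, channel="sjrf")
    if t_target is None:
        t_target = _target_grid(float(t[0]), float(t[-1] - t[0]))
    return t_target, _resample(t, filtered, t_target)


def _emg_envelope(x: np.ndarray, fs: float) -> np.ndarray:
    """Pre-normalization EMG envelope: high-pass 20 Hz → demean → rectify →
    low-pass 3 Hz, all 4th-order zero-phase Butterworth."""
    hp = butterworth_filter(x, fs, FilterSpec("high-pass", EMG_HIGHPASS_CUTOFF_HZ), channel="emg")
    hp = hp - hp.mean(axis=0)
    rect = np.abs(hp)
    return butterworth_filter(rect, fs, FilterSpec("low-pass", EMG_ENVELOPE_CUTOFF_HZ), channel="emg")


def process_emg(t: np.ndarray, raw: np.ndarray, reference: EmgNormalizationReference,
                fs: float = EMG_FS,
                t_target: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Full EMG chain for one channel: envelope, normalize, clip, resample.

    The output is the muscle activity as a dimensionless fraction of the
    submaximal static-posture reference, non-negative, at 25 Hz.
    """
    env = _emg_envelope(np.asarray(raw, dtype=float), fs)
    env = np.clip(env / reference.reference_value, 0.0, None)
    if t_target is None:
        t_target = _target_grid(float(t[0]), float(t[-1] - t[0]))
    return t_target, _resample(t, env, t_target)


def compute_emg_reference(t: np.ndarray, raw: np.ndarray, window_s: tuple[float, float],
                          muscle: str, fs: float = EMG_FS) -> EmgNormalizationReference:
    """Mean of the pre-normalization envelope over a static-posture window."""
    lo, hi = window_s
    if hi <= lo:
        raise ValueError("empty normalization window")
    mask = (t >= lo) & (t <= hi)
    if not np.any(mask):
        raise ValueError(f"window {window_s} outside the static recording for {muscle}")
    env = _emg_envelope(np.asarray(raw, dtype=float), fs)
    value = float(env[mask].mean())
    return EmgNormalizationReference(muscle=muscle, reference_value=value, source_window_s=(lo, hi))


# ---------------------------------------------------------------------------
# synchronization


def _sync_signal(t: np.ndarray, data: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Scalar synchronization trace: summed absolute deviation from the
    median across channels, interpolated onto a common 128 Hz grid."""
    data = np.atleast_2d(np.asarray(data, dtype=float).T).T
    s = np.abs(data - np.median(data, axis=0, keepdims=True)).sum(axis=1)
    out = np.interp(grid, t, s, left=0.0, right=0.0)
    out = out - out.mean()
    norm = np.linalg.norm(out)
    return out / norm if norm > 0 else out


def synchronize_streams(recording: SensorRecording, max_lag_s: float = 2.0,
                        peak_threshold: float = 0.2) -> dict[str, float]:
    """Estimate each stream's clock offset relative to the reference stream.

    A stream with offset ``d`` records a master-clock event of time ``tau``
    at local time ``tau + d``; the returned estimates are ``d`` per stream
    (0 for the reference).  Estimation maximizes the normalized
    cross-correlation of fiducial-burst traces over lags within
    ``±max_lag_s``; a peak below ``peak_threshold`` triggers a warning and a
    zero offset.
    """
    fs = IMU_FS
    t_ref, ref_data = recording.imu[REFERENCE_STREAM]
    grid = np.arange(int(np.floor((t_ref[-1]) * fs))) / fs
    ref = _sync_signal(t_ref, ref_data, grid)
    max_lag = int(round(max_lag_s * fs))

    offsets: dict[str, float] = {}
    streams: dict[str, tuple[np.ndarray, np.ndarray]] = dict(recording.imu)
    streams["emg"] = recording.emg
    for name, (t, data) in streams.items():
        if name == REFERENCE_STREAM:
            offsets[name] = 0.0
            continue
        sig = _sync_signal(t, data, grid)
        corr = np.correlate(sig, ref, mode="full")  # index lag: sig leads ref
        lags = np.arange(-len(ref) + 1, len(ref))
        window = np.abs(lags) <= max_lag
        corr, lags = corr[window], lags[window]
        k = int(np.argmax(corr))
        if corr[k] < peak_threshold:
            warnings.warn(
                f"synchronization peak {corr[k]:.2f} below threshold for stream {name!r}; assuming zero offset",
                stacklevel=2,
            )
            offsets[name] = 0.0
        else:
            offsets[name] = float(lags[k] / fs)
    return offsets


# ---------------------------------------------------------------------------
# aligned trial


def imu_column_names() -> list[str]:
    """Documented fixed order of the 30 IMU columns."""
    return [f"{stream}_{ch}" for stream in IMU_STREAMS for ch in IMU_CHANNEL_NAMES]


@dataclass
class AlignedTrial:
    """One subtrial aligned on the shared 25 Hz grid.

    ``imu`` is (n, 30) in the fixed :func:`imu_column_names` order, ``emg``
    (n, 2) dimensionless non-negative normalized envelopes, and ``sjrf``
    (n, 3) low-pass-filtered forces in newtons.
    """

    participant_id: int
    activity: str
    subtrial_index: int
    time_s: np.ndarray
    imu: np.ndarray
    emg: np.ndarray
    sjrf: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time_s)
        if not (self.imu.shape == (n, 30) and self.emg.shape == (n, 2) and self.sjrf.shape == (n, 3)):
            raise ValueError("aligned trial arrays are inconsistent")
        if np.any(~np.isfinite(self.imu)) or np.any(~np.isfinite(self.emg)) or np.any(~np.isfinite(self.sjrf)):
            raise ValueError("aligned trial contains non-finite values")
        if np.any(self.emg < 0):
            raise ValueError("EMG columns must be non-negative after processing")

    @property
    def key(self) -> tuple[int, str, int]:
        return (self.participant_id, self.activity, self.subtrial_index)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.time_s})
        for j, name in enumerate(imu_column_names()):
            df[name] = self.imu[:, j]
        for j, name in enumerate(EMG_CHANNELS):
            df[f"emg_{name}"] = self.emg[:, j]
        for j, name in enumerate(("Fx", "Fy", "Fz")):
            df[name] = self.sjrf[:, j]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, participant_id: int, activity: str,
                   subtrial_index: int) -> "AlignedTrial":
        imu_cols = imu_column_names()
        emg_cols = [f"emg_{n}" for n in EMG_CHANNELS]
        return cls(
            participant_id=participant_id,
            activity=activity,
            subtrial_index=subtrial_index,
            time_s=df["time_s"].to_numpy(),
            imu=df[imu_cols].to_numpy(),
            emg=df[emg_cols].to_numpy(),
            sjrf=df[["Fx", "Fy", "Fz"]].to_numpy(),
        )


def default_emg_references(static: SensorRecording,
                           window_s: tuple[float, float] | None = None) -> dict[str, EmgNormalizationReference]:
    """References from a participant's static recording, one per muscle.

    The default window covers the middle of the held posture (skipping the
    pre-trial burst segment).
    """
    t, raw = static.emg
    if window_s is None:
        a, b = static.trial_window_s
        window_s = (a + 0.2 * (b - a), b - 0.1 * (b - a))
    return {
        muscle: compute_emg_reference(t, raw[:, j], window_s, muscle)
        for j, muscle in enumerate(EMG_CHANNELS)
    }


def align_trial(recording: SensorRecording,
                emg_references: dict[str, EmgNormalizationReference],
                offsets: dict[str, float] | None = None) -> AlignedTrial:
    """Synchronize, filter and resample one recording onto the 25 Hz grid.

    The aligned window is the protocol-known activity window (after the
    synchronization motion), expressed on the reference-stream clock.
    """
    if offsets is None:
        offsets = synchronize_streams(recording)
    t0, t1 = recording.trial_window_s
    grid = _target_grid(t0, t1 - t0)

    imu_blocks = []
    for stream in IMU_STREAMS:
        t, data = recording.imu[stream]
        t_true = t - offsets.get(stream, 0.0)
        _, resampled = process_imu(t_true, data, t_target=grid)
        imu_blocks.append(resampled)
    imu = np.hstack(imu_blocks)

    t, raw = recording.emg
    t_true = t - offsets.get("emg", 0.0)
    emg_cols = []
    for j, muscle in enumerate(EMG_CHANNELS):
        _, env = process_emg(t_true, raw[:, j], emg_references[muscle], t_target=grid)
        emg_cols.append(env)
    emg = np.column_stack(emg_cols)

    t, force = recording.sjrf
    _, sjrf = process_sjrf(t, force, t_target=grid)

    return AlignedTrial(
        participant_id=recording.participant_id,
        activity=recording.activity,
        subtrial_index=recording.subtrial_index,
        time_s=grid,
        imu=imu,
        emg=emg,
        sjrf=sjrf,
    )


def preprocess_cohort(cohort: Cohort, valid_only: bool = True) -> dict[tuple[int, str, int], AlignedTrial]:
    """Align every (valid) subtrial of a cohort.

    EMG normalization references are computed once per participant from the
    static-posture recording.
    """
    refs = {pid: default_emg_references(rec) for pid, rec in cohort.statics.items()}
    keys = cohort.valid_keys() if valid_only else list(cohort.recordings)
    return {key: align_trial(cohort.recordings[key], refs[key[0]]) for key in keys}
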