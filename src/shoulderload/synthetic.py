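"""Synthetic wheelchair-activity cohort generator.

Emulates the data structure of a wearable-sensor study of manual wheelchair
users: each participant performs eight activities (treadmill propulsion at
three conditions, propulsion in a restricted space, ramp negotiation,
weight-relief lifts, manual material handling and desk work), recorded with
five IMUs (128 Hz, tri-axial acceleration and angular velocity), two EMG
channels (1024 Hz) and a ground-truth 3D shoulder-joint reaction force
(SJRF) series at 100 Hz.  Activities are split into 19 subtrials per
participant; a default cohort of 10 participants with 7 excluded subtrials
yields 183 valid subtrials.

The generative model is intentionally simple but well-posed: a small set of
smooth latent states per activity — arm elevation angle ``theta`` (rad),
normalized push force ``push`` in [0, 1], and two muscle activations
``act1``/``act2`` in [0, 1] — drive both the sensor channels and the SJRF
target through a documented nonlinear mapping (see :func:`sjrf_from_latents`).
Because the mapping contains a rectified push term and an
activation-times-elevation product, a purely feedforward affine model is
misspecified while the latent states remain recoverable from the emitted
channels, so sequence models can learn the task.

Every stream except the reference (upper-arm IMU) and the force series
carries a hidden clock offset drawn from ±0.5 s, and every stream starts
with a high-amplitude triphasic fiducial burst, giving the cross-correlation
synchronization stage a ground truth to recover.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ACTIVITIES",
    "IMU_STREAMS",
    "EMG_CHANNELS",
    "IMU_FS",
    "EMG_FS",
    "SJRF_FS",
    "PRE_TRIAL_S",
    "SJRF_COEFFS",
    "ParticipantTraits",
    "SensorRecording",
    "Cohort",
    "sample_traits",
    "evaluate_latents",
    "sjrf_from_latents",
    "generate_trial",
    "generate_static_recording",
    "build_manifest",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
]

# ---------------------------------------------------------------------------
# protocol constants

IMU_FS = 128.0  # Hz
EMG_FS = 1024.0  # Hz
SJRF_FS = 100.0  # Hz, native rate of the force series before downsampling

#: seconds of pre-trial recording holding the synchronization burst
PRE_TRIAL_S = 1.6
#: fiducial burst: centre time (true clock) and duration
BURST_CENTER_S = 0.9
BURST_DURATION_S = 0.6
#: extra recording tail so every stream covers the trial for any |offset|<=0.5 s
RECORD_PAD_S = 0.6
MAX_OFFSET_S = 0.5

IMU_STREAMS = ("lower_arm", "upper_arm", "thorax", "wc_frame", "wc_wheel")
EMG_CHANNELS = ("biceps_long_head", "deltoid_medial")
#: reference stream for synchronization; carries no clock offset
REFERENCE_STREAM = "upper_arm"

IMU_CHANNEL_NAMES = ("acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z")

#: the eight evaluation activities: name -> (n_subtrials, subtrial duration s)
ACTIVITIES: dict[str, tuple[int, float]] = {
    "weight_relief_lift": (2, 10.0),
    "propulsion_restricted": (3, 15.0),
    "propulsion_slow": (2, 15.0),  # treadmill, 0.56 m/s, level
    "propulsion_fast": (2, 15.0),  # treadmill, 1.1 m/s, level
    "propulsion_incline": (2, 15.0),  # treadmill, 0.56 m/s, 6 % incline
    "ramp": (2, 8.0),  # subtrial 0 = ascend, 1 = descend
    "material_handling": (3, 12.0),
    "desk_work": (3, 10.0),
}

_ACT_INDEX = {name: i for i, name in enumerate(ACTIVITIES)}

#: activation level held during the static normalization postures
STATIC_ACTIVATION = 0.4
STATIC_DURATION_S = 6.0

GRAVITY = 9.81  # m/s^2
RAD2DEG = 180.0 / np.pi

#: coefficients of the latent-state -> SJRF mapping, in newtons.
#: Fx = push_gain * max(push_slow - push_knee, 0)**2 * m + act1_gain_x * act1_slow + base_x
#: Fy = elev_act_gain * m * act2_slow * sin(theta) + theta_gain * theta
#: Fz = mass_gain * m + act1_gain_z * m * act1_slow + elev_gain_z * sin(theta)
#: with m = body_mass_scale and *_slow first-order lags (time constant
#: ``lag_tau_s``) of push force and muscle activations, emulating
#: activation-to-force dynamics (muscle force build-up and decay).  The
#: rectified-quadratic lagged push term and the act2_slow*sin(theta) product
#: are the deliberate non-affine components (the quadratic branch is only
#: reached during sustained pushes, so it must be learned from data that
#: contain them), and the lag states make the mapping non-instantaneous: a
#: per-sample affine or feedforward model cannot reconstruct them from the
#: current sensor sample alone.
SJRF_COEFFS = {
    "push_gain": 250.0,
    "push_knee": 0.4,
    "lag_tau_s": 0.8,
    "act1_gain_x": 30.0,
    "base_x": 5.0,
    "elev_act_gain": 120.0,
    "theta_gain": 20.0,
    "mass_gain": 40.0,
    "act1_gain_z": 60.0,
    "elev_gain_z": 25.0,
}


# ---------------------------------------------------------------------------
# participant traits


@dataclass(frozen=True)
class ParticipantTraits:
    """Per-participant generative parameters.

    ``body_mass_scale`` multiplies force magnitudes, ``cadence_hz`` sets the
    propulsion cycle frequency, ``emg_gain`` is a per-muscle amplifier gain
    pair (dimensionless; cancelled by submaximal normalization), and
    ``kinematic_offset`` is an additive per-axis bias (m/s²) on every IMU
    accelerometer channel, emulating mounting differences.
    """

    participant_id: int
    body_mass_scale: float
    cadence_hz: float
    emg_gain: tuple[float, float]
    kinematic_offset: tuple[float, float, float]
    seed: int


#: documented trait-distribution spread at heterogeneity = 1
TRAIT_SD = {
    "body_mass_scale": 0.25,
    "cadence_hz": 0.35,
    "log_emg_gain": 0.30,
    "kinematic_offset": 0.50,
}


def sample_traits(participant_id: int, heterogeneity: float = 0.3, seed: int = 0) -> ParticipantTraits:
    """Draw participant traits; spread scales linearly with ``heterogeneity``.

    ``heterogeneity = 0`` yields identical nominal traits for every
    participant; identical ``(participant_id, heterogeneity, seed)`` yields
    identical traits.
    """
    if heterogeneity < 0:
        raise ValueError("heterogeneity must be >= 0")
    rng = np.random.default_rng([seed, participant_id, 101])
    h = float(heterogeneity)
    body_mass_scale = float(np.clip(1.0 + h * TRAIT_SD["body_mass_scale"] * rng.standard_normal(), 0.3, None))
    cadence_hz = float(np.clip(1.0 + h * TRAIT_SD["cadence_hz"] * rng.standard_normal(), 0.6, 1.8))
    emg_gain = tuple(float(np.exp(h * TRAIT_SD["log_emg_gain"] * z)) for z in rng.standard_normal(2))
    kinematic_offset = tuple(float(h * TRAIT_SD["kinematic_offset"] * z) for z in rng.standard_normal(3))
    return ParticipantTraits(
        participant_id=int(participant_id),
        body_mass_scale=body_mass_scale,
        cadence_hz=cadence_hz,
        emg_gain=emg_gain,  # type: ignore[arg-type]
        kinematic_offset=kinematic_offset,  # type: ignore[arg-type]
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# latent-state templates


@dataclass(frozen=True)
class LatentSpec:
    """Deterministic recipe for one subtrial's latent-state trajectories.

    ``params`` holds the activity-specific randomized constants (phases,
    pulse centres, Fourier components) drawn once per subtrial, so that the
    latent states can be re-evaluated at arbitrary times.
    """

    activity: str
    duration_s: float
    params: dict

    def __call__(self, t: np.ndarray) -> dict[str, np.ndarray]:
        return evaluate_latents(self, t)


def _latent_spec(activity: str, traits: ParticipantTraits, subtrial_index: int, duration_s: float) -> LatentSpec:
    if activity not in ACTIVITIES and activity != "static_posture":
        raise ValueError(f"unknown activity {activity!r}")
    rng = np.random.default_rng(
        [traits.seed, traits.participant_id, _ACT_INDEX.get(activity, 99), subtrial_index, 202]
    )
    p: dict = {"cadence_hz": traits.cadence_hz}
    if activity in ("propulsion_slow", "propulsion_fast", "propulsion_incline", "propulsion_restricted", "ramp"):
        speed = {"propulsion_slow": 1.0, "propulsion_fast": 1.4, "propulsion_incline": 0.85,
                 "propulsion_restricted": 0.9, "ramp": 0.7}[activity]
        force = {"propulsion_slow": 0.75, "propulsion_fast": 0.85, "propulsion_incline": 1.0,
                 "propulsion_restricted": 0.7, "ramp": 1.0}[activity]
        if activity == "ramp" and subtrial_index == 1:  # descend: light braking
            speed, force = 0.6, 0.3
        p.update(
            kind="cyclic",
            freq_hz=traits.cadence_hz * speed,
            force_amp=force,
            theta0=0.55,
            theta_amp=0.35,
            phase=float(rng.uniform(0, 2 * np.pi)),
            mod_depth=0.3 if activity == "propulsion_restricted" else 0.0,
            mod_freq_hz=0.12,
            mod_phase=float(rng.uniform(0, 2 * np.pi)),
        )
    elif activity == "weight_relief_lift":
        p.update(
            kind="hold",
            t_on=0.2 * duration_s,
            t_off=0.8 * duration_s,
            edge_s=0.4,
            push_level=0.95,
            act_levels=(0.9, 0.85),
            theta0=0.15,
            theta_lift=0.35,
            # staggered timing: act1 leads the lift, push force builds late
            act1_lead_s=0.4,
            push_lag_s=0.3,
            # postural tremor under sustained load
            tremor_hz=2.2,
            tremor_amp=0.05,
            tremor_phase=float(rng.uniform(0, 2 * np.pi)),
        )
    elif activity == "material_handling":
        centers = duration_s * (np.array([0.2, 0.5, 0.8]) + rng.uniform(-0.04, 0.04, 3))
        p.update(
            kind="pulses",
            centers=[float(c) for c in centers],
            width_s=0.8,
            theta0=0.2,
            theta_pulse=1.0,
            act_pulse=(0.55, 0.5),
            push_pulse=0.25,
        )
    elif activity == "desk_work":
        k = 4
        p.update(
            kind="fourier",
            freqs_hz=[float(f) for f in rng.uniform(0.1, 1.5, k)],
            amps=[float(a) for a in rng.uniform(0.01, 0.05, k)],
            phases=[float(ph) for ph in rng.uniform(0, 2 * np.pi, k)],
            theta0=0.25,
            act0=0.05,
        )
    elif activity == "static_posture":
        p.update(kind="static", theta0=np.pi / 2, act_level=STATIC_ACTIVATION)
    return LatentSpec(activity=activity, duration_s=float(duration_s), params=p)


def _base_latents(spec: LatentSpec, t: np.ndarray) -> dict[str, np.ndarray]:
    t = np.clip(np.asarray(t, dtype=float), 0.0, spec.duration_s)
    p = spec.params
    kind = p["kind"]
    if kind == "cyclic":
        w = 2 * np.pi * p["freq_hz"]
        mod = 1.0 + p["mod_depth"] * np.sin(2 * np.pi * p["mod_freq_hz"] * t + p["mod_phase"])
        s = np.sin(w * t + p["phase"])
        theta = p["theta0"] + p["theta_amp"] * mod * s
        push = p["force_amp"] * mod * np.maximum(np.sin(w * t + p["phase"] + 0.5), 0.0)
        act1 = 0.15 + 0.55 * p["force_amp"] * mod * np.maximum(np.sin(w * t + p["phase"] + 0.9), 0.0)
        act2 = 0.15 + 0.45 * p["force_amp"] * mod * np.maximum(np.sin(w * t + p["phase"] + 0.2), 0.0)
    elif kind == "hold":
        def _hold(tt):
            return _sigmoid((tt - p["t_on"]) / p["edge_s"]) * _sigmoid((p["t_off"] - tt) / p["edge_s"])

        hold = _hold(t)
        theta = p["theta0"] + p["theta_lift"] * hold
        if p.get("tremor_amp", 0.0) > 0:
            theta = theta + p["tremor_amp"] * hold * np.sin(2 * np.pi * p["tremor_hz"] * t + p["tremor_phase"])
        push = p["push_level"] * _hold(t - p.get("push_lag_s", 0.0))
        act1 = 0.1 + p["act_levels"][0] * _hold(t + p.get("act1_lead_s", 0.0))
        act2 = 0.1 + p["act_levels"][1] * hold
    elif kind == "pulses":
        pulses = np.zeros_like(t)
        for c in p["centers"]:
            pulses += np.exp(-0.5 * ((t - c) / p["width_s"]) ** 2)
        pulses = np.clip(pulses, 0.0, 1.0)
        theta = p["theta0"] + p["theta_pulse"] * pulses
        push = p["push_pulse"] * pulses
        act1 = 0.1 + p["act_pulse"][0] * pulses
        act2 = 0.1 + p["act_pulse"][1] * pulses
    elif kind == "fourier":
        wander = np.zeros_like(t)
        for f, a, ph in zip(p["freqs_hz"], p["amps"], p["phases"]):
            wander += a * np.sin(2 * np.pi * f * t + ph)
        theta = p["theta0"] + wander
        push = np.zeros_like(t)
        act1 = p["act0"] + np.clip(wander, 0.0, None)
        act2 = p["act0"] + np.clip(-wander, 0.0, None)
    elif kind == "static":
        theta = np.full_like(t, p["theta0"])
        push = np.zeros_like(t)
        act1 = np.full_like(t, p["act_level"])
        act2 = np.full_like(t, p["act_level"])
    else:  # pragma: no cover
        raise ValueError(f"unknown latent kind {kind!r}")

    return {
        "theta": theta,
        "push": np.clip(push, 0.0, 1.2),
        "act1": np.clip(act1, 0.0, 1.0),
        "act2": np.clip(act2, 0.0, 1.0),
    }


#: internal grid rate (Hz) for the lagged force-buildup states
_LAG_GRID_FS = 100.0


def _lagged_states(spec: LatentSpec, t: np.ndarray) -> dict[str, np.ndarray]:
    """First-order lags (time constant ``lag_tau_s``) of push force and
    muscle activations, computed by exponential smoothing on a dense
    internal grid and interpolated at ``t``; emulates activation-to-force
    dynamics."""
    from scipy.signal import lfilter

    tau = SJRF_COEFFS["lag_tau_s"]
    dt = 1.0 / _LAG_GRID_FS
    grid = np.arange(0.0, spec.duration_s + dt, dt)
    base = _base_latents(spec, grid)
    alpha = np.exp(-dt / tau)
    t_clip = np.clip(np.asarray(t, dtype=float), 0.0, spec.duration_s)
    out = {}
    for key in ("push", "act1", "act2"):
        x = base[key]
        q, _ = lfilter([1.0 - alpha], [1.0, -alpha], x, zi=np.array([alpha * x[0]]))
        out[f"{key}_slow"] = np.interp(t_clip, grid, q)
    return out


def evaluate_latents(spec: LatentSpec, t: np.ndarray) -> dict[str, np.ndarray]:
    """Evaluate the latent states of ``spec`` at trial-local times ``t`` (s).

    Returns ``theta`` (rad) with its numeric derivatives, ``push`` in
    [0, 1.2], the two muscle activations in [0, 1], and the lagged
    force-buildup states ``push_slow``/``act1_slow``/``act2_slow``.  Times
    are clamped to ``[0, duration_s]`` so pre-trial padding holds the
    initial posture.
    """
    out = _base_latents(spec, t)
    t_clip = np.clip(np.asarray(t, dtype=float), 0.0, spec.duration_s)
    # numeric derivatives (latents are smooth; h well below the 10 Hz band)
    theta_dot, theta_ddot = _numeric_derivatives(spec, t_clip, h=1.0 / 512.0)
    out["theta_dot"] = theta_dot
    out["theta_ddot"] = theta_ddot
    out.update(_lagged_states(spec, t))
    return out


def _theta_only(spec: LatentSpec, t: np.ndarray) -> np.ndarray:
    return _base_latents(spec, t)["theta"]


def _numeric_derivatives(spec: LatentSpec, t: np.ndarray, h: float) -> tuple[np.ndarray, np.ndarray]:
    tm, tp = t - h, t + h
    th_m, th_0, th_p = _theta_only(spec, tm), _theta_only(spec, t), _theta_only(spec, tp)
    theta_dot = (th_p - th_m) / (2 * h)
    theta_ddot = (th_p - 2 * th_0 + th_m) / h**2
    return theta_dot, theta_ddot


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


# ---------------------------------------------------------------------------
# SJRF mapping


def sjrf_from_latents(latents: dict[str, np.ndarray], traits: ParticipantTraits) -> np.ndarray:
    """Map latent states to the (n, 3) SJRF target in newtons.

    The mapping is deliberately non-affine in the quantities the sensor
    channels expose (a rectified push term and an activation × elevation
    product), so a feedforward affine regressor on the channels is
    misspecified while the task remains exactly solvable from the emitted
    signals.
    """
    c = SJRF_COEFFS
    m = traits.body_mass_scale
    theta, push_slow = latents["theta"], latents["push_slow"]
    act1_slow, act2_slow = latents["act1_slow"], latents["act2_slow"]
    fx = (
        c["push_gain"] * m * np.maximum(push_slow - c["push_knee"], 0.0) ** 2
        + c["act1_gain_x"] * act1_slow
        + c["base_x"]
    )
    fy = c["elev_act_gain"] * m * act2_slow * np.sin(theta) + c["theta_gain"] * theta
    fz = c["mass_gain"] * m + c["act1_gain_z"] * m * act1_slow + c["elev_gain_z"] * np.sin(theta)
    return np.column_stack([fx, fy, fz])


# ---------------------------------------------------------------------------
# raw stream synthesis


@dataclass
class SensorRecording:
    """One subtrial's raw multi-rate streams.

    ``imu`` maps stream name to ``(time_s, data (n, 6))`` at 128 Hz, ``emg``
    is ``(time_s, data (n, 2))`` at 1024 Hz, and ``sjrf`` is
    ``(time_s, data (n, 3))`` at the native 100 Hz force rate on the master
    clock.  ``stream_offsets_s`` holds the injected clock offsets (hidden
    from the pipeline; retained as the synchronization oracle) and
    ``trial_window_s`` the protocol-known activity window on the master
    clock.  ``latent_spec`` allows tests to re-evaluate the generative latent
    states; it is ``None`` for recordings loaded from disk.
    """

    participant_id: int
    activity: str
    subtrial_index: int
    imu: dict[str, tuple[np.ndarray, np.ndarray]]
    emg: tuple[np.ndarray, np.ndarray]
    sjrf: tuple[np.ndarray, np.ndarray]
    stream_offsets_s: dict[str, float]
    trial_window_s: tuple[float, float]
    latent_spec: LatentSpec | None = None
    traits: ParticipantTraits | None = None

    @property
    def duration_s(self) -> float:
        a, b = self.trial_window_s
        return b - a


def _burst(tau: np.ndarray, amplitude: float) -> np.ndarray:
    """High-amplitude triphasic fiducial burst around the burst centre."""
    u = tau - (BURST_CENTER_S - BURST_DURATION_S / 2)
    inside = (u >= 0) & (u <= BURST_DURATION_S)
    out = np.zeros_like(tau)
    uu = u[inside]
    out[inside] = amplitude * np.sin(2 * np.pi * 2.5 * uu) * np.sin(np.pi * uu / BURST_DURATION_S) ** 2
    return out


def _imu_signals(stream: str, lat: dict[str, np.ndarray], traits: ParticipantTraits,
                 activity: str) -> np.ndarray:
    """Noise-free IMU channels (n, 6) as functions of the latent states."""
    theta, dth, ddth = lat["theta"], lat["theta_dot"], lat["theta_ddot"]
    push = lat["push"]
    n = theta.shape[0]
    acc = np.zeros((n, 3))
    gyro = np.zeros((n, 3))
    if stream == "upper_arm":
        acc[:, 0] = GRAVITY * np.sin(theta) + 0.30 * ddth
        acc[:, 1] = 2.0 * push
        acc[:, 2] = GRAVITY * np.cos(theta)
        gyro[:, 0] = RAD2DEG * dth
        gyro[:, 1] = 0.2 * RAD2DEG * dth
    elif stream == "lower_arm":
        acc[:, 0] = GRAVITY * np.sin(1.2 * theta) + 0.40 * ddth
        acc[:, 1] = 2.5 * push
        acc[:, 2] = GRAVITY * np.cos(1.2 * theta)
        gyro[:, 0] = 1.2 * RAD2DEG * dth
    elif stream == "thorax":
        acc[:, 0] = 1.5 * push + 0.2 * GRAVITY * np.sin(0.3 * theta)
        acc[:, 2] = GRAVITY
        gyro[:, 1] = 0.1 * RAD2DEG * dth
    elif stream == "wc_frame":
        acc[:, 0] = 2.5 * push
        acc[:, 2] = GRAVITY
        gyro[:, 2] = 8.0 * push
    elif stream == "wc_wheel":
        # wheel angular velocity: rolling speed plus cadence-locked push ripple
        acc[:, 0] = 2.0 * push
        acc[:, 2] = GRAVITY
        gyro[:, 1] = 40.0 * push  # dominant frequency = propulsion cadence
        gyro[:, 2] = 5.0
    else:  # pragma: no cover
        raise ValueError(f"unknown IMU stream {stream!r}")
    acc += np.asarray(traits.kinematic_offset)[None, :]
    return np.column_stack([acc, gyro])


def _emg_carrier(rng: np.random.Generator, n: int) -> np.ndarray:
    """Band-limited (30–400 Hz) unit-variance carrier for EMG amplitude modulation."""
    from scipy.signal import butter, lfilter

    white = rng.standard_normal(n + 512)
    b, a = butter(4, [30.0 / (EMG_FS / 2), 400.0 / (EMG_FS / 2)], btype="bandpass")
    x = lfilter(b, a, white)[512:]
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_trial(
    traits: ParticipantTraits,
    activity: str,
    subtrial_index: int = 0,
    noise_sd: float = 0.2,
    duration_scale: float = 1.0,
    with_offsets: bool = True,
    seed: int | None = None,
) -> SensorRecording:
    """Generate one subtrial's raw multi-rate streams plus ground-truth SJRF.

    ``noise_sd`` scales additive sensor noise (m/s² on accelerometers, ×5 on
    gyroscopes in °/s, and the EMG baseline).  With ``noise_sd = 0`` and
    offsets disabled, the SJRF target is an exact function of the emitted
    latent states via :func:`sjrf_from_latents`.
    """
    if activity not in ACTIVITIES and activity != "static_posture":
        raise ValueError(f"unknown activity {activity!r}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if activity == "static_posture":
        duration = STATIC_DURATION_S * duration_scale
    else:
        duration = ACTIVITIES[activity][1] * duration_scale
    seed = traits.seed if seed is None else seed
    rng = np.random.default_rng(
        [seed, traits.participant_id, _ACT_INDEX.get(activity, 99), subtrial_index, 303]
    )
    spec = _latent_spec(activity, traits, subtrial_index, duration)

    t0, t1 = PRE_TRIAL_S, PRE_TRIAL_S + duration
    record_len = t1 + RECORD_PAD_S

    offsets: dict[str, float] = {s: 0.0 for s in (*IMU_STREAMS, "emg")}
    if with_offsets:
        for s in offsets:
            if s != REFERENCE_STREAM:
                offsets[s] = float(rng.uniform(-MAX_OFFSET_S, MAX_OFFSET_S))

    imu: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for stream in IMU_STREAMS:
        n = int(np.floor(record_len * IMU_FS))
        t_local = np.arange(n) / IMU_FS
        tau = t_local - offsets[stream]  # true (master-clock) time of each sample
        lat = evaluate_latents(spec, tau - PRE_TRIAL_S)
        data = _imu_signals(stream, lat, traits, activity)
        data[:, :3] += _burst(tau, 25.0)[:, None]
        data[:, 3:] += _burst(tau, 300.0)[:, None]
        if noise_sd > 0:
            data[:, :3] += noise_sd * rng.standard_normal((n, 3))
            data[:, 3:] += 5.0 * noise_sd * rng.standard_normal((n, 3))
        imu[stream] = (t_local, data)

    n_emg = int(np.floor(record_len * EMG_FS))
    t_emg = np.arange(n_emg) / EMG_FS
    tau = t_emg - offsets["emg"]
    lat = evaluate_latents(spec, tau - PRE_TRIAL_S)
    emg = np.empty((n_emg, 2))
    for j, act_key in enumerate(("act1", "act2")):
        carrier = _emg_carrier(rng, n_emg)
        emg[:, j] = lat[act_key] * traits.emg_gain[j] * 0.5 * carrier
        emg[:, j] += 0.02 * noise_sd * rng.standard_normal(n_emg)
    emg += _burst(tau, 3.0)[:, None]

    n_f = int(np.floor(record_len * SJRF_FS))
    t_f = np.arange(n_f) / SJRF_FS
    lat_f = evaluate_latents(spec, t_f - PRE_TRIAL_S)
    sjrf = sjrf_from_latents(lat_f, traits)

    return SensorRecording(
        participant_id=traits.participant_id,
        activity=activity,
        subtrial_index=subtrial_index,
        imu=imu,
        emg=(t_emg, emg),
        sjrf=(t_f, sjrf),
        stream_offsets_s=offsets,
        trial_window_s=(t0, t1),
        latent_spec=spec,
        traits=traits,
    )


def generate_static_recording(traits: ParticipantTraits, noise_sd: float = 0.2,
                              seed: int | None = None) -> SensorRecording:
    """Static submaximal-contraction posture used for EMG normalization."""
    return generate_trial(traits, "static_posture", 0, noise_sd=noise_sd, with_offsets=False, seed=seed)


# ---------------------------------------------------------------------------
# cohort


@dataclass
class Cohort:
    """A generated cohort: manifest plus in-memory recordings.

    ``manifest`` has one row per subtrial with columns ``participant_id``,
    ``activity``, ``subtrial_index``, ``valid`` and ``path`` (empty unless
    written to disk).  ``recordings`` is keyed by
    ``(participant_id, activity, subtrial_index)``; ``statics`` maps
    participant id to the static normalization recording.
    """

    manifest: pd.DataFrame
    recordings: dict[tuple[int, str, int], SensorRecording]
    statics: dict[int, SensorRecording]
    traits: dict[int, ParticipantTraits]
    params: dict = field(default_factory=dict)

    def valid_keys(self) -> list[tuple[int, str, int]]:
        rows = self.manifest[self.manifest["valid"]]
        return [(int(r.participant_id), str(r.activity), int(r.subtrial_index)) for r in rows.itertuples()]

    @property
    def n_valid(self) -> int:
        return int(self.manifest["valid"].sum())


def subtrials_per_participant() -> int:
    """Total subtrials per participant implied by the activity templates."""
    return sum(n for n, _ in ACTIVITIES.values())


def build_manifest(
    n_participants: int = 10,
    n_exclusions: int = 7,
    seed: int = 0,
    force_orphan_weight_relief: bool = False,
) -> pd.DataFrame:
    """Cohort manifest: one row per subtrial, exclusions flagged.

    Exclusions mark subtrials invalid (emulating processing failures in the
    ground-truth pipeline); they are flagged, not deleted.  With
    ``force_orphan_weight_relief`` one exclusion is forced onto a single
    weight-relief subtrial of one participant, so exactly one weight-relief
    subtrial remains for that participant ("orphan" scenario).
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    total = n_participants * subtrials_per_participant()
    if n_exclusions >= total:
        raise ValueError("n_exclusions must be smaller than the number of subtrials")
    rng = np.random.default_rng([seed, 404])

    keys: list[tuple[int, str, int]] = []
    for pid in range(1, n_participants + 1):
        for act, (n_sub, _dur) in ACTIVITIES.items():
            for k in range(n_sub):
                keys.append((pid, act, k))

    excluded: set[tuple[int, str, int]] = set()
    if force_orphan_weight_relief and n_exclusions > 0:
        orphan_pid = 5 if n_participants >= 5 else 1
        excluded.add((orphan_pid, "weight_relief_lift", 1))
    pool = [k for k in keys if k not in excluded]
    extra = rng.choice(len(pool), size=n_exclusions - len(excluded), replace=False)
    excluded.update(pool[i] for i in sorted(extra))

    return pd.DataFrame(
        [
            {"participant_id": pid, "activity": act, "subtrial_index": k,
             "valid": (pid, act, k) not in excluded, "path": ""}
            for pid, act, k in keys
        ]
    )


def generate_cohort(
    n_participants: int = 10,
    heterogeneity: float = 0.3,
    noise_sd: float = 0.2,
    n_exclusions: int = 7,
    seed: int = 0,
    duration_scale: float = 1.0,
    force_orphan_weight_relief: bool = False,
) -> Cohort:
    """Generate a full cohort of raw recordings plus manifest (see
    :func:`build_manifest` for the exclusion scheme)."""
    manifest = build_manifest(n_participants, n_exclusions, seed, force_orphan_weight_relief)
    keys = [(int(r.participant_id), str(r.activity), int(r.subtrial_index))
            for r in manifest.itertuples()]

    traits = {pid: sample_traits(pid, heterogeneity, seed) for pid in range(1, n_participants + 1)}
    recordings = {
        key: generate_trial(traits[key[0]], key[1], key[2], noise_sd=noise_sd,
                            duration_scale=duration_scale, seed=seed)
        for key in keys
    }
    statics = {pid: generate_static_recording(traits[pid], noise_sd=noise_sd, seed=seed)
               for pid in traits}
    params = {
        "n_participants": n_participants,
        "heterogeneity": heterogeneity,
        "noise_sd": noise_sd,
        "n_exclusions": n_exclusions,
        "seed": seed,
        "duration_scale": duration_scale,
        "force_orphan_weight_relief": force_orphan_weight_relief,
    }
    return Cohort(manifest=manifest, recordings=recordings, statics=statics, traits=traits, params=params)


# ---------------------------------------------------------------------------
# file round trip (CSV streams + YAML sidecar per subtrial, CSV manifest)


def _subtrial_stem(pid: int, activity: str, subtrial_index: int) -> str:
    return f"P{pid:02d}_{activity}_S{subtrial_index}"


def _write_recording(rec: SensorRecording, root: Path, stem: str) -> None:
    for stream, (t, data) in rec.imu.items():
        df = pd.DataFrame(data, columns=IMU_CHANNEL_NAMES)
        df.insert(0, "time_s", t)
        df.to_csv(root / f"{stem}_imu_{stream}.csv", index=False, float_format="%.6f")
    t, data = rec.emg
    df = pd.DataFrame(data, columns=EMG_CHANNELS)
    df.insert(0, "time_s", t)
    df.to_csv(root / f"{stem}_emg.csv", index=False, float_format="%.6f")
    t, data = rec.sjrf
    df = pd.DataFrame(data, columns=["Fx", "Fy", "Fz"])
    df.insert(0, "time_s", t)
    df.to_csv(root / f"{stem}_sjrf.csv", index=False, float_format="%.6f")
    traits_repr = "" if rec.traits is None else repr(rec.traits).encode()
    sidecar = {
        "participant_id": rec.participant_id,
        "activity": rec.activity,
        "subtrial_index": rec.subtrial_index,
        "sampling_rates_hz": {"imu": IMU_FS, "emg": EMG_FS, "sjrf": SJRF_FS},
        "trial_window_s": [float(x) for x in rec.trial_window_s],
        "traits_hash": hashlib.sha1(traits_repr or b"?").hexdigest()[:12],
        # hidden ground truth, for test oracles only — the pipeline must not read it
        "hidden_stream_offsets_s": {k: float(v) for k, v in rec.stream_offsets_s.items()},
    }
    (root / f"{stem}_meta.yaml").write_text(yaml.safe_dump(sidecar, sort_keys=True))


def _read_recording(root: Path, stem: str) -> SensorRecording:
    meta = yaml.safe_load((root / f"{stem}_meta.yaml").read_text())
    imu = {}
    for stream in IMU_STREAMS:
        df = pd.read_csv(root / f"{stem}_imu_{stream}.csv")
        imu[stream] = (df["time_s"].to_numpy(), df[list(IMU_CHANNEL_NAMES)].to_numpy())
    df = pd.read_csv(root / f"{stem}_emg.csv")
    emg = (df["time_s"].to_numpy(), df[list(EMG_CHANNELS)].to_numpy())
    df = pd.read_csv(root / f"{stem}_sjrf.csv")
    sjrf = (df["time_s"].to_numpy(), df[["Fx", "Fy", "Fz"]].to_numpy())
    return SensorRecording(
        participant_id=int(meta["participant_id"]),
        activity=str(meta["activity"]),
        subtrial_index=int(meta["subtrial_index"]),
        imu=imu,
        emg=emg,
        sjrf=sjrf,
        stream_offsets_s={k: float(v) for k, v in meta["hidden_stream_offsets_s"].items()},
        trial_window_s=tuple(meta["trial_window_s"]),  # type: ignore[arg-type]
    )


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write every recording as CSV streams plus sidecar, and the manifest."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest.copy()
    for i, row in manifest.iterrows():
        key = (int(row.participant_id), str(row.activity), int(row.subtrial_index))
        stem = _subtrial_stem(*key)
        try:
            _write_recording(cohort.recordings[key], root, stem)
        except OSError as exc:  # surface the offending path
            raise OSError(f"failed writing subtrial files for {stem} under {root}: {exc}") from exc
        manifest.at[i, "path"] = stem
    for pid, rec in cohort.statics.items():
        _write_recording(rec, root, f"P{pid:02d}_static")
    manifest.to_csv(root / "manifest.csv", index=False)
    (root / "cohort_params.json").write_text(json.dumps(cohort.params, indent=2, sort_keys=True))
    return root


def load_cohort(root: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort` (latent specs are not
    persisted, so reloaded recordings support the pipeline but not the
    generative oracles)."""
    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv")
    recordings = {}
    for row in manifest.itertuples():
        key = (int(row.participant_id), str(row.activity), int(row.subtrial_index))
        recordings[key] = _read_recording(root, str(row.path))
    statics = {}
    for pid in sorted(manifest["participant_id"].unique()):
        p = root / f"P{int(pid):02d}_static_meta.yaml"
        if p.exists():
            statics[int(pid)] = _read_recording(root, f"P{int(pid):02d}_static")
    params_path = root / "cohort_params.json"
    params = json.loads(params_path.read_text()) if params_path.exists() else {}
    traits = {}
    if params:
        traits = {pid: sample_traits(pid, params.get("heterogeneity", 0.0), params.get("seed", 0))
                  for pid in statics}
    return Cohort(manifest=manifest, recordings=recordings, statics=statics, traits=traits, params=params)
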