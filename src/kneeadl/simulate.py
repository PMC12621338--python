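"""Synthetic dual-device knee IMU simulator.

Generates labeled femoral/tibial 50 Hz IMU streams whose flexion
kinematics follow the eight activity profiles.  The knee flexion axis
is sensor *x* for both devices and gravity lies along sensor *-z* at
full extension; accelerometers read specific force in m/s^2 and
gyroscopes angular rate in deg/s.

Realism knobs: white sensor noise, a gyroscope bias random walk,
asynchronous device start offsets, per-sample dropout, lever-arm
linear-acceleration terms, and decaying footstrike transients for
jogging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from kneeadl.activities import (
    CONTINUOUS_ACTIVITIES,
    ActivityProfile,
    Waveform,
    default_profiles,
)
from kneeadl.stream_io import (
    DatasetManifest,
    ImuStream,
    RecordingEntry,
    save_manifest,
    write_stream,
)

GRAVITY = 9.81  # m/s^2

#: decay constant of footstrike transients, seconds
IMPACT_TAU = 0.05

#: post-activity hold appended to transitional recordings, seconds,
#: so that every repetition survives alignment trimming as >= 1 window
TRANSITION_HOLD = 1.0

#: extra tail appended to continuous recordings, seconds
CONTINUOUS_TAIL = 0.5

#: floor on continuous-recording duration, seconds: a recording must
#: survive alignment trimming as at least one full 3 s window
MIN_CONTINUOUS_S = 3.6


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation run.

    Noise magnitudes are consumer-IMU scale defaults; all configurable.
    ``segment_length_*`` are the sensor lever arms (m) from the knee
    axis used for tangential/centripetal acceleration terms.
    """

    sample_rate: float = 50.0          # Hz
    reps_per_class: int = 100
    seed: int = 42
    accel_noise_sd: float = 0.5        # m/s^2
    gyro_noise_sd: float = 1.0         # deg/s
    gyro_bias_walk_sd: float = 0.05    # deg/s per sqrt(s)
    start_offset_max: float = 200.0    # ms
    dropout_prob: float = 0.01
    segment_length_femur: float = 0.12  # m
    segment_length_tibia: float = 0.10  # m
    cycles_per_recording: int = 10      # reps bundled into one continuous recording

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if not 0 <= self.dropout_prob < 0.5:
            raise ValueError("dropout_prob must be in [0, 0.5)")
        if self.reps_per_class < 1:
            raise ValueError("reps_per_class must be >= 1")
        if self.start_offset_max < 0:
            raise ValueError("start_offset_max must be >= 0")

    def without_noise(self) -> "SimulationConfig":
        """Copy with all stochastic corruption disabled (for oracles)."""
        return replace(
            self,
            accel_noise_sd=0.0,
            gyro_noise_sd=0.0,
            gyro_bias_walk_sd=0.0,
            dropout_prob=0.0,
            start_offset_max=0.0,
        )


def flexion_waveform(
    profile: ActivityProfile,
    t: np.ndarray | float,
    phase: float = 0.0,
) -> np.ndarray | float:
    """Knee flexion angle theta(t) in degrees for an activity.

    * ``periodic`` / ``quasi_static``: raised-cosine oscillation between
      ``rom_min`` and ``rom_max`` at the profile rate (minimum at
      ``t=0`` for ``phase=0``).
    * ``half_cycle_down``: one monotone cosine ramp of duration
      ``1/(2*rate)`` from ``rom_min`` to ``rom_max``, constant after.
    * ``half_cycle_up``: the reverse ramp, ``rom_max`` to ``rom_min``.

    The output always lies within ``[rom_min, rom_max]``.
    """
    t_arr = np.asarray(t, dtype=np.float64)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    span = profile.rom_span
    w = 2.0 * math.pi * profile.rate
    if profile.waveform in (Waveform.PERIODIC, Waveform.QUASI_STATIC):
        theta = profile.rom_min + span * 0.5 * (1.0 - np.cos(w * t_arr + phase))
    else:
        half = 0.5 / profile.rate
        ramp = span * 0.5 * (1.0 - np.cos(w * np.minimum(t_arr, half)))
        if profile.waveform is Waveform.HALF_CYCLE_DOWN:
            theta = profile.rom_min + ramp
        else:
            theta = profile.rom_max - ramp
    theta = np.clip(theta, profile.rom_min, profile.rom_max)
    return theta if isinstance(t, np.ndarray) else float(theta)


@dataclass
class SegmentKinematics:
    """World-frame orientations (deg) and angular velocities (deg/s)
    of the femoral and tibial segments about the knee axis."""

    femoral_orientation: np.ndarray
    tibial_orientation: np.ndarray
    femoral_velocity: np.ndarray
    tibial_velocity: np.ndarray
    dt: float


def segment_kinematics(
    theta_series: np.ndarray,
    profile: ActivityProfile,
    dt: float,
) -> SegmentKinematics:
    """Rigid-body stand-in mapping flexion angle to per-segment motion.

    Femoral orientation is ``femoral_share * theta`` plus the thigh
    inclination ramp (sit/stand transitions tilt the thigh synchronously
    with the flexion ramp); tibial orientation is defined so that
    ``tibial - femoral == -theta`` holds exactly at every step.
    Angular velocities are central finite differences.
    """
    theta = np.asarray(theta_series, dtype=np.float64)
    if theta.size == 0:
        raise ValueError("theta_series must be non-empty")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    thigh = np.zeros_like(theta)
    if profile.thigh_ramp != 0.0:
        # normalized flexion progress drives the thigh tilt
        thigh = profile.thigh_ramp * (theta - profile.rom_min) / profile.rom_span
    femoral = profile.femoral_share * theta + thigh
    tibial = femoral - theta
    if theta.size == 1:
        vf = np.zeros_like(theta)
        vt = np.zeros_like(theta)
    else:
        vf = np.gradient(femoral, dt)
        vt = np.gradient(tibial, dt)
    return SegmentKinematics(femoral, tibial, vf, vt, dt)


def synthesize_imu(
    orientation_deg: np.ndarray,
    angular_velocity_dps: np.ndarray,
    config: SimulationConfig,
    device: str,
    rng: np.random.Generator,
    profile: ActivityProfile | None = None,
    phase: float = 0.0,
) -> ImuStream:
    """Turn one segment's motion into a noisy, gappy 6-channel stream.

    The accelerometer reads gravity rotated into the sensor frame plus
    lever-arm tangential/centripetal terms, white noise, and (when the
    profile has ``impact_amplitude > 0``) decaying footstrike spikes at
    cycle frequency.  The gyroscope reads the knee-axis angular velocity
    plus a bias random walk and white noise.  Timestamps start at a
    device-specific uniform offset in ``[0, start_offset_max]`` ms and
    each sample is dropped independently with ``dropout_prob``.
    """
    phi_deg = np.asarray(orientation_deg, dtype=np.float64)
    omega_dps = np.asarray(angular_velocity_dps, dtype=np.float64)
    if phi_deg.shape != omega_dps.shape:
        raise ValueError("orientation and angular velocity series lengths differ")
    n = phi_deg.size
    dt = 1.0 / config.sample_rate
    t_s = np.arange(n) * dt
    lever = (config.segment_length_femur if device == "femoral"
             else config.segment_length_tibia)

    phi = np.deg2rad(phi_deg)
    omega = np.deg2rad(omega_dps)                       # rad/s
    alpha = np.gradient(omega, dt) if n > 1 else np.zeros(n)

    ax = np.zeros(n)
    ay = -GRAVITY * np.sin(phi) + lever * alpha
    az = GRAVITY * np.cos(phi) - lever * omega**2

    if profile is not None and profile.impact_amplitude > 0:
        amp = profile.impact_amplitude * (0.7 if device == "femoral" else 1.0)
        period = profile.period
        # footstrikes at waveform phase zero (cycle minimum)
        t0 = (-phase / (2.0 * math.pi)) * period
        k0 = math.ceil((0.0 - t0) / period)
        k1 = math.floor((t_s[-1] - t0) / period) if n else -1
        for k in range(k0, k1 + 1):
            tk = t0 + k * period
            after = t_s >= tk
            az[after] += amp * np.exp(-(t_s[after] - tk) / IMPACT_TAU)

    if config.accel_noise_sd > 0:
        ax = ax + rng.normal(0, config.accel_noise_sd, n)
        ay = ay + rng.normal(0, config.accel_noise_sd, n)
        az = az + rng.normal(0, config.accel_noise_sd, n)

    gx = omega_dps.copy()
    gy = np.zeros(n)
    gz = np.zeros(n)
    if config.gyro_bias_walk_sd > 0:
        for g in (gx, gy, gz):
            g += np.cumsum(rng.normal(0, config.gyro_bias_walk_sd * math.sqrt(dt), n))
    if config.gyro_noise_sd > 0:
        gx = gx + rng.normal(0, config.gyro_noise_sd, n)
        gy = gy + rng.normal(0, config.gyro_noise_sd, n)
        gz = gz + rng.normal(0, config.gyro_noise_sd, n)

    offset_ms = float(rng.uniform(0.0, config.start_offset_max)) if \
        config.start_offset_max > 0 else 0.0
    t_ms = (np.round(offset_ms + t_s * 1000.0)).astype(np.int64)

    keep = np.ones(n, dtype=bool)
    if config.dropout_prob > 0:
        keep = rng.random(n) >= config.dropout_prob
        if not keep.any():
            keep[0] = True

    accel = np.column_stack([ax, ay, az])[keep]
    gyro = np.column_stack([gx, gy, gz])[keep]
    return ImuStream(device_id=device, t_ms=t_ms[keep], accel=accel, gyro=gyro)


def simulate_recording(
    profile: ActivityProfile,
    config: SimulationConfig,
    duration_s: float,
    rng: np.random.Generator,
    phase: float = 0.0,
) -> tuple[ImuStream, ImuStream]:
    """Simulate one dual-device recording of ``duration_s`` seconds."""
    n = int(round(duration_s * config.sample_rate))
    dt = 1.0 / config.sample_rate
    t = np.arange(n) * dt
    theta = flexion_waveform(profile, t, phase=phase)
    kin = segment_kinematics(theta, profile, dt)
    fem = synthesize_imu(kin.femoral_orientation, kin.femoral_velocity,
                         config, "femoral", rng, profile, phase)
    tib = synthesize_imu(kin.tibial_orientation, kin.tibial_velocity,
                         config, "tibial", rng, profile, phase)
    return fem, tib


def _recording_plan(profile: ActivityProfile, config: SimulationConfig):
    """Yield (n_reps, duration_s) per recording for one activity class."""
    if profile.name in CONTINUOUS_ACTIVITIES:
        per = config.cycles_per_recording
        remaining = config.reps_per_class
        while remaining > 0:
            reps = min(per, remaining)
            duration = max(reps * profile.period + CONTINUOUS_TAIL,
                           MIN_CONTINUOUS_S)
            yield reps, duration
            remaining -= reps
    elif profile.waveform in (Waveform.HALF_CYCLE_DOWN, Waveform.HALF_CYCLE_UP):
        for _ in range(config.reps_per_class):
            yield 1, 0.5 * profile.period + TRANSITION_HOLD
    else:  # transitional full-cycle activity (knee bending)
        for _ in range(config.reps_per_class):
            yield 1, profile.period + CONTINUOUS_TAIL


def generate_dataset(
    config: SimulationConfig,
    profiles: dict[str, ActivityProfile] | None = None,
    output_dir: str | Path = ".",
) -> DatasetManifest:
    """Write a labeled dual-stream dataset and its JSON manifest.

    Continuous activities are emitted as multi-cycle recordings;
    transitional activities as one-repetition segments starting from the
    neutral position.  Every class totals at least
    ``config.reps_per_class`` repetitions.  Deterministic under
    ``config.seed``.
    """
    profiles = profiles if profiles is not None else default_profiles()
    out = Path(output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    root_seq = np.random.SeedSequence(config.seed)
    entries: list[RecordingEntry] = []
    for name in sorted(profiles):
        profile = profiles[name]
        class_seq = root_seq.spawn(1)[0]
        for idx, (reps, duration) in enumerate(_recording_plan(profile, config)):
            rng = np.random.Generator(np.random.PCG64(class_seq.spawn(1)[0]))
            phase = (float(rng.uniform(0, 2 * math.pi))
                     if profile.waveform in (Waveform.PERIODIC, Waveform.QUASI_STATIC)
                     else 0.0)
            fem, tib = simulate_recording(profile, config, duration, rng, phase)
            rec_id = f"{name}_{idx:04d}"
            fem_rel = f"{rec_id}_femoral.csv"
            tib_rel = f"{rec_id}_tibial.csv"
            write_stream(fem, out / fem_rel)
            write_stream(tib, out / tib_rel)
            entries.append(RecordingEntry(rec_id, name, fem_rel, tib_rel, reps))
    manifest = DatasetManifest(recordings=entries, root=out)
    save_manifest(manifest, out / "manifest.json")
    return manifest
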