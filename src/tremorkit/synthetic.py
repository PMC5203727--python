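"""Synthetic multi-sensor tremor cohorts.

Generates simulated recording sessions of the wearable-glove protocol:
two inertial units (3-axis accelerometer, gyroscope, magnetometer), two
EMG envelope channels and a pulse annotation channel, digitised at 50 Hz.
Each subject performs a sequence of four tasks (finger taps, finger to
nose, supination/pronation, rest) for 10 s each, repeated over five
trials separated by rest gaps, with an annotation pulse at every task
boundary.

The signal model is additive per inertial channel:

    gravity offset + slow polynomial drift + task-dependent voluntary
    oscillation (~0.5-3 Hz) + amplitude-modulated tremor sinusoid
    (4-6 Hz for parkinsonian groups) + white Gaussian noise

EMG channels are smoothed rectified versions of the local movement +
tremor content plus noise, and are nonnegative everywhere. Each model
component exists so that one downstream processing stage has something
to remove or extract: drift is removed by polynomial detrending, the
tremor oscillation is captured by instantaneous amplitude/frequency,
and task-dependent movement drives between-task differences.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from enum import Enum

import numpy as np

SAMPLE_RATE_HZ = 50.0

INERTIAL_CHANNELS = tuple(
    f"{sensor}{unit}_{axis}"
    for unit in (1, 2)
    for sensor in ("accel", "gyro", "mag")
    for axis in "xyz"
)
EMG_CHANNELS = ("emg1", "emg2")
CHANNEL_NAMES = INERTIAL_CHANNELS + EMG_CHANNELS


class GroupLabel(str, Enum):
    """Experimental group: healthy, PD on levodopa, PD with DBS."""

    S_H = "S_H"
    S_PD = "S_PD"
    S_DBS = "S_DBS"


class TaskLabel(str, Enum):
    """Clinical task within one trial sequence."""

    T1 = "T1"  # finger taps
    T2 = "T2"  # finger to nose
    T3 = "T3"  # supination / pronation
    T4 = "T4"  # rest, arm extended

    @property
    def description(self) -> str:
        return {
            "T1": "finger taps",
            "T2": "finger to nose",
            "T3": "supination and pronation",
            "T4": "rest (extended arm)",
        }[self.value]


TASK_ORDER = (TaskLabel.T1, TaskLabel.T2, TaskLabel.T3, TaskLabel.T4)

# relative voluntary-movement amplitude per task: largest for the
# finger-to-nose reach, zero for the static rest task
TASK_VOLUNTARY_AMPLITUDE = {
    TaskLabel.T1: 1.0,
    TaskLabel.T2: 1.6,
    TaskLabel.T3: 1.2,
    TaskLabel.T4: 0.0,
}
# voluntary oscillation frequency per task (Hz), within 0.5-3 Hz
TASK_VOLUNTARY_FREQ_HZ = {
    TaskLabel.T1: 2.5,
    TaskLabel.T2: 0.8,
    TaskLabel.T3: 1.5,
    TaskLabel.T4: 0.0,
}


@dataclass(frozen=True)
class SubjectSpec:
    """Per-subject signal-model parameters (sensor units)."""

    subject_id: str
    group: GroupLabel
    tremor_amplitude: float
    tremor_freq_hz: float
    drift_scale: float
    noise_sd: float
    rng_seed: int
    voluntary_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.tremor_amplitude < 0:
            raise ValueError("tremor_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.drift_scale < 0:
            raise ValueError("drift_scale must be >= 0")


@dataclass(frozen=True)
class ScheduleConfig:
    """Task/trial layout of one recording session.

    Defaults follow the acquisition protocol: four 10-s tasks in fixed
    order per trial, five trials, at least 30 s of rest between trials.
    The rest gap may be shortened for fast simulation; rest samples are
    never analysed.
    """

    task_duration_s: float = 10.0
    n_trials: int = 5
    rest_gap_s: float = 30.0
    sample_rate_hz: float = SAMPLE_RATE_HZ

    @property
    def task_samples(self) -> int:
        return int(round(self.task_duration_s * self.sample_rate_hz))

    @property
    def gap_samples(self) -> int:
        return int(round(self.rest_gap_s * self.sample_rate_hz))

    def layout(self) -> tuple[list[tuple[TaskLabel, int, int]], list[int]]:
        """Return (task_schedule, pulses).

        One pulse marks the start of every task and one the end of the
        last task of each trial (5 pulses per trial), mirroring the
        push-button annotation between movements.
        """
        schedule: list[tuple[TaskLabel, int, int]] = []
        pulses: list[int] = []
        pos = 0
        for _ in range(self.n_trials):
            for task in TASK_ORDER:
                pulses.append(pos)
                schedule.append((task, pos, pos + self.task_samples))
                pos += self.task_samples
            pulses.append(pos)
            pos += self.gap_samples
        return schedule, pulses

    @property
    def total_samples(self) -> int:
        n_seq = len(TASK_ORDER) * self.task_samples
        return self.n_trials * (n_seq + self.gap_samples)


@dataclass
class Recording:
    """One subject session: channel matrix, pulses and task schedule."""

    subject: SubjectSpec
    sample_rate_hz: float
    channels: dict[str, np.ndarray]
    pulses: list[int]
    task_schedule: list[tuple[TaskLabel, int, int]]

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    def validate(self) -> None:
        n = self.n_samples
        for name, arr in self.channels.items():
            if len(arr) != n:
                raise ValueError(f"channel {name} has inconsistent length")
        if any(b <= a for a, b in zip(self.pulses, self.pulses[1:])):
            raise ValueError("pulse indices must be strictly increasing")
        for name in EMG_CHANNELS:
            if np.any(self.channels[name] < 0):
                raise ValueError(f"EMG channel {name} has negative samples")
        spans = sorted((s, e) for _, s, e in self.task_schedule)
        for (_, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError("task segments overlap")


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


#: scale of the static per-axis offset on inertial channels. Chosen so
#: the static vector (gravity on accelerometers, the geomagnetic field
#: on magnetometers) dominates typical tremor excursions, as in real
#: recordings — the resultant then responds linearly to the oscillation
#: instead of rectifying it.
STATIC_OFFSET_SCALE = 3.0


def generate_subject(
    spec: SubjectSpec,
    schedule: ScheduleConfig | None = None,
    offset_scale: float = STATIC_OFFSET_SCALE,
) -> Recording:
    """Simulate one recording session from a subject's signal model.

    All randomness derives from ``spec.rng_seed``: two calls with the
    same spec and schedule return bit-identical recordings.
    """
    schedule = schedule or ScheduleConfig()
    task_schedule, pulses = schedule.layout()
    n = schedule.total_samples
    fs = schedule.sample_rate_hz
    t = np.arange(n) / fs
    rng = np.random.default_rng(spec.rng_seed)

    # slow stochastic amplitude modulation of the tremor, shared by all
    # channels of the limb; clipped away from zero so tremor never vanishes
    mod = 1.0 + 0.3 * _smooth(rng.standard_normal(n), int(2 * fs))
    mod = np.clip(mod, 0.2, None)
    tremor_phase = rng.uniform(0, 2 * np.pi)
    tremor = np.sin(2 * np.pi * spec.tremor_freq_hz * t + tremor_phase) * mod

    # task-gated voluntary movement, common waveform across channels
    voluntary = np.zeros(n)
    for task, s, e in task_schedule:
        amp = TASK_VOLUNTARY_AMPLITUDE[task] * spec.voluntary_scale
        freq = TASK_VOLUNTARY_FREQ_HZ[task]
        if amp > 0 and freq > 0:
            seg = t[s:e]
            voluntary[s:e] = amp * np.sin(
                2 * np.pi * freq * seg + rng.uniform(0, 2 * np.pi)
            )

    channels: dict[str, np.ndarray] = {}
    t_unit = np.linspace(-1.0, 1.0, n)
    for name in INERTIAL_CHANNELS:
        offset = rng.uniform(-1.0, 1.0) * offset_scale
        drift_coeffs = rng.standard_normal(4) * spec.drift_scale
        drift = np.polynomial.polynomial.polyval(t_unit, drift_coeffs)
        gain_t = rng.uniform(0.5, 1.0)  # projection of limb motion on axis
        gain_v = rng.uniform(0.5, 1.0)
        noise = (
            rng.standard_normal(n) * spec.noise_sd if spec.noise_sd > 0 else 0.0
        )
        channels[name] = (
            offset
            + drift
            + gain_v * voluntary
            + gain_t * spec.tremor_amplitude * tremor
            + noise
        )

    # EMG envelopes: smoothed rectified muscle drive tracking local
    # movement + tremor content; strictly nonnegative
    drive = np.abs(voluntary + spec.tremor_amplitude * tremor)
    for name in EMG_CHANNELS:
        gain = rng.uniform(0.5, 1.0)
        envelope = _smooth(gain * drive, int(0.2 * fs))
        noise = (
            np.abs(rng.standard_normal(n)) * spec.noise_sd
            if spec.noise_sd > 0
            else 0.0
        )
        channels[name] = np.clip(envelope + noise, 0.0, None)

    rec = Recording(
        subject=spec,
        sample_rate_hz=fs,
        channels=channels,
        pulses=pulses,
        task_schedule=task_schedule,
    )
    rec.validate()
    return rec


@dataclass(frozen=True)
class GroupParams:
    """Group-level distributions that subject parameters are drawn from.

    Tremor amplitudes are lognormal (median ``tremor_amplitude_median``,
    log-sd ``tremor_amplitude_sigma``) so subjects are heterogeneous and
    subject-wise data splitting is meaningful. Tremor frequency is
    uniform on ``tremor_freq_range_hz``.
    """

    tremor_amplitude_median: float
    tremor_amplitude_sigma: float = 0.4
    tremor_freq_range_hz: tuple[float, float] = (4.0, 6.0)
    drift_scale: float = 0.5
    noise_sd: float = 0.1
    voluntary_scale: float = 1.0


def default_group_params(effect_size: float = 1.0) -> dict[GroupLabel, GroupParams]:
    """Default cohort conditions with a tunable group separation.

    ``effect_size`` scales the between-group tremor-amplitude contrast:
    at 0 all groups share the healthy baseline (a null cohort carrying
    no group signal); at 1 the levodopa group's median amplitude is high,
    the DBS group intermediate and the healthy group near the noise floor,
    the classic clinical ordering.
    """
    base = 0.12
    return {
        GroupLabel.S_H: GroupParams(tremor_amplitude_median=base),
        GroupLabel.S_PD: GroupParams(
            tremor_amplitude_median=base * (1.0 + 8.0 * effect_size)
        ),
        GroupLabel.S_DBS: GroupParams(
            tremor_amplitude_median=base * (1.0 + 3.0 * effect_size)
        ),
    }


DEFAULT_COHORT_SIZES = {
    GroupLabel.S_H: 10,
    GroupLabel.S_PD: 16,
    GroupLabel.S_DBS: 12,
}


def generate_cohort(
    n_per_group: dict[GroupLabel, int] | None = None,
    group_params: dict[GroupLabel, GroupParams] | None = None,
    master_seed: int = 0,
    schedule: ScheduleConfig | None = None,
) -> list[Recording]:
    """Simulate a cohort; per-subject seeds derive from ``master_seed``."""
    n_per_group = n_per_group or dict(DEFAULT_COHORT_SIZES)
    group_params = group_params or default_group_params()
    for g, count in n_per_group.items():
        if count < 1:
            raise ValueError(f"group {g} needs at least one subject")
    ss = np.random.SeedSequence(master_seed)
    draw_rng = np.random.default_rng(ss.spawn(1)[0])
    n_total = sum(n_per_group.values())
    subject_seeds = [int(s) for s in ss.generate_state(n_total) % (2**31)]

    recordings: list[Recording] = []
    idx = 0
    for group in (GroupLabel.S_H, GroupLabel.S_PD, GroupLabel.S_DBS):
        if group not in n_per_group:
            continue
        params = group_params[group]
        for k in range(n_per_group[group]):
            amp = params.tremor_amplitude_median * np.exp(
                params.tremor_amplitude_sigma * draw_rng.standard_normal()
            )
            freq = draw_rng.uniform(*params.tremor_freq_range_hz)
            spec = SubjectSpec(
                subject_id=f"{group.value}_{k + 1:02d}",
                group=group,
                tremor_amplitude=float(amp),
                tremor_freq_hz=float(freq),
                drift_scale=params.drift_scale,
                noise_sd=params.noise_sd,
                rng_seed=subject_seeds[idx],
                voluntary_scale=params.voluntary_scale,
            )
            recordings.append(generate_subject(spec, schedule))
            idx += 1
    return recordings


# ---------------------------------------------------------------------------
# Plain-text recording format
#
# Header lines `# key: value`, then whitespace-separated columns:
# sample_index, 18 inertial channels, emg1, emg2, pulse (0/1).
# ---------------------------------------------------------------------------

_FMT_DECIMALS = 6


def write_recording(rec: Recording, path: str | os.PathLike) -> None:
    """Write a recording in the plain-text column format."""
    rec.validate()
    spec = rec.subject
    lines = [
        f"# subject_id: {spec.subject_id}",
        f"# group: {spec.group.value}",
        f"# sample_rate: {rec.sample_rate_hz:g}",
        f"# tremor_amplitude: {spec.tremor_amplitude!r}",
        f"# tremor_freq_hz: {spec.tremor_freq_hz!r}",
        f"# drift_scale: {spec.drift_scale!r}",
        f"# noise_sd: {spec.noise_sd!r}",
        f"# voluntary_scale: {spec.voluntary_scale!r}",
        f"# rng_seed: {spec.rng_seed}",
    ]
    for task, s, e in rec.task_schedule:
        lines.append(f"# task: {task.value} {s} {e}")
    lines.append("# columns: sample_index " + " ".join(CHANNEL_NAMES) + " pulse")

    pulse_col = np.zeros(rec.n_samples, dtype=int)
    pulse_col[np.asarray(rec.pulses, dtype=int)] = 1
    data = np.column_stack(
        [np.arange(rec.n_samples)]
        + [rec.channels[name] for name in CHANNEL_NAMES]
        + [pulse_col]
    )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(
            fh,
            data,
            fmt=["%d"] + [f"%.{_FMT_DECIMALS}f"] * len(CHANNEL_NAMES) + ["%d"],
        )


class RecordingParseError(ValueError):
    """Raised when a recording file violates the text format."""


def read_recording(path: str | os.PathLike) -> Recording:
    """Parse a recording from the plain-text column format.

    Raises :class:`RecordingParseError` naming the offending line for a
    malformed header, inconsistent column counts, an absent pulse
    column or non-monotone pulses.
    """
    meta: dict[str, str] = {}
    tasks: list[tuple[TaskLabel, int, int]] = []
    body = io.StringIO()
    n_header = 0
    columns_line: str | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                n_header += 1
                stripped = line[1:].strip()
                if ":" not in stripped:
                    raise RecordingParseError(
                        f"line {lineno}: malformed header line {line!r}"
                    )
                key, value = stripped.split(":", 1)
                key, value = key.strip(), value.strip()
                if key == "task":
                    parts = value.split()
                    if len(parts) != 3:
                        raise RecordingParseError(
                            f"line {lineno}: malformed task entry {value!r}"
                        )
                    tasks.append(
                        (TaskLabel(parts[0]), int(parts[1]), int(parts[2]))
                    )
                elif key == "columns":
                    columns_line = value
                else:
                    meta[key] = value
            else:
                body.write(line)

    for required in ("subject_id", "group", "sample_rate"):
        if required not in meta:
            raise RecordingParseError(f"header key {required!r} absent")
    expected_cols = ["sample_index", *CHANNEL_NAMES, "pulse"]
    if columns_line is not None:
        found = columns_line.split()
        if "pulse" not in found:
            raise RecordingParseError("pulse channel absent")
        if found != expected_cols:
            raise RecordingParseError(
                f"column manifest mismatch: expected {expected_cols}, found {found}"
            )

    body.seek(0)
    try:
        data = np.loadtxt(body, ndmin=2)
    except ValueError as exc:
        raise RecordingParseError(f"inconsistent data columns: {exc}") from exc
    if data.shape[1] != len(expected_cols):
        if data.shape[1] == len(expected_cols) - 1:
            raise RecordingParseError("pulse channel absent")
        raise RecordingParseError(
            f"expected {len(expected_cols)} columns, found {data.shape[1]} "
            f"(line {n_header + 1})"
        )

    channels = {
        name: data[:, i + 1].copy() for i, name in enumerate(CHANNEL_NAMES)
    }
    pulses = [int(i) for i in np.flatnonzero(data[:, -1] > 0.5)]
    if any(b <= a for a, b in zip(pulses, pulses[1:])):
        raise RecordingParseError("pulse indices not strictly increasing")

    spec = SubjectSpec(
        subject_id=meta["subject_id"],
        group=GroupLabel(meta["group"]),
        tremor_amplitude=float(meta.get("tremor_amplitude", 0.0)),
        tremor_freq_hz=float(meta.get("tremor_freq_hz", 5.0)),
        drift_scale=float(meta.get("drift_scale", 0.0)),
        noise_sd=float(meta.get("noise_sd", 0.0)),
        rng_seed=int(meta.get("rng_seed", 0)),
        voluntary_scale=float(meta.get("voluntary_scale", 1.0)),
    )
    rec = Recording(
        subject=spec,
        sample_rate_hz=float(meta["sample_rate"]),
        channels=channels,
        pulses=pulses,
        task_schedule=tasks,
    )
    return rec
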