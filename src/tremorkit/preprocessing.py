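"""Analytic-signal preprocessing of raw sensor channels.

The chain, applied per channel over the full record and in this order:

1. resultant — Euclidean norm of a 3-axis sensor's X, Y, Z channels
   (skipped for EMG envelopes, which are scalar);
2. band-pass — zero-phase 4th-order Butterworth, 0.5-25 Hz, removing
   gravity, geomagnetic offset and other quasi-static components;
3. detrend — subtraction of the mean and of a 20th-order least-squares
   polynomial capturing the remaining nonlinear trend;
4. analytic signal — Hilbert transform giving instantaneous amplitude
   a(t) = |x + iH(x)| and instantaneous frequency, the derivative of
   the unwrapped phase converted to Hz;
5. segmentation — task windows cut from the pulse annotations.

FS (the filtered, detrended signal), IA and IF are the three signal
representations the feature battery is computed on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .synthetic import (
    EMG_CHANNELS,
    GroupLabel,
    Recording,
    TASK_ORDER,
    TaskLabel,
)

#: resultant channels analysed downstream: six inertial resultants plus
#: the two scalar EMG envelopes
ANALYSIS_CHANNELS = (
    "accel1",
    "gyro1",
    "mag1",
    "accel2",
    "gyro2",
    "mag2",
    "emg1",
    "emg2",
)

DEFAULT_BAND_HZ = (0.5, 25.0)
DEFAULT_FILTER_ORDER = 4
DEFAULT_DETREND_ORDER = 20

# instantaneous frequency is forced to 0 where the amplitude is below
# this fraction of its maximum (the phase of a near-zero analytic signal
# is numerically meaningless)
IF_AMPLITUDE_FLOOR = 1e-12


def resultant(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Euclidean norm sqrt(x^2 + y^2 + z^2), elementwise."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise ValueError("resultant requires equal-length x, y, z series")
    return np.sqrt(x * x + y * y + z * z)


def bandpass(
    x: np.ndarray,
    sample_rate_hz: float = 50.0,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass.

    At 50 Hz sampling the nominal 25 Hz upper band edge coincides with
    Nyquist, where a digital band edge is undefined and near-Nyquist
    poles would ring for thousands of samples. An upper cutoff at or
    above Nyquist therefore degenerates the filter to the order-4
    high-pass at the lower cutoff — no content exists above Nyquist, so
    the intent (remove DC/gravity, keep everything below Nyquist) is
    realised exactly. Forward-backward filtering gives zero phase lag
    at the cost of squaring the magnitude response.
    """
    x = np.asarray(x, dtype=float)
    nyq = sample_rate_hz / 2.0
    low, high = band_hz
    if not 0 < low < high:
        raise ValueError(f"invalid band {band_hz} at fs={sample_rate_hz}")
    if high >= nyq:
        sos = sp_signal.butter(
            order, low, btype="highpass", fs=sample_rate_hz, output="sos"
        )
    else:
        sos = sp_signal.butter(
            order, [low, high], btype="bandpass", fs=sample_rate_hz, output="sos"
        )
    padlen = 3 * (2 * sos.shape[0] + 1 - min((sos[:, 2] == 0).sum(),
                                             (sos[:, 5] == 0).sum()))
    if x.size <= padlen:
        raise ValueError(
            f"series of length {x.size} too short for stable zero-phase "
            f"filtering (needs > {padlen} samples)"
        )
    return sp_signal.sosfiltfilt(sos, x)


def detrend(x: np.ndarray, poly_order: int = DEFAULT_DETREND_ORDER) -> np.ndarray:
    """Remove the mean and a least-squares polynomial trend.

    The fit uses numpy's scaled-domain polynomial basis (time mapped to
    [-1, 1]); a degree-20 fit on raw sample indices would be numerically
    singular. The residual mean is zero by construction because the
    basis contains the constant.
    """
    x = np.asarray(x, dtype=float)
    if x.size <= poly_order + 1:
        raise ValueError(
            f"series of length {x.size} too short for degree-{poly_order} detrend"
        )
    idx = np.arange(x.size)
    centred = x - x.mean()
    fit = np.polynomial.Polynomial.fit(idx, centred, deg=poly_order)
    return centred - fit(idx)


@dataclass
class AnalyticTriplet:
    """FS / IA / IF representations of one preprocessed channel.

    ``ia`` is the modulus of the analytic signal and bounds ``fs`` in
    absolute value pointwise; ``if_hz`` is the phase derivative in Hz.
    """

    fs: np.ndarray
    ia: np.ndarray
    if_hz: np.ndarray
    phase: np.ndarray
    sample_rate_hz: float

    def __post_init__(self) -> None:
        n = len(self.fs)
        if not (len(self.ia) == len(self.if_hz) == len(self.phase) == n):
            raise ValueError("triplet series must share one length")


def analytic(x: np.ndarray, sample_rate_hz: float = 50.0) -> AnalyticTriplet:
    """Analytic-signal decomposition of a band-passed, detrended series.

    Instantaneous frequency uses central finite differences of the
    unwrapped phase (one-sided at the edges), divided by 2*pi to give
    Hz. Samples where the instantaneous amplitude is below a numerical
    floor get IF = 0 rather than 0/0 phase noise.
    """
    x = np.asarray(x, dtype=float)
    h = np.imag(sp_signal.hilbert(x))
    ia = np.hypot(x, h)
    phase = np.unwrap(np.arctan2(h, x))
    if_hz = np.gradient(phase) * sample_rate_hz / (2.0 * np.pi)
    floor = IF_AMPLITUDE_FLOOR * (ia.max() if ia.size else 0.0)
    if_hz = np.where(ia <= floor, 0.0, if_hz)
    return AnalyticTriplet(
        fs=x, ia=ia, if_hz=if_hz, phase=phase, sample_rate_hz=sample_rate_hz
    )


@dataclass(frozen=True)
class TaskWindow:
    """One task execution: subject, trial, task and sample span.

    Samples are 0-based and the span half-open, ``[start, end)``.
    """

    subject_id: str
    group: GroupLabel
    trial_index: int
    task: TaskLabel
    start_sample: int
    end_sample: int

    def __post_init__(self) -> None:
        if self.end_sample <= self.start_sample:
            raise ValueError("window must satisfy end_sample > start_sample")


def segment(rec: Recording) -> list[TaskWindow]:
    """Cut task windows from the pulse annotations.

    Each trial contributes five pulses: the start of each of the four
    tasks plus the end of the last; windows are labelled T1..T4 in the
    fixed execution order. Inter-trial rest is excluded. A pulse count
    inconsistent with the 4-tasks-per-trial layout is an error.
    """
    pulses = list(rec.pulses)
    per_trial = len(TASK_ORDER) + 1
    if len(pulses) % per_trial != 0 or not pulses:
        raise ValueError(
            f"pulse count inconsistent with schedule: expected a multiple of "
            f"{per_trial} pulses (4 tasks per trial), found {len(pulses)}"
        )
    n_trials = len(pulses) // per_trial
    windows: list[TaskWindow] = []
    for trial in range(n_trials):
        chunk = pulses[trial * per_trial : (trial + 1) * per_trial]
        for k, task in enumerate(TASK_ORDER):
            windows.append(
                TaskWindow(
                    subject_id=rec.subject.subject_id,
                    group=rec.subject.group,
                    trial_index=trial + 1,
                    task=task,
                    start_sample=chunk[k],
                    end_sample=chunk[k + 1],
                )
            )
    return windows


def read_window_table(path) -> list[dict]:
    """Read an explicit window table (tab-separated) for real data.

    Columns: subject_id, trial, task, start_sample, end_sample.
    """
    rows = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        expected = ["subject_id", "trial", "task", "start_sample", "end_sample"]
        if header != expected:
            raise ValueError(f"window table header must be {expected}")
        for line in fh:
            sid, trial, task, start, end = line.strip().split("\t")
            rows.append(
                dict(
                    subject_id=sid,
                    trial=int(trial),
                    task=TaskLabel(task),
                    start_sample=int(start),
                    end_sample=int(end),
                )
            )
    return rows


def preprocess_recording(
    rec: Recording,
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
    filter_order: int = DEFAULT_FILTER_ORDER,
    detrend_order: int = DEFAULT_DETREND_ORDER,
) -> dict[str, AnalyticTriplet]:
    """Full-record preprocessing of the eight analysis channels.

    Inertial sensors are collapsed to their resultant first; EMG
    envelopes enter the shared filter/detrend/analytic chain directly.
    Detrending is applied to the whole record before windowing, so one
    smooth trend model serves all task segments.
    """
    fs_hz = rec.sample_rate_hz
    out: dict[str, AnalyticTriplet] = {}
    for name in ANALYSIS_CHANNELS:
        if name in EMG_CHANNELS:
            raw = rec.channels[name]
        else:
            raw = resultant(
                rec.channels[f"{name}_x"],
                rec.channels[f"{name}_y"],
                rec.channels[f"{name}_z"],
            )
        filtered = bandpass(raw, fs_hz, band_hz, filter_order)
        detrended = detrend(filtered, detrend_order)
        out[name] = analytic(detrended, fs_hz)
    return out
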