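"""The 12-feature battery and feature-matrix assembly.

Per task window, per analysis channel, and per signal representation
(FS, IA, IF) twelve classical time-domain features are computed:

amplitude — MAV, RMS, PEAK, MAVSDN, MAVSD, MAVFDN, MAVFD;
variability — INTERQ_RANGE, RANGE, STD, VAR;
entropy — APEN (approximate entropy, Pincus).

The "normalized" first/second-difference features (MAVFDN, MAVSDN) are
computed on the z-scored signal by default (min-max normalization is
available as an option). Approximate entropy uses the field-standard
parameters m = 2, r = 0.2 x SD, with self-matches included and the
Chebyshev distance on delay embeddings.

Feature matrices concatenate, per observation (one task window of one
subject trial), the 12 features x 8 channels of each representation in
a method combination — 96 columns per method — in a fixed method-major,
channel-minor order, and are z-score standardized column-wise before
distance-based projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import ANALYSIS_CHANNELS, AnalyticTriplet, TaskWindow
from .synthetic import TaskLabel

METHODS = ("FS", "IA", "IF")

#: the seven method combinations analysed, in reporting order
METHOD_COMBOS: tuple[tuple[str, ...], ...] = (
    ("FS",),
    ("IA",),
    ("IF",),
    ("FS", "IA"),
    ("FS", "IF"),
    ("IA", "IF"),
    ("FS", "IA", "IF"),
)

AMPLITUDE_FEATURES = ("MAV", "RMS", "PEAK", "MAVSDN", "MAVSD", "MAVFDN", "MAVFD")
VARIABILITY_FEATURES = ("INTERQ_RANGE", "RANGE", "STD", "VAR")
ENTROPY_FEATURES = ("APEN",)
FEATURE_NAMES = AMPLITUDE_FEATURES + VARIABILITY_FEATURES + ENTROPY_FEATURES


def combo_name(combo: tuple[str, ...]) -> str:
    return "-".join(combo)


def _normalize(x: np.ndarray, mode: str) -> np.ndarray:
    if mode == "zscore":
        sd = x.std()
        return np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd
    if mode == "minmax":
        span = x.max() - x.min()
        return np.zeros_like(x) if span == 0 else (x - x.min()) / span
    raise ValueError(f"unknown normalization mode {mode!r}")


def amplitude_features(x: np.ndarray, normalization: str = "zscore") -> dict[str, float]:
    """MAV, RMS, PEAK and mean-absolute first/second differences.

    PEAK is the global maximum of the signed series. The normalized
    variants are computed on the normalized signal; a zero-variance
    input makes them 0 by convention.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("amplitude features need at least 3 samples")
    xn = _normalize(x, normalization)
    d1, d2 = np.diff(x), np.diff(x, n=2)
    d1n, d2n = np.diff(xn), np.diff(xn, n=2)
    return {
        "MAV": float(np.mean(np.abs(x))),
        "RMS": float(np.sqrt(np.mean(x * x))),
        "PEAK": float(np.max(x)),
        "MAVSDN": float(np.mean(np.abs(d2n))),
        "MAVSD": float(np.mean(np.abs(d2))),
        "MAVFDN": float(np.mean(np.abs(d1n))),
        "MAVFD": float(np.mean(np.abs(d1))),
    }


def variability_features(x: np.ndarray) -> dict[str, float]:
    """Interquartile range, range, and sample (n-1) SD and variance."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("variability features need at least 2 samples")
    q1, q3 = np.percentile(x, [25, 75])
    return {
        "INTERQ_RANGE": float(q3 - q1),
        "RANGE": float(np.max(x) - np.min(x)),
        "STD": float(np.std(x, ddof=1)),
        "VAR": float(np.var(x, ddof=1)),
    }


def approximate_entropy(
    x: np.ndarray, m: int = 2, r_factor: float = 0.2
) -> float:
    """Approximate entropy ApEn(m, r) with r = r_factor x SD(x).

    Pincus's statistic: ApEn = Phi_m(r) - Phi_{m+1}(r), where Phi_m is
    the mean over template positions i of log C_i^m(r), C_i^m the
    fraction of length-m templates within Chebyshev distance r of
    template i (self-matches included). A constant series has ApEn 0.

    The Chebyshev distances between delay embeddings are accumulated as
    running maxima of shifted scalar-distance matrices, which keeps the
    computation at two O(n^2) passes instead of an O(n^2 m) embedding
    broadcast.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 10 * m:
        raise ValueError(f"approximate entropy needs >= {10 * m} samples")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = r_factor * sd
    D = np.abs(x[:, None] - x[None, :])

    def phi(mm: int) -> float:
        n_templates = x.size - mm + 1
        M = D[:n_templates, :n_templates].copy()
        for k in range(1, mm):
            np.maximum(M, D[k : k + n_templates, k : k + n_templates], out=M)
        counts = np.mean(M <= r, axis=1)  # includes the self-match
        return float(np.mean(np.log(counts)))

    return phi(m) - phi(m + 1)


def feature_vector(
    x: np.ndarray,
    normalization: str = "zscore",
    apen_m: int = 2,
    apen_r_factor: float = 0.2,
) -> dict[str, float]:
    """All 12 features of one series, in canonical order."""
    out = amplitude_features(x, normalization)
    out.update(variability_features(x))
    out["APEN"] = approximate_entropy(x, apen_m, apen_r_factor)
    return {name: out[name] for name in FEATURE_NAMES}


def extract_features(
    triplets: dict[str, AnalyticTriplet],
    windows: list[TaskWindow],
    channels: tuple[str, ...] = ANALYSIS_CHANNELS,
    normalization: str = "zscore",
    apen_m: int = 2,
    apen_r_factor: float = 0.2,
    tasks: tuple[TaskLabel, ...] | None = None,
) -> pd.DataFrame:
    """Feature table for one subject's windows.

    Rows: one per task window (restricted to ``tasks`` if given).
    Columns: metadata (subject_id, group, trial, task) plus a flat
    ``method:channel:feature`` feature block.
    """
    records = []
    for w in windows:
        if tasks is not None and w.task not in tasks:
            continue
        row: dict = {
            "subject_id": w.subject_id,
            "group": w.group.value,
            "trial": w.trial_index,
            "task": w.task.value,
        }
        for channel in channels:
            trip = triplets[channel]
            series = {
                "FS": trip.fs[w.start_sample : w.end_sample],
                "IA": trip.ia[w.start_sample : w.end_sample],
                "IF": trip.if_hz[w.start_sample : w.end_sample],
            }
            for method in METHODS:
                feats = feature_vector(
                    series[method], normalization, apen_m, apen_r_factor
                )
                for fname, value in feats.items():
                    row[f"{method}:{channel}:{fname}"] = value
        records.append(row)
    return pd.DataFrame.from_records(records)


@dataclass
class FeatureMatrix:
    """Observations x features block for one task and method combination."""

    X: np.ndarray
    columns: list[str]
    meta: pd.DataFrame  # subject_id, group, trial per row
    task: TaskLabel
    combo: tuple[str, ...]
    standardized: bool

    @property
    def n_observations(self) -> int:
        return self.X.shape[0]


def build_matrix(
    table: pd.DataFrame,
    task: TaskLabel,
    combo: tuple[str, ...],
    channels: tuple[str, ...] = ANALYSIS_CHANNELS,
    standardize: bool = True,
) -> FeatureMatrix:
    """Assemble the feature matrix of one task for one method combination.

    Column order is method-major, channel-minor, feature-innermost.
    Columns are z-scored across observations by default; constant
    columns standardize to 0. Any non-finite feature is an error naming
    the offending observation and column.
    """
    if not combo:
        raise ValueError("method combination must be nonempty")
    for method in combo:
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}")
    sub = table[table["task"] == task.value]
    if sub.empty:
        raise ValueError(f"no observations for task {task.value}")
    if set(sub["task"]) != {task.value}:
        raise ValueError("inconsistent tasks in feature table selection")
    sub = sub.sort_values(["subject_id", "trial"], kind="stable").reset_index(
        drop=True
    )
    columns = [
        f"{method}:{channel}:{fname}"
        for method in combo
        for channel in channels
        for fname in FEATURE_NAMES
    ]
    X = sub[columns].to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(X))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-finite feature at observation {i} "
            f"(subject {sub.loc[i, 'subject_id']}, trial {sub.loc[i, 'trial']}), "
            f"column {columns[j]}"
        )
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    meta = sub[["subject_id", "group", "trial"]].copy()
    return FeatureMatrix(
        X=X,
        columns=columns,
        meta=meta,
        task=task,
        combo=tuple(combo),
        standardized=standardize,
    )


def write_matrix(fm: FeatureMatrix, path) -> None:
    """Persist a feature matrix as TSV with a metadata header block."""
    with open(path, "w") as fh:
        fh.write(f"# task: {fm.task.value}\n")
        fh.write(f"# combo: {combo_name(fm.combo)}\n")
        fh.write(f"# standardized: {fm.standardized}\n")
        df = pd.concat(
            [fm.meta.reset_index(drop=True),
             pd.DataFrame(fm.X, columns=fm.columns)],
            axis=1,
        )
        df.to_csv(fh, sep="\t", index=False)
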