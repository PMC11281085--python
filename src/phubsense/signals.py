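"""Windowing, keyframe pairing, axis reductions, and signal-energy ranking.

A triaxial 50 Hz recording is cut into fixed-length sliding windows
(6 s length, 3 s step, i.e. 50% overlap between neighbours).  Each window can
be collapsed to a single series by one of eight reductions: a raw axis
(X, Y, Z), the magnitude V = sqrt(ax^2 + ay^2 + az^2), or an axis
subtraction (X-Y, X-Z, Y-Z, X-Y-Z).  Reductions are ranked by mean signal
energy — the mean squared deviation from the window mean — to pick the
series that best exposes behavioural oscillation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: The eight reduction methods, in canonical (tie-break) order.
REDUCTION_METHODS = ("x", "y", "z", "v", "x-y", "x-z", "y-z", "x-y-z")


class MissingFrameError(ValueError):
    """No video frame falls inside the acceleration window's span."""


@dataclass
class AccelRecording:
    """A continuous triaxial acceleration stream.

    timestamps are seconds, strictly increasing; ax/ay/az are m/s^2.
    """

    timestamps: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    rate: float
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        n = len(self.timestamps)
        if not (len(self.ax) == len(self.ay) == len(self.az) == n):
            raise ValueError("timestamp and axis arrays must have equal length")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def samples(self) -> np.ndarray:
        """(n, 3) array of [ax, ay, az] rows."""
        return np.column_stack([self.ax, self.ay, self.az])


@dataclass
class AccelWindow:
    """One fixed-length window: the unit of analysis (n x 3 samples)."""

    t_start: float
    t_end: float
    samples: np.ndarray  # (n, 3)
    rate: float
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array")

    @property
    def n(self) -> int:
        return self.samples.shape[0]


@dataclass
class ReducedSignal:
    """A 1-D series obtained from a window by one reduction method."""

    method: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.method not in REDUCTION_METHODS:
            raise ValueError(f"unknown reduction method {self.method!r}")
        self.values = np.asarray(self.values, dtype=float)


def segment(
    recording: AccelRecording, window_s: float = 6.0, step_s: float = 3.0
) -> list[AccelWindow]:
    """Cut a recording into half-open [t, t + window_s) sliding windows.

    The incomplete tail is discarded, so a recording shorter than one window
    yields an empty list.  With the 6 s / 3 s defaults adjacent windows
    overlap by 50%.
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    if not (0 < step_s <= window_s):
        raise ValueError("step_s must satisfy 0 < step_s <= window_s")
    n_win = int(round(window_s * recording.rate))
    n_step = int(round(step_s * recording.rate))
    data = recording.samples
    t0 = recording.timestamps[0] if len(recording.timestamps) else 0.0
    windows: list[AccelWindow] = []
    start = 0
    while start + n_win <= data.shape[0]:
        t_start = t0 + start / recording.rate
        windows.append(
            AccelWindow(
                t_start=t_start,
                t_end=t_start + window_s,
                samples=data[start : start + n_win],
                rate=recording.rate,
                subject_id=recording.subject_id,
            )
        )
        start += n_step
    return windows


def pair_keyframe(window: AccelWindow, frames: Sequence[tuple[float, object]]):
    """Select the endpoint keyframe for a window.

    ``frames`` is a sequence of (timestamp, frame) pairs.  The frame whose
    timestamp is nearest to the window's end is chosen (ties break to the
    earlier frame); it must lie within [t_start, t_end] or a
    MissingFrameError is raised.
    """
    if not frames:
        raise MissingFrameError("no frames supplied")
    times = np.array([t for t, _ in frames], dtype=float)
    dist = np.abs(times - window.t_end)
    order = np.lexsort((times, dist))  # nearest first, earlier wins ties
    best = order[0]
    if not (window.t_start <= times[best] <= window.t_end):
        raise MissingFrameError(
            f"nearest frame at t={times[best]:.3f} s lies outside window "
            f"[{window.t_start:.3f}, {window.t_end:.3f}]"
        )
    return frames[best]


def reduce_window(window: AccelWindow, method: str) -> ReducedSignal:
    """Collapse a triaxial window to one series by the named reduction."""
    if method not in REDUCTION_METHODS:
        raise ValueError(f"unknown reduction method {method!r}")
    ax, ay, az = window.samples.T
    if method == "x":
        values = ax
    elif method == "y":
        values = ay
    elif method == "z":
        values = az
    elif method == "v":
        values = np.sqrt(ax**2 + ay**2 + az**2)
    elif method == "x-y":
        values = ax - ay
    elif method == "x-z":
        values = ax - az
    elif method == "y-z":
        values = ay - az
    else:  # x-y-z
        values = ax - ay - az
    return ReducedSignal(method=method, values=values.copy())


def signal_energy(signal: ReducedSignal | np.ndarray) -> float:
    """Mean squared deviation from the series mean (mean-removed power).

    Removing the mean makes the statistic translation-invariant, so the
    gravity baseline does not swamp behavioural oscillation.
    """
    values = signal.values if isinstance(signal, ReducedSignal) else np.asarray(signal, float)
    if values.size < 2:
        raise ValueError("signal energy requires at least 2 samples")
    if values.max() == values.min():  # exactly constant: no residue noise
        return 0.0
    return float(np.mean((values - values.mean()) ** 2))


def rank_reductions(
    windows: Sequence[AccelWindow],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean signal energy of every reduction method over a window set.

    Returns a DataFrame with one row per method, sorted by descending mean
    energy (ties fall back to canonical method order).  When per-window
    ``labels`` are given, a per-label mean energy column is added for each
    distinct label, mirroring a behaviour-grouped energy table.
    """
    if len(windows) == 0:
        raise ValueError("rank_reductions requires a non-empty window set")
    if labels is not None and len(labels) != len(windows):
        raise ValueError("labels must match windows in length")

    energies = {
        m: np.array([signal_energy(reduce_window(w, m)) for w in windows])
        for m in REDUCTION_METHODS
    }
    rows = []
    for i, m in enumerate(REDUCTION_METHODS):
        row: dict[str, object] = {
            "method": m,
            "mean_energy": float(energies[m].mean()),
            "_order": i,
        }
        if labels is not None:
            lab = np.asarray(labels)
            for name in pd.unique(lab):
                row[f"mean_energy[{name}]"] = float(energies[m][lab == name].mean())
        rows.append(row)
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["mean_energy", "_order"], ascending=[False, True], kind="stable"
    ).drop(columns="_order")
    return table.reset_index(drop=True)


def read_accel_csv(path: str | Path, rate: float | None = None,
                   subject_id: str = "unknown") -> AccelRecording:
    """Read a t, ax, ay, az CSV (header required) into an AccelRecording."""
    df = pd.read_csv(path)
    required = {"t", "ax", "ay", "az"}
    if not required.issubset(df.columns):
        raise ValueError(f"accel CSV must have columns {sorted(required)}")
    t = df["t"].to_numpy(float)
    if rate is None:
        if len(t) < 2:
            raise ValueError("cannot infer rate from fewer than 2 samples")
        rate = 1.0 / float(np.median(np.diff(t)))
    return AccelRecording(
        timestamps=t, ax=df["ax"].to_numpy(float), ay=df["ay"].to_numpy(float),
        az=df["az"].to_numpy(float), rate=rate, subject_id=subject_id,
    )


def write_accel_csv(window: AccelWindow, path: str | Path) -> None:
    t = window.t_start + np.arange(window.n) / window.rate
    pd.DataFrame(
        {"t": t, "ax": window.samples[:, 0], "ay": window.samples[:, 1],
         "az": window.samples[:, 2]}
    ).to_csv(path, index=False)
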