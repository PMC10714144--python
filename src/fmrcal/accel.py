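"""Tri-axial acceleration processing: static/dynamic separation and VeDBA.

The raw signal from a body-mounted accelerometer mixes a slowly varying
gravitational (static) component, which reflects posture, with the dynamic
component produced by movement.  The static part is estimated as a centred
running mean per axis; the residual is the dynamic acceleration, and the
vectorial dynamic body acceleration is its per-sample Euclidean norm

    VeDBA = sqrt(Ax^2 + Ay^2 + Az^2)   [g]

which serves as the movement proxy for energy expenditure throughout the
package.  For devices that cannot be mounted on the animal's centre line
(here: tail-mounted), the vectorial form is preferred over the absolute-sum
ODBA because it is invariant to device orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AccelTrace",
    "VedbaSeries",
    "split_static_dynamic",
    "compute_vedba",
    "compute_odba",
    "summarize_vedba",
    "vedba_per_second",
    "read_accel_csv",
    "write_accel_csv",
]


@dataclass
class AccelTrace:
    """Uniformly sampled tri-axial acceleration in g.

    Axes follow the surge (x), sway (y), heave (z) convention.  ``time``
    holds per-sample timestamps (datetime64[ns]); sampling must be uniform
    at ``rate`` Hz.  Gaps larger than two sample intervals are flagged (not
    silently filled) and split the trace into segments for statistics.
    """

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise ValueError("time, x, y, z must have equal length")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def duration_s(self) -> float:
        if len(self) < 2:
            return 0.0
        return float((self.time[-1] - self.time[0]) / np.timedelta64(1, "s"))

    def gap_segments(self, max_gap_intervals: float = 2.0) -> list[slice]:
        """Contiguous segments split wherever the sampling gap exceeds
        ``max_gap_intervals`` sample intervals."""
        if len(self) == 0:
            return []
        dt = np.diff(self.time) / np.timedelta64(1, "s")
        breaks = np.nonzero(dt > max_gap_intervals / self.rate)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks + 1, [len(self)]))
        return [slice(int(a), int(b)) for a, b in zip(starts, ends)]

    def check_calibration(self, low: float = 0.8, high: float = 1.2) -> float:
        """Mean magnitude of the total acceleration vector; a correctly
        calibrated, mostly stationary record averages ~1 g.  Warns outside
        [low, high]."""
        mag = float(np.mean(np.sqrt(self.x**2 + self.y**2 + self.z**2)))
        if not (low <= mag <= high):
            warnings.warn(
                f"mean |acceleration| = {mag:.3f} g outside [{low}, {high}]; "
                "device calibration suspect",
                stacklevel=2,
            )
        return mag


@dataclass
class VedbaSeries:
    """Per-sample VeDBA (g, non-negative) with timestamps."""

    time: np.ndarray
    vedba: np.ndarray
    rate: float = field(default=25.0)

    def __len__(self) -> int:
        return len(self.vedba)


def _running_mean_truncated(v: np.ndarray, half: int) -> np.ndarray:
    """Centred running mean with the window truncated at the edges, so the
    static + dynamic decomposition reconstructs the input exactly."""
    n = len(v)
    c = np.concatenate(([0.0], np.cumsum(v, dtype=np.float64)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (c[hi] - c[lo]) / (hi - lo)


def split_static_dynamic(trace: AccelTrace, window_s: float = 2.0) -> tuple[AccelTrace, AccelTrace]:
    """Separate static (gravity/posture) and dynamic acceleration.

    Static is a centred running mean over ``window_s`` seconds per axis;
    dynamic is the residual.  The window is truncated (not padded) at the
    trace edges, so ``static + dynamic == input`` sample for sample.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    if len(trace) == 0:
        raise ValueError("empty trace")
    half = int(round(window_s * trace.rate / 2))
    if len(trace) < 2 * half + 1:
        raise ValueError(
            f"trace of {len(trace)} samples shorter than the {window_s} s window"
        )
    stat = {}
    dyn = {}
    for ax in ("x", "y", "z"):
        v = np.asarray(getattr(trace, ax), dtype=np.float64)
        s = _running_mean_truncated(v, half)
        stat[ax] = s
        dyn[ax] = v - s
    static = AccelTrace(trace.time, stat["x"], stat["y"], stat["z"], trace.rate)
    dynamic = AccelTrace(trace.time, dyn["x"], dyn["y"], dyn["z"], trace.rate)
    return static, dynamic


def compute_vedba(dynamic: AccelTrace) -> VedbaSeries:
    """Per-sample vectorial dynamic body acceleration (g)."""
    v = np.sqrt(dynamic.x**2 + dynamic.y**2 + dynamic.z**2)
    return VedbaSeries(dynamic.time, v, dynamic.rate)


def compute_odba(dynamic: AccelTrace) -> VedbaSeries:
    """Absolute-sum variant (ODBA); cross-check only, not used in the pipeline."""
    v = np.abs(dynamic.x) + np.abs(dynamic.y) + np.abs(dynamic.z)
    return VedbaSeries(dynamic.time, v, dynamic.rate)


def summarize_vedba(
    series: VedbaSeries,
    mask: np.ndarray | None = None,
    max_gap_intervals: float = 2.0,
) -> tuple[float, float]:
    """(VeDBA_sum in g*s, VeDBA_mean in g) over the samples selected by mask.

    The sum weights each sample by the sample interval.  Records with gaps
    are handled per contiguous segment and combined duration-weighted, which
    for uniform sampling reduces to the plain sum/mean over selected samples.
    """
    if mask is None:
        mask = np.ones(len(series), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.vedba.shape:
        raise ValueError("mask must match the series length")
    if not mask.any():
        raise ValueError("empty mask: no samples selected")
    dt = 1.0 / series.rate
    sel = series.vedba[mask]
    return float(sel.sum() * dt), float(sel.mean())


def vedba_per_second(series: VedbaSeries) -> tuple[np.ndarray, np.ndarray]:
    """Mean VeDBA within each whole second of the record.

    Returns (second_start_times, means); trailing partial seconds are
    dropped so the grid aligns with the 1-s ethogram.
    """
    per = int(round(series.rate))
    n_sec = len(series) // per
    if n_sec == 0:
        raise ValueError("record shorter than one second")
    v = series.vedba[: n_sec * per].reshape(n_sec, per)
    t = series.time[: n_sec * per : per]
    return t, v.mean(axis=1)


def read_accel_csv(path) -> AccelTrace:
    """Read the accel CSV dialect (time, x_g, y_g, z_g; ISO-8601 time)."""
    df = pd.read_csv(path, parse_dates=["time"])
    t = df["time"].to_numpy()
    dt = np.diff(t) / np.timedelta64(1, "s")
    if len(dt) == 0:
        raise ValueError("accel CSV holds fewer than two samples")
    rate = 1.0 / np.median(dt)
    return AccelTrace(t, df["x_g"].to_numpy(float), df["y_g"].to_numpy(float),
                      df["z_g"].to_numpy(float), float(rate))


def write_accel_csv(trace: AccelTrace, path) -> None:
    pd.DataFrame(
        {"time": trace.time, "x_g": trace.x, "y_g": trace.y, "z_g": trace.z}
    ).to_csv(path, index=False)
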