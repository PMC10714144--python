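"""Per-second behaviour classification from accelerometry.

Workflow (the standard unsupervised biologging ethogram recipe):

1. continuous Morlet wavelet transform of the heave axis over 0.5-12 Hz,
   amplitudes averaged within 1-s windows -> one spectral frame per second;
2. k-means on the standardized frames (over-clustered, default k = 12);
3. clusters mapped onto provisional classes by ordered heuristics
   (high-amplitude burst -> dive; periodic 2.5-5 Hz peak -> flapping;
   everything low-amplitude -> "low", disambiguated next);
4. GPS rules: low-amplitude seconds moving at or above a glide-speed
   threshold -> gliding; slower -> resting, split into resting on land vs
   at sea by colony location;
5. dive typing: a dive bout entered from flight is a plunge dive, one
   entered from sitting on the water is a duck dive.

Six final classes: flapping, gliding, rest_sea, rest_land, plunge_dive,
duck_dive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from sklearn.cluster import KMeans
from sklearn.preprocessing import StandardScaler

__all__ = [
    "BEHAVIOURS",
    "SpectralFrames",
    "Ethogram",
    "ActivityBudget",
    "wavelet_frames",
    "cluster_frames",
    "assign_behaviours",
    "apply_rules",
    "classify_dives",
    "budget",
]

BEHAVIOURS = ("flapping", "gliding", "rest_sea", "rest_land", "plunge_dive", "duck_dive")

#: provisional classes before GPS rules and dive typing
_PROVISIONAL = ("dive", "flapping", "low")


@dataclass
class SpectralFrames:
    """One wavelet-amplitude spectrum per second of heave-axis signal."""

    time: np.ndarray  # start of each 1-s window
    freqs_hz: np.ndarray  # band centre frequencies
    spectra: np.ndarray  # (n_seconds, n_bands) mean |CWT| amplitude
    rms_dynamic: np.ndarray  # per-second RMS of the heave dynamic signal

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class Ethogram:
    """Complete per-second behaviour labels with per-second mean VeDBA."""

    time: np.ndarray
    behaviour: np.ndarray  # array of str labels
    vedba_1s: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.vedba_1s is not None and len(self.vedba_1s) != len(self.behaviour):
            raise ValueError("vedba_1s must match behaviour length")

    def __len__(self) -> int:
        return len(self.behaviour)

    @property
    def duration_h(self) -> float:
        return len(self) / 3600.0

    def to_frame(self) -> pd.DataFrame:
        d = {"time": self.time, "behaviour": self.behaviour}
        if self.vedba_1s is not None:
            d["vedba_1s"] = self.vedba_1s
        return pd.DataFrame(d)


@dataclass
class ActivityBudget:
    """Per-bird time and VeDBA totals per behaviour."""

    T_h: dict[str, float]
    vedba_sum: dict[str, float]  # g*s per behaviour
    proportion: dict[str, float]
    n_plunge: int
    n_duck: int
    dive_rate_per_h: float  # dives per hour at sea
    total_h: float

    @property
    def time_at_sea_h(self) -> float:
        return self.total_h - self.T_h["rest_land"]


def _cwt_chunk(x: np.ndarray, scales: np.ndarray, rate: float) -> np.ndarray:
    coef, _ = pywt.cwt(x, scales, "morl", sampling_period=1.0 / rate, method="fft")
    return np.abs(coef)


def wavelet_frames(
    heave_dynamic: np.ndarray,
    rate: float,
    time: np.ndarray | None = None,
    fmin_hz: float = 0.5,
    fmax_hz: float = 12.0,
    n_bands: int = 12,
    chunk_s: float = 600.0,
) -> SpectralFrames:
    """Morlet CWT of the heave dynamic signal, averaged per 1-s window.

    Band centre frequencies are log-spaced over [fmin, fmax].  The
    transform is evaluated in overlapping chunks (2 s pad each side) to
    bound memory on long records; output is deterministic.
    """
    x = np.asarray(heave_dynamic, dtype=np.float64)
    per = int(round(rate))
    n_sec = len(x) // per
    if n_sec < 1:
        raise ValueError("trace shorter than one second")
    freqs = np.geomspace(fmin_hz, fmax_hz, n_bands)
    scales = pywt.frequency2scale("morl", freqs / rate)
    n_use = n_sec * per
    # pad each chunk by the effective support of the largest (lowest
    # frequency) wavelet so chunking does not perturb the transform
    pad = int(np.ceil(8.0 / fmin_hz)) * per
    chunk = max(per, int(round(chunk_s)) * per)
    spectra = np.empty((n_sec, n_bands))
    for start in range(0, n_use, chunk):
        stop = min(start + chunk, n_use)
        lo = max(0, start - pad)
        hi = min(len(x), stop + pad)
        amp = _cwt_chunk(x[lo:hi], scales, rate)[:, start - lo : stop - lo]
        secs = (stop - start) // per
        block = amp.reshape(n_bands, secs, per).mean(axis=2).T
        spectra[start // per : start // per + secs] = block
    rms = np.sqrt((x[:n_use] ** 2).reshape(n_sec, per).mean(axis=1))
    if time is None:
        t = np.arange(n_sec)
    else:
        t = np.asarray(time)[: n_use : per]
    return SpectralFrames(t, freqs, spectra, rms)


def cluster_frames(frames: SpectralFrames, k: int = 12, seed: int = 0) -> np.ndarray:
    """k-means labels (0..k-1) on standardized spectra + RMS features."""
    n = len(frames)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of frames ({n})")
    feats = np.column_stack([frames.spectra, frames.rms_dynamic])
    X = StandardScaler().fit_transform(feats)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return km.fit_predict(X)


def assign_behaviours(
    clusters: np.ndarray,
    frames: SpectralFrames,
    dive_rms_g: float = 1.8,
    flap_band_hz: tuple[float, float] = (2.5, 5.0),
    flap_rms_g: float = 0.5,
) -> tuple[np.ndarray, dict[int, str]]:
    """Map clusters onto provisional classes {dive, flapping, low}.

    Ordered heuristics per cluster: mean RMS above ``dive_rms_g`` -> dive;
    else a spectral peak inside the wingbeat band with mean RMS above
    ``flap_rms_g`` -> flapping; else low (gliding/resting, disambiguated by
    the GPS rules).  Returns (per-second provisional labels, mapping).
    """
    mapping: dict[int, str] = {}
    for c in np.unique(clusters):
        m = clusters == c
        if not m.any():
            warnings.warn(f"cluster {c} is empty; no behaviour assigned", stacklevel=2)
            continue
        rms = float(frames.rms_dynamic[m].mean())
        peak_hz = float(frames.freqs_hz[np.argmax(frames.spectra[m].mean(axis=0))])
        if rms >= dive_rms_g:
            mapping[c] = "dive"
        elif flap_band_hz[0] <= peak_hz <= flap_band_hz[1] and rms >= flap_rms_g:
            mapping[c] = "flapping"
        else:
            mapping[c] = "low"
    labels = np.array([mapping[c] for c in clusters], dtype=object)
    return labels, mapping


def apply_rules(
    provisional: np.ndarray,
    speed_kmh_1s: np.ndarray,
    on_land_1s: np.ndarray,
    glide_speed_threshold_kmh: float = 10.0,
) -> np.ndarray:
    """Resolve low-amplitude seconds with GPS speed and colony location.

    Low seconds at or above the glide-speed threshold become gliding;
    slower low seconds become resting, split into rest_land (inside the
    colony radius) and rest_sea.  Idempotent: final labels pass through
    unchanged.
    """
    n = len(provisional)
    if len(speed_kmh_1s) != n or len(on_land_1s) != n:
        raise ValueError("speed and land masks must be on the same 1-s grid")
    out = np.array(provisional, dtype=object)
    low = (out == "low") | (out == "gliding") | (out == "rest_sea") | (out == "rest_land")
    fast = np.asarray(speed_kmh_1s) >= glide_speed_threshold_kmh
    land = np.asarray(on_land_1s, dtype=bool)
    out[low & fast & ~land] = "gliding"
    out[low & ~fast & land] = "rest_land"
    out[low & ~fast & ~land] = "rest_sea"
    # a "moving" second inside the colony radius cannot be a glide
    out[low & fast & land] = "rest_land"
    return out


def classify_dives(
    labels: np.ndarray,
    merge_gap_s: int = 2,
    lookback_s: int = 5,
) -> tuple[np.ndarray, int, int]:
    """Split dive seconds into plunge vs duck dives.

    Contiguous dive seconds separated by less than ``merge_gap_s`` form one
    bout.  A bout preceded (within ``lookback_s``, skipping other dive
    seconds) by flight becomes a plunge dive; one preceded by resting on
    the sea surface becomes a duck dive.  A bout at the very start of the
    record cannot be typed and defaults, with a warning, to plunge (the
    dominant dive mode of the study species).

    Returns (labels, n_plunge, n_duck).
    """
    out = np.array(labels, dtype=object)
    is_dive = np.isin(out, ("dive", "plunge_dive", "duck_dive"))
    n = len(out)
    bouts = []
    i = 0
    while i < n:
        if not is_dive[i]:
            i += 1
            continue
        j = i
        while j + 1 < n:
            # merge across short non-dive gaps
            k = j + 1
            gap = 0
            while k < n and not is_dive[k] and gap < merge_gap_s:
                k += 1
                gap += 1
            if k < n and is_dive[k] and gap < merge_gap_s:
                j = k
            else:
                break
        bouts.append((i, j))
        i = j + 1
    n_plunge = n_duck = 0
    for a, b in bouts:
        kind = None
        for t in range(a - 1, max(-1, a - 1 - lookback_s), -1):
            if t < 0 or is_dive[t]:
                continue
            if out[t] in ("flapping", "gliding"):
                kind = "plunge_dive"
            elif out[t] == "rest_sea":
                kind = "duck_dive"
            if kind:
                break
        if kind is None:
            warnings.warn(
                "dive bout at record start cannot be typed; defaulting to plunge",
                stacklevel=2,
            )
            kind = "plunge_dive"
        sel = slice(a, b + 1)
        mask = is_dive[sel]
        seg = out[sel]
        seg[mask] = kind
        out[sel] = seg
        if kind == "plunge_dive":
            n_plunge += 1
        else:
            n_duck += 1
    return out, n_plunge, n_duck


def budget(ethogram: Ethogram, n_plunge: int | None = None, n_duck: int | None = None) -> ActivityBudget:
    """Time, VeDBA and dive totals per behaviour for one bird."""
    lab = ethogram.behaviour
    n = len(lab)
    if n == 0:
        raise ValueError("empty ethogram")
    unknown = set(np.unique(lab)) - set(BEHAVIOURS)
    if unknown:
        raise ValueError(f"unknown behaviour labels: {sorted(unknown)}")
    T = {}
    vs = {}
    prop = {}
    for b in BEHAVIOURS:
        m = lab == b
        T[b] = float(m.sum()) / 3600.0
        prop[b] = float(m.sum()) / n
        if ethogram.vedba_1s is not None:
            vs[b] = float(ethogram.vedba_1s[m].sum())  # 1-s means * 1 s -> g*s
        else:
            vs[b] = float("nan")
    if n_plunge is None:
        n_plunge = _count_bouts(lab, "plunge_dive")
    if n_duck is None:
        n_duck = _count_bouts(lab, "duck_dive")
    total_h = n / 3600.0
    sea_h = total_h - T["rest_land"]
    rate = (n_plunge + n_duck) / sea_h if sea_h > 0 else 0.0
    return ActivityBudget(T, vs, prop, int(n_plunge), int(n_duck), rate, total_h)


def _count_bouts(labels: np.ndarray, kind: str) -> int:
    m = np.asarray(labels == kind, dtype=int)
    return int(np.sum(np.diff(np.concatenate(([0], m))) == 1))
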