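"""Track linking and dynamic CCP statistics.

Per-frame detections are linked into tracks by greedy mutual-nearest-
neighbour assignment with gap closing; tracks are then classified:

* persistent — present in every frame of the acquisition (stalled pits,
  analysed separately, as a surface density per unit area);
* bona fide — trajectories whose maximum master amplitude passes an
  intensity threshold (real pits that grow, mature and undergo scission);
* transient — everything else (abortive coat assemblies).

Downstream statistics mirror the live-cell CCP analyses: lifetime
distributions and the mean lifetime of the top 5% ("p95"), slave-positive
subclassification (e.g. NECAP-positive vs -negative pits), cohort-averaged
intensity traces (mean +/- SE on a common resampled axis per lifetime
range), and sub-sample recruitment-timing estimates (Gaussian-smoothed
traces, cubic interpolation around the discrete argmax, central differences
for the recruitment-rate peak).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "Track",
    "CohortSummary",
    "PeakEstimate",
    "LifetimeStats",
    "link",
    "classify",
    "slave_positivity",
    "slave_significance_from_traces",
    "lifetime_stats",
    "persistent_density",
    "cohort_traces",
    "max_intensity_time",
    "max_rate_time",
    "tracks_to_frame",
]


@dataclass
class Track:
    """One linked CCP trajectory with per-channel amplitude traces."""

    track_id: int
    frames: np.ndarray                # observed frame indices, increasing
    x: np.ndarray
    y: np.ndarray
    amplitude: dict[str, np.ndarray]  # channel -> trace (master mandatory)
    significant: dict[str, np.ndarray] = field(default_factory=dict)
    frame_interval: float = 2.0
    category: str | None = None
    slave_positive: bool | None = None

    @property
    def first(self) -> int:
        return int(self.frames[0])

    @property
    def last(self) -> int:
        return int(self.frames[-1])

    @property
    def lifetime_s(self) -> float:
        return (self.last - self.first + 1) * self.frame_interval

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class CohortSummary:
    """Mean +/- SE traces for tracks within one lifetime range."""

    lifetime_range: tuple[float, float]
    n_tracks: int
    time_axis: np.ndarray             # normalized 0..1, fixed length
    mean: dict[str, np.ndarray]
    se: dict[str, np.ndarray]


@dataclass
class PeakEstimate:
    """Sub-sample timing of a trace maximum (or rate maximum)."""

    time_s: float
    value: float
    degenerate: bool = False
    reliable: bool = True


@dataclass
class LifetimeStats:
    lifetimes_s: np.ndarray
    mean_s: float
    p95_value_s: float   # 95th percentile of the lifetime distribution
    p95_mean_s: float    # mean lifetime of the top-5% tracks
    hist_edges: np.ndarray
    hist_counts: np.ndarray


# ---------------------------------------------------------------------------
# linking


def link(detections: pd.DataFrame, max_displacement: float = 3.0,
         max_gap: int = 2, frame_interval: float = 2.0,
         extra_channels: tuple[str, ...] = ()) -> list[Track]:
    """Greedy mutual-nearest-neighbour linking with gap closing.

    ``detections`` is a table with columns frame, x, y, amplitude (master),
    optionally significant, plus ``<ch>_amplitude`` / ``<ch>_significant``
    for each name in ``extra_channels`` (dependent slave measurements riding
    along with their master detection).  Detections must be sortable by
    frame; each detection joins at most one track.
    """
    if len(detections) == 0:
        return []
    det = detections.sort_values("frame", kind="stable").reset_index(drop=True)
    frames = det["frame"].to_numpy(int)
    xs = det["x"].to_numpy(float)
    ys = det["y"].to_numpy(float)

    assigned = np.full(len(det), -1)
    # active track state: id -> (last_index, last_frame)
    active: dict[int, tuple[int, int]] = {}
    next_id = 0
    for f in np.unique(frames):
        idx = np.flatnonzero(frames == f)
        # candidate links: active tracks not yet past the gap limit
        cands = []
        for tid, (li, lf) in active.items():
            if f - lf - 1 > max_gap:
                continue
            d = np.hypot(xs[idx] - xs[li], ys[idx] - ys[li])
            for j, dist in zip(idx, d):
                if dist <= max_displacement:
                    cands.append((dist, tid, j))
        cands.sort(key=lambda c: c[0])
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        for dist, tid, j in cands:
            if tid in used_tracks or j in used_dets:
                continue
            assigned[j] = tid
            active[tid] = (j, f)
            used_tracks.add(tid)
            used_dets.add(j)
        for j in idx:
            if assigned[j] < 0:
                assigned[j] = next_id
                active[next_id] = (j, f)
                next_id += 1
        # retire tracks beyond gap reach
        active = {tid: (li, lf) for tid, (li, lf) in active.items()
                  if f - lf <= max_gap}

    tracks = []
    for tid in range(next_id):
        sel = np.flatnonzero(assigned == tid)
        amp = {"master": det["amplitude"].to_numpy(float)[sel]}
        sig = {}
        if "significant" in det.columns:
            sig["master"] = det["significant"].to_numpy(bool)[sel]
        for ch in extra_channels:
            amp[ch] = det[f"{ch}_amplitude"].to_numpy(float)[sel]
            scol = f"{ch}_significant"
            if scol in det.columns:
                sig[ch] = det[scol].to_numpy(bool)[sel]
        tracks.append(Track(tid, frames[sel], xs[sel], ys[sel], amp, sig,
                            frame_interval))
    return tracks


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Long-format track table (track_id, frame, channel, amplitude, significant)."""
    rows = []
    for t in tracks:
        for ch, trace in t.amplitude.items():
            sig = t.significant.get(ch)
            for i, f in enumerate(t.frames):
                rows.append({
                    "track_id": t.track_id, "frame": int(f), "channel": ch,
                    "amplitude": float(trace[i]),
                    "significant": bool(sig[i]) if sig is not None else True,
                })
    return pd.DataFrame(rows, columns=["track_id", "frame", "channel",
                                       "amplitude", "significant"])


# ---------------------------------------------------------------------------
# classification


def classify(tracks: list[Track], n_frames: int, intensity_threshold: float,
             min_frames: int = 4) -> list[Track]:
    """Assign each track exactly one category in place (and return them).

    persistent: spans the entire acquisition, regardless of amplitude;
    bona_fide: at least ``min_frames`` long and maximum master amplitude at
    or above the threshold; transient: everything else.
    """
    if intensity_threshold <= 0:
        raise ValueError("intensity_threshold must be positive")
    for t in tracks:
        if t.first == 0 and t.last == n_frames - 1:
            t.category = "persistent"
        elif len(t) >= min_frames and t.amplitude["master"].max() >= intensity_threshold:
            t.category = "bona_fide"
        else:
            t.category = "transient"
    return tracks


def slave_significance_from_traces(slave_amplitudes, noise_sd: float,
                                   alpha: float = 0.05) -> np.ndarray:
    """Per-frame slave significance when the noise SD is known exactly.

    One-sided z-test of amplitude > 0 (as for pre-linked track tables whose
    additive noise level is part of the record); no selection-bias offset is
    needed because no candidate search happened.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    a = np.asarray(slave_amplitudes, float)
    if noise_sd == 0:
        return a > 0
    p = stats.norm.sf(a / noise_sd)
    return p < alpha


def slave_positivity(track: Track, min_significant_fraction: float = 0.3,
                     channel: str = "slave") -> bool:
    """A track is slave-positive if enough of its frames carry significant
    slave signal (default: at least 30%)."""
    if channel not in track.significant:
        raise ValueError(f"track {track.track_id} has no {channel!r} significance trace")
    frac = float(np.mean(track.significant[channel]))
    track.slave_positive = frac >= min_significant_fraction
    return track.slave_positive


# ---------------------------------------------------------------------------
# lifetime statistics


def lifetime_stats(tracks: list[Track], n_bins: int = 20) -> LifetimeStats:
    """Lifetime distribution of bona fide tracks and the p95 statistic.

    The p95 statistic is the mean lifetime of the tracks at or above the
    95th percentile of the lifetime distribution (the longest-lived 5%).
    """
    lifetimes = np.array([t.lifetime_s for t in tracks
                          if t.category == "bona_fide"])
    if lifetimes.size < 20:
        raise ValueError("need >= 20 bona fide tracks for lifetime statistics")
    p95 = float(np.percentile(lifetimes, 95))
    top = lifetimes[lifetimes >= p95]
    counts, edges = np.histogram(lifetimes, bins=n_bins)
    return LifetimeStats(lifetimes, float(lifetimes.mean()), p95,
                         float(top.mean()), edges, counts)


def persistent_density(tracks: list[Track], cell_area_um2: float) -> float:
    """Persistent structures per square micron."""
    if cell_area_um2 <= 0:
        raise ValueError("cell area must be positive")
    n = sum(1 for t in tracks if t.category == "persistent")
    return n / cell_area_um2


# ---------------------------------------------------------------------------
# cohorts


def cohort_traces(tracks: list[Track], cohort_bounds: list[tuple[float, float]],
                  n_points: int = 50,
                  channels: tuple[str, ...] = ("master",)) -> list[CohortSummary]:
    """Average per-channel traces within lifetime cohorts.

    Bounds must be non-overlapping and increasing; a track falls in cohort
    (lo, hi] by its lifetime in seconds.  Each trace is linearly resampled
    onto a common normalized time axis of ``n_points`` samples; mean and
    standard error are pointwise.  A single-track cohort has SE = 0 by
    convention; an empty cohort yields an empty summary.
    """
    for (a, b), (c, d) in zip(cohort_bounds, cohort_bounds[1:]):
        if b > c or a >= b or c >= d:
            raise ValueError("cohort bounds must be non-overlapping, increasing")
    axis = np.linspace(0.0, 1.0, n_points)
    out = []
    for lo, hi in cohort_bounds:
        members = [t for t in tracks if lo < t.lifetime_s <= hi]
        if not members:
            out.append(CohortSummary((lo, hi), 0, axis, {}, {}))
            continue
        mean, se = {}, {}
        for ch in channels:
            resampled = np.stack([
                np.interp(axis, np.linspace(0, 1, len(t)), t.amplitude[ch])
                for t in members if ch in t.amplitude
            ])
            mean[ch] = resampled.mean(axis=0)
            if resampled.shape[0] > 1:
                se[ch] = resampled.std(axis=0, ddof=1) / math.sqrt(resampled.shape[0])
            else:
                se[ch] = np.zeros(n_points)
        out.append(CohortSummary((lo, hi), len(members), axis, mean, se))
    return out


# ---------------------------------------------------------------------------
# recruitment timing


def _subsample_argmax(y: np.ndarray) -> tuple[float, float]:
    """Continuous argmax of a sampled trace via cubic interpolation around
    the discrete argmax.  Returns (index, value)."""
    i = int(np.argmax(y))
    if len(y) < 4:
        return float(i), float(y[i])
    spline = CubicSpline(np.arange(len(y)), y)
    lo, hi = max(i - 1, 0), min(i + 1, len(y) - 1)
    fine = np.arange(lo, hi + 1e-9, 1e-3)
    vals = spline(fine)
    j = int(np.argmax(vals))
    return float(fine[j]), float(vals[j])


def _smooth(trace: np.ndarray, kernel_sd: float) -> np.ndarray:
    return gaussian_filter1d(np.asarray(trace, float), kernel_sd, mode="nearest")


def _reliability(smoothed: np.ndarray, raw: np.ndarray) -> bool:
    # peak must rise above a noise floor estimated from first differences
    d = np.diff(raw)
    noise = 1.4826 * np.median(np.abs(d - np.median(d))) / math.sqrt(2)
    return (smoothed.max() - np.median(smoothed)) >= 3.0 * noise


def max_intensity_time(trace, frame_interval: float,
                       kernel_sd: float = 1.2) -> PeakEstimate:
    """Sub-sample time of maximum intensity.

    The trace is smoothed with a Gaussian kernel (SD in samples, default
    1.2) and the maximum localized with sub-sample precision by cubic
    interpolation.  A flat trace returns its earliest maximum with the
    degeneracy flag set; a peak that does not clear a noise-derived floor is
    flagged unreliable.
    """
    trace = np.asarray(trace, float)
    if len(trace) < 5:
        raise ValueError("trace too short (need >= 5 samples)")
    if np.ptp(trace) == 0:
        return PeakEstimate(0.0, float(trace[0]), degenerate=True, reliable=False)
    sm = _smooth(trace, kernel_sd)
    idx, val = _subsample_argmax(sm)
    return PeakEstimate(idx * frame_interval, val,
                        reliable=_reliability(sm, trace))


def max_rate_time(trace, frame_interval: float,
                  kernel_sd: float = 1.2) -> PeakEstimate:
    """Sub-sample time of the maximum recruitment rate.

    The rate is the central difference of the Gaussian-smoothed trace; its
    maximum is localized as in :func:`max_intensity_time`.
    """
    trace = np.asarray(trace, float)
    if len(trace) < 5:
        raise ValueError("trace too short (need >= 5 samples)")
    if np.ptp(trace) == 0:
        return PeakEstimate(0.0, 0.0, degenerate=True, reliable=False)
    sm = _smooth(trace, kernel_sd)
    rate = np.empty(len(sm) - 2)
    rate[:] = (sm[2:] - sm[:-2]) / (2.0 * frame_interval)
    idx, val = _subsample_argmax(rate)
    # rate[i] sits at sample i+1 of the original trace
    return PeakEstimate((idx + 1.0) * frame_interval, val,
                        reliable=_reliability(sm, trace))
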