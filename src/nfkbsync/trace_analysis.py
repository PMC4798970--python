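"""Oscillation statistics for single-cell NCI time series.

The quantification pipeline mirrors how the live-imaging traces are
analysed: peaks are min–max–min triplets of local extrema, a peak's
height θ is measured from the higher of its two flanking minima, and
only peaks with θ above a noise threshold (default 0.15) that span more
than three consecutive samples count as significant.  Significant peaks
anchor an oscillation phase (2π at maxima, π at the minima between
them), and the phase lag Δφ = 2π·ΔT/T_f between each forcing cycle and
the closest significant peak feeds an entropy-based synchrony intensity

    η = 1 − S/S_max,   S = −Σ_k p_k log p_k  over 8 phase bins,

which is 0 for a flat Δφ distribution (asynchronous cohort) and 1 for a
delta-like one (perfect locking).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import ForcingSignal

__all__ = [
    "TraceSet", "Peak", "PeakList", "PhaseSeries", "SynchronyResult",
    "detect_peaks", "assign_phase", "experimental_periods",
    "peak_heights_per_cycle", "phase_difference", "synchrony_intensity",
    "synchrony_per_cycle", "analyze_cohort",
]

DEFAULT_THRESHOLD = 0.15
DEFAULT_MIN_TRACK_MIN = 7.0 * 60.0
N_PHASE_BINS = 8


@dataclass
class TraceSet:
    """Per-cell NCI series on a shared uniform sampling grid."""

    cells: dict[str, tuple[np.ndarray, np.ndarray]]
    sampling_interval: float = 6.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, (t, v) in self.cells.items():
            t = np.asarray(t, dtype=float)
            v = np.asarray(v, dtype=float)
            dt = np.diff(t)
            if len(t) and not np.allclose(dt, self.sampling_interval, rtol=0, atol=1e-6):
                raise ValueError(f"cell {cid}: sampling not uniform at {self.sampling_interval} min")
            if np.any(v < 0):
                raise ValueError(f"cell {cid}: negative NCI values")
            self.cells[cid] = (t, v)

    def __len__(self) -> int:
        return len(self.cells)

    def to_frame(self) -> pd.DataFrame:
        frames = [pd.DataFrame({"cell_id": cid, "time_min": t, "nci": v})
                  for cid, (t, v) in self.cells.items()]
        return pd.concat(frames, ignore_index=True)

    @staticmethod
    def from_frame(df: pd.DataFrame, sampling_interval: float | None = None,
                   metadata: dict | None = None) -> "TraceSet":
        cells = {}
        for cid, sub in df.groupby("cell_id", sort=False):
            sub = sub.sort_values("time_min")
            cells[str(cid)] = (sub["time_min"].to_numpy(float), sub["nci"].to_numpy(float))
        if sampling_interval is None:
            any_t = next(iter(cells.values()))[0]
            sampling_interval = float(np.median(np.diff(any_t))) if len(any_t) > 1 else 6.0
        return TraceSet(cells, sampling_interval, metadata or {})


@dataclass(frozen=True)
class Peak:
    time: float           # min, location of the maximum
    value: float
    left_min_time: float
    left_min_value: float
    right_min_time: float
    right_min_value: float
    height: float         # value − max(flanking minima)
    n_samples: int        # samples from left min to right min inclusive
    significant: bool
    noise: bool           # min-max-min made of only 3 consecutive samples


@dataclass
class PeakList:
    times: np.ndarray
    values: np.ndarray
    peaks: list[Peak]
    threshold: float
    long_enough: bool     # track meets the minimum-length requirement

    def significant_times(self) -> np.ndarray:
        return np.array([p.time for p in self.peaks if p.significant])

    def significant_heights(self) -> np.ndarray:
        return np.array([p.height for p in self.peaks if p.significant])


def _local_extrema(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima; plateaus collapse to
    their midpoint sample, series endpoints are never extrema."""
    n = len(v)
    maxima, minima = [], []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and v[j + 1] == v[j]:
            j += 1
        if j == n - 1:
            break
        left, right = v[i - 1], v[j + 1]
        mid = (i + j) // 2
        if v[i] > left and v[i] > right:
            maxima.append(mid)
        elif v[i] < left and v[i] < right:
            minima.append(mid)
        i = j + 1
    return np.array(maxima, dtype=int), np.array(minima, dtype=int)


def detect_peaks(times: np.ndarray, values: np.ndarray,
                 threshold: float = DEFAULT_THRESHOLD,
                 min_track_min: float = DEFAULT_MIN_TRACK_MIN) -> PeakList:
    """Find min–max–min peaks and mark the significant ones.

    Peak height is measured from the higher ("highest minimum") of the
    two flanking minima; a peak is significant when its height exceeds
    ``threshold`` and the min-max-min triplet spans more than three
    consecutive samples (a three-sample bump is a noise peak).  Missing
    flanking minima at the track edges are substituted by the edge
    sample value.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 3:
        raise ValueError("need at least 3 samples to detect peaks")
    maxima, minima = _local_extrema(values)
    peaks: list[Peak] = []
    for m in maxima:
        left_candidates = minima[minima < m]
        right_candidates = minima[minima > m]
        li = int(left_candidates[-1]) if len(left_candidates) else 0
        ri = int(right_candidates[0]) if len(right_candidates) else len(values) - 1
        height = values[m] - max(values[li], values[ri])
        n_samples = ri - li + 1
        noise = n_samples <= 3
        peaks.append(Peak(
            time=float(times[m]), value=float(values[m]),
            left_min_time=float(times[li]), left_min_value=float(values[li]),
            right_min_time=float(times[ri]), right_min_value=float(values[ri]),
            height=float(height), n_samples=n_samples,
            significant=bool(height > threshold and not noise),
            noise=noise,
        ))
    span = times[-1] - times[0]
    return PeakList(times=times, values=values, peaks=peaks,
                    threshold=threshold, long_enough=bool(span >= min_track_min))


@dataclass
class PhaseSeries:
    """φ(t) anchored at 2π on significant maxima and π on intervening minima.

    Values are NaN before the first and after the last anchor.  Between
    anchors the phase interpolates linearly in time, so it rises 0→π
    from a maximum to the next minimum and π→2π on to the next maximum.
    """

    times: np.ndarray
    phase: np.ndarray    # NaN where undefined

    def defined(self) -> np.ndarray:
        return ~np.isnan(self.phase)


def assign_phase(peaklist: PeakList) -> PhaseSeries:
    times = peaklist.times
    sig = [p for p in peaklist.peaks if p.significant]
    phase = np.full(len(times), np.nan)
    if not sig:
        return PhaseSeries(times, phase)
    # anchor sequence: max, (min between consecutive maxima, max)*
    anchors_t = [sig[0].time]
    anchors_v = [2.0 * np.pi]
    for prev, nxt in zip(sig[:-1], sig[1:]):
        # the minimum between the two maxima: prev.right flank
        anchors_t.append(prev.right_min_time)
        anchors_v.append(np.pi)
        anchors_t.append(nxt.time)
        anchors_v.append(2.0 * np.pi)
    if len(sig) == 1:
        idx = np.argmin(np.abs(times - sig[0].time))
        phase[idx] = 2.0 * np.pi
        return PhaseSeries(times, phase)
    # piecewise-linear φ: 2π≡0 at a maximum rising to π at the minimum,
    # then π to 2π on the way to the next maximum
    for k in range(len(anchors_t) - 1):
        t0, t1 = anchors_t[k], anchors_t[k + 1]
        v0, v1 = anchors_v[k], anchors_v[k + 1]
        if v0 == 2.0 * np.pi and v1 == np.pi:
            v0 = 0.0
        mask = (times >= t0) & (times <= t1)
        if t1 > t0:
            phase[mask] = v0 + (v1 - v0) * (times[mask] - t0) / (t1 - t0)
    # exact anchors
    for t_a, v_a in zip(anchors_t, anchors_v):
        idx = np.argmin(np.abs(times - t_a))
        phase[idx] = v_a
    return PhaseSeries(times, phase)


def experimental_periods(peaklists: PeakList | list[PeakList]) -> np.ndarray:
    """Pooled inter-peak intervals T_exp (min) over all cells.

    Each cell contributes the successive differences of its significant
    maxima times; cells with fewer than two significant peaks contribute
    nothing.
    """
    if isinstance(peaklists, PeakList):
        peaklists = [peaklists]
    out = []
    for pl in peaklists:
        t = pl.significant_times()
        if len(t) >= 2:
            out.extend(np.diff(t))
    return np.array(out)


def period_histogram(periods: np.ndarray, bin_width: float = 30.0,
                     t_max: float = 360.0) -> tuple[np.ndarray, np.ndarray]:
    """Histogram helper for T_exp distributions (counts, bin edges)."""
    edges = np.arange(0.0, t_max + bin_width, bin_width)
    counts, _ = np.histogram(periods, bins=edges)
    return counts, edges


def peak_heights_per_cycle(peaklists: PeakList | list[PeakList],
                           T_ref: float) -> pd.DataFrame:
    """Mean ± sd of significant-peak heights per reference interval.

    Peaks are bucketed by n = floor(t_peak/T_ref) + 1, i.e. interval
    [(n−1)·T_ref, n·T_ref).  Under slow forcing (T_f = 2·T_ref) even n
    collects the post-stimulation peaks and odd n the small inter-pulse
    ones.
    """
    if T_ref <= 0:
        raise ValueError("T_ref must be positive")
    if isinstance(peaklists, PeakList):
        peaklists = [peaklists]
    buckets: dict[int, list[float]] = {}
    for pl in peaklists:
        for p in pl.peaks:
            if p.significant:
                n = int(np.floor(p.time / T_ref)) + 1
                buckets.setdefault(n, []).append(p.height)
    rows = [{"interval": n, "mean_height": float(np.mean(h)),
             "sd_height": float(np.std(h)), "n_peaks": len(h)}
            for n, h in sorted(buckets.items())]
    return pd.DataFrame(rows, columns=["interval", "mean_height", "sd_height", "n_peaks"])


def phase_difference(peaklist: PeakList, forcing: ForcingSignal,
                     forward_only: bool = False) -> np.ndarray:
    """Δφ = 2π·ΔT/T_f between each forcing-cycle start and the closest
    significant peak, reduced to [0, 2π).

    The closest peak is searched in both time directions by default
    (ties broken toward the earlier peak); ``forward_only`` restricts
    the search to peaks at or after the cycle start.
    """
    if forcing.kind == "constant":
        raise ValueError("phase difference needs a periodic forcing")
    peaks = peaklist.significant_times()
    if len(peaks) == 0:
        return np.array([])
    t_last = peaklist.times[-1]
    starts = forcing.cycle_starts(t_last)
    T_f = forcing.period
    out = []
    for s in starts:
        cand = peaks[peaks >= s] if forward_only else peaks
        if len(cand) == 0:
            continue
        dt = cand - s
        order = np.lexsort((cand, np.abs(dt)))  # distance, then earlier peak
        delta_t = dt[order[0]]
        out.append(np.mod(2.0 * np.pi * delta_t / T_f, 2.0 * np.pi))
    return np.array(out)


@dataclass
class SynchronyResult:
    delta_phi: np.ndarray
    probabilities: np.ndarray   # 8-bin histogram, sums to 1
    entropy: float
    eta: float
    n_bins: int


def synchrony_intensity(delta_phi: np.ndarray,
                        n_bins: int = N_PHASE_BINS) -> SynchronyResult:
    """Entropy-based synchrony η of a phase-difference sample.

    Δφ values are binned uniformly on [0, 2π); S = −Σ p_k log p_k with
    0·log 0 := 0 and S_max = log(n_bins), so η = 1 − S/S_max lies in
    [0, 1] regardless of the logarithm base.
    """
    delta_phi = np.asarray(delta_phi, dtype=float)
    if delta_phi.size == 0:
        raise ValueError("synchrony undefined for an empty phase-difference sample")
    wrapped = np.mod(delta_phi, 2.0 * np.pi)
    counts, _ = np.histogram(wrapped, bins=n_bins, range=(0.0, 2.0 * np.pi))
    p = counts / counts.sum()
    nz = p[p > 0]
    S = float(-np.sum(nz * np.log(nz)))
    eta = 1.0 - S / np.log(n_bins)
    return SynchronyResult(delta_phi=wrapped, probabilities=p, entropy=S,
                           eta=float(eta), n_bins=n_bins)


def synchrony_per_cycle(peaklists: PeakList | list[PeakList],
                        forcing: ForcingSignal, n_cycles: int,
                        n_bins: int = N_PHASE_BINS) -> list[float | None]:
    """η_n computed from peaks falling in each cycle window.

    For cycle n ≥ 1 the window is [(n−1)·T_f, n·T_f); each significant
    peak in the window contributes Δφ relative to its own cycle start.
    Cycles with no peaks anywhere in the cohort give None.
    """
    if isinstance(peaklists, PeakList):
        peaklists = [peaklists]
    T_f = forcing.period
    per_cycle: dict[int, list[float]] = {n: [] for n in range(1, n_cycles + 1)}
    for pl in peaklists:
        for t_pk in pl.significant_times():
            n = int(np.floor((t_pk - forcing.t_start) / T_f)) + 1
            if 1 <= n <= n_cycles:
                start = forcing.t_start + (n - 1) * T_f
                dphi = np.mod(2.0 * np.pi * (t_pk - start) / T_f, 2.0 * np.pi)
                per_cycle[n].append(dphi)
    out: list[float | None] = []
    for n in range(1, n_cycles + 1):
        vals = per_cycle[n]
        out.append(synchrony_intensity(np.array(vals), n_bins).eta if vals else None)
    return out


def analyze_cohort(traces: TraceSet, forcing: ForcingSignal | None = None,
                   threshold: float = DEFAULT_THRESHOLD,
                   min_track_min: float = DEFAULT_MIN_TRACK_MIN,
                   n_bins: int = N_PHASE_BINS) -> dict:
    """Full per-cohort quantification: peaks, periods, synchrony.

    Cells shorter than the minimum track length are excluded from
    cohort statistics.  Returns a dict with per-cell peak lists, pooled
    T_exp, and (for periodic forcing) Δφ pooled over cells with η.
    """
    peaklists = {}
    for cid, (t, v) in traces.cells.items():
        peaklists[cid] = detect_peaks(t, v, threshold, min_track_min)
    included = {cid: pl for cid, pl in peaklists.items() if pl.long_enough}
    periods = experimental_periods(list(included.values()))
    result: dict = {
        "peaklists": peaklists,
        "n_cells": len(traces),
        "n_included": len(included),
        "periods": periods,
    }
    if forcing is not None and forcing.kind != "constant":
        dphi = np.concatenate([phase_difference(pl, forcing)
                               for pl in included.values()]) if included else np.array([])
        if dphi.size:
            sync = synchrony_intensity(dphi, n_bins)
            result["delta_phi"] = dphi
            result["synchrony"] = sync
            result["eta"] = sync.eta
    return result
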