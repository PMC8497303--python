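"""Spontaneous network-activity analysis.

Per-electrode event-rate maps over the 1 s trace structure, low/high slice
classification (mean rate under/over 1 event/s), polarity-resolved frequency
and amplitude statistics, pooled interspike-interval (ISI) histograms in
coarse (5 ms) and fine (1 ms) bins, frequency-band occupancy defined on
instantaneous rate 1/ISI, and a diagnostic population-synchrony index.

ISIs are always computed between consecutive events on the same electrode
and then pooled across the electrodes in scope; intervals between events on
different electrodes are never formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SpikeTrainSet

DELTA_BAND_HZ = (0.6, 4.0)


@dataclass
class ActivityMap:
    """Event counts per electrode per recorded segment."""

    counts: np.ndarray  # (n_electrodes, n_segments)
    segment_duration_s: float
    per_electrode_rate_hz: np.ndarray
    slice_mean_rate_hz: float


@dataclass
class ISIHistogram:
    bin_width_s: float
    max_isi_s: float
    counts: np.ndarray
    n_isis: int
    scope: str = "slice-pooled"

    @property
    def bin_left_edges_s(self) -> np.ndarray:
        return np.arange(self.counts.size) * self.bin_width_s


@dataclass
class PolarityStats:
    overall_rate_hz: float
    pos_rate_hz: float
    neg_rate_hz: float
    pos_amp_mean_mv: float
    pos_amp_sem_mv: float
    pos_amp_median_mv: float
    neg_amp_mean_mv: float
    neg_amp_sem_mv: float
    neg_amp_median_mv: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class SynchronyResult:
    index: float
    n_events: int
    k: int
    window_ms: float
    defined: bool


def build_activity_map(trains: SpikeTrainSet) -> ActivityMap:
    """Count events per electrode per segment; rates in events/s."""
    if trains.total_duration_s <= 0:
        raise ValueError("zero-duration recording")
    if trains.segments:
        edges = [trains.segments[0][0]]
        for s, d in trains.segments:
            edges.append(s + d)
        edges = np.asarray(edges)
        seg_dur = trains.segments[0][1]
    else:
        edges = np.array([0.0, trains.total_duration_s])
        seg_dur = trains.total_duration_s
    m = trains.n_electrodes
    counts = np.zeros((m, edges.size - 1), dtype=int)
    for e, times in trains.times_by_electrode().items():
        if times.size:
            counts[e], _ = np.histogram(times, bins=edges)
    rates = counts.sum(axis=1) / trains.total_duration_s
    return ActivityMap(
        counts=counts,
        segment_duration_s=float(seg_dur),
        per_electrode_rate_hz=rates,
        slice_mean_rate_hz=float(rates.mean()),
    )


def classify_activity(amap: ActivityMap, cutoff_hz: float = 1.0) -> str:
    """"low" iff the slice mean rate is strictly below the cutoff, else "high"."""
    return "low" if amap.slice_mean_rate_hz < cutoff_hz else "high"


def polarity_stats(trains: SpikeTrainSet) -> PolarityStats:
    """Event rates and |amplitude| statistics split by spike polarity.

    Empty polarity classes are flagged with NaN amplitude statistics.
    """
    dur = trains.total_duration_s
    pos = np.array([abs(e.amplitude_mv) for e in trains.events if e.polarity > 0])
    neg = np.array([abs(e.amplitude_mv) for e in trains.events if e.polarity < 0])

    def stats(a: np.ndarray) -> tuple[float, float, float]:
        if a.size == 0:
            return (float("nan"),) * 3
        sem = float(a.std(ddof=1) / np.sqrt(a.size)) if a.size > 1 else float("nan")
        return float(a.mean()), sem, float(np.median(a))

    pm, ps, pmed = stats(pos)
    nm, ns, nmed = stats(neg)
    return PolarityStats(
        overall_rate_hz=len(trains.events) / dur,
        pos_rate_hz=pos.size / dur,
        neg_rate_hz=neg.size / dur,
        pos_amp_mean_mv=pm,
        pos_amp_sem_mv=ps,
        pos_amp_median_mv=pmed,
        neg_amp_mean_mv=nm,
        neg_amp_sem_mv=ns,
        neg_amp_median_mv=nmed,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )


def pooled_isis(trains: SpikeTrainSet, max_isi_s: float | None = None) -> np.ndarray:
    """Consecutive-event ISIs per electrode, pooled; > max excluded if given."""
    isis = []
    for times in trains.times_by_electrode().values():
        if times.size >= 2:
            isis.append(np.diff(np.sort(times)))
    if not isis:
        return np.empty(0)
    out = np.concatenate(isis)
    if max_isi_s is not None:
        out = out[out <= max_isi_s]
    return out


def isi_histogram(
    trains: SpikeTrainSet,
    bin_width_s: float,
    max_isi_s: float,
    scope: str = "slice-pooled",
) -> ISIHistogram:
    """Histogram of pooled per-electrode ISIs in half-open bins [kw, (k+1)w)."""
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be positive")
    isis = pooled_isis(trains, max_isi_s=max_isi_s)
    n_bins = int(np.floor(max_isi_s / bin_width_s)) + 1
    counts = np.zeros(n_bins, dtype=int)
    if isis.size:
        # 1e-12 s slack keeps ISIs that are exact bin multiples up to float
        # representation (e.g. 0.3 - 0.1) in their nominal half-open bin
        idx = np.floor((isis + 1e-12) / bin_width_s).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)  # isi == max lands in the last bin
        np.add.at(counts, idx, 1)
    return ISIHistogram(
        bin_width_s=bin_width_s,
        max_isi_s=max_isi_s,
        counts=counts,
        n_isis=int(isis.size),
        scope=scope,
    )


def cumulative_isi(h: ISIHistogram) -> np.ndarray:
    """Cumulative fraction per bin; nondecreasing, ends at 1.0."""
    if h.n_isis == 0:
        raise ValueError("cumulative distribution undefined for an empty histogram")
    return np.cumsum(h.counts) / h.n_isis


def high_freq_fraction(isis: np.ndarray, cut_hz: float = 20.0) -> float:
    """Fraction of ISIs with instantaneous rate above the cut (ISI < 1/cut)."""
    isis = np.asarray(isis, dtype=float)
    if isis.size == 0:
        raise ValueError("no ISIs in scope")
    return float(np.mean(isis < 1.0 / cut_hz))


def band_fraction(isis: np.ndarray, band_hz: tuple[float, float] = DELTA_BAND_HZ) -> float:
    """Fraction of ISIs whose rate 1/ISI lies in (lo, hi] -> ISI in [1/hi, 1/lo).

    The default delta band 0.6-4 Hz maps to ISIs in (0.25 s, 1/0.6 s].
    """
    isis = np.asarray(isis, dtype=float)
    if isis.size == 0:
        raise ValueError("no ISIs in scope")
    lo_hz, hi_hz = band_hz
    return float(np.mean((isis > 1.0 / hi_hz) & (isis <= 1.0 / lo_hz)))


def band_occupancy(
    trains: SpikeTrainSet,
    max_isi_s: float = 2.0,
    high_cut_hz: float = 20.0,
    delta_band_hz: tuple[float, float] = DELTA_BAND_HZ,
) -> dict:
    """High-frequency and delta-band ISI occupancy over the pooled scope.

    The three reported fractions (high, delta, other) partition the ISIs at
    or below ``max_isi_s`` and sum to 1 (the high band ISI < 1/high_cut never
    overlaps the delta mapping because 1/high_cut < 1/delta_hi).
    """
    isis = pooled_isis(trains, max_isi_s=max_isi_s)
    if isis.size == 0:
        return {"n_isis": 0, "high_fraction": None, "delta_fraction": None, "other_fraction": None}
    hi = high_freq_fraction(isis, high_cut_hz)
    delta = band_fraction(isis, delta_band_hz)
    return {
        "n_isis": int(isis.size),
        "high_fraction": hi,
        "delta_fraction": delta,
        "other_fraction": 1.0 - hi - delta,
    }


def synchrony_index(
    trains: SpikeTrainSet,
    window_ms: float = 5.0,
    k: int | None = None,
) -> SynchronyResult:
    """Fraction of events participating in >= k-electrode coincidences.

    An event participates if, inside a centred window of total width
    ``window_ms``, events from at least ``k`` distinct electrodes (its own
    included) occur.  Default k is a strict majority of electrodes.  This is
    a diagnostic index of population synchrony, monotone in the simulator's
    ``sync_fraction``; it is not a quantity the source experiments report.
    """
    m = trains.n_electrodes
    if m < 2:
        raise ValueError("synchrony requires >= 2 electrodes")
    if k is None:
        k = m // 2 + 1
    evs = sorted((e.time_s, e.electrode) for e in trains.events)
    n = len(evs)
    if n == 0:
        return SynchronyResult(0.0, 0, k, window_ms, defined=False)
    half = window_ms * 1e-3 / 2.0
    times = np.array([t for t, _ in evs])
    elecs = np.array([e for _, e in evs])
    count = np.zeros(m, dtype=int)
    distinct = 0
    lo = hi = 0
    participating = 0
    for i in range(n):
        t = times[i]
        while hi < n and times[hi] <= t + half:
            if count[elecs[hi]] == 0:
                distinct += 1
            count[elecs[hi]] += 1
            hi += 1
        while times[lo] < t - half:
            count[elecs[lo]] -= 1
            if count[elecs[lo]] == 0:
                distinct -= 1
            lo += 1
        if distinct >= k:
            participating += 1
    return SynchronyResult(participating / n, n, k, window_ms, defined=True)


def electrode_subset_analysis(
    trains: SpikeTrainSet,
    electrodes,
    isi_bin_s: float = 0.001,
    max_isi_s: float = 2.0,
) -> dict:
    """Full spontaneous analysis restricted to an electrode subset.

    Used to analyse activity on the electrodes later used for evoked
    recordings.  Semantics are identical to the slice-level analysis on the
    restriction; empty results are flagged with n_isis = 0 / NaN statistics.
    """
    sub = trains.subset(electrodes)
    amap = build_activity_map(sub)
    hist = isi_histogram(sub, isi_bin_s, max_isi_s, scope="electrode-subset")
    return {
        "electrodes": sorted(set(int(e) for e in electrodes)),
        "activity_map": amap,
        "classification": classify_activity(amap),
        "polarity": polarity_stats(sub),
        "isi_histogram": hist,
        "bands": band_occupancy(sub, max_isi_s=max_isi_s),
    }
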