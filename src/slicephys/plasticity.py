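"""Evoked fEPSP analysis: slope measurement, LTP/LTD time courses,
input-output curves and 1 Hz induction-train statistics.

The central measure is the descending slope of the (by default
negative-going) field potential over the 10-90% section of the phase running
from deflection onset to peak, reported as a magnitude in mV/ms.  Plasticity
magnitude is the mean of per-sweep slopes normalized to the mean slope over
the 3 min of baseline immediately before induction, expressed in percent:
100% means no change, ~145% a typical parallel-fibre LTP, ~60% a typical
climbing-fibre LTD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import RunConfig, Sweep, SweepSet

log = logging.getLogger(__name__)

LTP_THRESHOLD_PCT = 110.0
LTD_THRESHOLD_PCT = 90.0


@dataclass
class FEPSPMeasure:
    peak_amplitude_mv: float  # signed extremum in the response window
    slope_10_90_mv_per_ms: float  # magnitude
    latency_to_peak_ms: float
    valid: bool


@dataclass
class PlasticityTimeCourse:
    measures: list[FEPSPMeasure]
    times_min: np.ndarray  # sweep times relative to induction end, minutes
    normalized_percent: np.ndarray  # per included sweep
    pair_times_min: np.ndarray
    pair_normalized_percent: np.ndarray
    baseline_mean_slope: float
    induction_interval_s: tuple[float, float]
    magnitude_percent: float
    direction: str  # "LTP" | "LTD" | "none"
    n_excluded: int = 0
    baseline_stable: bool | None = None


@dataclass
class IOCurve:
    stimulus_levels_ua: np.ndarray
    mean_amplitude_mv: np.ndarray  # |peak| magnitude per level
    n_per_level: np.ndarray
    threshold_stimulus_ua: float


@dataclass
class TrainAnalysis:
    first_amp_mv: float
    amplitudes_mv: np.ndarray
    normalized: np.ndarray
    last5_first5_ratio: float
    tail_mean_last_100: float


def measure_fepsp(sweep: Sweep, cfg: RunConfig) -> FEPSPMeasure:
    """Measure one sweep: signed peak, 10-90 descending slope, latency.

    The stimulus artifact window is blanked; the response window is the rest
    of the sweep.  The descending phase runs from deflection onset (last
    zero-crossing, or last sample within the noise floor of zero, before the
    peak) to the peak; the slope is the magnitude of a least-squares line
    over the samples whose |v| lies in [0.1, 0.9] x |peak| on that phase.
    """
    fs = sweep.sampling_rate_hz
    v = sweep.voltage_mv
    start = int(round(cfg.artifact_window_ms * 1e-3 * fs))
    if start >= v.size:
        raise ValueError("artifact window covers the whole sweep")
    resp = v[start:]
    # light boxcar smoothing suppresses the extreme-value bias a per-sample
    # extremum search would pick up from wide-band noise
    smooth_n = int(round(cfg.fepsp_smooth_ms * 1e-3 * fs))
    if smooth_n > 1:
        kernel = np.ones(smooth_n) / smooth_n
        resp = np.convolve(resp, kernel, mode="same")
    invalid = FEPSPMeasure(0.0, 0.0, float("nan"), valid=False)
    if resp.size < 3 or np.ptp(resp) == 0:
        return invalid
    if cfg.fepsp_polarity < 0:
        peak_rel = int(np.argmin(resp))
    else:
        peak_rel = int(np.argmax(resp))
    # amplitude from a short average around the extremum: the single
    # extremum sample carries an extreme-value noise bias that would not
    # cancel between baseline and post sweeps of different amplitude
    k = max(1, smooth_n // 2)
    peak = float(resp[max(0, peak_rel - k) : peak_rel + k + 1].mean())
    if cfg.fepsp_polarity * peak <= 0 or abs(peak) < cfg.fepsp_noise_floor_mv:
        return invalid

    # onset: walk back from the peak to the last sample near/through zero
    sgn = 1.0 if peak > 0 else -1.0
    onset = 0
    for i in range(peak_rel - 1, -1, -1):
        if sgn * resp[i] <= cfg.fepsp_noise_floor_mv:
            onset = i
            break
    phase = resp[onset : peak_rel + 1]
    lo, hi = 0.1 * abs(peak), 0.9 * abs(peak)
    # 10-90 section as a contiguous time window bounded by the first 10% and
    # first 90% crossings (fitting only samples whose value happens to fall
    # inside the band would truncate on the noisy ordinate and bias the
    # slope toward zero)
    above_lo = np.flatnonzero(sgn * phase >= lo)
    above_hi = np.flatnonzero(sgn * phase >= hi)
    if above_lo.size == 0 or above_hi.size == 0:
        return invalid
    i10, i90 = int(above_lo[0]), int(above_hi[0])
    if i90 - i10 < 1:
        return invalid
    sel = np.arange(i10, i90 + 1)
    t_ms = (onset + sel) / fs * 1e3
    coeffs = np.polyfit(t_ms, phase[sel], 1)
    return FEPSPMeasure(
        peak_amplitude_mv=peak,
        slope_10_90_mv_per_ms=float(abs(coeffs[0])),
        latency_to_peak_ms=(start + peak_rel) / fs * 1e3 - cfg.artifact_window_ms,
        valid=True,
    )


def pair_average(series: np.ndarray) -> tuple[np.ndarray, bool]:
    """Average non-overlapping consecutive pairs.

    Returns (paired values, odd_flag); an odd trailing element is kept as its
    own (flagged) point, mirroring plots where each point is the average of
    two successive test responses.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    n_pairs = series.size // 2
    paired = series[: 2 * n_pairs].reshape(n_pairs, 2).mean(axis=1)
    if series.size % 2:
        return np.append(paired, series[-1]), True
    return paired, False


def build_timecourse(sweeps: SweepSet, cfg: RunConfig) -> PlasticityTimeCourse:
    """Baseline-normalized slope time course and LTP/LTD summary magnitude.

    Baseline normalization uses the mean 10-90 slope over the
    ``cfg.baseline_norm_window_min`` minutes (default 3) immediately before
    induction.  The summary magnitude is the mean normalized slope over
    ``cfg.summary_window_min`` (default minutes 56-60) after induction ends,
    so "1 h after induction" is read as the last four minutes of a one-hour
    follow-up.  Direction calls LTP above 110%, LTD below 90%.
    """
    baseline = sweeps.block("baseline")
    post = sweeps.block("post")
    induction = sweeps.block("induction")
    if not baseline:
        raise ValueError("no baseline sweeps")
    if induction:
        t_ind = (induction[0].stimulus_time_s, induction[-1].stimulus_time_s)
    elif post:
        # no recorded train: anchor the induction interval midway between
        # the blocks so baseline times are strictly negative, post positive
        mid = 0.5 * (baseline[-1].stimulus_time_s + post[0].stimulus_time_s)
        t_ind = (mid, mid)
    else:
        raise ValueError("no induction or post sweeps to anchor the induction interval")

    bl_window_s = cfg.baseline_norm_window_min * 60.0
    bl_measures = []
    n_excluded = 0
    for sw in baseline:
        if sw.stimulus_time_s < t_ind[0] - bl_window_s:
            continue
        m = measure_fepsp(sw, cfg)
        if m.valid:
            bl_measures.append(m)
        else:
            n_excluded += 1
            log.warning("excluded invalid baseline sweep at t=%.1f s", sw.stimulus_time_s)
    if not bl_measures:
        raise ValueError("no valid baseline sweeps in the normalization window")
    baseline_mean = float(np.mean([m.slope_10_90_mv_per_ms for m in bl_measures]))
    if baseline_mean == 0:
        raise ValueError("baseline mean slope is zero")

    measures: list[FEPSPMeasure] = []
    times = []
    norm = []
    for sw in baseline + post:
        m = measure_fepsp(sw, cfg)
        if not m.valid:
            n_excluded += 1
            log.warning("excluded invalid sweep at t=%.1f s", sw.stimulus_time_s)
            continue
        measures.append(m)
        times.append((sw.stimulus_time_s - t_ind[1]) / 60.0)
        norm.append(100.0 * m.slope_10_90_mv_per_ms / baseline_mean)
    times = np.asarray(times)
    norm = np.asarray(norm)

    if cfg.pair_average and norm.size >= 2:
        pair_norm, _ = pair_average(norm)
        pair_t, _ = pair_average(times)
    else:
        pair_norm, pair_t = norm.copy(), times.copy()

    post_mask = times > 0
    w0, w1 = cfg.summary_window_min
    sel = post_mask & (times >= w0) & (times <= w1)
    if not np.any(sel):
        if not np.any(post_mask):
            raise ValueError("no post-induction sweeps")
        # fall back to the final window's worth of post sweeps
        n_tail = max(1, int(round((w1 - w0) * 60.0 / 30.0)))
        idx = np.flatnonzero(post_mask)[-n_tail:]
        sel = np.zeros_like(post_mask)
        sel[idx] = True
        log.warning("summary window empty; using the last %d post sweeps", idx.size)
    magnitude = float(norm[sel].mean())
    direction = (
        "LTP" if magnitude >= LTP_THRESHOLD_PCT else "LTD" if magnitude <= LTD_THRESHOLD_PCT else "none"
    )

    # advisory baseline-stability check: drift of the last 10 min of baseline
    stable: bool | None = None
    bl_mask = times <= 0
    bl_t = times[bl_mask]
    if bl_t.size >= 3 and (bl_t.max() - bl_t.min()) > 0:
        recent = bl_mask & (times >= times[bl_mask].max() - 10.0)
        if np.sum(recent) >= 3:
            drift = np.polyfit(times[recent], norm[recent], 1)[0] * 10.0  # % per 10 min
            stable = bool(abs(drift) <= 5.0)
            if not stable:
                log.warning("baseline drift %.1f%% per 10 min exceeds 5%%", drift)

    return PlasticityTimeCourse(
        measures=measures,
        times_min=times,
        normalized_percent=norm,
        pair_times_min=pair_t,
        pair_normalized_percent=pair_norm,
        baseline_mean_slope=baseline_mean,
        induction_interval_s=t_ind,
        magnitude_percent=magnitude,
        direction=direction,
        n_excluded=n_excluded,
        baseline_stable=stable,
    )


def build_io_curve(
    sweeps: SweepSet, cfg: RunConfig, blocks: tuple[str, ...] = ("io_pre",)
) -> IOCurve:
    """Mean |peak amplitude| per stimulus level, plus the threshold stimulus.

    The threshold (test) stimulus is ``cfg.threshold_stim_fraction`` (default
    0.35, the midpoint of the 30-40% rule) times the stimulus level at which
    the mean response amplitude is maximal; exact ties go to the largest
    level.
    """
    selected = [s for s in sweeps if s.block in blocks]
    levels = sorted({s.stimulus_current_ua for s in selected})
    if len(levels) < 2:
        raise ValueError("an I/O curve needs at least two distinct stimulus levels")
    means = []
    ns = []
    for lv in levels:
        amps = []
        for s in selected:
            if s.stimulus_current_ua == lv:
                m = measure_fepsp(s, cfg)
                if m.valid:
                    amps.append(abs(m.peak_amplitude_mv))
        if not amps:
            raise ValueError(f"no valid sweeps at stimulus {lv} uA")
        means.append(float(np.mean(amps)))
        ns.append(len(amps))
    means_arr = np.asarray(means)
    max_level = np.asarray(levels)[np.flatnonzero(means_arr == means_arr.max())[-1]]
    return IOCurve(
        stimulus_levels_ua=np.asarray(levels, dtype=float),
        mean_amplitude_mv=means_arr,
        n_per_level=np.asarray(ns),
        threshold_stimulus_ua=float(cfg.threshold_stim_fraction * max_level),
    )


def analyze_train(sweeps: SweepSet, cfg: RunConfig) -> TrainAnalysis:
    """Analyse the 1 Hz induction-train responses.

    Responses are numbered 1-based in stimulus order; the summary ratio is
    the mean amplitude of responses #596-600 (more generally, the last five)
    divided by the mean of responses #1-5, and the tail statistic is the mean
    first-response-normalized amplitude over the final 100 responses.
    """
    train = sweeps.block("induction")
    if len(train) < 10:
        raise ValueError("train analysis needs at least 10 responses")
    amps = []
    for s in train:
        m = measure_fepsp(s, cfg)
        amps.append(abs(m.peak_amplitude_mv) if m.valid else np.nan)
    amps = np.asarray(amps)
    if np.isnan(amps).any():
        log.warning("train contains %d invalid responses", int(np.isnan(amps).sum()))
    if not np.isfinite(amps[0]) or amps[0] == 0:
        raise ValueError("first train response has zero amplitude")
    normalized = amps / amps[0]
    first5 = np.nanmean(amps[:5])
    last5 = np.nanmean(amps[-5:])
    n_tail = min(100, amps.size)
    return TrainAnalysis(
        first_amp_mv=float(amps[0]),
        amplitudes_mv=amps,
        normalized=normalized,
        last5_first5_ratio=float(last5 / first5),
        tail_mean_last_100=float(np.nanmean(normalized[-n_tail:])),
    )
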