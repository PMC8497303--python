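"""Filtering and amplitude-threshold spike extraction.

The extraction rule is the classic acquisition-software one: a fixed pair of
voltage thresholds (default +0.021 / -0.021 mV) applied to each electrode
independently after a 2-pole Bessel high-pass (1 kHz) and a baseline ("DC")
filter parameterised by the typical spike length (1 ms).  Comparisons are
strict (a sample exactly at threshold does not trigger) and each accepted
event imposes a dead time of one spike length measured from its extremum
sample, so consecutive same-electrode events are never closer than the spike
length.  Segment boundaries (the 600 x 1 s structure of spontaneous
recordings) are never bridged: filtering, detection and dead time all restart
at each segment.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal

from .core import RawRecording, RunConfig, SpikeEvent, SpikeTrainSet


def bessel_highpass(
    trace: np.ndarray,
    sampling_rate_hz: float,
    cutoff_hz: float = 1000.0,
    order: int = 2,
) -> np.ndarray:
    """Zero-phase Bessel high-pass (forward-backward filtfilt).

    The filter is magnitude-normalised so the -3 dB point sits at
    ``cutoff_hz``; the two passes square the magnitude response, so a
    sinusoid at cutoff emerges at half amplitude.  Output length equals
    input length and event times are not lag-shifted.
    """
    trace = np.asarray(trace, dtype=np.float64)
    nyquist = sampling_rate_hz / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, {nyquist}) Hz")
    if order < 1:
        raise ValueError("order must be >= 1")
    b, a = signal.bessel(order, cutoff_hz, btype="highpass", fs=sampling_rate_hz, norm="mag")
    return signal.filtfilt(b, a, trace, axis=-1)


def bessel_response_magnitude(
    freq_hz: float, sampling_rate_hz: float, cutoff_hz: float = 1000.0, order: int = 2
) -> float:
    """|H(f)|^2 of the forward-backward high-pass (analytic design response)."""
    b, a = signal.bessel(order, cutoff_hz, btype="highpass", fs=sampling_rate_hz, norm="mag")
    _, h = signal.freqz(b, a, worN=[freq_hz], fs=sampling_rate_hz)
    return float(np.abs(h[0]) ** 2)


def remove_dc(
    trace: np.ndarray,
    spike_length_ms: float,
    sampling_rate_hz: float,
    window_spike_lengths: float = 10.0,
) -> np.ndarray:
    """Subtract a running baseline (sliding-window median).

    The window is ``window_spike_lengths`` x ``spike_length_ms`` wide
    (default 10 x 1 ms), long enough that transients no wider than one spike
    length leave the median — and hence their own amplitude — essentially
    untouched, while drifts slower than the window are removed.
    """
    trace = np.asarray(trace, dtype=np.float64)
    win = int(round(window_spike_lengths * spike_length_ms * 1e-3 * sampling_rate_hz))
    win = max(3, win | 1)  # odd, >= 3 samples
    if win > trace.shape[-1]:
        raise ValueError(
            f"baseline window ({win} samples) longer than trace ({trace.shape[-1]})"
        )
    size = (1,) * (trace.ndim - 1) + (win,)
    baseline = ndimage.median_filter(trace, size=size, mode="nearest")
    return trace - baseline


def _prefilter(block: np.ndarray, cfg: RunConfig, fs: float) -> np.ndarray:
    """Apply the configured conditioning to an electrode x sample block."""
    out = block
    if cfg.apply_highpass:
        out = bessel_highpass(out, fs, cfg.highpass_cutoff_hz, cfg.highpass_order)
    if cfg.dc_filter_mode == "median_baseline":
        out = remove_dc(out, cfg.spike_length_ms, fs, cfg.dc_window_spike_lengths)
    elif cfg.dc_filter_mode == "highpass":
        # alternative reading of the acquisition "DC filter": a gentle
        # high-pass whose corner is set by the typical spike length
        corner = 1.0 / (cfg.dc_window_spike_lengths * cfg.spike_length_ms * 1e-3)
        out = bessel_highpass(out, fs, corner, 1)
    return out


def _scan_trace(
    x: np.ndarray, pos_thr: float, neg_thr: float, dead_samples: int
) -> list[tuple[int, int, float]]:
    """Threshold scan of one segment trace -> (extremum_idx, polarity, amp).

    A crossing is a sample strictly above pos_thr or strictly below neg_thr.
    The event extremum is the largest-|v| sample within one dead time of the
    crossing (ties -> earliest sample); further crossings within one dead
    time after the extremum are suppressed.
    """
    n = x.shape[0]
    crossings = np.flatnonzero((x > pos_thr) | (x < neg_thr))
    events: list[tuple[int, int, float]] = []
    next_allowed = 0
    for idx in crossings:
        if idx < next_allowed:
            continue
        window = x[idx : min(idx + dead_samples, n)]
        ext_rel = int(np.argmax(np.abs(window)))
        ext = idx + ext_rel
        amp = float(x[ext])
        polarity = 1 if amp > 0 else -1
        events.append((ext, polarity, amp))
        next_allowed = ext + dead_samples
    return events


def detect_spikes(
    rec: RawRecording, cfg: RunConfig, apply_filters: bool | None = None
) -> SpikeTrainSet:
    """Extract threshold-crossing events from every electrode.

    Parameters
    ----------
    rec
        The recording; its own sampling rate is used (cfg.sampling_rate_hz is
        a simulation/analysis default, not an override).
    cfg
        Thresholds, spike length (dead time and snippet width) and filter
        settings.
    apply_filters
        Force conditioning on/off; default follows ``cfg.apply_highpass`` /
        ``cfg.dc_filter_mode`` (pass False for traces already conditioned).
    """
    if not (cfg.pos_threshold_mv > 0 > cfg.neg_threshold_mv):
        raise ValueError("thresholds must satisfy pos > 0 > neg")
    fs = rec.sampling_rate_hz
    dead = max(1, int(round(cfg.spike_length_ms * 1e-3 * fs)))
    margin = int(round(cfg.snippet_margin_ms * 1e-3 * fs))
    snip_len = dead + 2 * margin
    half = dead // 2

    events: list[SpikeEvent] = []
    for seg_idx, (start, stop) in enumerate(rec.segment_sample_bounds()):
        block = rec.traces[:, start:stop]
        filt = block if apply_filters is False else _prefilter(block, cfg, fs)
        seg_t0 = rec.t0 + rec.segments[seg_idx][0]
        for elec in range(rec.n_electrodes):
            x = filt[elec]
            for ext, polarity, amp in _scan_trace(
                x, cfg.pos_threshold_mv, cfg.neg_threshold_mv, dead
            ):
                s0 = ext - margin - half
                snippet = np.zeros(snip_len, dtype=np.float64)
                lo = max(s0, 0)
                hi = min(s0 + snip_len, x.shape[0])
                snippet[lo - s0 : hi - s0] = x[lo:hi]
                truncated = s0 < 0 or s0 + snip_len > x.shape[0]
                events.append(
                    SpikeEvent(
                        electrode=elec,
                        time_s=seg_t0 + ext / fs,
                        polarity=polarity,
                        amplitude_mv=amp,
                        snippet=snippet,
                        truncated=truncated,
                    )
                )
    total = sum(d for _, d in rec.segments)
    return SpikeTrainSet(
        events=events,
        n_electrodes=rec.n_electrodes,
        total_duration_s=total,
        sampling_rate_hz=fs,
        segments=list(rec.segments),
    )
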