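"""Synthetic MEA recordings and evoked fEPSP sweep series with ground truth.

Every downstream stage of the pipeline is testable against these generators
because they return the programmed event times, amplitudes and plasticity
factors alongside the simulated voltages.

Spontaneous events are a homogeneous Poisson process per electrode, thinned
by an absolute refractory period; cross-electrode synchrony is injected by a
shared "network event" train that each electrode copies with probability
``sync_fraction`` and per-electrode Gaussian jitter.  Spike waveforms are
biphasic difference-of-Gaussians of total width ``spike_width_ms`` riding on
white Gaussian noise.

Evoked sweeps carry a negative-going difference-of-exponentials fEPSP after
a blanked stimulus artifact; a multiplicative ``plasticity_factor`` is
applied to every sweep after the simulated 1 Hz induction train.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ArrayGeometry, RawRecording, Sweep, SweepSet, SpikeEvent, SpikeTrainSet


# --------------------------------------------------------------------------
# spontaneous activity


@dataclass
class SpontaneousSimParams:
    """Conditions for a spontaneous network-activity recording.

    Defaults emulate a "high-activity" slice: 61 hexagonally arranged
    electrodes, 600 x 1 s traces, ~2 events/s per electrode, spike amplitudes
    well above the +/-0.021 mV detection thresholds, and a noise floor of
    3.5 uV RMS (typical for planar arrays).
    """

    geometry: ArrayGeometry = field(default_factory=ArrayGeometry.hexagonal)
    duration_s: float = 600.0
    segment_duration_s: float = 1.0
    sampling_rate_hz: float = 20000.0
    per_electrode_rate_hz: np.ndarray | float = 2.0
    pos_fraction: float = 0.4
    pos_amp_mean_mv: float = 0.08
    pos_amp_sd_mv: float = 0.008
    neg_amp_mean_mv: float = 0.08
    neg_amp_sd_mv: float = 0.008
    sync_fraction: float = 0.5
    sync_jitter_ms: float = 1.0
    noise_sd_mv: float = 0.0035
    waveform: str = "biphasic"  # "biphasic" | "monophasic"
    spike_width_ms: float = 1.0
    refractory_ms: float = 2.0
    seed: int = 0

    def rates(self) -> np.ndarray:
        r = np.broadcast_to(
            np.asarray(self.per_electrode_rate_hz, dtype=float),
            (self.geometry.n_electrodes,),
        ).copy()
        return r

    def validate(self) -> None:
        r = self.rates()
        if np.any(r < 0):
            raise ValueError("per-electrode rates must be >= 0")
        if not 0 <= self.pos_fraction <= 1:
            raise ValueError("pos_fraction must be in [0, 1]")
        if not 0 <= self.sync_fraction <= 1:
            raise ValueError("sync_fraction must be in [0, 1]")
        if self.noise_sd_mv < 0:
            raise ValueError("noise_sd_mv must be >= 0")
        if self.waveform not in ("biphasic", "monophasic"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        ref_s = self.refractory_ms * 1e-3
        if ref_s > 0 and np.any(r * ref_s >= 1.0):
            raise ValueError(
                "event rate too high for the refractory period "
                f"(need rate < {1.0 / ref_s:.0f} Hz)"
            )
        if self.duration_s <= 0 or self.segment_duration_s <= 0:
            raise ValueError("durations must be positive")


def spike_kernel(
    spike_width_ms: float, sampling_rate_hz: float, waveform: str = "biphasic"
) -> np.ndarray:
    """Unit-peak spike waveform sampled at the acquisition rate.

    Biphasic: difference of two Gaussians (main lobe centred, opposing lobe
    delayed), total support one spike width; the extremum sits at the centre
    sample so ground-truth times coincide with detected extremum times.
    """
    n = int(round(spike_width_ms * 1e-3 * sampling_rate_hz))
    n = max(5, n | 1)  # odd
    t = np.arange(n) - n // 2
    sigma = n / 8.0
    main = np.exp(-0.5 * (t / sigma) ** 2)
    if waveform == "monophasic":
        kernel = main
    else:
        counter = 0.45 * np.exp(-0.5 * ((t - 2.2 * sigma) / (1.3 * sigma)) ** 2)
        kernel = main - counter
    return kernel / np.abs(kernel).max()


def _poisson_train(rng: np.random.Generator, rate_hz: float, duration_s: float) -> np.ndarray:
    if rate_hz <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def _thin_refractory(times: np.ndarray, refractory_s: float) -> np.ndarray:
    if times.size == 0 or refractory_s <= 0:
        return times
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory_s:
            kept.append(t)
    return np.asarray(kept)


def simulate_spontaneous(p: SpontaneousSimParams) -> tuple[RawRecording, SpikeTrainSet]:
    """Simulate one spontaneous recording; returns (recording, ground truth).

    Per electrode the event train is the union of (i) jittered copies of a
    shared network train, thinned to probability ``sync_fraction`` per shared
    event, and (ii) an independent Poisson train at rate
    ``(1 - sync_fraction) * rate``; the shared train itself fires at
    ``sync_fraction * mean(rate)``, so with uniform rates the per-electrode
    total rate equals the programmed rate.  The merged train is thinned by
    the absolute refractory period.
    """
    p.validate()
    rng = np.random.default_rng(p.seed)
    fs = p.sampling_rate_hz
    m = p.geometry.n_electrodes
    rates = p.rates()
    n_samples = int(round(p.duration_s * fs))
    traces = (
        rng.normal(0.0, p.noise_sd_mv, size=(m, n_samples))
        if p.noise_sd_mv > 0
        else np.zeros((m, n_samples))
    )

    shared = _poisson_train(rng, p.sync_fraction * float(rates.mean()), p.duration_s)
    jitter_s = p.sync_jitter_ms * 1e-3
    ref_s = p.refractory_ms * 1e-3
    kernel = spike_kernel(p.spike_width_ms, fs, p.waveform)
    half_k = len(kernel) // 2

    n_seg = max(1, int(round(p.duration_s / p.segment_duration_s)))
    seg_edges = np.arange(n_seg + 1) * p.segment_duration_s
    seg_edges[-1] = p.duration_s
    seg_bounds_samp = np.round(seg_edges * fs).astype(int)
    seg_bounds_samp[-1] = n_samples

    events: list[SpikeEvent] = []
    for e in range(m):
        own = _poisson_train(rng, (1.0 - p.sync_fraction) * rates[e], p.duration_s)
        if shared.size:
            take = rng.random(shared.size) < p.sync_fraction if p.sync_fraction < 1 else np.ones(shared.size, bool)
            copies = shared[take]
            if jitter_s > 0 and copies.size:
                copies = copies + rng.normal(0.0, jitter_s, size=copies.size)
            copies = copies[(copies >= 0) & (copies < p.duration_s)]
        else:
            copies = np.empty(0)
        times = _thin_refractory(np.sort(np.concatenate([own, copies])), ref_s)

        for t in times:
            pol = 1 if rng.random() < p.pos_fraction else -1
            if pol > 0:
                amp = abs(rng.normal(p.pos_amp_mean_mv, p.pos_amp_sd_mv))
            else:
                amp = -abs(rng.normal(p.neg_amp_mean_mv, p.neg_amp_sd_mv))
            idx = int(round(t * fs))
            if idx >= n_samples:
                continue
            # clip the waveform at the segment edges: acquisition traces are
            # independent 1 s records and spikes never bridge them
            seg = int(np.searchsorted(seg_bounds_samp, idx, side="right")) - 1
            seg = min(max(seg, 0), n_seg - 1)
            lo_bound, hi_bound = seg_bounds_samp[seg], seg_bounds_samp[seg + 1]
            k0 = idx - half_k
            lo = max(k0, lo_bound)
            hi = min(k0 + len(kernel), hi_bound)
            if hi <= lo:
                continue
            traces[e, lo:hi] += amp * kernel[lo - k0 : hi - k0]
            events.append(
                SpikeEvent(
                    electrode=e,
                    time_s=idx / fs,
                    polarity=pol,
                    amplitude_mv=amp,
                )
            )

    segments = [
        (float(seg_edges[i]), float(seg_edges[i + 1] - seg_edges[i])) for i in range(n_seg)
    ]
    rec = RawRecording(
        traces=traces,
        sampling_rate_hz=fs,
        geometry=p.geometry,
        segments=segments,
    )
    truth = SpikeTrainSet(
        events=events,
        n_electrodes=m,
        total_duration_s=p.duration_s,
        sampling_rate_hz=fs,
        segments=segments,
    )
    return rec, truth


# --------------------------------------------------------------------------
# evoked fEPSP series


@dataclass
class EvokedSimParams:
    """Conditions for an evoked LTP/LTD experiment.

    The protocol mirrors the standard slice paradigm: test stimuli every
    30 s, a 600-pulse 1 Hz induction train (10 min), then test stimuli for a
    further hour.  ``plasticity_factor`` multiplies the fEPSP from induction
    onward (1.45: LTP-like; 0.60: LTD-like; 1.0: no change).
    """

    n_baseline_sweeps: int = 20
    n_post_sweeps: int = 120
    inter_sweep_s: float = 30.0
    sweep_duration_ms: float = 50.0
    sampling_rate_hz: float = 20000.0
    artifact_window_ms: float = 5.0
    rise_ms: float = 1.5
    decay_ms: float = 8.0
    baseline_peak_mv: float = -0.4
    plasticity_factor: float = 1.0
    n_pulses: int = 600
    pulse_rate_hz: float = 1.0
    train_growth: float = 1.0
    noise_sd_mv: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.inter_sweep_s <= self.sweep_duration_ms * 1e-3:
            raise ValueError("inter_sweep_s must exceed the sweep duration")
        if self.plasticity_factor <= 0:
            raise ValueError("plasticity_factor must be positive")
        if self.artifact_window_ms >= self.sweep_duration_ms:
            raise ValueError("artifact window must be shorter than the sweep")
        if self.n_baseline_sweeps < 1:
            raise ValueError("need at least one baseline sweep")
        if self.rise_ms <= 0 or self.decay_ms <= 0 or self.rise_ms >= self.decay_ms:
            raise ValueError("need 0 < rise_ms < decay_ms")


def fepsp_waveform(
    sweep_duration_ms: float,
    sampling_rate_hz: float,
    artifact_window_ms: float,
    rise_ms: float,
    decay_ms: float,
    peak_mv: float,
) -> np.ndarray:
    """Difference-of-exponentials field potential, unit sweep.

    The synaptic deflection starts at the end of the artifact window and is
    scaled so its extremum equals ``peak_mv`` (negative for the default
    negative-going potential).  A +2 mV, 1 ms square stimulus artifact is
    placed at sweep start; analysis blanks it via the artifact window.
    """
    n = int(round(sweep_duration_ms * 1e-3 * sampling_rate_hz))
    t_ms = np.arange(n) / sampling_rate_hz * 1e3
    v = np.zeros(n)
    # stimulus artifact: first 1 ms
    v[t_ms < 1.0] = 2.0
    tt = t_ms - artifact_window_ms
    mask = tt > 0
    shape = np.zeros(n)
    shape[mask] = np.exp(-tt[mask] / decay_ms) - np.exp(-tt[mask] / rise_ms)
    peak = shape.max()
    if peak > 0:
        v += peak_mv * shape / peak
    return v


def simulate_evoked_series(p: EvokedSimParams) -> SweepSet:
    """Simulate baseline / induction / post sweep blocks with known factor."""
    p.validate()
    rng = np.random.default_rng(p.seed)
    fs = p.sampling_rate_hz

    def make(t: float, amp_mv: float, block: str, current_ua: float) -> Sweep:
        v = fepsp_waveform(
            p.sweep_duration_ms, fs, p.artifact_window_ms, p.rise_ms, p.decay_ms, amp_mv
        )
        if p.noise_sd_mv > 0:
            v = v + rng.normal(0.0, p.noise_sd_mv, size=v.shape)
        return Sweep(
            voltage_mv=v,
            sampling_rate_hz=fs,
            stimulus_time_s=t,
            stimulus_current_ua=current_ua,
            block=block,
        )

    sweeps: list[Sweep] = []
    t = 0.0
    test_current = 35.0
    for _ in range(p.n_baseline_sweeps):
        sweeps.append(make(t, -abs(p.baseline_peak_mv), "baseline", test_current))
        t += p.inter_sweep_s
    # induction train at pulse_rate_hz
    t_ind0 = t
    amp = -abs(p.baseline_peak_mv)
    for i in range(p.n_pulses):
        pulse_amp = amp * (p.train_growth**i)
        sweeps.append(make(t_ind0 + i / p.pulse_rate_hz, pulse_amp, "induction", test_current))
    t = t_ind0 + p.n_pulses / p.pulse_rate_hz + p.inter_sweep_s
    post_amp = -abs(p.baseline_peak_mv) * p.plasticity_factor
    for _ in range(p.n_post_sweeps):
        sweeps.append(make(t, post_amp, "post", test_current))
        t += p.inter_sweep_s
    return SweepSet(sweeps)


# --------------------------------------------------------------------------
# input-output curves


@dataclass
class IOSimParams:
    """Conditions for an input-output (stimulus vs response) family.

    The noiseless response follows a saturating Hill sigmoid
    ``max_amp * s^h / (half_max^h + s^h)`` over stimulus currents 5-100 uA.
    """

    stimulus_levels_ua: np.ndarray = field(
        default_factory=lambda: np.arange(5.0, 101.0, 5.0)
    )
    n_repeats: int = 2
    max_amp_mv: float = 0.8
    half_max_ua: float = 30.0
    slope_param: float = 2.0
    sweep_duration_ms: float = 50.0
    sampling_rate_hz: float = 20000.0
    artifact_window_ms: float = 5.0
    rise_ms: float = 1.5
    decay_ms: float = 8.0
    noise_sd_mv: float = 0.0
    block: str = "io_pre"
    seed: int = 0

    def validate(self) -> None:
        s = np.asarray(self.stimulus_levels_ua, dtype=float)
        if s.size == 0:
            raise ValueError("stimulus level vector must be nonempty")
        if np.any(s <= 0) or np.any(np.diff(s) <= 0):
            raise ValueError("stimulus levels must be positive and strictly increasing")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def io_response_mv(p: IOSimParams, stimulus_ua: np.ndarray | float) -> np.ndarray:
    """Closed-form noiseless response amplitude (mV, magnitude) at a stimulus."""
    s = np.asarray(stimulus_ua, dtype=float)
    h = p.slope_param
    return p.max_amp_mv * s**h / (p.half_max_ua**h + s**h)


def simulate_io(p: IOSimParams) -> SweepSet:
    """Simulate an I/O sweep family (``n_repeats`` sweeps per level)."""
    p.validate()
    rng = np.random.default_rng(p.seed)
    fs = p.sampling_rate_hz
    sweeps: list[Sweep] = []
    t = 0.0
    for s in np.asarray(p.stimulus_levels_ua, dtype=float):
        amp = float(io_response_mv(p, s))
        for _ in range(p.n_repeats):
            v = fepsp_waveform(
                p.sweep_duration_ms, fs, p.artifact_window_ms, p.rise_ms, p.decay_ms, -amp
            )
            if p.noise_sd_mv > 0:
                v = v + rng.normal(0.0, p.noise_sd_mv, size=v.shape)
            sweeps.append(
                Sweep(
                    voltage_mv=v,
                    sampling_rate_hz=fs,
                    stimulus_time_s=t,
                    stimulus_current_ua=float(s),
                    block=p.block,
                )
            )
            t += 10.0
    return SweepSet(sweeps)
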