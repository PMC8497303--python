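# Methods

This note documents the models, measurement definitions, numerical choices
and known limitations of the `slicephys` pipeline. Every number quoted here
is either a configurable default or a quantity the test suite /
`scripts/acceptance.py` actually computes.

## Units and conventions

Times in seconds, voltages in mV, stimulus currents in µA, electrode
positions in µm. Electrode indices are 0-based in files and APIs; induction
train responses are numbered 1-based (so "responses #596–600" means the
last five of a 600-pulse train). All time-window parameters are given in
physical units and converted to samples at use, because the acquisition
sampling rate is a configuration value (default 20 kHz, typical of the
planar-array systems this pipeline mirrors), not a constant.

## Signal conditioning

Two stages precede spike detection, both zero-phase so event times are not
lag-shifted:

* **Bessel high-pass** — 2-pole, 1 kHz, magnitude-normalised so the −3 dB
  point sits at the cutoff, applied forward–backward (`scipy.signal.bessel`
  + `filtfilt`). The two passes square the magnitude response: a sinusoid
  at cutoff emerges at half amplitude, which the tests verify against the
  design's analytic transfer function.
* **Baseline ("DC") filter** — the acquisition-software notion of a DC
  filter "with a typical spike length" is under-specified (it could be a
  gentle high-pass or a baseline subtraction), so both are available behind
  `RunConfig.dc_filter_mode`. The default is a sliding-median baseline
  subtraction with window 10 × the spike length (10 ms): the median of a
  200-sample window is essentially untouched by a ≤ 1 ms transient, so
  spike amplitudes are preserved (tested to within 5 %) while drifts slower
  than the window are removed.

## Spike detection

An event is registered when the conditioned trace strictly exceeds the
positive threshold (+0.021 mV) or strictly falls below the negative one
(−0.021 mV); boundary-equal samples never trigger (a deterministic,
documented tie rule). The event extremum is the largest-|v| sample within
one spike length (1 ms) of the crossing, ties going to the earliest sample;
polarity is the extremum's sign; a dead time of one spike length after the
extremum suppresses re-triggering, so consecutive same-electrode events are
never closer than the spike length. Snippets span the spike ±1 ms of
baseline; at segment edges they are zero-padded and flagged `truncated`.
Electrodes are detected independently (activity is reported per electrode;
no spatial de-duplication), and segment boundaries — the 600 × 1 s
structure of spontaneous protocols — are never bridged by filtering,
detection or dead time.

The implementation is verified sample-for-sample against a naive
per-sample scan oracle on randomized traces (100+ cases), and against
generator ground truth: with amplitudes ≥ 3× threshold and a noise floor
≤ threshold/4 it recovers ≥ 99 % of programmed events with ≤ 1 % false
positives.

## Network-activity measures

* **Activity map / classification** — events per electrode per 1 s trace;
  slice mean rate = mean over electrodes of per-electrode rates; *low*
  activity iff mean rate < 1 event/s (strict), else *high*.
* **ISI analyses** — ISIs are intervals between consecutive events on the
  same electrode, pooled across the electrodes in scope; across-electrode
  intervals are never formed ("interspike interval" in its standard
  per-train sense). Histograms use half-open bins [kw, (k+1)w) with
  1e−12 s of slack so ISIs that are exact bin multiples up to float
  representation stay in their nominal bin; ISIs above 2 s are excluded
  (configurable for the coarse 5 ms analysis, fixed for the fine 1 ms
  cumulative analysis).
* **Band occupancy** — defined on instantaneous rate 1/ISI. The high band
  (> 20 Hz) is ISI < 0.05 s, strict, matching the strict inequality in the
  verbal definition; the delta band (0.6–4 Hz) maps to ISI ∈ (0.25 s,
  1/0.6 s], the only self-consistent half-open reading for ISI data. High,
  delta and "other" partition the retained ISIs and sum to 1.
* **Synchrony index** — the fraction of events that sit inside a
  population coincidence: events from ≥ k distinct electrodes (default a
  strict majority) within a centred 5 ms window. This is a diagnostic
  metric of the pipeline, not a quantity the source experiments report; it
  is deterministic, invariant under electrode relabeling, monotone in the
  generator's synchrony parameter, and sits at the analytic chance level
  1 − exp(−r·w) for independent Poisson trains.

## fEPSP measurement

Field potentials are negative-going by default (`RunConfig.fepsp_polarity`
flips this for positive-going data). Per sweep, after blanking the
stimulus-artifact window (default 5 ms):

1. the response is smoothed with a 1 ms boxcar (`fepsp_smooth_ms`; 0
   disables). Smoothing is linear, hence exactly scale-equivariant — it
   cancels in every normalized quantity — and it suppresses two noise
   biases that do not cancel: the extreme-value inflation of a per-sample
   extremum search, and the early-crossing bias of threshold detection on
   noisy traces;
2. the peak is the extremum of the smoothed response, with amplitude taken
   as a short average around the extremum sample (again to avoid
   extreme-value bias);
3. deflection onset is the last sample before the peak whose value is
   within the noise floor of zero (or of opposite sign);
4. the 10–90 section is the contiguous time window from the first 10 %
   crossing to the first 90 % crossing of |peak| on the onset→peak phase.
   Selecting samples individually by membership of their (noisy) value in
   the 10–90 band would truncate on the dependent variable and bias the
   fitted slope toward zero, so the window is defined by crossing times
   and *all* samples inside it enter the least-squares fit;
5. the slope is the magnitude of the least-squares line over that window,
   in mV/ms. Sweeps whose peak misses the noise floor, or that never cross
   10 % of peak, are flagged invalid and excluded (logged).

With these choices the programmed plasticity factors 0.6 / 1.0 / 1.5 are
recovered as 60 / 100 / 150 ± 5 percentage points under sweep noise of 10 %
of the baseline peak (seed-averaged; computed by the test suite and the
acceptance script).

## Time courses, I/O curves, train analysis

* Baseline normalization uses the mean slope over the 3 min immediately
  before induction (6 sweeps at 30 s spacing). The induction interval
  comes from the tagged induction block; when a series has no recorded
  train, the interval is anchored midway between the last baseline and
  first post sweep.
* The summary magnitude is the mean normalized slope over minutes 56–60
  after induction (configurable): "one hour after induction" is a time
  point in the verbal protocol, read here as the last four minutes of a
  one-hour follow-up. Direction is called LTP above 110 %, LTD below 90 %.
* Plotted series are optionally pair-averaged (non-overlapping consecutive
  pairs, odd trailing point kept and flagged), matching displays where
  each point is the average of two successive test responses.
* Baseline stability ("stable baseline of at least 10 min") is an advisory
  check: a linear fit to the last 10 min of baseline normalized values
  warns above ±5 %/10 min but never gates the analysis, since with noisy
  short baselines the drift estimate itself is noisy.
* I/O curves report mean |peak amplitude| per stimulus level (peak, not
  slope, matching how such curves are displayed; slope remains available).
  The threshold (test) stimulus is 0.35 × the level with the maximal mean
  response — the midpoint of the conventional 30–40 % rule, with both
  endpoints reachable by configuration; exact amplitude ties resolve to
  the largest level.
* Train analysis normalizes each of the 600 induction responses to the
  first and reports the mean of responses #596–600 over the mean of #1–5,
  plus the mean normalized amplitude of the last 100 responses.

## The synthetic-data generator

The generator emulates the *statistical* structure the pipeline must
resolve, not the biophysics:

* **Spontaneous events** — homogeneous Poisson per electrode, thinned by
  an absolute refractory period (2 ms; rates ≥ 1/refractory are rejected
  as infeasible). No generative model of real slice activity is claimed;
  Poisson is the minimal null with analytically known ISI structure, which
  is exactly what the ISI tests need.
* **Synchrony** — a single shared "network event" train (rate =
  sync_fraction × mean electrode rate) copied to each electrode with
  probability `sync_fraction` and per-electrode Gaussian jitter (1 ms),
  plus an independent train at the residual rate. One scalar moves the
  pipeline's synchrony readout monotonically from chance to 1.
* **Waveform** — biphasic difference-of-Gaussians, total width 1 ms,
  extremum at the event sample so ground-truth and detected times
  coincide; sign from a Bernoulli polarity draw, magnitude Gaussian per
  polarity. Default amplitude 0.08 mV (≈ 4× threshold, the scale of the
  spikes such arrays resolve) and noise 3.5 µV RMS, a typical planar-array
  noise floor.
* **fEPSP sweeps** — negative-going difference of exponentials (rise
  1.5 ms, decay 8 ms) peaking at −0.4 mV after a blanked square artifact;
  a multiplicative `plasticity_factor` applies from induction onward, and
  the 600-pulse 1 Hz train is generated as its own tagged block with an
  optional per-pulse geometric drift. Sweep noise is additive white
  Gaussian (`noise_sd_mv` is the only noise knob; "10 % sweep noise" means
  noise SD = 0.1 × |baseline peak|).
* **I/O families** — noiseless response amplitude follows a saturating
  Hill sigmoid max_amp · s^h / (half^h + s^h) (half-max 30 µA, h = 2) over
  5–100 µA.

What passing tests therefore show: the measurement chain recovers known
rates, amplitudes, synchrony orderings and plasticity factors from data
with the stated noise and structure. What they cannot show: performance on
real recordings with correlated noise, electrode drift, bursting,
overlapping units or artifact contamination — none of which the generator
models.

## Problem sizes

The verification runs use scaled-down recordings chosen as the package's
default check sizes: detection recovery on 4 electrodes × 20 s × 10 seeds
(the full protocol's 61 × 600 s is supported but adds nothing to the
check), plasticity recovery on complete 20-baseline/120-post sweep series
across 10–20 seeds, and the cohort drivers under `analysis/` on 4 slices
per group, 8 electrodes, 30 s of spontaneous activity each. The
acceptance-script quantities are seed-averaged Monte Carlo estimates; their
sampling error at these sizes is small relative to the ±5-point recovery
bands they are compared against.

## Known limitations

* No spike sorting: threshold events are multi-unit activity per
  electrode, as in the acquisition software this mirrors.
* The "band" statements are ISI-based by construction; no spectral
  (Fourier/wavelet) power is computed.
* Two-way repeated-measures ANOVA (used for cohort time-course comparisons
  in the experimental literature) is deliberately not re-implemented;
  standard statistical packages should be used on the exported tables.
* Cohort-level magnitudes from real experiments (e.g. a 145 % LTP in a
  control cohort) depend on the actual recordings and are not
  desk-reproducible; the pipeline demonstrates recovery of *programmed*
  effects at comparable sizes instead.
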