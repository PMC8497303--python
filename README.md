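# slicephys

Analysis pipeline for slice multi-electrode-array (MEA) electrophysiology:
spontaneous network-activity characterisation and evoked synaptic-plasticity
quantification, with a synthetic-data generator providing ground-truthed
recordings so every stage is testable without access to raw acquisition
files.

It is aimed at the kind of experiment where a cerebellar (or other) slice
sits on a 61-electrode hexagonal array (70 µm pitch): minutes of spontaneous
activity are recorded as 600 × 1 s traces per slice, then one pathway is
stimulated every 30 s to follow field excitatory postsynaptic potentials
(fEPSPs) through an input–output (I/O) protocol, a 600-pulse 1 Hz induction
train, and an hour of follow-up.

## What it computes

**Spike extraction** — traces are conditioned with a zero-phase 2-pole
Bessel high-pass (1 kHz, −3 dB) and a sliding-median baseline ("DC") filter
parameterised by the typical spike length (1 ms), then events are extracted
wherever the voltage strictly exceeds +0.021 mV or falls below −0.021 mV.
Event time is the extremum sample, polarity its sign, and a dead time of one
spike length suppresses re-triggering; waveform snippets keep 1 ms of
baseline on both sides.

**Network activity** — per-electrode event counts per 1 s trace; slices
classified *low* (mean rate < 1 event/s) or *high*; event rates and
amplitudes split by spike polarity; interspike-interval (ISI) histograms in
5 ms and 1 ms bins with cumulative distributions (ISIs > 2 s excluded);
band occupancy on instantaneous rate 1/ISI, with the >20 Hz band mapped to
ISI < 0.05 s and the delta band (0.6–4 Hz) to ISI ∈ (0.25 s, 1/0.6 s]; and a
diagnostic population-synchrony index.

**Plasticity** — per sweep, the fEPSP peak and the magnitude of the
least-squares slope over the 10–90 % section of the descending phase
(mV/ms). Long-term potentiation/depression (LTP/LTD) is the per-sweep slope
normalized to the mean slope over the 3 min of baseline before induction:

    normalized(t) = 100 · slope(t) / mean(slope, last 3 min of baseline)  [%]

with the summary magnitude the mean over minutes 56–60 after induction
(values ≈ 145 % mean strong LTP, ≈ 60 % strong LTD, ≈ 100 % no change).
I/O curves give mean |peak| per stimulus (5–100 µA) and the threshold (test)
stimulus as 35 % of the stimulus producing the maximal response; the 1 Hz
train is summarised by the ratio of the mean amplitude of responses
#596–600 to that of #1–5.

**Statistics** — uncorrected Pearson chi-square for the 2×2 low/high
activity table, Mann–Whitney U and Wilcoxon signed-rank tests (midrank
ties; exact enumeration for small samples), and a per-group mean ± SEM
report assembler.

## Worked example

```python
import slicephys as sp

# a slice with a known 1.45x potentiation and 5% sweep noise
params = sp.EvokedSimParams(plasticity_factor=1.45, noise_sd_mv=0.02, seed=1)
sweeps = sp.simulate_evoked_series(params)
tc = sp.build_timecourse(sweeps, sp.RunConfig())
print(f"baseline slope {tc.baseline_mean_slope:.3f} mV/ms")
print(f"magnitude {tc.magnitude_percent:.1f}% -> {tc.direction}")
```

prints

```
baseline slope 0.185 mV/ms
magnitude 142.8% -> LTP
```

i.e. the fEPSP descending slope averaged 0.185 mV/ms during baseline and
settled at 142.8 % of baseline in the final summary window — the programmed
45 % potentiation recovered from noisy sweeps.

The `analysis/` directory holds the numbered study drivers
(`01_simulate.py` … `06_group_stats.py`): they simulate a scaled-down
two-group cohort (synchronised control-like slices vs desynchronised,
low-amplitude, plasticity-deficient mutant-like slices), run every pipeline
stage, and write the cohort tables under `results/analysis/`. There is also
a CLI over the same stages:

```
slicephys simulate --config cfg.yaml --out-dir out/
slicephys detect   --config cfg.yaml --out-dir out/
slicephys network  --config cfg.yaml --out-dir out/
```

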