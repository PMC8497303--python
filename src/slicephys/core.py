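"""Core domain containers for slice MEA recordings and evoked sweeps.

Unit conventions used throughout the package: times in seconds, voltages in
mV, stimulus currents in uA, electrode positions in um.  Electrode indices
are 0-based everywhere (files and APIs).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

HEX_N_ELECTRODES = 61
HEX_SPACING_UM = 70.0


class ConsistencyError(ValueError):
    """Metadata and data disagree (e.g. electrode-count mismatch)."""


class FormatError(ValueError):
    """A file is not in the documented exchange layout."""


@dataclass(frozen=True)
class ArrayGeometry:
    """Planar electrode-array geometry.

    The default layout mirrors a hexagonal 61-electrode probe with 70 um
    nearest-neighbour spacing (five concentric hexagonal rings).
    """

    n_electrodes: int
    layout: str  # "hexagonal" | "grid" | "custom"
    spacing_um: float
    coordinates: np.ndarray  # (n_electrodes, 2) x/y in um

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "coordinates", coords)
        if self.n_electrodes < 1:
            raise ValueError("n_electrodes must be >= 1")
        if self.layout not in ("hexagonal", "grid", "custom"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if coords.shape != (self.n_electrodes, 2):
            raise ConsistencyError(
                f"coordinates shape {coords.shape} != ({self.n_electrodes}, 2)"
            )

    @classmethod
    def hexagonal(cls, spacing_um: float = HEX_SPACING_UM) -> "ArrayGeometry":
        """61-electrode hexagonal array (rings of 1+6+12+18+24 sites)."""
        coords = []
        for q in range(-4, 5):
            for r in range(-4, 5):
                if abs(q + r) <= 4:
                    x = spacing_um * (q + r / 2.0)
                    y = spacing_um * (np.sqrt(3.0) / 2.0) * r
                    coords.append((x, y))
        coords = np.array(sorted(coords, key=lambda p: (round(p[1], 6), round(p[0], 6))))
        return cls(HEX_N_ELECTRODES, "hexagonal", spacing_um, coords)

    @classmethod
    def grid(cls, n_rows: int, n_cols: int, spacing_um: float) -> "ArrayGeometry":
        xs, ys = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
        coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float) * spacing_um
        return cls(n_rows * n_cols, "grid", spacing_um, coords)

    def __eq__(self, other) -> bool:  # dataclass eq breaks on ndarray fields
        if not isinstance(other, ArrayGeometry):
            return NotImplemented
        return (
            self.n_electrodes == other.n_electrodes
            and self.layout == other.layout
            and self.spacing_um == other.spacing_um
            and np.array_equal(self.coordinates, other.coordinates)
        )


@dataclass
class RawRecording:
    """Multi-electrode voltage traces plus acquisition metadata.

    ``segments`` lists the contiguous recorded traces as (start_s, duration_s)
    pairs in recording time; spontaneous protocols are typically 600 segments
    of 1 s each.  Rows of ``traces`` are electrodes, columns samples; the
    segments are laid out back-to-back along the sample axis.
    """

    traces: np.ndarray  # (n_electrodes, n_samples), mV
    sampling_rate_hz: float
    geometry: ArrayGeometry
    segments: list[tuple[float, float]]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=np.float64)
        if self.traces.ndim != 2:
            raise ValueError("traces must be a 2-D electrode x sample matrix")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.geometry.n_electrodes != self.traces.shape[0]:
            raise ConsistencyError(
                f"geometry declares {self.geometry.n_electrodes} electrodes, "
                f"trace matrix has {self.traces.shape[0]} rows"
            )
        self.segments = [(float(s), float(d)) for s, d in self.segments]
        total = sum(d for _, d in self.segments)
        n_expected = total * self.sampling_rate_hz
        if abs(n_expected - self.traces.shape[1]) > 1.0 + 1e-9:
            raise ConsistencyError(
                f"segments cover {total} s = {n_expected:.1f} samples but "
                f"traces have {self.traces.shape[1]}"
            )

    @property
    def n_electrodes(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_s(self) -> float:
        return self.traces.shape[1] / self.sampling_rate_hz

    def segment_sample_bounds(self) -> list[tuple[int, int]]:
        """(start, stop) sample indices of each contiguous segment."""
        bounds = []
        pos = 0
        for _, dur in self.segments:
            n = int(round(dur * self.sampling_rate_hz))
            bounds.append((pos, pos + n))
            pos += n
        if bounds:
            bounds[-1] = (bounds[-1][0], self.traces.shape[1])
        return bounds

    def __eq__(self, other) -> bool:
        if not isinstance(other, RawRecording):
            return NotImplemented
        return (
            np.array_equal(self.traces, other.traces)
            and self.sampling_rate_hz == other.sampling_rate_hz
            and self.t0 == other.t0
            and self.geometry == other.geometry
            and self.segments == other.segments
        )


@dataclass
class RunConfig:
    """All tunable analysis parameters, in physical units.

    Defaults follow the acquisition-software settings used for this kind of
    MED-style array recording: +/-0.021 mV spike thresholds, a 2-pole 1 kHz
    Bessel high-pass, and a DC (baseline) filter parameterised by a typical
    spike length of 1 ms.
    """

    pos_threshold_mv: float = 0.021
    neg_threshold_mv: float = -0.021
    spike_length_ms: float = 1.0
    snippet_margin_ms: float = 1.0
    highpass_cutoff_hz: float = 1000.0
    highpass_order: int = 2
    sampling_rate_hz: float = 20000.0
    isi_bin_coarse_ms: float = 5.0
    isi_bin_fine_ms: float = 1.0
    isi_max_s: float = 2.0
    delta_band_hz: tuple[float, float] = (0.6, 4.0)
    high_freq_cut_hz: float = 20.0
    baseline_norm_window_min: float = 3.0
    pair_average: bool = True
    rng_seed: int = 0
    # filtering behaviour ahead of spike detection
    apply_highpass: bool = True
    dc_filter_mode: str = "median_baseline"  # "median_baseline" | "highpass" | "off"
    dc_window_spike_lengths: float = 10.0
    # evoked-response measurement
    artifact_window_ms: float = 5.0
    fepsp_polarity: int = -1  # -1: negative-going field potential
    fepsp_noise_floor_mv: float = 0.01
    fepsp_smooth_ms: float = 1.0  # boxcar ahead of peak/slope measurement; 0 disables
    summary_window_min: tuple[float, float] = (56.0, 60.0)
    threshold_stim_fraction: float = 0.35  # midpoint of the 30-40% rule
    activity_cutoff_hz: float = 1.0
    sync_window_ms: float = 5.0

    def __post_init__(self) -> None:
        if not (self.pos_threshold_mv > 0 > self.neg_threshold_mv):
            raise ValueError("need pos_threshold_mv > 0 > neg_threshold_mv")
        for name in (
            "spike_length_ms",
            "snippet_margin_ms",
            "highpass_cutoff_hz",
            "sampling_rate_hz",
            "isi_bin_coarse_ms",
            "isi_bin_fine_ms",
            "isi_max_s",
            "baseline_norm_window_min",
            "artifact_window_ms",
            "sync_window_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.highpass_order < 1:
            raise ValueError("highpass_order must be >= 1")
        if self.dc_filter_mode not in ("median_baseline", "highpass", "off"):
            raise ValueError(f"unknown dc_filter_mode {self.dc_filter_mode!r}")
        if self.fepsp_polarity not in (-1, 1):
            raise ValueError("fepsp_polarity must be +1 or -1")
        self.delta_band_hz = tuple(self.delta_band_hz)  # type: ignore[assignment]
        self.summary_window_min = tuple(self.summary_window_min)  # type: ignore[assignment]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["delta_band_hz"] = list(self.delta_band_hz)
        d["summary_window_min"] = list(self.summary_window_min)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class SpikeEvent:
    """A threshold-crossing event on one electrode.

    ``time_s`` is the time of the extremum sample; ``amplitude_mv`` the signed
    voltage there.  ``snippet`` spans the spike plus a margin of baseline on
    both sides; ``truncated`` marks snippets zero-padded at segment edges.
    """

    electrode: int
    time_s: float
    polarity: int  # +1 | -1
    amplitude_mv: float
    snippet: np.ndarray | None = None
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")


@dataclass
class SpikeTrainSet:
    """Detected (or ground-truth) events for one slice recording."""

    events: list[SpikeEvent]
    n_electrodes: int
    total_duration_s: float
    sampling_rate_hz: float
    segments: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.total_duration_s <= 0:
            raise ValueError("total_duration_s must be positive")
        self.events = sorted(self.events, key=lambda e: (e.electrode, e.time_s))

    def __len__(self) -> int:
        return len(self.events)

    def times_by_electrode(self) -> dict[int, np.ndarray]:
        out: dict[int, np.ndarray] = {e: [] for e in range(self.n_electrodes)}
        for ev in self.events:
            out[ev.electrode].append(ev.time_s)
        return {k: np.asarray(v, dtype=float) for k, v in out.items()}

    def subset(self, electrodes: Sequence[int]) -> "SpikeTrainSet":
        """Restrict to a nonempty set of electrode indices (indices kept)."""
        electrodes = sorted(set(int(e) for e in electrodes))
        if not electrodes:
            raise ValueError("electrode subset must be nonempty")
        bad = [e for e in electrodes if e < 0 or e >= self.n_electrodes]
        if bad:
            raise IndexError(f"electrode indices out of range: {bad}")
        keep = set(electrodes)
        return SpikeTrainSet(
            events=[ev for ev in self.events if ev.electrode in keep],
            n_electrodes=self.n_electrodes,
            total_duration_s=self.total_duration_s,
            sampling_rate_hz=self.sampling_rate_hz,
            segments=list(self.segments),
        )


SWEEP_BLOCKS = ("baseline", "induction", "post", "io_pre", "io_post")


@dataclass
class Sweep:
    """One evoked sweep, aligned so sample 0 is stimulus onset."""

    voltage_mv: np.ndarray
    sampling_rate_hz: float
    stimulus_time_s: float  # wall clock
    stimulus_current_ua: float
    block: str

    def __post_init__(self) -> None:
        self.voltage_mv = np.asarray(self.voltage_mv, dtype=np.float64)
        if self.voltage_mv.ndim != 1:
            raise ValueError("sweep voltage must be 1-D")
        if self.block not in SWEEP_BLOCKS:
            raise ValueError(f"unknown sweep block {self.block!r}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, Sweep):
            return NotImplemented
        return (
            np.array_equal(self.voltage_mv, other.voltage_mv)
            and self.sampling_rate_hz == other.sampling_rate_hz
            and self.stimulus_time_s == other.stimulus_time_s
            and self.stimulus_current_ua == other.stimulus_current_ua
            and self.block == other.block
        )


@dataclass
class SweepSet:
    """An ordered series of evoked sweeps from one pathway."""

    sweeps: list[Sweep]

    def __post_init__(self) -> None:
        self.sweeps = sorted(self.sweeps, key=lambda s: s.stimulus_time_s)

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self):
        return iter(self.sweeps)

    def block(self, name: str) -> list[Sweep]:
        if name not in SWEEP_BLOCKS:
            raise ValueError(f"unknown sweep block {name!r}")
        return [s for s in self.sweeps if s.block == name]

    def __eq__(self, other) -> bool:
        if not isinstance(other, SweepSet):
            return NotImplemented
        return len(self.sweeps) == len(other.sweeps) and all(
            a == b for a, b in zip(self.sweeps, other.sweeps)
        )
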