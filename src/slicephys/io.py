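"""Exchange formats for recordings, sweep sets, events and results.

Two dialects for raw recordings:

* binary container (HDF5): ``/traces`` (electrode-major float64),
  ``/meta`` group with sampling rate, t0, segments and geometry — voltages
  round-trip bit-exactly and repeated writes of the same object are
  byte-identical (object timestamps disabled);
* delimited text: CSV with one column per electrode (sample rows) plus a
  YAML sidecar (``<stem>.yaml``) carrying the metadata — voltages
  round-trip to the printed precision (1e-9 mV).

Spike events travel as CSV with columns
``electrode,time_s,polarity,amplitude_mv,snippet_file_offset`` (ground truth
adds ``source=truth``).  Sweep sets use the binary container only
(``/sweeps`` matrix plus per-sweep attribute arrays).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import (
    ArrayGeometry,
    ConsistencyError,
    FormatError,
    RawRecording,
    SpikeEvent,
    SpikeTrainSet,
    Sweep,
    SweepSet,
)

TEXT_PRECISION = "%.9f"


def _h5_kwargs() -> dict:
    return {"track_times": False}


# --------------------------------------------------------------------------
# raw recordings


def write_recording(rec: RawRecording, path: str | Path, dialect: str = "binary") -> None:
    """Write a recording in the requested dialect ("binary" or "text")."""
    path = Path(path)
    if dialect == "binary":
        with h5py.File(path, "w", libver="earliest") as f:
            f.create_dataset("traces", data=rec.traces, **_h5_kwargs())
            meta = f.create_group("meta")
            meta.attrs["sampling_rate_hz"] = rec.sampling_rate_hz
            meta.attrs["t0"] = rec.t0
            meta.create_dataset("segments", data=np.asarray(rec.segments, dtype=float), **_h5_kwargs())
            geo = meta.create_group("geometry")
            geo.attrs["layout"] = rec.geometry.layout
            geo.attrs["spacing_um"] = rec.geometry.spacing_um
            geo.create_dataset("coordinates", data=rec.geometry.coordinates, **_h5_kwargs())
    elif dialect == "text":
        cols = {f"e{idx}": rec.traces[idx] for idx in range(rec.n_electrodes)}
        pd.DataFrame(cols).to_csv(path, index=False, float_format=TEXT_PRECISION)
        sidecar = {
            "n_electrodes": rec.n_electrodes,
            "sampling_rate_hz": float(rec.sampling_rate_hz),
            "t0": float(rec.t0),
            "segments": [[float(s), float(d)] for s, d in rec.segments],
            "geometry": {
                "layout": rec.geometry.layout,
                "spacing_um": float(rec.geometry.spacing_um),
                "coordinates": [[float(x), float(y)] for x, y in rec.geometry.coordinates],
            },
        }
        _sidecar_path(path).write_text(yaml.safe_dump(sidecar, sort_keys=True))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".yaml")


def read_recording(path: str | Path) -> RawRecording:
    """Read either dialect back into a RawRecording (dialect from suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "traces" not in f or "meta" not in f:
                raise FormatError(f"{path} lacks /traces or /meta")
            traces = f["traces"][()]
            meta = f["meta"]
            geo = meta["geometry"]
            geometry = ArrayGeometry(
                n_electrodes=traces.shape[0],
                layout=str(geo.attrs["layout"]),
                spacing_um=float(geo.attrs["spacing_um"]),
                coordinates=geo["coordinates"][()],
            )
            return RawRecording(
                traces=traces,
                sampling_rate_hz=float(meta.attrs["sampling_rate_hz"]),
                t0=float(meta.attrs["t0"]),
                geometry=geometry,
                segments=[tuple(row) for row in meta["segments"][()]],
            )
    if path.suffix == ".csv":
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FormatError(f"missing metadata sidecar {sidecar}")
        meta = yaml.safe_load(sidecar.read_text())
        df = pd.read_csv(path)
        traces = df.to_numpy(dtype=float).T
        if traces.shape[0] != int(meta["n_electrodes"]):
            raise ConsistencyError(
                f"sidecar declares {meta['n_electrodes']} electrodes, "
                f"CSV has {traces.shape[0]} columns"
            )
        g = meta["geometry"]
        geometry = ArrayGeometry(
            n_electrodes=int(meta["n_electrodes"]),
            layout=g["layout"],
            spacing_um=float(g["spacing_um"]),
            coordinates=np.asarray(g["coordinates"], dtype=float),
        )
        return RawRecording(
            traces=traces,
            sampling_rate_hz=float(meta["sampling_rate_hz"]),
            t0=float(meta["t0"]),
            geometry=geometry,
            segments=[tuple(seg) for seg in meta["segments"]],
        )
    raise FormatError(f"unrecognised recording file {path}")


# --------------------------------------------------------------------------
# spike events


def write_events_csv(trains: SpikeTrainSet, path: str | Path, source: str | None = None) -> None:
    rows = {
        "electrode": [e.electrode for e in trains.events],
        "time_s": [e.time_s for e in trains.events],
        "polarity": [e.polarity for e in trains.events],
        "amplitude_mv": [e.amplitude_mv for e in trains.events],
        "snippet_file_offset": [-1] * len(trains.events),
    }
    df = pd.DataFrame(rows, columns=list(rows))
    if source is not None:
        df["source"] = source
    df.to_csv(path, index=False, float_format="%.9g")


def read_events_csv(
    path: str | Path,
    n_electrodes: int,
    total_duration_s: float,
    sampling_rate_hz: float,
    segments: list[tuple[float, float]] | None = None,
) -> SpikeTrainSet:
    df = pd.read_csv(path)
    required = {"electrode", "time_s", "polarity", "amplitude_mv"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path} missing columns {sorted(required - set(df.columns))}")
    events = [
        SpikeEvent(
            electrode=int(r.electrode),
            time_s=float(r.time_s),
            polarity=int(r.polarity),
            amplitude_mv=float(r.amplitude_mv),
        )
        for r in df.itertuples()
    ]
    return SpikeTrainSet(
        events=events,
        n_electrodes=n_electrodes,
        total_duration_s=total_duration_s,
        sampling_rate_hz=sampling_rate_hz,
        segments=segments or [],
    )


# --------------------------------------------------------------------------
# sweep sets


def write_sweeps(sweeps: SweepSet, path: str | Path) -> None:
    sw = sweeps.sweeps
    if not sw:
        raise ValueError("refusing to write an empty sweep set")
    n = max(s.voltage_mv.size for s in sw)
    mat = np.zeros((len(sw), n))
    for i, s in enumerate(sw):
        mat[i, : s.voltage_mv.size] = s.voltage_mv
    with h5py.File(path, "w", libver="earliest") as f:
        f.create_dataset("sweeps", data=mat, **_h5_kwargs())
        f.create_dataset(
            "block",
            data=np.array([s.block for s in sw], dtype=h5py.string_dtype()),
            **_h5_kwargs(),
        )
        f.create_dataset("stimulus_time_s", data=[s.stimulus_time_s for s in sw], **_h5_kwargs())
        f.create_dataset(
            "stimulus_current_ua", data=[s.stimulus_current_ua for s in sw], **_h5_kwargs()
        )
        f.create_dataset("n_samples", data=[s.voltage_mv.size for s in sw], **_h5_kwargs())
        f.attrs["sampling_rate_hz"] = sw[0].sampling_rate_hz


def read_sweeps(path: str | Path) -> SweepSet:
    with h5py.File(path, "r") as f:
        if "sweeps" not in f:
            raise FormatError(f"{path} lacks /sweeps")
        mat = f["sweeps"][()]
        blocks = [b.decode() if isinstance(b, bytes) else str(b) for b in f["block"][()]]
        t = f["stimulus_time_s"][()]
        cur = f["stimulus_current_ua"][()]
        ns = f["n_samples"][()]
        fs = float(f.attrs["sampling_rate_hz"])
    return SweepSet(
        [
            Sweep(
                voltage_mv=mat[i, : ns[i]],
                sampling_rate_hz=fs,
                stimulus_time_s=float(t[i]),
                stimulus_current_ua=float(cur[i]),
                block=blocks[i],
            )
            for i in range(mat.shape[0])
        ]
    )


# --------------------------------------------------------------------------
# results


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, allow_nan=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
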