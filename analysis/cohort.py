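"""Shared cohort definition for the numbered analysis scripts.

A deliberately scaled-down study: 4 slices per genotype-like group, 8
electrodes, 30 s of spontaneous activity per slice (the full protocol uses
61 electrodes and 600 x 1 s traces), and complete evoked LTP/LTD series.
Group differences mirror the phenomena of interest: the mutant-like group
has desynchronised spontaneous activity, smaller spike amplitudes, a shifted
positive/negative spike balance, a flat plasticity factor (~0.96, no LTP or
LTD) and a smaller maximal evoked response; the control-like group
potentiates to ~1.45x (LTP protocol) and depresses to ~0.60x (LTD protocol).
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results" / "analysis"

N_SLICES_PER_GROUP = 4
BASE_SEED = 20260929

GROUPS = {
    "WT": {
        "spontaneous": {
            "geometry": {"layout": "grid", "n_rows": 2, "n_cols": 4},
            "duration_s": 30.0,
            "per_electrode_rate_hz": 2.0,
            "sync_fraction": 0.8,
            "pos_fraction": 0.40,
            "pos_amp_mean_mv": 0.08,
            "neg_amp_mean_mv": 0.08,
        },
        "ltp_factor": 1.45,
        "ltd_factor": 0.60,
        "io_max_amp_mv": 0.8,
    },
    "MUT": {
        "spontaneous": {
            "geometry": {"layout": "grid", "n_rows": 2, "n_cols": 4},
            "duration_s": 30.0,
            "per_electrode_rate_hz": 2.0,
            "sync_fraction": 0.2,
            "pos_fraction": 0.55,
            "pos_amp_mean_mv": 0.055,
            "neg_amp_mean_mv": 0.055,
        },
        "ltp_factor": 0.96,
        "ltd_factor": 0.96,
        "io_max_amp_mv": 0.6,
    },
}


def slice_dir(group: str, index: int) -> Path:
    return SCRATCH / "slices" / f"{group.lower()}_{index:02d}"


def slice_seed(group: str, index: int) -> int:
    return BASE_SEED + 1000 * list(GROUPS).index(group) + index


def slice_config(group: str, index: int, protocol: str = "ltp") -> dict:
    spec = GROUPS[group]
    factor = spec["ltp_factor"] if protocol == "ltp" else spec["ltd_factor"]
    return {
        "run": {"rng_seed": slice_seed(group, index)},
        "spontaneous": dict(spec["spontaneous"]),
        "evoked": {
            "plasticity_factor": factor,
            "noise_sd_mv": 0.02,
            "n_pulses": 600,
        },
        "io": {"max_amp_mv": spec["io_max_amp_mv"], "noise_sd_mv": 0.01, "n_repeats": 2},
    }


def all_slices():
    for group in GROUPS:
        for i in range(N_SLICES_PER_GROUP):
            yield group, i
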