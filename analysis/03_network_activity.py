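"""Spontaneous network-activity analysis per slice: rate maps, low/high
classification, polarity-resolved rates and amplitudes, ISI band occupancy
and the synchrony index.  Collects the slice summaries into one cohort
table under results/analysis/.
"""

import shutil
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from cohort import RESULTS, all_slices, slice_config, slice_dir

from slicephys import io as sio
from slicephys.pipeline import run_pipeline


def main() -> None:
    rows = []
    for group, i in all_slices():
        d = slice_dir(group, i)
        run_pipeline("network", d, slice_config(group, i))
        s = sio.read_json(d / "slice_network.json")
        rows.append(
            {
                "group": group,
                "slice": i,
                "classification": s["classification"],
                "overall_rate_hz": s["overall_rate_hz"],
                "pos_rate_hz": s["pos_rate_hz"],
                "neg_rate_hz": s["neg_rate_hz"],
                "pos_amp_mean_mv": s["pos_amp_mean_mv"],
                "neg_amp_mean_mv": s["neg_amp_mean_mv"],
                "high_band_fraction": s["bands"]["high_fraction"],
                "delta_band_fraction": s["bands"]["delta_fraction"],
                "synchrony_index": s["synchrony"]["index"],
            }
        )
        print(
            f"{group} slice {i}: {s['classification']} activity, "
            f"{s['overall_rate_hz']:.2f} ev/s, synchrony {s['synchrony']['index']:.2f}"
        )
    df = pd.DataFrame(rows)
    RESULTS.mkdir(parents=True, exist_ok=True)
    df.to_csv(RESULTS / "network_summary.csv", index=False, float_format="%.5f")
    for col in ("synchrony_index", "pos_amp_mean_mv", "high_band_fraction"):
        by = df.groupby("group")[col].mean()
        print(f"\nmean {col}: " + ", ".join(f"{g}={v:.3f}" for g, v in by.items()))


if __name__ == "__main__":
    main()
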