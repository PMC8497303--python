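"""Evoked plasticity per slice: baseline-normalized fEPSP slope time
courses under the LTP protocol and a separate LTD-protocol series, plus the
1 Hz induction-train ratio.  Collects magnitudes into a cohort table.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from cohort import RESULTS, all_slices, slice_config, slice_dir

from slicephys import io as sio
from slicephys.pipeline import run_pipeline


def main() -> None:
    rows = []
    for protocol in ("ltp", "ltd"):
        for group, i in all_slices():
            d = slice_dir(group, i) / protocol
            cfg = slice_config(group, i, protocol=protocol)
            run_pipeline("simulate", d, cfg)
            run_pipeline("plasticity", d, cfg)
            s = sio.read_json(d / "slice_plasticity.json")
            rows.append(
                {
                    "protocol": protocol,
                    "group": group,
                    "slice": i,
                    "magnitude_percent": s["magnitude_percent"],
                    "direction": s["direction"],
                    "train_last5_first5_ratio": s.get("train_last5_first5_ratio"),
                }
            )
            print(
                f"{protocol.upper()} {group} slice {i}: "
                f"{s['magnitude_percent']:.1f}% of baseline ({s['direction']})"
            )
    df = pd.DataFrame(rows)
    RESULTS.mkdir(parents=True, exist_ok=True)
    df.to_csv(RESULTS / "plasticity_summary.csv", index=False, float_format="%.4f")
    for (protocol, group), sub in df.groupby(["protocol", "group"]):
        m = sub["magnitude_percent"]
        print(
            f"\n{protocol.upper()} {group}: {m.mean():.1f} +/- "
            f"{m.sem():.1f}% normalized slope (n={len(m)})"
        )


if __name__ == "__main__":
    main()
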