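"""Input-output curves per slice over 5-100 uA and the derived threshold
(test) stimulus, 35% of the stimulus giving the maximal response.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from cohort import RESULTS, all_slices, slice_config, slice_dir

from slicephys import io as sio
from slicephys.pipeline import run_pipeline


def main() -> None:
    curve_rows = []
    thr_rows = []
    for group, i in all_slices():
        d = slice_dir(group, i)
        run_pipeline("io_curve", d, slice_config(group, i))
        curve = pd.read_csv(d / "io_curve.csv")
        curve.insert(0, "group", group)
        curve.insert(1, "slice", i)
        curve_rows.append(curve)
        thr = sio.read_json(d / "io_summary.json")["threshold_stimulus_ua"]
        thr_rows.append({"group": group, "slice": i, "threshold_stimulus_ua": thr})
        print(f"{group} slice {i}: threshold stimulus {thr:.1f} uA")
    RESULTS.mkdir(parents=True, exist_ok=True)
    pd.concat(curve_rows).to_csv(RESULTS / "io_curves.csv", index=False, float_format="%.5f")
    thr = pd.DataFrame(thr_rows)
    thr.to_csv(RESULTS / "io_thresholds.csv", index=False, float_format="%.2f")
    big = pd.concat(curve_rows)
    strong = big[big.stimulus_ua >= 60.0].groupby("group")["mean_amplitude_mv"].mean()
    print("\nmean response at >=60 uA: " + ", ".join(f"{g}={v:.3f} mV" for g, v in strong.items()))


if __name__ == "__main__":
    main()
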