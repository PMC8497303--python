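"""Simulate the study cohorts: spontaneous MEA recordings plus evoked
LTP series and input-output families for every slice.

Writes raw recordings and sweep containers into scratch/analysis/slices/
(one directory per slice) for the downstream numbered scripts.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from cohort import all_slices, slice_config, slice_dir

from slicephys.pipeline import run_pipeline


def main() -> None:
    n = 0
    for group, i in all_slices():
        d = slice_dir(group, i)
        run_pipeline("simulate", d, slice_config(group, i))
        n += 1
        print(f"simulated {group} slice {i} -> {d}")
    print(f"\n{n} slices simulated (spontaneous + evoked + I/O per slice).")


if __name__ == "__main__":
    main()
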