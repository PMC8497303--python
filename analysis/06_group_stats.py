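"""Group-level statistics: per-group means +/- SEM of the slice metrics,
the low/high activity contingency test (including the published 20/9 vs
15/10 table), and Mann-Whitney comparisons of the cohort metrics.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from cohort import RESULTS

from slicephys import io as sio
from slicephys.stats import (
    ContingencyTable2x2,
    assemble_report,
    chi_square_2x2,
    mann_whitney,
)


def main() -> None:
    network = pd.read_csv(RESULTS / "network_summary.csv")
    plasticity = pd.read_csv(RESULTS / "plasticity_summary.csv")

    summaries = [
        {k: row[k] for k in network.columns if k != "slice"} for _, row in network.iterrows()
    ]
    report = assemble_report(summaries)

    # published slice-level low/high activity counts (input table)
    published = chi_square_2x2(
        ContingencyTable2x2(20, 9, 15, 10, ("WT", "MUT"), ("low", "high"))
    )
    report["tests"]["published_low_high_chi_square"] = published.to_dict()
    print(
        f"published low/high table: chi-square {published.statistic:.4f}, "
        f"p = {published.p_value:.4f}"
    )

    for col in ("synchrony_index", "pos_amp_mean_mv", "high_band_fraction"):
        wt = network.loc[network.group == "WT", col].dropna()
        mut = network.loc[network.group == "MUT", col].dropna()
        r = mann_whitney(wt, mut)
        report["tests"][f"{col}_mann_whitney"] = r.to_dict()
        print(f"{col}: WT vs MUT Mann-Whitney U={r.statistic:.1f}, p={r.p_value:.4f}")

    for protocol in ("ltp", "ltd"):
        sub = plasticity[plasticity.protocol == protocol]
        wt = sub.loc[sub.group == "WT", "magnitude_percent"]
        mut = sub.loc[sub.group == "MUT", "magnitude_percent"]
        r = mann_whitney(wt, mut)
        report["tests"][f"{protocol}_magnitude_mann_whitney"] = r.to_dict()
        print(
            f"{protocol.upper()} magnitude: WT {wt.mean():.1f}% vs MUT {mut.mean():.1f}%, "
            f"Mann-Whitney p={r.p_value:.4f}"
        )

    sio.write_json(report, RESULTS / "group_report.json")
    print(f"\ngroup report written to {RESULTS / 'group_report.json'}")


if __name__ == "__main__":
    main()
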