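#!/usr/bin/env python
"""Correlate regional mean SUVR-1 with the target-density vector.

For each analysis window and each of the four candidate reference regions,
correlates the cohort-mean SUVR-1 of the 11 target regions with the
(synthetic) region-wise MAO-B density vector — the window/reference grid a
real study would use to pick its semi-quantitative protocol.  Prints the
matrix computed by the pipeline and the window ordering it implies.
"""

from pathlib import Path

import pandas as pd

from petkinfit.correlate import format_p

ROOT = Path(__file__).resolve().parents[1]
ANA = ROOT / "results" / "analysis"


def main() -> None:
    table = pd.read_csv(ANA / "suvr_density_correlations.csv")
    print("SUVR-1 vs density, per window and reference region:")
    print(table.assign(r=table.r.round(4),
                       p=table.p.map(format_p)).to_string(index=False))

    by_window = table.groupby("window")["r"].mean()
    print("\nmean r per window:")
    for window, r in by_window.items():
        print(f"  {window} min: {r:.4f}")
    spread = table.groupby("window")["r"].agg(lambda s: s.max() - s.min())
    print(f"\nreference-region choice moves r by at most "
          f"{spread.max():.4f} within a window; the window choice matters "
          f"more than the reference.")
    if by_window.drop("30-50").min() >= by_window["30-50"]:
        print("=> late windows (50-70, 70-90 min) track the density vector "
              "at least as well as 30-50 min.")


if __name__ == "__main__":
    main()
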