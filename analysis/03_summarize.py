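#!/usr/bin/env python
"""Frequency tables by NOVA group and subgroup (the headline-table shape).

For each row: n, share of the sample, and the percentage of items with a
nutrient in excess, any cosmetic additive, flavors-or-colors, and the
combined criterion.  Nutrient-model columns stay blank for groups 1-2.
"""

import argparse
from pathlib import Path

import pandas as pd

from upfscan.catalog import write_results
from upfscan.tables import group_frequencies, pooled_rate, render_percentages

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=ROOT / "scratch/classification_results.csv")
    parser.add_argument("--outdir", type=Path, default=ROOT / "results")
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    results = pd.read_csv(args.results)
    by_group = group_frequencies(results, ["nova_group"])
    by_subgroup = group_frequencies(results, ["nova_group", "subgroup"])
    write_results(render_percentages(by_group), args.outdir / "frequency_by_group.csv")
    write_results(render_percentages(by_subgroup), args.outdir / "frequency_by_subgroup.csv")

    print(render_percentages(by_group).to_string(index=False))
    pooled = pooled_rate(
        list(by_group["share_pct"]), list(by_group["pct_cosmetic_additive"])
    )
    print(f"\nwhole-sample cosmetic-additive rate (pooled over groups): {pooled:.1f}%")
    print(f"wrote tables under {args.outdir}")


if __name__ == "__main__":
    main()
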