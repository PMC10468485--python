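#!/usr/bin/env python
"""Generate the synthetic supermarket catalog used by the downstream steps.

Emulates the structure of a large supermarket label census (NOVA-group shares 71.9/13.7/2.4/12.0%,
per-group cosmetic-additive and nutrient-excess rates, 10.8% voluntary sugar
declaration) at a desk-scale n.  The catalog and its hidden truth table are
bulky, reproducible artifacts, so they go under scratch/.
"""

import argparse
from pathlib import Path

from upfscan.additives import default_lexicon
from upfscan.catalog import write_catalog, write_results
from upfscan.synth import default_synth_config, generate_catalog

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--n", type=int, default=3000)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--outdir", type=Path, default=ROOT / "scratch")
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    config = default_synth_config(n_items=args.n, seed=args.seed)
    lexicon = default_lexicon()
    records, truth = generate_catalog(config, lexicon)

    catalog_path = args.outdir / "synthetic_catalog.csv"
    truth_path = args.outdir / "synthetic_truth.csv"
    write_catalog(records, catalog_path)
    write_results(truth, truth_path)

    by_group = truth.groupby("nova_group").size()
    print(f"wrote {len(records)} records to {catalog_path}")
    print(f"wrote hidden truth table to {truth_path}")
    print("items per NOVA group:")
    for group, count in by_group.items():
        print(f"  group {group}: {count} ({100 * count / len(records):.1f}%)")


if __name__ == "__main__":
    main()
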