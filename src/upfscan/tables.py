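"""Frequency tables by NOVA group and subgroup, and pooled rates.

Reproduces the shape of a label-census summary table: for each (group,
subgroup) row, the number of items, their share of the total sample, and the
percentage carrying each flag.  Nutrient-model columns are rendered blank
(NaN), not zero, for NOVA groups 1–2 where the model does not apply.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["group_frequencies", "pooled_rate", "render_percentages"]

FLAG_COLUMNS = {
    "npm_any_excess": "pct_nutrient_excess",
    "has_cosmetic_additive": "pct_cosmetic_additive",
    "has_flavor_or_color": "pct_flavor_or_color",
    "combined_flag": "pct_combined",
}

#: Columns only defined where the nutrient model applies (NOVA 3-4).
NPM_GATED = ("pct_nutrient_excess", "pct_combined")


def group_frequencies(results: pd.DataFrame, grouping: Sequence[str]) -> pd.DataFrame:
    """Per-group n, share of total (%), and percentage with each flag.

    ``results`` is the classification results table (optionally joined to
    extra catalog columns); ``grouping`` is e.g. ``["nova_group"]`` or
    ``["nova_group", "subgroup"]``.  Groups emptied by upstream filtering
    simply do not appear.  Percentages use each row's own n as denominator.
    """
    if results.empty:
        raise ValueError("results table is empty")
    grouping = list(grouping)
    for key in grouping:
        if key not in results.columns:
            raise KeyError(f"unknown grouping key {key!r}")

    total = len(results)
    rows = []
    grouped = results.groupby(grouping, dropna=False, sort=True)
    for keys, chunk in grouped:
        if not isinstance(keys, tuple):
            keys = (keys,)
        row = dict(zip(grouping, keys))
        n = len(chunk)
        row["n"] = n
        row["share_pct"] = 100.0 * n / total
        for source, target in FLAG_COLUMNS.items():
            if source in chunk.columns:
                row[target] = 100.0 * chunk[source].astype(bool).mean()
        nova = row.get("nova_group")
        if nova is not None and not pd.isna(nova) and int(nova) in (1, 2):
            for target in NPM_GATED:
                row[target] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    ordered = grouping + ["n", "share_pct"] + [
        c for c in FLAG_COLUMNS.values() if c in table.columns
    ]
    return table[ordered]


def pooled_rate(group_shares: Sequence[float], group_rates: Sequence[float]) -> float:
    """Share-weighted pooled percentage: Σ share·rate / Σ share.

    Used to recover whole-sample rates from per-group rows (a convex
    combination, so the result lies between the extreme group rates).
    """
    if len(group_shares) != len(group_rates):
        raise ValueError(
            f"length mismatch: {len(group_shares)} shares vs {len(group_rates)} rates"
        )
    shares = np.asarray(group_shares, dtype=float)
    rates = np.asarray(group_rates, dtype=float)
    if np.any(shares <= 0):
        raise ValueError("shares must be > 0")
    return float(np.sum(shares * rates) / np.sum(shares))


def render_percentages(table: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Presentation copy with percentages rounded to table precision;
    the raw fractions stay available in the machine output."""
    out = table.copy()
    for column in out.columns:
        if column.endswith("_pct") or column.startswith("pct_"):
            out[column] = out[column].round(decimals)
    return out
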