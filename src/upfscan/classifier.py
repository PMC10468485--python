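"""Combine the additive and nutrient-profile criteria into the UPF flag.

The working hypothesis is that an ultra-processed product betrays itself on
its own label: it carries at least one cosmetic additive, or (when the
nutrient-profile model applies) at least one critical nutrient in excess.
``combined_flag`` is exactly that disjunction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .additives import AdditiveProfile, Lexicon, additive_profile
from .catalog import ProductRecord, ValidationIssue, validate_record
from .npm import (
    NPMConfig,
    NPMResult,
    SugarReferenceTable,
    estimate_added_sugars,
    evaluate_npm,
    free_sugars,
)

__all__ = [
    "ClassifyPolicies",
    "ClassificationResult",
    "ClassifyOutput",
    "combined_flag",
    "classify_catalog",
    "RESULT_COLUMNS",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "product_id",
    "subgroup",
    "nova_group",
    "has_cosmetic_additive",
    "has_flavor_or_color",
    "npm_applicable",
    "npm_any_excess",
    "combined_flag",
    "criteria_fired",
    "sugar_source",
    "note",
]


@dataclass(frozen=True)
class ClassifyPolicies:
    """Explicit switches for every ambiguity the method leaves open.

    sweetener_excluded: keep sweeteners out of the cosmetic count (they are
        counted via the nutrient-profile model instead).
    use_declared_total_as_added: treat a declared total-sugars value as an
        upper proxy for added sugars when no added value exists.
    missing_label_mode: when a record has no reference NOVA group
        ("screening" use), either apply the nutrient model to every record
        with a panel ("apply_all") or fall back to additives only
        ("additive_only").
    """

    sweetener_excluded: bool = True
    use_declared_total_as_added: bool = True
    missing_label_mode: str = "apply_all"  # or "additive_only"

    def __post_init__(self):
        if self.missing_label_mode not in ("apply_all", "additive_only"):
            raise ValueError(f"unknown missing_label_mode {self.missing_label_mode!r}")


@dataclass(frozen=True)
class ClassificationResult:
    product_id: str
    has_cosmetic_additive: bool
    has_flavor_or_color: bool
    npm_applicable: bool
    npm_any_excess: bool
    combined_flag: bool
    criteria_fired: frozenset[str]
    note: str = ""


def combined_flag(profile: AdditiveProfile, npm: NPMResult) -> ClassificationResult:
    """The UPF-identification disjunction for one product."""
    criteria = set()
    if profile.has_cosmetic_additive:
        criteria.add("cosmetic_additive")
    if npm.applicable and npm.any_excess:
        criteria.add("critical_nutrient_excess")
    return ClassificationResult(
        product_id=profile.product_id,
        has_cosmetic_additive=profile.has_cosmetic_additive,
        has_flavor_or_color=profile.has_flavor_or_color,
        npm_applicable=npm.applicable,
        npm_any_excess=npm.applicable and npm.any_excess,
        combined_flag=bool(criteria),
        criteria_fired=frozenset(criteria),
    )


@dataclass
class ClassifyOutput:
    results: pd.DataFrame
    excluded: list[tuple[str, list[ValidationIssue]]]
    warnings: list[ValidationIssue]
    counts: dict[str, int] = field(default_factory=dict)


def _panel_missing(record: ProductRecord) -> bool:
    facts = record.facts
    return all(
        getattr(facts, name) is None
        for name in (
            "total_fat_g",
            "sat_fat_g",
            "trans_fat_g",
            "sodium_mg",
            "total_sugars_g",
            "added_sugars_g",
        )
    )


def classify_catalog(
    records: Sequence[ProductRecord],
    lexicon: Lexicon,
    npm_config: Optional[NPMConfig] = None,
    sugar_ref: Optional[SugarReferenceTable] = None,
    policies: Optional[ClassifyPolicies] = None,
) -> ClassifyOutput:
    """Run the full per-catalog classification.

    Records failing validation are excluded and listed separately; row order
    follows input order.  Deterministic: same inputs, same table.
    """
    npm_config = npm_config or NPMConfig()
    policies = policies or ClassifyPolicies()

    rows = []
    excluded: list[tuple[str, list[ValidationIssue]]] = []
    warnings: list[ValidationIssue] = []
    if not records:
        logger.warning("empty catalog: nothing to classify")

    for record in records:
        issues = validate_record(record)
        errors = [i for i in issues if i.level == "error"]
        warnings.extend(i for i in issues if i.level == "warning")
        if errors:
            excluded.append((record.product_id, errors))
            continue

        profile = additive_profile(
            record, lexicon, sweetener_excluded=policies.sweetener_excluded
        )
        added_g, source = estimate_added_sugars(
            record, sugar_ref, use_declared_total=policies.use_declared_total_as_added
        )
        free_g = free_sugars(added_g, record)

        applicable: Optional[bool] = None
        if record.nova_group is None:
            applicable = policies.missing_label_mode == "apply_all"
        npm = evaluate_npm(
            record, profile, free_g, npm_config, sugar_source=source, applicable=applicable
        )
        result = combined_flag(profile, npm)

        note = ""
        if _panel_missing(record) and not record.ingredients_text.strip():
            note = "insufficient data"
        rows.append(
            {
                "product_id": record.product_id,
                "subgroup": record.subgroup,
                "nova_group": record.nova_group,
                "has_cosmetic_additive": result.has_cosmetic_additive,
                "has_flavor_or_color": result.has_flavor_or_color,
                "npm_applicable": result.npm_applicable,
                "npm_any_excess": result.npm_any_excess,
                "combined_flag": result.combined_flag,
                "criteria_fired": ";".join(sorted(result.criteria_fired)),
                "sugar_source": npm.sugar_source,
                "note": note,
            }
        )

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    counts = {
        "input": len(records),
        "classified": len(rows),
        "excluded": len(excluded),
        "combined_flag_true": int(results["combined_flag"].sum()) if len(rows) else 0,
    }
    logger.info(
        "classified %d/%d records (%d excluded, %d flagged)",
        counts["classified"],
        counts["input"],
        counts["excluded"],
        counts["combined_flag_true"],
    )
    return ClassifyOutput(results=results, excluded=excluded, warnings=warnings, counts=counts)
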