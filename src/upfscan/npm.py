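"""PAHO nutrient-profile-model evaluation.

The model flags a product as excessive in a critical nutrient via
energy-relative thresholds: free sugars contributing ≥ 10% of total energy,
total fat ≥ 30%, saturated fat ≥ 10%, trans fat ≥ 1% (4 kcal/g for sugars,
9 kcal/g for fats), and sodium at ≥ 1 mg per kcal.  Non-sugar sweeteners
count by presence alone.  The model applies only to processed foods and
ultra-processed products (NOVA groups 3–4); unprocessed foods and culinary
ingredients are outside its scope by design.

All thresholds live in :class:`NPMConfig` so jurisdictional variants stay
configuration, not code.  Missing is never zero: an undeclared nutrient
yields a missing flag, not an excess.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .additives import AdditiveProfile, fold_text, normalize_ingredient_text
from .catalog import ProductRecord

__all__ = [
    "NPMConfig",
    "NPMResult",
    "SugarReferenceTable",
    "UndefinedFractionError",
    "percent_energy",
    "estimate_added_sugars",
    "free_sugars",
    "with_juice_sugars",
    "detect_trans_fat_sources",
    "evaluate_npm",
    "default_npm_config",
]

DEFAULT_TRANS_KEYWORDS = (
    "hydrogenated vegetable fat",
    "partially hydrogenated fat",
    "hydrogenated vegetable oil",
    "hydrogenated",
    "gordura vegetal hidrogenada",
    "gordura parcialmente hidrogenada",
    "oleo vegetal hidrogenado",
    "hidrogenada",
    "hidrogenado",
)


class UndefinedFractionError(ValueError):
    """Energy is zero, so a nutrient's energy fraction is undefined."""


class NPMConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    kcal_per_g_sugar: float = 4.0
    kcal_per_g_fat: float = 9.0
    free_sugar_energy_threshold: float = 0.10
    total_fat_energy_threshold: float = 0.30
    sat_fat_energy_threshold: float = 0.10
    trans_fat_energy_threshold: float = 0.01
    sodium_mg_per_kcal_threshold: float = 1.0
    zero_energy_sodium_rule: str = "excess_if_any_sodium"  # or "never_excess"
    trans_source_keywords: tuple[str, ...] = DEFAULT_TRANS_KEYWORDS

    @field_validator(
        "kcal_per_g_sugar",
        "kcal_per_g_fat",
        "free_sugar_energy_threshold",
        "total_fat_energy_threshold",
        "sat_fat_energy_threshold",
        "trans_fat_energy_threshold",
        "sodium_mg_per_kcal_threshold",
    )
    @classmethod
    def _positive(cls, value: float) -> float:
        if value <= 0:
            raise ValueError("thresholds and energy densities must be > 0")
        return value

    @field_validator("trans_source_keywords")
    @classmethod
    def _nonempty(cls, value: tuple[str, ...]) -> tuple[str, ...]:
        if not value:
            raise ValueError("trans_source_keywords must be non-empty")
        return value

    @field_validator("zero_energy_sodium_rule")
    @classmethod
    def _rule(cls, value: str) -> str:
        if value not in ("excess_if_any_sodium", "never_excess"):
            raise ValueError(f"unknown zero_energy_sodium_rule {value!r}")
        return value

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NPMConfig":
        with open(path, encoding="utf-8") as handle:
            payload = yaml.safe_load(handle) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        payload = self.model_dump()
        payload["trans_source_keywords"] = list(payload["trans_source_keywords"])
        with open(path, "w", encoding="utf-8") as handle:
            yaml.safe_dump(payload, handle, sort_keys=False, allow_unicode=True)


def default_npm_config() -> NPMConfig:
    from importlib.resources import files

    return NPMConfig.from_yaml(files("upfscan.data") / "npm_paho_default.yaml")


class SugarReferenceTable:
    """Per-subgroup reference added-sugar content (g per 100 g/mL) used to
    impute sugars for products that do not declare them.

    The shipped table is an illustrative fixture; the real study imputed from
    a food-composition table via a published estimation method, which this
    pluggable interface stands in for.
    """

    def __init__(self, values: Optional[dict[str, float]] = None):
        self.values = dict(values or {})
        for subgroup, grams in self.values.items():
            if grams < 0:
                raise ValueError(f"negative reference sugars for {subgroup!r}: {grams}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SugarReferenceTable":
        values: dict[str, float] = {}
        with open(path, encoding="utf-8") as handle:
            for row in csv.DictReader(handle):
                values[row["subgroup"]] = float(row["added_sugars_g_per_100"])
        return cls(values)

    def get(self, subgroup: str) -> Optional[float]:
        return self.values.get(subgroup)


def percent_energy(nutrient_g: float, kcal_per_g: float, energy_kcal: float) -> float:
    """Fraction of total energy contributed by ``nutrient_g`` grams.

    Basis-free: per-100 g and per-100 mL records behave identically because
    both numerator and denominator refer to the same portion.
    """
    if nutrient_g < 0:
        raise ValueError("nutrient quantity must be non-negative")
    if energy_kcal <= 0:
        raise UndefinedFractionError("energy is zero; fraction undefined")
    return nutrient_g * kcal_per_g / energy_kcal


def estimate_added_sugars(
    record: ProductRecord,
    ref: Optional[SugarReferenceTable] = None,
    use_declared_total: bool = True,
) -> tuple[Optional[float], str]:
    """Added sugars (g) and provenance: declared > declared-total proxy >
    subgroup imputation > missing.

    ``use_declared_total`` treats a voluntarily declared total-sugars value
    as an upper proxy for added sugars when no added-sugars value exists.
    """
    facts = record.facts
    if facts.added_sugars_g is not None:
        return facts.added_sugars_g, "declared"
    if use_declared_total and facts.total_sugars_g is not None:
        return facts.total_sugars_g, "declared"
    if ref is not None:
        value = ref.get(record.subgroup)
        if value is not None:
            return value, "imputed"
    return None, "missing"


def free_sugars(
    added_g: Optional[float],
    record: Optional[ProductRecord] = None,
    policy: Optional[Callable[[Optional[float], Optional[ProductRecord]], Optional[float]]] = None,
) -> Optional[float]:
    """Free sugars from added sugars.  Default policy: free = added.

    Alternative policies (e.g. adding juice-derived sugars) plug in as a
    callable taking (added_g, record).
    """
    if policy is None:
        return added_g
    return policy(added_g, record)


def with_juice_sugars(juice_sugars_g: float):
    """Extended free-sugar policy adding a fixed juice-derived term."""

    def policy(added_g: Optional[float], record: Optional[ProductRecord]) -> Optional[float]:
        if added_g is None:
            return juice_sugars_g if juice_sugars_g > 0 else None
        return added_g + juice_sugars_g

    return policy


def detect_trans_fat_sources(tokens: Sequence[str], config: NPMConfig) -> bool:
    """True when any token contains a configured trans-fat-source keyword
    (diacritic/case-insensitive substring)."""
    keywords = [fold_text(k) for k in config.trans_source_keywords]
    return any(keyword in token for token in tokens for keyword in keywords)


@dataclass(frozen=True)
class NPMResult:
    product_id: str
    applicable: bool
    excess_free_sugars: Optional[bool]
    excess_sodium: Optional[bool]
    excess_total_fat: Optional[bool]
    excess_sat_fat: Optional[bool]
    trans_fat_present: Optional[bool]
    sweetener_present: Optional[bool]
    any_excess: bool
    sugar_source: str  # declared | imputed | missing

    @property
    def flags(self) -> dict[str, Optional[bool]]:
        return {
            "excess_free_sugars": self.excess_free_sugars,
            "excess_sodium": self.excess_sodium,
            "excess_total_fat": self.excess_total_fat,
            "excess_sat_fat": self.excess_sat_fat,
            "trans_fat_present": self.trans_fat_present,
            "sweetener_present": self.sweetener_present,
        }


def _energy_fraction_flag(
    grams: Optional[float], kcal_per_g: float, energy: float, threshold: float
) -> Optional[bool]:
    if grams is None:
        return None
    if energy > 0:
        return percent_energy(grams, kcal_per_g, energy) >= threshold
    # Zero-energy product declaring a positive quantity: the fraction
    # diverges, treated as excess (conservative, mirrors the sodium rule).
    return grams > 0


def evaluate_npm(
    record: ProductRecord,
    profile: AdditiveProfile,
    free_sugars_g: Optional[float],
    config: Optional[NPMConfig] = None,
    sugar_source: str = "missing",
    applicable: Optional[bool] = None,
) -> NPMResult:
    """Apply the model to one record.

    ``applicable`` defaults to NOVA group ∈ {3, 4}; callers in screening mode
    (no reference labels) may force it.  Threshold comparisons use ≥
    semantics: a value exactly at a threshold is flagged.
    """
    config = config or NPMConfig()
    if applicable is None:
        applicable = record.nova_group in (3, 4)
    if not applicable:
        return NPMResult(
            product_id=record.product_id,
            applicable=False,
            excess_free_sugars=None,
            excess_sodium=None,
            excess_total_fat=None,
            excess_sat_fat=None,
            trans_fat_present=None,
            sweetener_present=None,
            any_excess=False,
            sugar_source=sugar_source,
        )

    facts = record.facts
    energy = facts.energy_kcal

    sugars = _energy_fraction_flag(
        free_sugars_g, config.kcal_per_g_sugar, energy, config.free_sugar_energy_threshold
    )
    total_fat = _energy_fraction_flag(
        facts.total_fat_g, config.kcal_per_g_fat, energy, config.total_fat_energy_threshold
    )
    sat_fat = _energy_fraction_flag(
        facts.sat_fat_g, config.kcal_per_g_fat, energy, config.sat_fat_energy_threshold
    )

    if facts.sodium_mg is None:
        sodium: Optional[bool] = None
    elif energy > 0:
        sodium = facts.sodium_mg / energy >= config.sodium_mg_per_kcal_threshold
    elif config.zero_energy_sodium_rule == "excess_if_any_sodium":
        sodium = facts.sodium_mg > 0
    else:
        sodium = False

    tokens = normalize_ingredient_text(record.ingredients_text)
    keyword_hit = detect_trans_fat_sources(tokens, config)
    declared_trans = _energy_fraction_flag(
        facts.trans_fat_g, config.kcal_per_g_fat, energy, config.trans_fat_energy_threshold
    )
    if keyword_hit:
        trans: Optional[bool] = True
    else:
        trans = declared_trans  # None when grams undeclared and no keyword

    sweetener = profile.has_sweetener

    flags = (sugars, sodium, total_fat, sat_fat, trans, sweetener)
    any_excess = any(flag is True for flag in flags)
    return NPMResult(
        product_id=record.product_id,
        applicable=True,
        excess_free_sugars=sugars,
        excess_sodium=sodium,
        excess_total_fat=total_fat,
        excess_sat_fat=sat_fat,
        trans_fat_present=trans,
        sweetener_present=sweetener,
        any_excess=any_excess,
        sugar_source=sugar_source,
    )
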