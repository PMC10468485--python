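"""Seeded generator of synthetic label catalogs with known ground truth.

Large reference label catalogs are typically restricted, so the pipeline is exercised on
synthetic catalogs that emulate its statistical structure: the NOVA-group
mix, per-group rates of cosmetic additives and nutrient excess (with the
overlap between the two criteria parameterized by an odds ratio), and the
low voluntary sugar-declaration rate.

Generation is flag-level first: for each item the generator draws which
criteria the item should satisfy, then *materializes* a label (ingredient
text and panel numbers) that realizes exactly those flags.  The drawn flags
are emitted as a hidden truth table, so tests can require the pipeline to
recover them item by item — any mismatch is a bug in the generator or the
pipeline, with no statistical slack.

Synthetic runs use no sugar-imputation reference: items that do not declare
sugars have a missing sugar flag, and drawn nutrient excess is realized
through per-item quantities (sodium, fats, trans keywords, sweeteners, or
declared sugars).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .additives import COSMETIC_CLASSES, SWEETENER, Lexicon, resolve_function
from .catalog import Basis, NutritionFacts, ProductRecord

__all__ = [
    "DistributionSpec",
    "SubgroupSpec",
    "SynthConfig",
    "ItemDraw",
    "joint_bernoulli",
    "generate_catalog",
    "materialize_item",
    "default_synth_config",
]

EXCESS_CHANNELS = ("sodium", "total_fat", "sat_fat", "trans", "sweetener", "sugars")

DEFAULT_FILLERS = ("agua", "farinha de trigo", "acucar", "sal", "oleo de soja")


def joint_bernoulli(
    pA: float, pB: float, odds_ratio: float
) -> tuple[float, float, float, float]:
    """Joint cell probabilities (p11, p10, p01, p00) of two Bernoulli flags
    with given marginals and 2×2 odds ratio.

    Solves the Plackett quadratic for p11 and keeps the root inside the
    Fréchet bounds, so the marginals are reproduced exactly.  Degenerate
    marginals (0 or 1) force independence (the odds ratio is unidentifiable
    there).
    """
    if not (0.0 <= pA <= 1.0 and 0.0 <= pB <= 1.0):
        raise ValueError("marginals must be in [0, 1]")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be > 0")
    if pA in (0.0, 1.0) or pB in (0.0, 1.0) or odds_ratio == 1.0:
        p11 = pA * pB
    else:
        s = 1.0 + (pA + pB) * (odds_ratio - 1.0)
        disc = s * s - 4.0 * odds_ratio * (odds_ratio - 1.0) * pA * pB
        if disc < 0:
            raise ValueError("no feasible joint for these marginals and odds ratio")
        p11 = (s - math.sqrt(disc)) / (2.0 * (odds_ratio - 1.0))
    lower = max(0.0, pA + pB - 1.0)
    upper = min(pA, pB)
    if p11 < lower - 1e-9 or p11 > upper + 1e-9:
        raise ValueError("no feasible joint for these marginals and odds ratio")
    p11 = min(max(p11, lower), upper)
    p10 = pA - p11
    p01 = pB - p11
    p00 = 1.0 - pA - pB + p11
    return p11, p10, p01, p00


class DistributionSpec(BaseModel):
    """A small distribution spec: lognormal(mu, sigma), truncnorm(mean, sd,
    low, high), or point(value)."""

    model_config = ConfigDict(frozen=True)

    family: str = "lognormal"
    params: dict[str, float] = {}

    @field_validator("family")
    @classmethod
    def _family(cls, value: str) -> str:
        if value not in ("lognormal", "truncnorm", "point"):
            raise ValueError(f"unknown distribution family {value!r}")
        return value

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "point":
            return float(self.params.get("value", 0.0))
        if self.family == "lognormal":
            mu = self.params.get("mu", 5.3)
            sigma = self.params.get("sigma", 0.4)
            return float(rng.lognormal(mu, sigma))
        mean = self.params.get("mean", 0.0)
        sd = self.params.get("sd", 1.0)
        low = self.params.get("low", -math.inf)
        high = self.params.get("high", math.inf)
        for _ in range(100):
            value = rng.normal(mean, sd)
            if low <= value <= high:
                return float(value)
        return float(min(max(mean, low), high))


DEFAULT_ENERGY = DistributionSpec(family="lognormal", params={"mu": 5.3, "sigma": 0.4})


class SubgroupSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    nova_group: int
    weight: float
    p_cosmetic: float = 0.0
    p_excess: float = 0.0  # ignored for NOVA groups 1-2 (model not applied)
    odds_ratio: float = 1.0
    p_sugar_declared: float = 0.108
    p_additive_class: dict[str, float] = {}
    nutrient_models: dict[str, DistributionSpec] = {}
    ingredient_templates: tuple[str, ...] = DEFAULT_FILLERS

    @model_validator(mode="after")
    def _check(self) -> "SubgroupSpec":
        if self.nova_group not in (1, 2, 3, 4):
            raise ValueError(f"{self.name}: nova_group must be 1-4")
        if not 0 < self.weight <= 1:
            raise ValueError(f"{self.name}: weight must be in (0, 1]")
        for field in ("p_cosmetic", "p_excess", "p_sugar_declared"):
            value = getattr(self, field)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{self.name}: {field} must be in [0, 1]")
        for cls_name, prob in self.p_additive_class.items():
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"{self.name}: p_additive_class[{cls_name}] out of [0, 1]")
        return self

    @property
    def applies_npm(self) -> bool:
        return self.nova_group in (3, 4)

    def energy_model(self) -> DistributionSpec:
        return self.nutrient_models.get("energy_kcal", DEFAULT_ENERGY)


class SynthConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    subgroups: tuple[SubgroupSpec, ...]
    n_items: int
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "SynthConfig":
        if self.n_items <= 0:
            raise ValueError("n_items must be > 0")
        total = sum(s.weight for s in self.subgroups)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"subgroup weights must sum to 1 (got {total:.6f})")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "SynthConfig":
        with open(path, encoding="utf-8") as handle:
            payload = yaml.safe_load(handle)
        payload.update(overrides)
        return cls(**payload)


def default_synth_config(**overrides) -> SynthConfig:
    """The shipped configuration emulating a large supermarket label census."""
    from importlib.resources import files

    return SynthConfig.from_yaml(files("upfscan.data") / "synth_default.yaml", **overrides)


@dataclass(frozen=True)
class ItemDraw:
    """Flag-level draws for one item, before materialization."""

    cosmetic: bool
    excess: bool
    sugar_declared: bool
    excess_channel: Optional[str]
    additive_classes: tuple[str, ...]


def _entries_by_class(lexicon: Lexicon, subgroup: str) -> dict[str, list[int]]:
    by_class: dict[str, list[int]] = {}
    for index, entry in enumerate(lexicon.entries):
        function = resolve_function(entry, subgroup)
        by_class.setdefault(function, []).append(index)
    return by_class


def _draw_item(spec: SubgroupSpec, rng: np.random.Generator) -> ItemDraw:
    sugar_declared = rng.random() < spec.p_sugar_declared
    if spec.applies_npm:
        p11, p10, p01, _ = joint_bernoulli(spec.p_excess, spec.p_cosmetic, spec.odds_ratio)
        u = rng.random()
        if u < p11:
            excess, cosmetic = True, True
        elif u < p11 + p10:
            excess, cosmetic = True, False
        elif u < p11 + p10 + p01:
            excess, cosmetic = False, True
        else:
            excess, cosmetic = False, False
    else:
        excess = False
        cosmetic = rng.random() < spec.p_cosmetic

    channel: Optional[str] = None
    if excess:
        channels = ["sodium", "total_fat", "sat_fat", "trans", "sweetener"]
        if sugar_declared:
            channels.append("sugars")
        channel = channels[int(rng.integers(len(channels)))]

    classes: list[str] = []
    cosmetic_pool = {
        name: prob
        for name, prob in spec.p_additive_class.items()
        if name in COSMETIC_CLASSES and name != SWEETENER
    }
    other_pool = {
        name: prob
        for name, prob in spec.p_additive_class.items()
        if name not in COSMETIC_CLASSES
    }
    if cosmetic:
        for name in sorted(cosmetic_pool):
            if rng.random() < cosmetic_pool[name]:
                classes.append(name)
        if not any(name in cosmetic_pool for name in classes):
            names = sorted(cosmetic_pool) or ["color"]
            weights = np.array([cosmetic_pool.get(n, 1.0) for n in names])
            weights = weights / weights.sum() if weights.sum() > 0 else None
            classes.append(str(rng.choice(names, p=weights)))
    for name in sorted(other_pool):
        if rng.random() < other_pool[name]:
            classes.append(name)
    return ItemDraw(
        cosmetic=cosmetic,
        excess=excess,
        sugar_declared=sugar_declared,
        excess_channel=channel,
        additive_classes=tuple(classes),
    )


def materialize_item(
    spec: SubgroupSpec,
    draws: ItemDraw,
    rng: np.random.Generator,
    lexicon: Lexicon,
    product_id: str,
) -> ProductRecord:
    """Build a label record realizing the drawn flags exactly.

    Nutrient quantities are placed with a wide margin on the intended side of
    every threshold, so panel rounding can never flip a flag; additive names
    are drawn from the lexicon entries whose resolved function in this
    subgroup is the drawn class.
    """
    energy = float(np.clip(spec.energy_model().sample(rng), 60.0, 600.0))

    # Baseline fractions safely below every threshold.
    total_fat_frac = rng.uniform(0.05, 0.20)
    sat_fat_frac = rng.uniform(0.01, 0.05)
    sodium_ratio = rng.uniform(0.1, 0.5)
    sugar_frac = rng.uniform(0.01, 0.07)

    extra_tokens: list[str] = []
    channel = draws.excess_channel
    if channel == "total_fat":
        total_fat_frac = rng.uniform(0.35, 0.55)
    elif channel == "sat_fat":
        sat_fat_frac = rng.uniform(0.12, 0.20)
        total_fat_frac = min(sat_fat_frac + rng.uniform(0.03, 0.08), 0.28)
    elif channel == "sodium":
        sodium_ratio = rng.uniform(1.1, 2.0)
    elif channel == "sugars":
        sugar_frac = rng.uniform(0.12, 0.30)
    elif channel == "trans":
        extra_tokens.append("gordura vegetal hidrogenada")

    by_class = _entries_by_class(lexicon, spec.name)
    additive_names: list[str] = []
    wanted = list(draws.additive_classes)
    if channel == "sweetener":
        wanted.append(SWEETENER)
    for cls_name in wanted:
        candidates = by_class.get(cls_name)
        if not candidates:
            raise ValueError(
                f"subgroup {spec.name!r} draws class {cls_name!r} but the lexicon has "
                f"no entry resolving to it"
            )
        entry = lexicon.entries[candidates[int(rng.integers(len(candidates)))]]
        additive_names.append(entry.canonical_name)

    n_fillers = int(rng.integers(2, min(5, len(spec.ingredient_templates) + 1)))
    filler_idx = rng.choice(len(spec.ingredient_templates), size=n_fillers, replace=False)
    fillers = [spec.ingredient_templates[i] for i in filler_idx]
    ingredients = ", ".join(fillers + extra_tokens + additive_names)

    sat_g = sat_fat_frac * energy / 9.0
    total_g = max(total_fat_frac * energy / 9.0, sat_g)
    facts = NutritionFacts(
        basis=Basis.per_100g,
        energy_kcal=round(energy, 1),
        total_fat_g=round(total_g, 2),
        sat_fat_g=round(sat_g, 2),
        trans_fat_g=0.0,
        sodium_mg=round(sodium_ratio * energy, 1),
        total_sugars_g=round(sugar_frac * energy / 4.0, 2) if draws.sugar_declared else None,
        added_sugars_g=None,
    )
    return ProductRecord(
        product_id=product_id,
        name=f"{spec.name} item {product_id}",
        subgroup=spec.name,
        nova_group=spec.nova_group,
        facts=facts,
        ingredients_text=ingredients,
    )


def generate_catalog(
    config: SynthConfig, lexicon: Lexicon
) -> tuple[list[ProductRecord], pd.DataFrame]:
    """Generate a catalog plus its hidden truth table.

    A single seeded stream is consumed in a fixed per-item order, so the same
    config and seed always reproduce the identical catalog byte for byte.
    """
    rng = np.random.default_rng(config.seed)
    weights = np.array([s.weight for s in config.subgroups], dtype=float)
    weights = weights / weights.sum()

    records: list[ProductRecord] = []
    truth_rows = []
    for index in range(config.n_items):
        spec = config.subgroups[int(rng.choice(len(config.subgroups), p=weights))]
        draws = _draw_item(spec, rng)
        product_id = f"SKU{index:05d}"
        record = materialize_item(spec, draws, rng, lexicon, product_id)
        records.append(record)
        truth_rows.append(
            {
                "product_id": product_id,
                "subgroup": spec.name,
                "nova_group": spec.nova_group,
                "true_cosmetic": draws.cosmetic,
                "true_excess": draws.excess,
                "true_combined": draws.cosmetic or draws.excess,
                "excess_channel": draws.excess_channel or "",
                "sugar_declared": draws.sugar_declared,
            }
        )
    return records, pd.DataFrame(truth_rows)
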