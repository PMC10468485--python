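"""Ingredient-list parsing and cosmetic-additive detection.

Additives printed in a label's ingredient list are matched against a
functional lexicon (name, synonyms, INS code, functional classes).  Under the
NOVA taxonomy an additive is *cosmetic* when its function is sensory appeal
rather than safety: flavors, flavor enhancers, colors, emulsifiers,
emulsifying salts, sweeteners, thickeners, anti-foaming, bulking,
carbonating, foaming, gelling and glazing agents.  Sweeteners are both a
cosmetic class and a nutrient-profile criterion; by default they are counted
only on the nutrient-profile side so their frequency is not double-counted
(``sweetener_excluded`` policy flag).

Multifunction additives are resolved per product category: an explicit
``category_overrides`` entry for the product's subgroup wins, otherwise the
entry's ``default_function`` is used — mirroring the practice of assigning
the function most commonly authorized for that food category.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "FLAVOR",
    "FLAVOR_ENHANCER",
    "COLOR",
    "SWEETENER",
    "COSMETIC_CLASSES",
    "FLAVOR_OR_COLOR_CLASSES",
    "AdditiveLexiconEntry",
    "Lexicon",
    "LexiconError",
    "AdditiveMatch",
    "AdditiveProfile",
    "fold_text",
    "normalize_ingredient_text",
    "load_lexicon",
    "default_lexicon",
    "detect_additives",
    "resolve_function",
    "additive_profile",
]

# Functional-class vocabulary (free strings in the lexicon; these are the
# classes the starter lexicon uses).
FLAVOR = "flavor"
FLAVOR_ENHANCER = "flavor_enhancer"
COLOR = "color"
EMULSIFIER = "emulsifier"
EMULSIFYING_SALT = "emulsifying_salt"
SWEETENER = "sweetener"
THICKENER = "thickener"
ANTI_FOAMING = "anti_foaming"
BULKING = "bulking"
CARBONATING = "carbonating"
FOAMING = "foaming"
GELLING = "gelling"
GLAZING = "glazing"

#: The NOVA cosmetic classes.  Any function outside this set (preservative,
#: antioxidant, acidulant, stabilizer, raising agent, ...) is non-cosmetic by
#: default; per-entry ``is_cosmetic_by_function`` can override either way.
COSMETIC_CLASSES = frozenset(
    {
        FLAVOR,
        FLAVOR_ENHANCER,
        COLOR,
        EMULSIFIER,
        EMULSIFYING_SALT,
        SWEETENER,
        THICKENER,
        ANTI_FOAMING,
        BULKING,
        CARBONATING,
        FOAMING,
        GELLING,
        GLAZING,
    }
)

FLAVOR_OR_COLOR_CLASSES = frozenset({FLAVOR, FLAVOR_ENHANCER, COLOR})


class LexiconError(Exception):
    pass


def fold_text(text: str) -> str:
    """Lowercase, strip diacritics (NFKD) and collapse whitespace."""
    decomposed = unicodedata.normalize("NFKD", text)
    stripped = "".join(ch for ch in decomposed if not unicodedata.combining(ch))
    return re.sub(r"\s+", " ", stripped.lower()).strip()


def normalize_ingredient_text(text: str) -> list[str]:
    """Split free ingredient text into folded tokens.

    Commas and semicolons separate ingredients; parenthesized/bracketed
    sub-lists (compound ingredients) are flattened into additional tokens so
    that additives declared inside them are scanned.
    """
    folded = fold_text(text)
    flattened = re.sub(r"[()\[\]]", ",", folded)
    tokens = []
    for piece in re.split(r"[,;]", flattened):
        token = piece.strip().strip(".").strip()
        if token:
            tokens.append(token)
    return tokens


class AdditiveLexiconEntry(BaseModel):
    model_config = ConfigDict(frozen=True)

    canonical_name: str
    synonyms: tuple[str, ...] = ()
    ins_code: Optional[str] = None
    functions: tuple[str, ...]
    default_function: str
    category_overrides: dict[str, str] = {}
    is_cosmetic_by_function: dict[str, bool] = {}

    @model_validator(mode="after")
    def _check(self) -> "AdditiveLexiconEntry":
        if not self.functions:
            raise ValueError(f"{self.canonical_name}: functions list is empty")
        if self.default_function not in self.functions:
            raise ValueError(
                f"{self.canonical_name}: default_function {self.default_function!r} "
                f"not among functions {list(self.functions)}"
            )
        for subgroup, function in self.category_overrides.items():
            if function not in self.functions:
                raise ValueError(
                    f"{self.canonical_name}: override for {subgroup!r} names unknown "
                    f"function {function!r}"
                )
        # Fill the cosmetic map from the NOVA class list, then require cover.
        cosmetic = dict(self.is_cosmetic_by_function)
        for function in self.functions:
            cosmetic.setdefault(function, function in COSMETIC_CLASSES)
        object.__setattr__(self, "is_cosmetic_by_function", cosmetic)
        return self

    def patterns(self) -> list[str]:
        out = [fold_text(self.canonical_name)]
        out.extend(fold_text(s) for s in self.synonyms)
        if self.ins_code:
            out.append(fold_text(self.ins_code))
        return [p for p in out if p]


class Lexicon:
    """A loaded additive lexicon with a pattern → entry index.

    Normalized patterns must be unique across entries; a synonym shared by
    two entries is rejected at load time, naming both.
    """

    def __init__(self, entries: Sequence[AdditiveLexiconEntry]):
        self.entries: list[AdditiveLexiconEntry] = list(entries)
        self._pattern_to_entry: dict[str, int] = {}
        for index, entry in enumerate(self.entries):
            for pattern in entry.patterns():
                other = self._pattern_to_entry.get(pattern)
                if other is not None and other != index:
                    raise LexiconError(
                        f"synonym collision: {pattern!r} appears in both "
                        f"{self.entries[other].canonical_name!r} and {entry.canonical_name!r}"
                    )
                self._pattern_to_entry[pattern] = index
        self._compiled = {
            pattern: re.compile(r"(?<![a-z0-9])" + re.escape(pattern) + r"(?![a-z0-9])")
            for pattern in self._pattern_to_entry
        }

    def __len__(self) -> int:
        return len(self.entries)

    def entry_index(self, entry: AdditiveLexiconEntry) -> int:
        return self.entries.index(entry)

    def iter_patterns(self):
        return self._pattern_to_entry.items()

    def pattern_matches(self, pattern: str, token: str) -> bool:
        return self._compiled[pattern].search(token) is not None


def load_lexicon(path: str | Path) -> Lexicon:
    with open(path, encoding="utf-8") as handle:
        payload = json.load(handle)
    raw_entries = payload["entries"] if isinstance(payload, dict) else payload
    try:
        entries = [AdditiveLexiconEntry(**raw) for raw in raw_entries]
    except ValueError as exc:
        raise LexiconError(str(exc)) from exc
    return Lexicon(entries)


def default_lexicon() -> Lexicon:
    """The starter lexicon shipped with the package (Anvisa-style classes,
    Portuguese + English names; illustrative, user-extensible)."""
    from importlib.resources import files

    return load_lexicon(files("upfscan.data") / "lexicon_starter.json")


@dataclass(frozen=True)
class AdditiveMatch:
    entry: AdditiveLexiconEntry
    matched_text: str
    position: int  # token index of the first occurrence
    resolved_function: str
    is_cosmetic: bool
    is_sweetener: bool


def _token_hits(token: str, lexicon: Lexicon) -> list[tuple[str, int]]:
    """All (pattern, entry_index) matching one token, longest-dominant.

    A pattern that is a proper substring of another matching pattern in the
    same token is suppressed ("partially hydrogenated fat" beats
    "hydrogenated"); disjoint patterns all survive, so one token naming two
    colors yields two matches.
    """
    hits = [
        (pattern, index)
        for pattern, index in lexicon.iter_patterns()
        if lexicon.pattern_matches(pattern, token)
    ]
    kept = []
    for pattern, index in hits:
        dominated = any(
            pattern != other and pattern in other for other, _ in hits
        )
        if not dominated:
            kept.append((pattern, index))
    kept.sort(key=lambda item: (-len(item[0]), item[1]))
    return kept


def resolve_function(entry: AdditiveLexiconEntry, subgroup: str) -> str:
    """Category override for the product's subgroup, else the default function."""
    return entry.category_overrides.get(subgroup, entry.default_function)


def detect_additives(
    tokens: Sequence[str], lexicon: Lexicon, subgroup: str = ""
) -> list[AdditiveMatch]:
    """Match normalized tokens against the lexicon.

    Matching is case/diacritic-insensitive (tokens are assumed folded) over
    canonical names, synonyms and INS codes, aligned to word boundaries.
    Each lexicon entry contributes at most one match per product; repeats
    across tokens collapse to the first occurrence.
    """
    matched: dict[int, AdditiveMatch] = {}
    for position, token in enumerate(tokens):
        for pattern, index in _token_hits(token, lexicon):
            if index in matched:
                continue
            entry = lexicon.entries[index]
            function = resolve_function(entry, subgroup)
            matched[index] = AdditiveMatch(
                entry=entry,
                matched_text=pattern,
                position=position,
                resolved_function=function,
                is_cosmetic=entry.is_cosmetic_by_function[function],
                is_sweetener=function == SWEETENER,
            )
    return sorted(matched.values(), key=lambda m: (m.position, -len(m.matched_text)))


@dataclass(frozen=True)
class AdditiveProfile:
    product_id: str
    matches: tuple[AdditiveMatch, ...]
    has_cosmetic_additive: bool
    has_flavor_or_color: bool
    has_sweetener: bool


def additive_profile(record, lexicon: Lexicon, sweetener_excluded: bool = True) -> AdditiveProfile:
    """Scan one record's ingredient list and derive the product-level flags.

    ``sweetener_excluded`` (default) keeps sweeteners out of
    ``has_cosmetic_additive`` — they are counted via the nutrient-profile
    model instead, so one additive never fires both criteria.
    """
    tokens = normalize_ingredient_text(record.ingredients_text)
    matches = detect_additives(tokens, lexicon, subgroup=record.subgroup)
    has_sweetener = any(m.is_sweetener for m in matches)
    has_cosmetic = any(
        m.is_cosmetic and not (m.is_sweetener and sweetener_excluded) for m in matches
    )
    has_flavor_or_color = any(
        m.resolved_function in FLAVOR_OR_COLOR_CLASSES for m in matches
    )
    return AdditiveProfile(
        product_id=record.product_id,
        matches=tuple(matches),
        has_cosmetic_additive=has_cosmetic,
        has_flavor_or_color=has_flavor_or_color,
        has_sweetener=has_sweetener,
    )
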