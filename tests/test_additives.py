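"""Additive parsing: normalization, lexicon validation, matching precedence,
function resolution, and the cosmetic/sweetener policy flags."""

import json
import re

import numpy as np
import pytest

from upfscan.additives import (
    COSMETIC_CLASSES,
    Lexicon,
    LexiconError,
    AdditiveLexiconEntry,
    additive_profile,
    detect_additives,
    load_lexicon,
    normalize_ingredient_text,
    resolve_function,
)


@pytest.mark.parametrize(
    "text,expected",
    [
        ("Açúcar, CORANTE caramelo", ["acucar", "corante caramelo"]),
        ("", []),
        ("farinha (trigo, ferro), sal", ["farinha", "trigo", "ferro", "sal"]),
        ("leite;  água ,", ["leite", "agua"]),
    ],
)
def test_normalize_ingredient_text(text, expected):
    assert normalize_ingredient_text(text) == expected


def entry(**kwargs):
    base = dict(functions=["color"], default_function="color")
    base.update(kwargs)
    return base


def load_from(tmp_path, entries):
    path = tmp_path / "lex.json"
    path.write_text(json.dumps({"entries": entries}), encoding="utf-8")
    return load_lexicon(path)


def test_color_entry_is_cosmetic_by_default(tmp_path):
    lex = load_from(tmp_path, [entry(canonical_name="corante x")])
    assert lex.entries[0].is_cosmetic_by_function["color"] is True


def test_default_function_must_be_listed(tmp_path):
    with pytest.raises(LexiconError, match="default_function"):
        load_from(tmp_path, [entry(canonical_name="x", default_function="flavor")])


def test_override_naming_unknown_function_rejected(tmp_path):
    with pytest.raises(LexiconError, match="unknown"):
        load_from(
            tmp_path,
            [entry(canonical_name="x", category_overrides={"Cheese": "flavor"})],
        )


def test_synonym_collision_names_both_entries(tmp_path):
    with pytest.raises(LexiconError) as exc:
        load_from(
            tmp_path,
            [
                entry(canonical_name="lecitina de soja", synonyms=["lecitina"],
                      functions=["emulsifier"], default_function="emulsifier"),
                entry(canonical_name="lecitina de girassol", synonyms=["lecitina"],
                      functions=["emulsifier"], default_function="emulsifier"),
            ],
        )
    assert "lecitina de soja" in str(exc.value)
    assert "lecitina de girassol" in str(exc.value)


def test_two_colors_in_one_token(lexicon):
    tokens = normalize_ingredient_text(
        "wheat flour enriched with iron and folic acid, egg white, eggs, "
        "and natural colorings urucum and turmeric"
    )
    matches = detect_additives(tokens, lexicon)
    assert sorted(m.entry.canonical_name for m in matches) == ["curcuma", "urucum"]
    assert all(m.resolved_function == "color" for m in matches)


def test_plain_ingredients_match_nothing(lexicon):
    assert detect_additives(["water", "salt"], lexicon) == []


def test_longest_match_precedence(tmp_path):
    lex = load_from(
        tmp_path,
        [
            entry(canonical_name="hydrogenated", functions=["emulsifier"],
                  default_function="emulsifier"),
            entry(canonical_name="partially hydrogenated fat", functions=["emulsifier"],
                  default_function="emulsifier"),
        ],
    )
    matches = detect_additives(["partially hydrogenated fat"], lex)
    assert [m.entry.canonical_name for m in matches] == ["partially hydrogenated fat"]


def test_generic_color_dominated_by_specific_name(lexicon):
    matches = detect_additives(["corante caramelo"], lexicon)
    assert [m.entry.canonical_name for m in matches] == ["corante caramelo"]


def test_ins_code_matching(lexicon):
    matches = detect_additives(["espessante ins 415"], lexicon)
    assert [m.entry.canonical_name for m in matches] == ["goma xantana"]


def test_resolve_function_override_then_default(lexicon):
    carragena = next(e for e in lexicon.entries if e.canonical_name == "carragena")
    assert resolve_function(carragena, "Dairy beverages") == "thickener"
    assert resolve_function(carragena, "Sweets in general") == "gelling"
    tartrazina = next(e for e in lexicon.entries if e.canonical_name == "tartrazina")
    assert resolve_function(tartrazina, "anything") == "color"


@pytest.mark.parametrize(
    "ingredients,cosmetic,flavor_color,sweetener",
    [
        ("agua, sucralose", False, False, True),  # sweetener counted on the NPM side only
        ("agua, tartrazina", True, True, False),
        ("agua, benzoato de sodio", False, False, False),
        ("agua, goma guar", True, False, False),
    ],
)
def test_profile_flags(lexicon, record_factory, ingredients, cosmetic, flavor_color, sweetener):
    profile = additive_profile(record_factory(ingredients=ingredients), lexicon)
    assert profile.has_cosmetic_additive is cosmetic
    assert profile.has_flavor_or_color is flavor_color
    assert profile.has_sweetener is sweetener


def test_sweetener_counts_as_cosmetic_when_policy_off(lexicon, record_factory):
    record = record_factory(ingredients="agua, aspartame")
    assert additive_profile(record, lexicon).has_cosmetic_additive is False
    assert additive_profile(record, lexicon, sweetener_excluded=False).has_cosmetic_additive is True


def test_policy_off_truth_set_is_superset(lexicon, record_factory):
    ingredient_lists = [
        "agua, sucralose",
        "agua, tartrazina",
        "agua, benzoato de sodio",
        "agua, aspartame, goma guar",
        "farinha, sal",
    ]
    for ingredients in ingredient_lists:
        record = record_factory(ingredients=ingredients)
        default = additive_profile(record, lexicon).has_cosmetic_additive
        inclusive = additive_profile(record, lexicon, sweetener_excluded=False).has_cosmetic_additive
        assert inclusive or not default  # default true-set ⊆ inclusive true-set


def test_flags_invariant_to_token_permutation_and_noise(lexicon, record_factory):
    base = "acucar, tartrazina, goma xantana, benzoato de sodio"
    permuted = "goma xantana, benzoato de sodio, acucar, tartrazina"
    noisy = base + ", polpa de fruta, agua mineral"
    profiles = [
        additive_profile(record_factory(ingredients=text), lexicon)
        for text in (base, permuted, noisy)
    ]
    flags = {
        (p.has_cosmetic_additive, p.has_flavor_or_color, p.has_sweetener) for p in profiles
    }
    assert len(flags) == 1
    assert {m.entry.canonical_name for m in profiles[0].matches} == {
        m.entry.canonical_name for m in profiles[2].matches
    }


def brute_force_profile_flags(tokens, lexicon, subgroup):
    """Independent oracle: try every entry pattern against every token with
    the same word-boundary rule, then apply substring dominance per token."""
    per_token = []
    for token in tokens:
        hits = []
        for index, lex_entry in enumerate(lexicon.entries):
            for pattern in lex_entry.patterns():
                if re.search(r"(?<![a-z0-9])" + re.escape(pattern) + r"(?![a-z0-9])", token):
                    hits.append((pattern, index))
        kept = [
            (pattern, index)
            for pattern, index in hits
            if not any(pattern != other and pattern in other for other, _ in hits)
        ]
        per_token.extend(kept)
    matched_entries = {index for _, index in per_token}
    functions = {
        resolve_function(lexicon.entries[index], subgroup) for index in matched_entries
    }
    cosmetic = any(
        lexicon.entries[index].is_cosmetic_by_function[resolve_function(lexicon.entries[index], subgroup)]
        and resolve_function(lexicon.entries[index], subgroup) != "sweetener"
        for index in matched_entries
    )
    return {
        "cosmetic": cosmetic,
        "flavor_or_color": bool(functions & {"flavor", "flavor_enhancer", "color"}),
        "sweetener": "sweetener" in functions,
    }


def test_matcher_agrees_with_brute_force_oracle(lexicon, record_factory):
    rng = np.random.default_rng(20230830)
    names = [e.canonical_name for e in lexicon.entries]
    fillers = ["agua", "farinha de trigo", "acucar", "sal", "polpa de tomate", "leite"]
    for _ in range(50):
        k_add = int(rng.integers(0, 4))
        k_fill = int(rng.integers(1, 4))
        parts = list(rng.choice(names, size=k_add, replace=False)) + list(
            rng.choice(fillers, size=k_fill, replace=False)
        )
        rng.shuffle(parts)
        text = ", ".join(parts)
        record = record_factory(ingredients=text, subgroup="Dairy beverages")
        tokens = normalize_ingredient_text(text)
        expected = brute_force_profile_flags(tokens, lexicon, "Dairy beverages")
        profile = additive_profile(record, lexicon)
        assert profile.has_cosmetic_additive == expected["cosmetic"], text
        assert profile.has_flavor_or_color == expected["flavor_or_color"], text
        assert profile.has_sweetener == expected["sweetener"], text


def test_starter_lexicon_covers_every_cosmetic_class(lexicon):
    covered = set()
    for lex_entry in lexicon.entries:
        for function in lex_entry.functions:
            covered.add(function)
    assert COSMETIC_CLASSES <= covered
    assert {"preservative", "antioxidant", "acidulant"} <= covered
    assert len(lexicon) >= 40
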