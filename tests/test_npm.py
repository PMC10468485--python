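"""Nutrient-profile model: energy fractions, thresholds (≥ semantics),
sugar estimation fallbacks, trans-fat keywords, and the applicability gate."""

import pytest

from upfscan.additives import additive_profile
from upfscan.npm import (
    NPMConfig,
    SugarReferenceTable,
    UndefinedFractionError,
    detect_trans_fat_sources,
    estimate_added_sugars,
    evaluate_npm,
    free_sugars,
    percent_energy,
    with_juice_sugars,
)


@pytest.fixture(scope="module")
def config():
    return NPMConfig()


def evaluate(record, lexicon, config, free_g=None, source="missing", applicable=None):
    profile = additive_profile(record, lexicon)
    return evaluate_npm(record, profile, free_g, config, sugar_source=source, applicable=applicable)


@pytest.mark.parametrize(
    "grams,kcal_per_g,energy,expected",
    [(20, 4, 500, 0.16), (0, 9, 250, 0.0), (10, 4, 400, 0.10)],
)
def test_percent_energy_arithmetic(grams, kcal_per_g, energy, expected):
    assert percent_energy(grams, kcal_per_g, energy) == pytest.approx(expected)


def test_percent_energy_zero_energy_is_undefined():
    with pytest.raises(UndefinedFractionError):
        percent_energy(5, 4, 0)


def test_estimate_added_sugars_fallback_chain(record_factory):
    ref = SugarReferenceTable({"Sweet cookies": 25.0})
    declared = record_factory(added_sugars_g=12.0)
    assert estimate_added_sugars(declared, ref) == (12.0, "declared")

    total_only = record_factory(total_sugars_g=18.0)
    assert estimate_added_sugars(total_only, ref) == (18.0, "declared")
    assert estimate_added_sugars(total_only, ref, use_declared_total=False) == (25.0, "imputed")

    undeclared = record_factory()
    assert estimate_added_sugars(undeclared, ref) == (25.0, "imputed")

    unknown_subgroup = record_factory(subgroup="Mystery")
    assert estimate_added_sugars(unknown_subgroup, ref) == (None, "missing")


def test_free_sugars_policies():
    assert free_sugars(12.0) == 12.0
    assert free_sugars(None) is None
    assert free_sugars(5.0, policy=with_juice_sugars(3.0)) == 8.0


@pytest.mark.parametrize(
    "tokens,expected",
    [
        (["sugar", "hydrogenated vegetable oil", "cocoa"], True),
        (["sunflower oil"], False),
        (["gordura vegetal hidrogenada"], True),
        (["oleo parcialmente hidrogenado"], True),
    ],
)
def test_trans_fat_keyword_detection(tokens, expected, config):
    assert detect_trans_fat_sources(tokens, config) is expected


def test_not_applicable_outside_groups_3_4(record_factory, lexicon, config):
    result = evaluate(record_factory(nova_group=1, sodium_mg=900.0), lexicon, config)
    assert result.applicable is False
    assert result.any_excess is False
    assert result.excess_sodium is None


def test_sodium_ratio_excess(record_factory, lexicon, config):
    result = evaluate(record_factory(energy_kcal=250.0, sodium_mg=300.0), lexicon, config)
    assert result.excess_sodium is True  # 1.2 mg/kcal >= 1.0
    assert result.any_excess is True


def test_all_zero_record_has_no_excess(record_factory, lexicon, config):
    record = record_factory(
        energy_kcal=100.0, total_fat_g=0.0, sat_fat_g=0.0, trans_fat_g=0.0, sodium_mg=0.0
    )
    result = evaluate(record, lexicon, config, free_g=0.0, source="declared")
    assert result.any_excess is False
    assert result.flags["trans_fat_present"] is False


@pytest.mark.parametrize(
    "kwargs,free_g,flag",
    [
        # value exactly at the threshold is flagged (>= semantics), all five criteria
        ({"energy_kcal": 400.0}, 10.0, "excess_free_sugars"),  # 40/400 = 0.10
        ({"energy_kcal": 300.0, "total_fat_g": 10.0}, None, "excess_total_fat"),  # 90/300 = 0.30
        ({"energy_kcal": 360.0, "sat_fat_g": 4.0}, None, "excess_sat_fat"),  # 36/360 = 0.10
        ({"energy_kcal": 900.0, "trans_fat_g": 1.0}, None, "trans_fat_present"),  # 9/900 = 0.01
        ({"energy_kcal": 250.0, "sodium_mg": 250.0}, None, "excess_sodium"),  # ratio = 1.0
    ],
)
def test_threshold_boundaries_inclusive(record_factory, lexicon, config, kwargs, free_g, flag):
    result = evaluate(record_factory(**kwargs), lexicon, config, free_g=free_g)
    assert result.flags[flag] is True


def test_missing_nutrient_never_flags(record_factory, lexicon, config):
    result = evaluate(record_factory(energy_kcal=100.0), lexicon, config)
    assert result.excess_sodium is None
    assert result.excess_total_fat is None
    assert result.trans_fat_present is None
    assert result.any_excess is False


def test_sweetener_presence_fires_model(record_factory, lexicon, config):
    result = evaluate(record_factory(ingredients="agua, sucralose"), lexicon, config)
    assert result.sweetener_present is True
    assert result.any_excess is True


def test_trans_keyword_fires_even_with_zero_declared(record_factory, lexicon, config):
    record = record_factory(trans_fat_g=0.0, ingredients="gordura vegetal hidrogenada, sal")
    assert evaluate(record, lexicon, config).trans_fat_present is True


def test_monotone_in_each_nutrient(record_factory, lexicon, config):
    energy = 400.0
    for field, low, high in [
        ("sodium_mg", 100.0, 900.0),
        ("total_fat_g", 5.0, 25.0),
        ("sat_fat_g", 2.0, 9.0),
    ]:
        flag_low = evaluate(record_factory(energy_kcal=energy, **{field: low}), lexicon, config)
        flag_high = evaluate(record_factory(energy_kcal=energy, **{field: high}), lexicon, config)
        name = {
            "sodium_mg": "excess_sodium",
            "total_fat_g": "excess_total_fat",
            "sat_fat_g": "excess_sat_fat",
        }[field]
        # increasing the nutrient can only turn the flag on, never off
        assert not (flag_low.flags[name] is True and flag_high.flags[name] is False)


def test_scale_invariance_of_energy_fractions(record_factory, lexicon, config):
    base = dict(energy_kcal=200.0, total_fat_g=8.0, sat_fat_g=3.0, sodium_mg=150.0)
    scaled = {k: v * 3.7 for k, v in base.items()}
    r1 = evaluate(record_factory(**base), lexicon, config, free_g=4.0)
    r2 = evaluate(record_factory(**scaled), lexicon, config, free_g=4.0 * 3.7)
    assert r1.flags == r2.flags


def test_zero_energy_sodium_rule(record_factory, lexicon):
    record = record_factory(energy_kcal=0.0, sodium_mg=40.0)
    default = evaluate(record, lexicon, NPMConfig())
    assert default.excess_sodium is True
    lenient = evaluate(record, lexicon, NPMConfig(zero_energy_sodium_rule="never_excess"))
    assert lenient.excess_sodium is False


def test_config_yaml_round_trip(tmp_path):
    config = NPMConfig(sodium_mg_per_kcal_threshold=1.2)
    path = tmp_path / "npm.yaml"
    config.to_yaml(path)
    assert NPMConfig.from_yaml(path) == config


def test_config_rejects_nonpositive_threshold():
    with pytest.raises(ValueError):
        NPMConfig(total_fat_energy_threshold=0.0)
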