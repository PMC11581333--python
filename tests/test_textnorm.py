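import pytest
from hypothesis import given, settings, strategies as st

from oudharmony import textnorm
from oudharmony.textnorm import (canonicalize_drug, categorize_drug,
                                 collapse_daily, default_lexicon,
                                 impute_missing_drink_amount,
                                 parse_standard_drinks)
from oudharmony.synth import _HEAVY_TEMPLATES, _LIGHT_TEMPLATES


class TestCanonicalize:
    @pytest.mark.parametrize("raw, expected", [
        ("Vicodin/Percocet", ["hydrocodone", "oxycodone"]),
        ("Percocets and Vicodin", ["oxycodone", "hydrocodone"]),
        ("adderall 5 mg", ["amphetamine"]),
        ("adderall - 2 tabs", ["amphetamine"]),
        ("", []),
        ("extacy", ["mdma"]),
        ("crack cocaine", ["crack"]),
        ("totally novel substance", ["unknown"]),
    ])
    def test_examples(self, raw, expected):
        assert canonicalize_drug(raw) == expected

    def test_at_least_five_ecstasy_spellings(self):
        lex = default_lexicon()
        spellings = [v for v, c in lex.variants.items() if c == "mdma"]
        assert len(spellings) >= 5

    def test_idempotent_on_canonical_tokens(self):
        lex = default_lexicon()
        for token in sorted(lex.canonical_tokens()):
            if "_" in token:  # multi-word tokens round-trip via their spelling
                continue
            assert canonicalize_drug(token) == [token]


class TestCategorize:
    @pytest.mark.parametrize("token, category", [
        ("crack", "Cocaine"),
        ("cocaine", "Cocaine"),
        ("methamphetamine", "Amphetamine"),
        ("opiates", "Heroin"),      # nonspecific structured item reads as heroin
        ("oxycodone", "Opioid"),
        ("mdma", "MDMA"),
    ])
    def test_examples(self, token, category):
        assert categorize_drug(token) == category

    def test_unknown_token_raises(self):
        with pytest.raises(KeyError):
            categorize_drug("not-a-drug")

    def test_category_map_total_over_lexicon(self):
        lex = default_lexicon()
        for token in lex.canonical_tokens():
            assert categorize_drug(token)


class TestCollapse:
    def test_crack_and_powder_one_entry(self):
        out = collapse_daily([(1, 5, "Cocaine"), (1, 5, "Cocaine")])
        assert out == [(1, 5, "Cocaine")]

    def test_preserves_distinct_categories(self):
        mentions = [(1, 5, "Cocaine"), (1, 5, "Heroin"), (1, 5, "Cocaine")]
        out = collapse_daily(mentions)
        assert [c for _, _, c in out] == ["Cocaine", "Heroin"]

    def test_empty(self):
        assert collapse_daily([]) == []

    @given(st.lists(st.sampled_from(["Cocaine", "Heroin", "THC", "Alcohol"]),
                    max_size=20))
    @settings(deadline=None, derandomize=True)
    def test_never_grows_and_never_drops(self, cats):
        out = collapse_daily([(1, 0, c) for c in cats])
        assert len(out) <= len(cats)
        assert {c for _, _, c in out} == set(cats)


class TestStandardDrinks:
    @pytest.mark.parametrize("raw, expected", [
        ("1/2 12oz beer", 0.5),
        ("6pk beer & 1/2 gal. rum", 49.0),
        ("many glasses of wine", 5.0),
        ("2 beers", 2.0),
        ("1/2 beer", 0.5),
        ("1/2 of a beer", 0.5),
        ("3 shots of vodka", 3.0),
        ("1 1/2 glasses of wine", 1.5),
    ])
    def test_printed_anchors_and_basics(self, raw, expected):
        assert parse_standard_drinks(raw).value == expected

    def test_empty_and_unparseable_are_flagged_missing(self):
        assert parse_standard_drinks("").flag == "missing"
        res = parse_standard_drinks("weird stuff")
        assert res.value is None and res.flag == "unparseable"

    @given(st.integers(min_value=0, max_value=30))
    @settings(deadline=None, derandomize=True)
    def test_n_beers_scale_consistency(self, n):
        assert parse_standard_drinks(f"{n} beers").value == float(n)

    def test_deterministic(self):
        s = "6pk beer & 1/2 gal. rum"
        assert parse_standard_drinks(s) == parse_standard_drinks(s)

    @pytest.mark.parametrize("template, value",
                             list(_LIGHT_TEMPLATES) + list(_HEAVY_TEMPLATES))
    def test_generator_grammar_agrees_with_parser(self, template, value):
        # the synthetic generator's alcohol strings carry their value by
        # construction; the parser must recover every one of them
        assert parse_standard_drinks(template).value == value


class TestImputation:
    def test_consistent_heavy_pattern_imputes_median(self):
        res = impute_missing_drink_amount([6, 7, 8])
        assert res.value == 7 and res.imputed == 1

    def test_inconsistent_pattern_stays_missing(self):
        res = impute_missing_drink_amount([1, 1, 9])
        assert res.value is None and res.flag == "pattern-inconsistent"

    def test_no_known_amounts(self):
        res = impute_missing_drink_amount([])
        assert res.value is None and res.imputed == 0

    def test_consistent_light_pattern(self):
        res = impute_missing_drink_amount([1, 2, 2, 3])
        assert res.value == 2 and res.imputed == 1
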