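import pytest
from hypothesis import given
from hypothesis import strategies as st

from asthmasteps import (
    ParsedDose,
    daily_dose,
    extract_frequency,
    extract_quantity,
    extract_strength,
    impute_by_mode,
    validate_strength,
)
from asthmasteps.dose_text import MICROGRAM_VALUES, MILLIGRAM_VALUES


class TestExtractFrequency:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("TAKE TWO PUFFS TWICE DAILY", 2),
            ("4 TIMES A DAY WHEN REQUIRED", 4),
            ("ONE TABLET ONCE DAILY", 1),
            ("TWO PUFFS MORNING AND NIGHT", 2),
            ("1 PUFF BD", 2),
            ("ONE TDS", 3),
            ("", None),
            ("USE AS DIRECTED", None),
        ],
    )
    def test_keyword_rules(self, frequency_keywords, text, expected):
        assert extract_frequency(text, frequency_keywords) == expected

    def test_longest_phrase_wins(self, frequency_keywords):
        # "4 TIMES" must beat any shorter hit inside the same text
        assert extract_frequency("INHALE 4 TIMES DAILY", frequency_keywords) == 4


class TestExtractQuantity:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("TAKE TWO PUFFS TWICE DAILY", 2),
            ("2 PUFS AT NIGHT", 2),            # single-'f' typo form
            ("INHALE ONE PUFF EVERY MORNING", 1),
            ("3 TO BE TAKEN EACH DAY", 3),
            ("2 P TWICE DAILY", 2),            # 'p' shorthand needs a following space
            ("FOUR DAILY", 4),
            ("USE AS DIRECTED", None),
            ("5 PUFFS DAILY", None),           # the rule stops at four
            ("", None),
        ],
    )
    def test_anchored_number_rules(self, text, expected):
        assert extract_quantity(text) == expected


class TestExtractStrength:
    def test_suffix_safety_exhaustive(self):
        """Every printed value parses to itself, never to a proper suffix."""
        for value in MICROGRAM_VALUES:
            for unit in ("MCG", "MICROGRAM", " MCG"):
                got = extract_strength(f"PRODUCT {value:g}{unit} INHALER")
                assert got == (float(value), None), f"{value}{unit}"
        for value in MILLIGRAM_VALUES:
            for unit in ("MG", "MILLIGRAM", " MG"):
                got = extract_strength(f"PRODUCT {value:g}{unit} TABLETS")
                assert got == (float(value) * 1000.0, None), f"{value}{unit}"

    @pytest.mark.parametrize(
        "text, expected",
        [
            ("FLUTICASONE 250MCG INHALER", (250.0, None)),
            ("FLUTICASONE 250 MCG INHALER", (250.0, None)),
            ("BUDESONIDE 0.5MG RESPULES", (500.0, None)),
            ("USE ONE PUFF DAILY", None),
        ],
    )
    def test_unit_forms(self, text, expected):
        assert extract_strength(text) == expected

    def test_combo_slash_components(self):
        assert extract_strength("SERETIDE 250/25 EVOHALER", is_combo=True) == (250.0, 25.0)
        assert extract_strength("SYMBICORT 100/6 TURBOHALER", is_combo=True) == (100.0, 6.0)
        # slash form only applies to combination products
        assert extract_strength("SERETIDE 250/25 EVOHALER", is_combo=False) is None

    def test_micrograms_searched_before_milligrams(self):
        assert extract_strength("PRODUCT 500MCG") == (500.0, None)
        assert extract_strength("PRODUCT 500 MG") is None  # 500 not a printed mg value

    @given(st.sampled_from(MICROGRAM_VALUES), st.booleans(), st.booleans())
    def test_spacing_and_case_do_not_change_result(self, value, space, lower):
        text = f"product {value:g}{' ' if space else ''}mcg"
        assert extract_strength(text if lower else text.upper()) == (float(value), None)


class TestImputeByMode:
    def test_mode_fills_absent(self):
        parsed = [
            ("drug", ParsedDose(frequency_per_day=2)),
            ("drug", ParsedDose(frequency_per_day=2)),
            ("drug", ParsedDose(frequency_per_day=1)),
            ("drug", ParsedDose()),
        ]
        out = impute_by_mode(parsed)
        assert out[3][1].frequency_per_day == 2
        assert out[3][1].imputed_frequency

    def test_tie_breaks_to_smallest(self):
        parsed = [("drug", ParsedDose(frequency_per_day=f)) for f in (1, 1, 2, 2)]
        parsed.append(("drug", ParsedDose()))
        assert impute_by_mode(parsed)[-1][1].frequency_per_day == 1

    def test_fully_observed_table_unchanged(self):
        parsed = [("drug", ParsedDose(2, 2, 100.0))]
        assert impute_by_mode(parsed) == parsed

    def test_no_observed_values_stays_absent(self):
        out = impute_by_mode([("drug", ParsedDose())])
        assert out[0][1].frequency_per_day is None
        assert not out[0][1].imputed_frequency

    def test_empty_input(self):
        assert impute_by_mode([]) == []

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["a", "b"]),
                st.one_of(st.none(), st.integers(min_value=1, max_value=4)),
            ),
            max_size=20,
        )
    )
    def test_observed_values_conserved_and_missingness_resolved(self, rows):
        """Imputation never alters observed values; per-key missingness drops
        to zero whenever the key has at least one observed value."""
        parsed = [(k, ParsedDose(frequency_per_day=v)) for k, v in rows]
        out = impute_by_mode(parsed)
        for (k_in, d_in), (k_out, d_out) in zip(parsed, out):
            assert k_in == k_out
            if d_in.frequency_per_day is not None:
                assert d_out.frequency_per_day == d_in.frequency_per_day
                assert not d_out.imputed_frequency
        observed_keys = {k for k, v in rows if v is not None}
        for k, d in out:
            if k in observed_keys:
                assert d.frequency_per_day is not None


class TestStrengthValidationAndDailyDose:
    def test_licensed_strength_ok(self, catalogue_map):
        entry = catalogue_map["budesonide"]
        assert validate_strength(entry, 200.0)
        assert not validate_strength(entry, 10000.0)

    def test_daily_dose_product_and_propagation(self):
        assert daily_dose(ParsedDose(2, 2, 100.0)) == 400.0
        assert daily_dose(ParsedDose(1, 1, 500.0)) == 500.0
        assert daily_dose(ParsedDose(None, 2, 100.0)) is None
        assert daily_dose(ParsedDose(2, 2, None)) is None

    @given(st.integers(1, 4), st.integers(1, 4), st.sampled_from(MICROGRAM_VALUES))
    def test_daily_dose_monotone_in_each_component(self, f, q, s):
        base = daily_dose(ParsedDose(f, q, float(s)))
        assert daily_dose(ParsedDose(f + 1, q, float(s))) > base
        assert daily_dose(ParsedDose(f, q + 1, float(s))) > base
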