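import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from perijoint import schema
from perijoint.published_counts import ELIGIBILITY_FLOW, eligibility_records


class TestEncodePreterm:
    @pytest.mark.parametrize(
        "weeks,expected",
        [(36, 1), (36.9, 1), (37, 0), (42, 0), (20, 1), (45, 0)],
    )
    def test_threshold_at_37_completed_weeks(self, weeks, expected):
        assert schema.encode_preterm(weeks) == expected

    def test_missing_propagates(self):
        assert np.isnan(schema.encode_preterm(None))
        assert np.isnan(schema.encode_preterm(float("nan")))

    @pytest.mark.parametrize("weeks", [10, 19.9, 45.1, 99])
    def test_rejects_implausible_gestational_age(self, weeks):
        with pytest.raises(schema.SchemaError):
            schema.encode_preterm(weeks)


class TestCooccurrence:
    def test_bijection_between_binary_pairs_and_codes(self):
        codes = {schema.encode_cooccurrence(p, d) for p, d in itertools.product((0, 1), repeat=2)}
        assert codes == {0, 1, 2, 3}
        for p, d in itertools.product((0, 1), repeat=2):
            code = schema.encode_cooccurrence(p, d)
            assert schema.decode_cooccurrence(code) == (p, d)

    @pytest.mark.parametrize(
        "p,d,code", [(0, 0, 0), (1, 1, 1), (0, 1, 2), (1, 0, 3)]
    )
    def test_published_coding(self, p, d, code):
        assert schema.encode_cooccurrence(p, d) == code

    def test_missing_component_propagates(self):
        assert np.isnan(schema.encode_cooccurrence(np.nan, 1))
        assert np.isnan(schema.encode_cooccurrence(0, None))

    def test_non_binary_rejected(self):
        with pytest.raises(schema.SchemaError):
            schema.encode_cooccurrence(2, 0)


class TestEligibility:
    def test_toy_fixture_tally(self, toy_records):
        kept, tally = schema.apply_eligibility(toy_records)
        assert len(kept) == 5
        assert (tally.missing_mother_id, tally.multiple_gestation, tally.unknown_plurality) == (2, 3, 0)

    def test_tally_sums_to_input(self, toy_records):
        _, tally = schema.apply_eligibility(toy_records)
        assert (
            tally.missing_mother_id + tally.multiple_gestation + tally.unknown_plurality + tally.kept
            == tally.total
        )

    def test_no_exclusions_on_clean_singletons(self):
        df = pd.DataFrame(
            {
                "mother_id": ["a", "b"],
                "birth_index": [1, 1],
                "year": [2010, 2011],
                "gestational_age_weeks": [38.0, 35.0],
                "perinatal_death": [0.0, 1.0],
                "plurality": ["singleton", "singleton"],
            }
        )
        kept, tally = schema.apply_eligibility(df)
        assert len(kept) == 2 and tally.kept == 2
        assert tally.missing_mother_id == tally.multiple_gestation == tally.unknown_plurality == 0

    def test_empty_input(self):
        df = pd.DataFrame(columns=["mother_id", "birth_index", "year",
                                   "gestational_age_weeks", "perinatal_death", "plurality"])
        kept, tally = schema.apply_eligibility(df)
        assert len(kept) == 0 and tally.total == 0

    def test_published_cohort_flow(self):
        kept, tally = schema.apply_eligibility(eligibility_records())
        assert tally.total == ELIGIBILITY_FLOW["total"]
        assert tally.kept == 55_907

    def test_order_preserved(self, toy_records):
        kept, _ = schema.apply_eligibility(toy_records)
        assert list(kept["mother_id"]) == sorted(kept["mother_id"], key=list(toy_records["mother_id"]).index)


class TestValidation:
    def test_unknown_category_rejected(self, toy_records):
        bad = toy_records.assign(anc_visits="sometimes")
        with pytest.raises(schema.SchemaError, match="anc_visits"):
            schema.validate_registry(bad)

    def test_noncontiguous_birth_index_rejected(self, toy_records):
        bad = toy_records.copy()
        bad.loc[5, "birth_index"] = 3
        with pytest.raises(schema.SchemaError, match="birth_index"):
            schema.validate_registry(bad)

    def test_both_age_binnings_accepted(self, toy_records):
        for cat in ("25-34", "25-29"):
            schema.validate_registry(toy_records.assign(maternal_age=cat))


class TestRoundTrip:
    def test_csv_round_trip_preserves_outcomes(self, tmp_path, small_bivariate_registry):
        df = small_bivariate_registry
        path = tmp_path / "registry.csv"
        schema.write_registry(df, path)
        back = schema.load_registry(path)
        for col in ("preterm", "perinatal_death", "cooccurrence"):
            a, b = df[col].to_numpy(float), back[col].to_numpy(float)
            assert ((a == b) | (np.isnan(a) & np.isnan(b))).all()


@settings(max_examples=50, deadline=None)
@given(
    weeks=st.one_of(st.none(), st.floats(min_value=20, max_value=45)),
    death=st.one_of(st.none(), st.integers(min_value=0, max_value=1)),
)
def test_derived_cooccurrence_consistent_with_components(weeks, death):
    """cooccurrence is missing iff a component is, else encodes the pair."""
    df = pd.DataFrame(
        {
            "mother_id": ["m1"],
            "birth_index": [1],
            "year": [2010],
            "gestational_age_weeks": [np.nan if weeks is None else weeks],
            "perinatal_death": [np.nan if death is None else float(death)],
        }
    )
    out = schema.derive_outcomes(df)
    pt, co = out.loc[0, "preterm"], out.loc[0, "cooccurrence"]
    if weeks is None or death is None:
        assert np.isnan(co)
    else:
        assert co == schema.encode_cooccurrence(int(pt), death)
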