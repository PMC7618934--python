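"""Scoring engine: dichotomization, risk labels, zero-variance filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import shortform as sf
from shortform.instrument import InstrumentError

from conftest import make_cohort, make_record, make_toy_instrument


@pytest.fixture
def item():
    return sf.ItemDefinition(item_id="x", scale="unusual_thought_content")


class TestDichotomizeItem:
    def test_truth_table_matches_rule_for_all_49_pairs(self):
        """Exhaustive oracle: enumerate every (severity, frequency) pair and
        compare against a direct statement of the cutoff rule."""
        for lo, hi, fmin, psych in [(3, 5, 3, 6), (2, 4, 1, 5), (1, 6, 0, None)]:
            if psych is not None and psych <= hi:
                continue
            it = sf.ItemDefinition(
                item_id="x",
                scale="non_bizarre_ideas",
                severity_positive_range=(lo, hi),
                frequency_min=fmin,
                psychosis_severity_min=psych,
            )
            for sev in range(7):
                for freq in range(7):
                    expected = int(lo <= sev <= hi and freq >= fmin)
                    assert sf.dichotomize_item(sev, freq, it) == expected

    def test_psychosis_level_severity_is_not_a_positive_indicator(self):
        it = sf.ItemDefinition(
            item_id="x", scale="unusual_thought_content",
            severity_positive_range=(3, 5), frequency_min=3, psychosis_severity_min=6,
        )
        assert sf.dichotomize_item(6, 6, it) == 0
        assert sf.dichotomize_item(4, 4, it) == 1
        assert sf.dichotomize_item(0, 0, it) == 0

    @pytest.mark.parametrize("sev,freq", [(-1, 0), (7, 0), (0, -2), (0, 9)])
    def test_out_of_range_ratings_raise_naming_the_item(self, item, sev, freq):
        with pytest.raises(InstrumentError, match="'x'"):
            sf.dichotomize_item(sev, freq, item)


class TestItemDefinitionValidation:
    def test_psychosis_threshold_must_exceed_positive_range(self):
        with pytest.raises(InstrumentError):
            sf.ItemDefinition(
                item_id="x", scale="unusual_thought_content",
                severity_positive_range=(3, 5), psychosis_severity_min=5,
            )

    def test_severity_range_must_be_ordered_and_bounded(self):
        with pytest.raises(InstrumentError):
            sf.ItemDefinition(
                item_id="x", scale="unusual_thought_content",
                severity_positive_range=(5, 3),
            )

    def test_default_instrument_has_four_scales_of_sixty_items(self):
        instr = sf.Instrument.default()
        assert len(instr) == 60
        assert instr.scale_counts == {
            "unusual_thought_content": 13,
            "non_bizarre_ideas": 11,
            "perceptual_abnormalities": 22,
            "disorganized_speech": 14,
        }

    def test_duplicate_item_ids_rejected(self):
        it = sf.ItemDefinition(item_id="x", scale="unusual_thought_content")
        with pytest.raises(InstrumentError, match="duplicate"):
            sf.Instrument(items=[it, it])


class TestFullScaleStatus:
    def test_label_precedence_and_any_item_rule(self):
        instr = make_toy_instrument(4)
        all_zero = make_record(instr, "a")
        one_pos = make_record(instr, "b", positive_items=["it_01"])
        psych = make_record(instr, "c", psychosis_items=["it_02"])
        both = make_record(instr, "d", positive_items=["it_00"], psychosis_items=["it_03"])
        assert sf.full_scale_status(all_zero, instr) == sf.NOT_AT_RISK
        assert sf.full_scale_status(one_pos, instr) == sf.CHR_P  # single item suffices
        assert sf.full_scale_status(psych, instr) == sf.PSYCHOSIS
        assert sf.full_scale_status(both, instr) == sf.PSYCHOSIS  # psychosis overrides

    def test_chr_p_iff_positive_row_sum_and_no_psychosis_item(self, default_cohort):
        ds = default_cohort
        row_sums = ds.binary_matrix.sum(axis=1)
        for pid, label in ds.risk_labels.items():
            if label == sf.CHR_P:
                assert row_sums[pid] >= 1
            elif label == sf.NOT_AT_RISK:
                assert row_sums[pid] == 0

    def test_missing_item_response_is_a_validation_error(self):
        instr = make_toy_instrument(3)
        rec = make_record(instr, "a")
        del rec.severity["it_01"]
        with pytest.raises(InstrumentError, match="missing severity"):
            rec.validate(instr)


class TestDichotomizeCohort:
    def test_all_zero_cohort_scores_to_not_at_risk(self):
        instr = make_toy_instrument(3)
        ds = make_cohort(instr, [("a", [], []), ("b", [], []), ("c", [], [])])
        assert (ds.binary_matrix.to_numpy() == 0).all()
        assert set(ds.risk_labels.values()) == {sf.NOT_AT_RISK}

    def test_single_endorsement_gives_chr_p_and_unit_row_sum(self):
        instr = make_toy_instrument(8)
        ds = make_cohort(instr, [("a", ["it_06"], []), ("b", [], [])])
        assert ds.risk_labels["a"] == sf.CHR_P
        assert ds.binary_matrix.loc["a"].sum() == 1
        assert ds.binary_matrix.loc["a", "it_06"] == 1

    def test_empty_cohort_rejected(self):
        instr = make_toy_instrument(3)
        with pytest.raises(InstrumentError, match="empty"):
            sf.dichotomize_cohort(sf.CohortDataset(instrument=instr, records=[]))

    def test_generated_prevalence_within_three_binomial_se_of_target(self):
        target, n = 0.23, 490
        ds = sf.generate_cohort(sf.GeneratorConfig(seed=1, n_participants=n))
        _X, y = ds.analysis_set()
        se = np.sqrt(target * (1 - target) / n)
        assert abs(y.mean() - target) < 3 * se

    def test_scoring_invariant_to_item_order_permutation(self):
        instr = make_toy_instrument(6)
        specs = [("a", ["it_02"], []), ("b", [], ["it_04"]), ("c", [], [])]
        ds = make_cohort(instr, specs)
        shuffled = sf.Instrument(items=list(reversed(instr.items)))
        ds2 = make_cohort(shuffled, specs)
        assert ds.risk_labels == ds2.risk_labels
        pd.testing.assert_frame_equal(
            ds.binary_matrix, ds2.binary_matrix[ds.binary_matrix.columns]
        )


class TestDropZeroVariance:
    def test_constant_columns_removed_and_reported(self):
        m = pd.DataFrame(
            {"a": [0] * 10, "b": [0, 1] * 5, "c": [0] * 10, "d": [1, 0] * 5}
        )
        reduced, removed = sf.drop_zero_variance(m)
        assert removed == ["a", "c"]
        assert list(reduced.columns) == ["b", "d"]

    def test_no_constant_column_is_identity(self):
        m = pd.DataFrame({"a": [0, 1, 0], "b": [1, 0, 0]})
        reduced, removed = sf.drop_zero_variance(m)
        assert removed == []
        pd.testing.assert_frame_equal(reduced, m)

    def test_all_constant_raises(self):
        m = pd.DataFrame({"a": [0, 0], "b": [1, 1]})
        with pytest.raises(InstrumentError, match="zero-variance"):
            sf.drop_zero_variance(m)

    @given(st.integers(0, 2**32 - 1))
    def test_idempotent_on_random_binary_matrices(self, seed):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(
            rng.integers(0, 2, size=(8, 6)) * rng.integers(0, 2, size=6),
            columns=list("abcdef"),
        )
        if m.nunique().le(1).all():
            return
        once, removed = sf.drop_zero_variance(m)
        twice, removed2 = sf.drop_zero_variance(once)
        assert removed2 == []
        pd.testing.assert_frame_equal(once, twice)


class TestCsvRoundTrip:
    def test_cohort_round_trips_through_wide_csv(self, tmp_path):
        instr = make_toy_instrument(5)
        ds = make_cohort(
            instr,
            [
                ("a", ["it_01"], [], {"sex": "male", "ethnicity_white": False, "age_years": 19.5}),
                ("b", [], ["it_03"], {}),
            ],
        )
        path = tmp_path / "cohort.csv"
        ds.to_csv(path)
        back = sf.CohortDataset.from_csv(path, instr)
        sf.dichotomize_cohort(back)
        assert back.risk_labels == ds.risk_labels
        pd.testing.assert_frame_equal(back.binary_matrix, ds.binary_matrix)
        assert back.records[0].sex == "male"
        assert back.records[0].ethnicity_white is False
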