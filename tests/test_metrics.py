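"""Agreement/discrimination metrics against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import cohen_kappa_score, roc_auc_score

import shortform as sf
from shortform.metrics import MetricError, pool_metrics


def brute_force_c(scores, labels):
    """All-pairs concordance oracle (ties scored 0.5)."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = conc = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                conc += 1
            elif p == q:
                conc += 0.5
    return conc / total


class TestCohensKappa:
    def test_identical_two_class_vectors_give_one(self):
        v = [0, 1, 0, 1, 1]
        assert sf.cohens_kappa(v, v) == 1.0

    def test_hand_computed_2x2_table(self):
        # table [[45, 5], [5, 45]]: p_o = 0.9, p_e = 0.5 -> kappa = 0.8
        a = [1] * 50 + [0] * 50
        b = [1] * 45 + [0] * 5 + [1] * 5 + [0] * 45
        assert sf.cohens_kappa(a, b) == pytest.approx(0.8, abs=1e-12)

    def test_independent_labels_give_kappa_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 10_000)
        b = rng.integers(0, 2, 10_000)
        assert abs(sf.cohens_kappa(a, b)) < 0.05

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=2, max_size=40))
    def test_symmetric_and_matches_sklearn_oracle(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        k_ab = sf.cohens_kappa(a, b)
        assert k_ab == pytest.approx(sf.cohens_kappa(b, a), abs=1e-12)
        oracle = cohen_kappa_score(a, b)
        if not math.isnan(oracle):
            assert k_ab == pytest.approx(oracle, abs=1e-12)

    def test_length_mismatch_raises(self):
        with pytest.raises(MetricError, match="mismatch"):
            sf.cohens_kappa([0, 1], [0, 1, 1])


class TestHarrellC:
    def test_perfect_separation_gives_one(self):
        assert sf.harrell_c([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert sf.harrell_c([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_four_point_example_enumerated_by_hand(self):
        # pairs (0.7 vs 0.2) conc, (0.7 vs 0.5) conc, (0.4 vs 0.2) conc,
        # (0.4 vs 0.5) disc -> 3/4
        assert sf.harrell_c([0.2, 0.7, 0.5, 0.4], [0, 1, 0, 1]) == pytest.approx(0.75)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            return
        assert sf.harrell_c(scores, labels) == pytest.approx(
            brute_force_c(scores, labels), abs=1e-12
        )
        assert sf.harrell_c(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_labels_raise(self):
        with pytest.raises(MetricError, match="both classes"):
            sf.harrell_c([0.1, 0.2], [1, 1])


class TestConfusionMetrics:
    def test_reported_operating_point_of_the_short_form(self):
        """Se 95.6%, Sp 100% -> balanced accuracy 97.8%, PPV 100%."""
        truth = [1] * 45 + [0] * 45
        pred = [1] * 43 + [0] * 2 + [0] * 45
        m = sf.confusion_metrics(pred, truth)
        assert (m.tp, m.fn, m.tn, m.fp) == (43, 2, 45, 0)
        assert m.sensitivity == pytest.approx(43 / 45)
        assert m.specificity == 1.0
        assert m.balanced_accuracy == pytest.approx((43 / 45 + 1) / 2)
        assert m.ppv == 1.0

    def test_perfect_and_inverted_predictions(self):
        truth = [0, 1, 0, 1]
        perfect = sf.confusion_metrics(truth, truth)
        for name in ("sensitivity", "specificity", "balanced_accuracy", "ppv", "npv", "f1"):
            assert getattr(perfect, name) == 1.0
        inverted = sf.confusion_metrics([1 - t for t in truth], truth)
        assert inverted.sensitivity == 0.0
        assert inverted.specificity == 0.0

    def test_undefined_ratio_reported_as_nan_with_warning(self):
        with pytest.warns(UserWarning, match="PPV undefined"):
            m = sf.confusion_metrics([0, 0, 0, 0], [0, 0, 1, 1])
        assert math.isnan(m.ppv)
        assert m.sensitivity == 0.0

    @given(st.integers(0, 2**31 - 1))
    def test_identities_hold_in_every_metric_set(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        truth = rng.integers(0, 2, n)
        pred = rng.integers(0, 2, n)
        if truth.sum() in (0, n):
            return
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = sf.confusion_metrics(pred, truth)
        assert m.tp + m.fp + m.tn + m.fn == n
        if not math.isnan(m.sensitivity) and not math.isnan(m.specificity):
            assert m.balanced_accuracy == (m.sensitivity + m.specificity) / 2
        if not math.isnan(m.f1) and (m.ppv + m.sensitivity) > 0:
            assert m.f1 == pytest.approx(
                2 * m.ppv * m.sensitivity / (m.ppv + m.sensitivity), abs=1e-12
            )


class TestPoolMetrics:
    def test_identical_sets_pool_to_zero_width_interval(self):
        sets = [sf.MetricSet(kappa=0.9, sensitivity=0.8)] * 25
        pooled = pool_metrics(sets)
        assert pooled.mean["kappa"] == pytest.approx(0.9)
        assert pooled.ci_low["kappa"] == pytest.approx(pooled.ci_high["kappa"])

    def test_seeded_normal_draws_match_direct_formula(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0.7, 0.05, 25)
        sets = [sf.MetricSet(sensitivity=v) for v in vals]
        pooled = pool_metrics(sets)
        m = vals.mean()
        half = 1.96 * vals.std(ddof=1) / np.sqrt(25)
        assert pooled.mean["sensitivity"] == pytest.approx(m, abs=1e-12)
        assert pooled.ci_low["sensitivity"] == pytest.approx(m - half, abs=1e-12)
        assert pooled.ci_high["sensitivity"] == pytest.approx(m + half, abs=1e-12)

    def test_missing_values_excluded_from_pooling(self):
        sets = [sf.MetricSet(sensitivity=0.5), sf.MetricSet(sensitivity=math.nan),
                sf.MetricSet(sensitivity=1.0)]
        pooled = pool_metrics(sets)
        assert pooled.mean["sensitivity"] == pytest.approx(0.75)
        assert math.isnan(pooled.mean["kappa"])
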