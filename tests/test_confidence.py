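"""Bayes confidence scoring and threshold abstention."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icccml.confidence import (
    CalibrationError,
    CalibrationSample,
    ConfidenceModel,
    EmpiricalDistribution,
    confidence_score,
    decide,
    fit_conditionals,
    fit_priors,
    summarize_softmax,
)


def samples_from(correct_scores, incorrect_scores):
    return [CalibrationSample(s, True) for s in correct_scores] + [
        CalibrationSample(s, False) for s in incorrect_scores
    ]


class TestSummarizeSoftmax:
    @pytest.mark.parametrize(
        "y,expected",
        [
            ([0.25, 0.25, 0.25, 0.25], 0.25),
            ([0.0, 1.0, 0.0], 1.0),
            ([0.7, 0.2, 0.1], 0.7),
        ],
    )
    def test_returns_max(self, y, expected):
        assert summarize_softmax(y) == pytest.approx(expected)

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError, match="not normalized"):
            summarize_softmax([0.5, 0.2])


class TestPriors:
    @pytest.mark.parametrize(
        "n_correct,n_total,expected",
        [(900, 1000, (0.9, 0.1)), (3, 3, (1.0, 0.0)), (1, 3, (1 / 3, 2 / 3))],
    )
    def test_relative_frequencies(self, n_correct, n_total, expected):
        samples = [
            CalibrationSample(0.5, i < n_correct) for i in range(n_total)
        ]
        p_c, p_i = fit_priors(samples)
        assert (p_c, p_i) == pytest.approx(expected)
        assert p_c + p_i == pytest.approx(1.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fit_priors([])


class TestConditionals:
    def test_separated_strata(self):
        cond_c, cond_i = fit_conditionals(
            samples_from([1.0, 1.0, 1.0], [0.0, 0.0])
        )
        assert cond_c.survival(0.99) == 1.0
        assert max(cond_i.survival(0.99), 1e-6) == 1e-6

    def test_hand_evaluated_survival(self):
        dist = EmpiricalDistribution([0.6, 0.8, 1.0])
        assert dist.survival(0.7) == pytest.approx(2 / 3)
        assert dist.survival(0.6) == pytest.approx(1.0)   # inclusive
        assert dist.cdf(0.8) == pytest.approx(2 / 3)

    def test_empty_stratum_raises(self):
        with pytest.raises(CalibrationError, match="validation"):
            fit_conditionals([CalibrationSample(0.9, True)])

    def test_tau_trims_stratum_tails(self):
        scores = list(np.linspace(0.0, 1.0, 101))
        samples = samples_from(scores, [0.1, 0.2])
        cond_c, _ = fit_conditionals(samples, tau=0.1)
        kept = cond_c.scores
        assert kept.min() == pytest.approx(0.1)
        assert kept.max() == pytest.approx(0.9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=30),
        st.floats(0, 1),
        st.floats(0, 1),
    )
    def test_ecdf_monotone(self, scores, a, b):
        dist = EmpiricalDistribution(scores)
        lo, hi = min(a, b), max(a, b)
        assert dist.cdf(lo) <= dist.cdf(hi)
        assert dist.survival(lo) >= dist.survival(hi)


class TestConfidenceScore:
    def test_equal_likelihoods_return_prior(self):
        # identical strata -> p(y|correct) = p(y|incorrect) at any score
        scores = [0.2, 0.5, 0.8]
        model = ConfidenceModel.fit(samples_from(scores * 2, scores))
        for s in (0.1, 0.5, 0.7):
            assert confidence_score(s, model) == pytest.approx(
                model.p_correct
            )

    def test_direct_arithmetic(self):
        """0.8 * 0.9 / (0.8 * 0.9 + 0.3 * 0.1) = 0.96."""
        correct = [0.4] + [0.6] * 4          # survival(0.5) = 0.8
        incorrect = [0.4] * 7 + [0.6] * 3    # survival(0.5) = 0.3
        model = ConfidenceModel.fit(samples_from(correct, incorrect))
        assert (model.p_correct, model.p_incorrect) == (
            pytest.approx(1 / 3), pytest.approx(2 / 3)
        )
        # override priors to the worked example
        model.p_correct, model.p_incorrect = 0.9, 0.1
        assert confidence_score(0.5, model) == pytest.approx(0.96)

    def test_zero_incorrect_prior_gives_certainty(self):
        model = ConfidenceModel.fit(
            [CalibrationSample(0.9, True), CalibrationSample(0.3, True)]
        )
        assert model.p_incorrect == 0.0
        assert confidence_score(0.1, model) == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=20),
        st.lists(st.floats(0, 1), min_size=1, max_size=20),
        st.floats(0, 1),
    )
    def test_confidence_bounded(self, correct, incorrect, s):
        model = ConfidenceModel.fit(samples_from(correct, incorrect))
        assert 0.0 <= confidence_score(s, model) <= 1.0

    def test_monotone_in_correct_likelihood(self):
        """Richer high-score correct stratum can only raise confidence."""
        incorrect = [0.2, 0.4, 0.5]
        weak = ConfidenceModel.fit(
            samples_from([0.3, 0.4, 0.9], incorrect)
        )
        strong = ConfidenceModel.fit(
            samples_from([0.9, 0.95, 1.0], incorrect)
        )
        strong.p_correct, strong.p_incorrect = weak.p_correct, weak.p_incorrect
        for s in (0.5, 0.7, 0.9):
            assert confidence_score(s, strong) >= confidence_score(s, weak)


class TestDecide:
    def test_threshold_rule(self):
        certain = ConfidenceModel.fit([CalibrationSample(0.9, True)] * 3)
        d = decide([0.1, 0.8, 0.1], certain, label_space=["a", "b", "c"])
        assert d == ("b", 1.0, False)
        hopeless = ConfidenceModel.fit([CalibrationSample(0.9, False)] * 3)
        assert decide([0.6, 0.4], hopeless).abstained

    def test_equality_assigns(self):
        # confidence exactly 1.0 at threshold 1.0 -> assign
        model = ConfidenceModel.fit(
            [CalibrationSample(0.9, True)] * 3, threshold=1.0
        )
        d = decide([0.9, 0.1], model)
        assert d.confidence == 1.0 and not d.abstained

    def test_argmax_tie_breaks_to_lowest_index(self):
        model = ConfidenceModel.fit([CalibrationSample(0.9, True)] * 2)
        assert decide([0.5, 0.5], model).predicted_label == 0
        assert decide([0.25] * 4, model, label_space="wxyz").predicted_label == "w"

    def test_raw_score_mode_thresholds_max_softmax(self):
        model = ConfidenceModel.fit(
            samples_from([0.95, 0.99], [0.4]),
            threshold=0.9, score_mode="raw",
        )
        assert not decide([0.95, 0.05], model).abstained
        assert decide([0.85, 0.15], model).abstained

    def test_coverage_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        cal = samples_from(rng.uniform(0.5, 1, 200), rng.uniform(0, 0.9, 80))
        vectors = rng.dirichlet(np.ones(5), size=300)
        previous = -1.0
        for threshold in (0.1, 0.3, 0.5, 0.7, 0.9, 1.0):
            model = ConfidenceModel.fit(cal, threshold=threshold)
            frac = np.mean([decide(y, model).abstained for y in vectors])
            assert frac >= previous
            previous = frac

    def test_perfect_validation_abstains_nothing(self):
        model = ConfidenceModel.fit([CalibrationSample(0.8, True)] * 10)
        rng = np.random.default_rng(1)
        for y in rng.dirichlet(np.ones(4), size=50):
            d = decide(y, model)
            assert d.confidence == 1.0 and not d.abstained
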