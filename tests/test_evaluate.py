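"""Folds, F1 metrics, abstention accounting, scenario harness."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icccml.evaluate import (
    MetricsReport,
    ScenarioSpec,
    UQConfig,
    abstention_rate,
    compare_reports,
    f1_scores,
    read_comparison,
    run_scenario,
    stratified_folds,
    write_comparison,
)
from icccml.recode import CCDI_SUBGROUPS

from conftest import TINY_CNN


def f1_oracle(true, pred, classes):
    """Brute-force confusion-matrix F1, independent of sklearn."""
    per = {}
    tp_all = fp_all = fn_all = 0
    for c in classes:
        tp = sum(1 for t, p in zip(true, pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(true, pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(true, pred) if t == c and p != c)
        tp_all, fp_all, fn_all = tp_all + tp, fp_all + fp, fn_all + fn
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        per[c] = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    micro_p = tp_all / (tp_all + fp_all) if tp_all + fp_all else 0.0
    micro_r = tp_all / (tp_all + fn_all) if tp_all + fn_all else 0.0
    micro = (
        2 * micro_p * micro_r / (micro_p + micro_r)
        if micro_p + micro_r else 0.0
    )
    return per, micro, sum(per.values()) / len(classes)


class TestScenarioSpec:
    def test_the_four_scenarios(self):
        assert ScenarioSpec.from_id("1a").training_population == "all-ages"
        assert ScenarioSpec.from_id("1b").label_mode == "icdo3-then-recode"
        assert ScenarioSpec.from_id("2a").label_mode == "direct-iccc"
        assert ScenarioSpec.from_id("2b").training_population == (
            "childhood+ccdi"
        )

    def test_inconsistent_combination_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec("1a", "childhood-only", "icdo3-then-recode")


class TestStratifiedFolds:
    def test_exact_divisibility(self):
        labels = [str(i % 10) for i in range(100)]
        plan = stratified_folds(labels, k=10, seed=0)
        labels = np.array(labels)
        for fold in range(10):
            fold_labels = labels[plan.assignments == fold]
            assert len(fold_labels) == 10
            assert sorted(fold_labels) == sorted(set(labels))

    def test_same_seed_reproduces(self):
        labels = list("aabbbccccddddd") * 3
        p1 = stratified_folds(labels, k=4, seed=9)
        p2 = stratified_folds(labels, k=4, seed=9)
        np.testing.assert_array_equal(p1.assignments, p2.assignments)

    def test_k_too_small(self):
        with pytest.raises(ValueError):
            stratified_folds(["a", "b"], k=1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        labels=st.lists(
            st.sampled_from("abcde"), min_size=10, max_size=120
        ),
        k=st.integers(2, 10),
        seed=st.integers(0, 100),
    )
    def test_balance_properties(self, labels, k, seed):
        """Each record lands in exactly one fold; fold sizes and
        per-class counts deviate from proportionality by at most 1."""
        plan = stratified_folds(labels, k=k, seed=seed)
        arr = np.array(labels)
        assert ((plan.assignments >= 0) & (plan.assignments < k)).all()
        sizes = np.bincount(plan.assignments, minlength=k)
        assert sizes.sum() == len(labels)
        assert sizes.max() - sizes.min() <= 1
        for cls in set(labels):
            counts = np.bincount(
                plan.assignments[arr == cls], minlength=k
            )
            assert counts.max() - counts.min() <= 1

    def test_balance_matches_sklearn_for_large_classes(self):
        from sklearn.model_selection import StratifiedKFold

        labels = np.repeat(list("abc"), [30, 20, 10])
        plan = stratified_folds(labels, k=5, seed=3)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=3)
        sk_assign = np.empty(len(labels), dtype=int)
        for fold, (_, test_idx) in enumerate(skf.split(labels, labels)):
            sk_assign[test_idx] = fold
        for cls in "abc":
            ours = np.bincount(plan.assignments[labels == cls], minlength=5)
            theirs = np.bincount(sk_assign[labels == cls], minlength=5)
            assert sorted(ours) == sorted(theirs)


class TestF1Scores:
    def test_perfect_predictions(self):
        per, micro, macro = f1_scores(list("abab"), list("abab"), ["a", "b"])
        assert per == {"a": 1.0, "b": 1.0}
        assert micro == macro == 1.0

    def test_worked_example(self):
        per, micro, macro = f1_scores(
            ["A", "A", "B"], ["A", "B", "B"], ["A", "B"]
        )
        assert per["A"] == pytest.approx(2 / 3)
        assert per["B"] == pytest.approx(2 / 3)
        assert micro == pytest.approx(2 / 3)
        assert macro == pytest.approx(2 / 3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            f1_scores(["a"], ["a", "b"], ["a", "b"])

    def test_oracle_equivalence_random_vectors(self):
        """Agreement with a brute-force confusion-matrix oracle."""
        rng = np.random.default_rng(0)
        classes = list("abcde")
        for _ in range(1000):
            n = rng.integers(2, 30)
            true = rng.choice(classes, size=n).tolist()
            pred = rng.choice(classes, size=n).tolist()
            per, micro, macro = f1_scores(true, pred, classes)
            o_per, o_micro, o_macro = f1_oracle(true, pred, classes)
            for c in classes:
                assert per[c] == pytest.approx(o_per[c], abs=1e-12)
            assert micro == pytest.approx(o_micro, abs=1e-12)
            assert macro == pytest.approx(o_macro, abs=1e-12)

    def test_micro_equals_accuracy_for_single_label(self):
        rng = np.random.default_rng(1)
        classes = list("abcd")
        for _ in range(200):
            n = rng.integers(2, 40)
            true = rng.choice(classes, size=n)
            pred = rng.choice(classes, size=n)
            _, micro, _ = f1_scores(true.tolist(), pred.tolist(), classes)
            assert micro == pytest.approx(np.mean(true == pred), abs=1e-12)


class TestAbstentionRate:
    @pytest.mark.parametrize(
        "n_cases,n_retained,expected,digits",
        [(8042, 7171, 0.108, 3), (137, 61, 0.555, 3), (29206, 24892, 0.148, 3)],
    )
    def test_published_rates(self, n_cases, n_retained, expected, digits):
        assert round(abstention_rate(n_cases, n_retained), digits) == expected

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            abstention_rate(0, 0)
        with pytest.raises(ValueError):
            abstention_rate(10, 11)


def _mini_report(scenario_id, per_class, micro, macro):
    classes = sorted(per_class)
    return MetricsReport(
        scenario_id=scenario_id,
        class_list=classes,
        per_class_f1=per_class,
        micro_f1=micro,
        macro_f1=macro,
        n_cases={c: 10 for c in classes},
        n_retained={c: 10 for c in classes},
        abstention_rate_overall=0.0,
        abstention_rate_per_class={c: 0.0 for c in classes},
        micro_f1_all=micro,
        macro_f1_all=macro,
    )


class TestCompareReports:
    def test_identical_reports_show_no_differences(self):
        r = _mini_report("2a", {"011": 0.9, "021": 0.8}, 0.85, 0.85)
        s = _mini_report("2b", {"011": 0.9, "021": 0.8}, 0.85, 0.85)
        frame = compare_reports({"2a": r, "2b": s})
        assert (frame["2a"] == frame["2b"]).all()
        assert len(frame) == 2 + 2  # classes + micro/macro rows

    def test_mismatched_class_lists_rejected(self):
        r = _mini_report("1a", {"011": 0.9}, 0.9, 0.9)
        s = _mini_report("2a", {"021": 0.9}, 0.9, 0.9)
        with pytest.raises(ValueError, match="class list"):
            compare_reports({"1a": r, "2a": s})

    def test_tsv_round_trip(self, tmp_path):
        r = _mini_report("1a", {"011": 0.5, "021": 0.25}, 0.4, 0.375)
        s = _mini_report("2a", {"011": 0.75, "021": 0.5}, 0.7, 0.625)
        frame = compare_reports({"1a": r, "2a": s})
        path = tmp_path / "comparison.tsv"
        write_comparison(frame, path)
        loaded = read_comparison(path)
        pd.testing.assert_frame_equal(loaded, frame)


class TestRunScenario:
    def test_scenario_2b_training_set_grows_by_ccdi_count(self, small_corpus):
        r2a = run_scenario("2a", small_corpus, TINY_CNN, k=3, seed=0)
        r2b = run_scenario("2b", small_corpus, TINY_CNN, k=3, seed=0)
        df = small_corpus
        eligible = (
            df.iccc_subgroup.isin(CCDI_SUBGROUPS) & df.age.between(20, 39)
        )
        assert eligible.sum() > 0
        # same fold seed -> same partition; per-fold size differences must
        # total the eligible records seen k-1 times each
        diff = sum(r2b.train_sizes) - sum(r2a.train_sizes)
        assert diff == 2 * int(eligible.sum())

    def test_evaluation_restricted_to_childhood(self, small_corpus):
        report = run_scenario("2a", small_corpus, TINY_CNN, k=3, seed=0)
        n_childhood = int((small_corpus.age <= 19).sum())
        assert report.total_cases == n_childhood
        assert report.total_retained == n_childhood  # no UQ -> all kept
        assert report.abstention_rate_overall == 0.0

    def test_recode_scenario_produces_valid_report(self, small_corpus):
        report = run_scenario("1b", small_corpus, TINY_CNN, k=3, seed=0)
        assert 0.0 <= report.micro_f1 <= 1.0
        assert set(report.per_class_f1) == set(report.class_list)

    def test_abstention_bookkeeping(self, small_corpus):
        report = run_scenario(
            "2a", small_corpus, TINY_CNN, UQConfig(threshold=0.9),
            k=3, seed=0,
        )
        assert report.total_retained <= report.total_cases
        assert sum(report.n_retained.values()) == report.total_retained
        # overall abstention is the case-weighted mean of per-class rates
        weighted = sum(
            report.n_cases[c] * report.abstention_rate_per_class[c]
            for c in report.class_list
        ) / report.total_cases
        assert report.abstention_rate_overall == pytest.approx(weighted)

    def test_2b_without_eligible_records_warns_and_proceeds(
        self, small_corpus, caplog
    ):
        childhood_only = small_corpus[small_corpus.age <= 19].reset_index(
            drop=True
        )
        with caplog.at_level(logging.WARNING):
            report = run_scenario("2b", childhood_only, TINY_CNN, k=3, seed=0)
        assert "CCDI" in caplog.text
        assert report.total_cases == len(childhood_only)
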