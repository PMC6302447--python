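import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from srnakit import (
    DnaSequence,
    LabeledDataset,
    confusion_and_rates,
    grid_search_lambda,
    paired_t_test,
    roc_auc,
    run_cross_validation,
    stratified_kfold,
)
from srnakit.errors import ConfigError, SplitError, ValidationError


class TestConfusionAndRates:
    def test_hand_computed_example(self):
        # TP=90, FN=10, TN=80, FP=20
        labels = [1] * 100 + [0] * 100
        probs = [0.9] * 90 + [0.1] * 10 + [0.1] * 80 + [0.9] * 20
        r = confusion_and_rates(labels, probs)
        assert (r.counts.tp, r.counts.fn, r.counts.tn, r.counts.fp) == (90, 10, 80, 20)
        assert r.sn == pytest.approx(0.9)
        assert r.sp == pytest.approx(0.8)
        assert r.acc == pytest.approx(0.85)

    def test_all_correct(self):
        r = confusion_and_rates([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2])
        assert (r.sn, r.sp, r.acc) == (1.0, 1.0, 1.0)

    def test_undefined_rate_is_nan_not_zero(self):
        r = confusion_and_rates([0, 0], [0.9, 0.1])
        assert math.isnan(r.sn)
        assert r.undefined == ("SN",)
        assert r.sp == pytest.approx(0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            confusion_and_rates([], [])

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.tuples(st.integers(0, 1), st.floats(0, 1)), min_size=1, max_size=60))
    def test_counts_partition_all_instances(self, pairs):
        labels = [l for l, _ in pairs]
        probs = [p for _, p in pairs]
        r = confusion_and_rates(labels, probs)
        assert r.counts.total == len(pairs)
        # independent recount
        pred = [int(p >= 0.5) for p in probs]
        assert r.counts.tp == sum(1 for l, q in zip(labels, pred) if l == 1 and q == 1)
        assert r.counts.tn == sum(1 for l, q in zip(labels, pred) if l == 0 and q == 0)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_four_pair_example(self):
        # pairs: (.8>.6, .8>.2, .4<.6, .4>.2) -> 3/4
        assert roc_auc([1, 1, 0, 0], [0.8, 0.4, 0.6, 0.2]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 1], [0.5, 0.6])

    def test_null_expectation_on_shuffled_labels(self):
        rng = np.random.default_rng(0)
        labels = rng.permutation([1] * 500 + [0] * 500)
        scores = rng.random(1000)
        assert abs(roc_auc(labels, scores) - 0.5) < 0.06

    @settings(derandomize=True, max_examples=60)
    @given(st.data())
    def test_matches_all_pairs_oracle_with_ties(self, data):
        n = data.draw(st.integers(4, 50))
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < len(ls)
            )
        )
        # coarse grid forces ties
        scores = data.draw(
            st.lists(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]), min_size=n, max_size=n)
        )
        assert roc_auc(labels, scores) == pytest.approx(
            oracles.naive_auc(labels, scores), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self, rng):
        labels = [1] * 20 + [0] * 30
        scores = rng.random(50)
        a = roc_auc(labels, scores)
        assert roc_auc(labels, np.exp(5 * scores)) == pytest.approx(a, abs=1e-12)
        assert roc_auc(labels, np.log(scores + 1e-9)) == pytest.approx(a, abs=1e-12)


def _dummy_dataset(n_pos, n_neg):
    seqs = [DnaSequence(f"s{i}", "ACGTACGTACGT") for i in range(n_pos + n_neg)]
    return LabeledDataset(seqs, [1] * n_pos + [0] * n_neg)


class TestStratifiedKfold:
    def test_exact_divisibility(self):
        splits = stratified_kfold(_dummy_dataset(10, 10), k=5, seed=0)
        labels = np.array([1] * 10 + [0] * 10)
        for s in splits:
            te = labels[list(s.test_idx)]
            assert (te == 1).sum() == 2 and (te == 0).sum() == 2

    def test_benchmark_sized_partition_arithmetic(self):
        # 182 positives, 910 negatives at 1:5 -> fold pos in {36,37}, neg = 182
        splits = stratified_kfold(_dummy_dataset(182, 910), k=5, seed=1)
        labels = np.array([1] * 182 + [0] * 910)
        pos_counts = sorted(
            int((labels[list(s.test_idx)] == 1).sum()) for s in splits
        )
        neg_counts = {int((labels[list(s.test_idx)] == 0).sum()) for s in splits}
        assert set(pos_counts) <= {36, 37}
        assert sum(pos_counts) == 182
        assert neg_counts == {182}

    def test_union_of_test_folds_is_everything(self):
        splits = stratified_kfold(_dummy_dataset(13, 29), k=5, seed=3)
        covered = sorted(i for s in splits for i in s.test_idx)
        assert covered == list(range(42))
        # disjoint
        assert len(covered) == len(set(covered))

    def test_deterministic_under_seed(self):
        a = stratified_kfold(_dummy_dataset(20, 20), k=5, seed=7)
        b = stratified_kfold(_dummy_dataset(20, 20), k=5, seed=7)
        assert a == b

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(SplitError):
            stratified_kfold(_dummy_dataset(3, 20), k=5)


class TestRunCrossValidation:
    def test_fold_record_count_and_report_shape(self, planted_small):
        rep = run_cross_validation("base:F3", planted_small, folds=5, runs=1, seed=0)
        assert len(rep.folds) == 5
        assert set(rep.overall) == {"sn", "sp", "acc", "auc"}
        assert 0.0 <= rep.auc <= 1.0
        assert rep.run_aucs().shape == (1,)

    def test_two_runs_reshuffle_folds(self, planted_small):
        rep = run_cross_validation("base:F1", planted_small, folds=5, runs=2, seed=0)
        assert sorted(rep.folds["run"].unique()) == [0, 1]
        assert len(rep.folds) == 10

    def test_unknown_method_rejected(self, planted_small):
        with pytest.raises(ConfigError):
            run_cross_validation("stacking:deep", planted_small)

    def test_baseline_configs_run_svm_engines(self, planted_small):
        carter = run_cross_validation(
            "baseline:carter", planted_small, folds=3, runs=1, seed=0
        )
        barman = run_cross_validation(
            "baseline:barman", planted_small, folds=3, runs=1, seed=0
        )
        # tri-nucleotide composition carries the planted 3-mer signal;
        # mono+di composition carries much less
        assert barman.auc > 0.8
        assert 0.0 <= carter.auc <= 1.0

    def test_feature_cache_reused_across_calls(self, planted_small):
        cache = {}
        r1 = run_cross_validation(
            "base:F2", planted_small, folds=3, runs=1, seed=0, feature_cache=cache
        )
        assert "spectrum:k=2" in cache
        r2 = run_cross_validation(
            "base:F2", planted_small, folds=3, runs=1, seed=0, feature_cache=cache
        )
        assert r1.folds.equals(r2.folds)


class TestGridSearchLambda:
    def test_single_row(self, planted_small):
        table = grid_search_lambda(planted_small, "PCPseDNC", [1], runs=1, seed=0)
        assert list(table["lambda"]) == [1]
        assert table["best"].sum() == 1

    def test_bound_check_uses_shortest_sequence(self):
        seqs = [DnaSequence(f"s{i}", "ACGT" * 12) for i in range(20)]  # L = 48
        data = LabeledDataset(seqs, [1] * 10 + [0] * 10)
        with pytest.raises(ConfigError, match=r"\[1, 46\]"):
            grid_search_lambda(data, "PCPseDNC", [47])

    def test_lag_signal_recovered_at_planted_rank(self):
        from srnakit import SyntheticSpec, gen_planted_dataset

        data = gen_planted_dataset(
            SyntheticSpec(
                n_pos=60,
                length_bounds=(60, 150),
                correlation_lag=3,
                copy_prob=0.6,
                seed=21,
            )
        )
        table = grid_search_lambda(
            data, "PCPseDNC", [1, 2, 3, 4], folds=3, runs=1, seed=5
        )
        best_lambda = int(table.loc[table["auc"].idxmax(), "lambda"])
        assert best_lambda >= 3


class TestPairedTTest:
    def test_identical_samples_degenerate_p_one(self):
        r = paired_t_test([0.9, 0.8, 0.85], [0.9, 0.8, 0.85])
        assert r.degenerate and r.p_value == 1.0

    def test_constant_nonzero_difference_degenerate(self):
        r = paired_t_test([0.9, 0.8, 0.7], [0.8, 0.7, 0.6])
        assert r.degenerate and math.isnan(r.p_value)

    def test_matches_closed_form_on_toy_sample(self):
        a = [0.93, 0.95, 0.91, 0.96, 0.94]
        b = [0.90, 0.92, 0.90, 0.93, 0.91]
        d = np.array(a) - np.array(b)
        t_expected = d.mean() / (d.std(ddof=1) / math.sqrt(5))
        from scipy.stats import t as t_dist

        p_expected = 2 * t_dist.sf(abs(t_expected), df=4)
        r = paired_t_test(a, b)
        assert r.statistic == pytest.approx(t_expected, abs=1e-9)
        assert r.p_value == pytest.approx(p_expected, abs=1e-9)

    def test_mismatched_or_tiny_samples_rejected(self):
        with pytest.raises(ConfigError):
            paired_t_test([0.9], [0.8])
        with pytest.raises(ConfigError):
            paired_t_test([0.9, 0.8], [0.8])
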