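"""Linear-SVM training, class-adjusted accuracy and role permutations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import balanced_accuracy_score

from okndecode.decoding import (
    DEFAULT_COST_GRID,
    PerceptDecoder,
    RoleAssignment,
    balanced_accuracy,
    run_role_permutations,
    score_hit_rate,
    select_model,
    train_svm,
)
from okndecode.features import EXCLUDED, FeatureMatrix
from okndecode.simulate import INTEGRATED, NONE, SEGREGATED, ReportTrace


def _clusters(n=400, sep=4.0, seed=0, d=5):
    """Two well-separated Gaussian clusters with percept labels."""
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 1.0, (n // 2, d))
    X1 = rng.normal(sep, 1.0, (n // 2, d))
    X = np.vstack([X0, X1])
    y = np.concatenate(
        [np.full(n // 2, INTEGRATED), np.full(n // 2, SEGREGATED)]
    ).astype(np.int8)
    perm = rng.permutation(n)
    return X[perm], y[perm]


def _feature_matrix(X, rate=100.0):
    n = len(X)
    return FeatureMatrix(
        t=np.arange(n) / rate,
        X=X,
        complete=np.ones(n, dtype=bool),
        lags=np.zeros(X.shape[1] // 3 if X.shape[1] % 3 == 0 else 1),
    )


class TestCostGrid:
    def test_default_grid(self):
        assert DEFAULT_COST_GRID == (
            0.0001, 0.0005, 0.001, 0.005, 0.01, 0.1, 1, 2, 5, 10, 100,
        )
        assert len(DEFAULT_COST_GRID) == 11


class TestTrain:
    def test_separable_clusters_fit_perfectly(self):
        X, y = _clusters()
        dec = train_svm(X, y, cost=1.0)
        assert dec.score(X, y) == 1.0

    def test_shuffled_labels_decode_at_chance(self):
        rng = np.random.default_rng(1)
        X, y = _clusters(n=2000)
        y_shuf = rng.permutation(y)
        dec = train_svm(X[:1000], y_shuf[:1000], cost=1.0)
        acc = dec.score(X[1000:], y_shuf[1000:])
        assert acc == pytest.approx(0.5, abs=0.05)

    def test_training_is_deterministic(self):
        X, y = _clusters()
        d1 = train_svm(X, y, cost=0.1)
        d2 = train_svm(X, y, cost=0.1)
        assert np.array_equal(d1.coef_, d2.coef_)
        assert d1.intercept_ == d2.intercept_

    def test_single_class_labels_error_names_missing_class(self):
        X, y = _clusters()
        y_all = np.full_like(y, INTEGRATED)
        with pytest.raises(ValueError, match="segregated"):
            train_svm(X, y_all, cost=1.0)

    def test_dimension_mismatch_rejected(self):
        X, y = _clusters(d=5)
        dec = train_svm(X, y, cost=1.0)
        with pytest.raises(ValueError):
            dec.predict(np.zeros((10, 7)))


class TestBalancedAccuracy:
    def test_perfect_predictions(self):
        y = np.array([SEGREGATED, INTEGRATED, SEGREGATED, INTEGRATED], dtype=np.int8)
        res = balanced_accuracy(y.copy(), y)
        assert res.acc_seg == res.acc_int == res.balanced == 1.0

    def test_asymmetric_class_accuracies_average(self):
        # seg: 80/100 correct, int: 40/100 correct -> (0.8 + 0.4)/2 = 0.60
        y = np.concatenate([np.full(100, SEGREGATED), np.full(100, INTEGRATED)])
        pred = y.copy()
        pred[:20] = INTEGRATED
        pred[100:160] = SEGREGATED
        res = balanced_accuracy(pred, y)
        assert res.acc_seg == pytest.approx(0.8)
        assert res.acc_int == pytest.approx(0.4)
        assert res.balanced == pytest.approx(0.6)

    def test_majority_predictor_scores_chance(self):
        y = np.concatenate([np.full(90, SEGREGATED), np.full(10, INTEGRATED)])
        pred = np.full(100, SEGREGATED)
        assert balanced_accuracy(pred, y).balanced == pytest.approx(0.5)

    def test_missing_class_errors(self):
        y = np.full(10, SEGREGATED, dtype=np.int8)
        with pytest.raises(ValueError, match="integrated"):
            balanced_accuracy(y.copy(), y)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(2)
        y = rng.choice([INTEGRATED, SEGREGATED], 1000, p=[0.7, 0.3]).astype(np.int8)
        pred = rng.choice([INTEGRATED, SEGREGATED], 1000).astype(np.int8)
        ours = balanced_accuracy(pred, y).balanced
        assert ours == pytest.approx(balanced_accuracy_score(y, pred), abs=1e-12)

    @settings(derandomize=True, max_examples=25)
    @given(k=st.integers(min_value=2, max_value=10), seed=st.integers(0, 100))
    def test_duplicating_minority_rows_invariant(self, k, seed):
        """Balanced accuracy is a ratio per class: k-fold duplication of the
        minority class changes it by < 1e-12."""
        rng = np.random.default_rng(seed)
        y = np.concatenate([np.full(50, SEGREGATED), np.full(10, INTEGRATED)])
        pred = rng.choice([INTEGRATED, SEGREGATED], 60).astype(np.int8)
        base = balanced_accuracy(pred, y).balanced
        minority = y == INTEGRATED
        y_dup = np.concatenate([y, np.tile(y[minority], k)])
        pred_dup = np.concatenate([pred, np.tile(pred[minority], k)])
        assert abs(balanced_accuracy(pred_dup, y_dup).balanced - base) < 1e-12

    def test_random_guessing_chance_level(self):
        """Mean balanced accuracy of fair-coin guessing on 90/10 labels is
        50% within 1 percentage point (200 x 10,000 timepoints)."""
        rng = np.random.default_rng(42)
        accs = []
        for _ in range(200):
            y = np.where(rng.random(10_000) < 0.9, SEGREGATED, INTEGRATED).astype(np.int8)
            pred = np.where(rng.random(10_000) < 0.5, SEGREGATED, INTEGRATED).astype(np.int8)
            accs.append(balanced_accuracy(pred, y).balanced)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.01)


class TestSelection:
    def test_single_candidate_returned(self):
        X, y = _clusters()
        dec = train_svm(X, y, 1.0)
        chosen, cost, acc = select_model([(1.0, dec)], X, y)
        assert chosen is dec and cost == 1.0

    def test_argmax_over_candidates(self):
        X, y = _clusters(n=600, seed=3)
        Xo, yo = _clusters(n=600, seed=4)
        cands = [(c, train_svm(X, y, c)) for c in (0.001, 1.0, 100.0)]
        chosen, cost, acc = select_model(cands, Xo, yo)
        accs = {c: d.score(Xo, yo) for c, d in cands}
        assert acc == max(accs.values())

    def test_tie_breaks_toward_smallest_cost(self):
        X, y = _clusters()
        d1 = train_svm(X, y, 0.01)
        d2 = train_svm(X, y, 1.0)
        # both perfect on the training data -> tie -> smaller cost wins
        _, cost, _ = select_model([(1.0, d2), (0.01, d1)], X, y)
        assert cost == 0.01

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_model([], np.zeros((1, 2)), np.zeros(1))


class TestRolePermutations:
    def _three_blocks(self, seed=0):
        blocks = []
        for i in range(3):
            X, y = _clusters(n=600, seed=seed + i, d=6)
            blocks.append((_feature_matrix(X), y))
        return blocks

    def test_three_blocks_give_six_models(self):
        models = run_role_permutations(self._three_blocks(), cost_grid=(0.01, 1.0))
        assert len(models) == 6
        roles = {(m.roles.train_block, m.roles.opt_block, m.roles.eval_block)
                 for m in models}
        assert len(roles) == 6
        for m in models:
            assert len({m.roles.train_block, m.roles.opt_block, m.roles.eval_block}) == 3
            assert m.eval_accuracy is not None

    def test_identical_blocks_give_equal_accuracies(self):
        X, y = _clusters(n=600, seed=9, d=6)
        blocks = [(_feature_matrix(X.copy()), y.copy()) for _ in range(3)]
        models = run_role_permutations(blocks, cost_grid=(1.0,))
        accs = {round(m.eval_accuracy, 12) for m in models}
        assert len(accs) == 1

    def test_wrong_block_count_rejected(self):
        with pytest.raises(ValueError):
            run_role_permutations(self._three_blocks()[:2])

    def test_role_assignment_distinctness_enforced(self):
        with pytest.raises(ValueError):
            RoleAssignment(0, 0, 1)


class TestHitRate:
    def _schedule(self):
        return [(INTEGRATED, 7.5), (SEGREGATED, 7.5), (INTEGRATED, 7.5), (SEGREGATED, 7.5)]

    def _report_from(self, states, rate=100.0):
        return ReportTrace(rate=rate, states=np.asarray(states, dtype=np.int8))

    def test_perfect_report_scores_100(self):
        sched = self._schedule()
        states = np.concatenate(
            [np.full(750, s, dtype=np.int8) for s, _ in sched]
        )
        assert score_hit_rate(self._report_from(states), sched) == 100.0

    def test_inverted_report_scores_0(self):
        sched = self._schedule()
        states = np.concatenate(
            [np.full(750, 1 - s, dtype=np.int8) for s, _ in sched]
        )
        assert score_hit_rate(self._report_from(states), sched) == 0.0

    def test_none_time_excluded_from_denominator(self):
        # 30-s schedule: 12 s correct, 8 s wrong, 10 s none -> 60%
        sched = [(INTEGRATED, 15.0), (SEGREGATED, 7.5), (INTEGRATED, 3.75), (SEGREGATED, 3.75)]
        states = np.full(3000, NONE, dtype=np.int8)
        states[:1200] = INTEGRATED           # 12 s correct
        states[1200:1500] = SEGREGATED       # 3 s wrong (still integrated period)
        states[1500:2000] = INTEGRATED       # 5 s wrong (segregated period)
        assert score_hit_rate(self._report_from(states), sched) == pytest.approx(60.0)

    def test_all_none_report_signals_undefined(self):
        sched = self._schedule()
        states = np.full(3000, NONE, dtype=np.int8)
        with pytest.raises(ValueError):
            score_hit_rate(self._report_from(states), sched)


class TestDecodeTimecourse:
    def test_zero_weights_positive_bias_constant_prediction(self):
        from okndecode.decoding import DecoderModel, decode_timecourse

        dec = PerceptDecoder(cost=1.0)
        dec.coef_ = np.zeros(6)
        dec.intercept_ = 1.0
        dec.classes_ = np.array([INTEGRATED, SEGREGATED], dtype=np.int8)
        dec.n_features_in_ = 6
        model = DecoderModel(
            decoder=dec, cost=1.0, roles=RoleAssignment(0, 1, 2),
            stats=None, opt_accuracy=1.0,
        )
        X, _ = _clusters(d=6)
        fm = _feature_matrix(X)
        fm.complete[:10] = False
        pred = decode_timecourse(model, fm)
        assert np.all(pred[:10] == EXCLUDED)
        assert np.all(pred[10:] == SEGREGATED)  # positive class

    def test_training_block_at_least_as_good_as_eval(self):
        blocks = []
        for i in range(3):
            X, y = _clusters(n=600, seed=20 + i, d=6)
            blocks.append((_feature_matrix(X), y))
        models = run_role_permutations(blocks, cost_grid=(1.0,))
        for m in models:
            fm, y = blocks[m.roles.train_block]
            from okndecode.features import standardize

            fm_std = standardize(fm, m.stats)[0] if m.stats is not None else fm
            train_acc = m.decoder.score(fm_std.X, y)
            assert train_acc >= m.eval_accuracy - 1e-9
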