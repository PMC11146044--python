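"""Consistency, percept statistics, and theoretical/expected bounds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import linprog

from okndecode.coupling import (
    compute_consistency,
    correlation,
    expected_bounds,
    group_tests,
    median_phase_duration,
    paired_test,
    percept_proportions,
    theoretical_bounds,
)
from okndecode.decoding import DecoderModel, PerceptDecoder, RoleAssignment
from okndecode.features import FeatureMatrix
from okndecode.simulate import INTEGRATED, NONE, SEGREGATED, ReportTrace


# --------------------------------------------------------------------------
# Oracles
# --------------------------------------------------------------------------

def lp_bound(a, v, maximize):
    """Optimize balanced consistency over all joint distributions with
    marginals (a, v) via linear programming.

    Variables: p_ss, p_si, p_is, p_ii >= 0 (auditory x visual percepts).
    Objective: 1/2 * (p_ss/a + p_ii/(1-a)).
    """
    c = np.array([0.5 / a, 0.0, 0.0, 0.5 / (1 - a)])
    if maximize:
        c = -c
    A_eq = np.array(
        [
            [1, 1, 0, 0],   # auditory segregated marginal
            [1, 0, 1, 0],   # visual segregated marginal
            [1, 1, 1, 1],   # total mass
        ]
    )
    b_eq = np.array([a, v, 1.0])
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=[(0, 1)] * 4, method="highs")
    assert res.success
    return -res.fun if maximize else res.fun


def mc_expected_bound(a, v, d, r, maximize, n=400_000, seed=0, condition="true"):
    """Monte-Carlo oracle: simulate latent percept pairs at the theoretical
    extreme, pass them through independent decode/report noise, and score
    the balanced consistency of the observed labels.

    ``condition="true"`` computes per-class accuracies over the true
    auditory percept (the construction of the closed form);
    ``condition="observed"`` conditions on the reported percept, as the
    empirical consistency measure does.
    """
    rng = np.random.default_rng(seed)
    # joint distribution at the chosen extreme
    p_ss = min(a, v) if maximize else max(0.0, a + v - 1.0)
    p = np.array([p_ss, a - p_ss, v - p_ss, 1.0 - a - v + p_ss])
    p = np.clip(p, 0.0, None)
    cells = rng.choice(4, size=n, p=p / p.sum())
    aud = np.isin(cells, [0, 1])   # auditory segregated
    vis = np.isin(cells, [0, 2])   # visual segregated
    aud_obs = np.where(rng.random(n) < r, aud, ~aud)
    vis_obs = np.where(rng.random(n) < d, vis, ~vis)
    cls = aud if condition == "true" else aud_obs
    acc_seg = (vis_obs == aud_obs)[cls].mean()
    acc_int = (vis_obs == aud_obs)[~cls].mean()
    return 0.5 * (acc_seg + acc_int)


# --------------------------------------------------------------------------

class TestTheoreticalBounds:
    def test_equal_proportions_allow_perfect_consistency(self):
        for p in (0.2, 0.5, 0.8):
            mx, _ = theoretical_bounds(p, p)
            assert mx == pytest.approx(1.0)

    def test_known_asymmetric_values(self):
        mx, mn = theoretical_bounds(0.6, 0.4)
        assert mx == pytest.approx(5 / 6, abs=1e-12)
        assert mn == pytest.approx(0.0, abs=1e-12)
        _, mn2 = theoretical_bounds(0.7, 0.6)
        assert mn2 == pytest.approx(0.5 * (0.3 / 0.7), abs=1e-9)

    def test_degenerate_proportions_rejected(self):
        for a, v in ((0.0, 0.5), (1.0, 0.5), (0.5, 0.0), (0.5, 1.0)):
            with pytest.raises(ValueError):
                theoretical_bounds(a, v)

    def test_matches_lp_oracle_on_grid(self):
        """Closed forms equal the joint-distribution LP oracle to 1e-9 on a
        20 x 20 grid of (a, v)."""
        grid = np.linspace(0.05, 0.95, 20)
        for a in grid:
            for v in grid:
                mx, mn = theoretical_bounds(a, v)
                assert mx == pytest.approx(lp_bound(a, v, True), abs=1e-9)
                assert mn == pytest.approx(lp_bound(a, v, False), abs=1e-9)


class TestExpectedBounds:
    def test_perfect_accuracy_recovers_theoretical(self):
        mx_t, mn_t = theoretical_bounds(0.6, 0.45)
        mx_e, mn_e, q = expected_bounds(0.6, 0.45, 1.0, 1.0)
        assert q == 1.0
        assert mx_e == pytest.approx(mx_t)
        assert mn_e == pytest.approx(mn_t)

    def test_chance_decoder_pins_bounds_at_half(self):
        for r in (0.6, 0.9, 1.0):
            mx, mn, q = expected_bounds(0.55, 0.45, 0.5, r)
            assert q == pytest.approx(0.5)
            assert mx == pytest.approx(0.5)
            assert mn == pytest.approx(0.5)

    def test_match_transmission_probability(self):
        _, _, q = expected_bounds(0.5, 0.5, 0.829, 0.871)
        assert q == pytest.approx(0.829 * 0.871 + 0.171 * 0.129, abs=1e-9)
        assert q == pytest.approx(0.7442, abs=5e-4)

    @pytest.mark.parametrize(
        "a,v,d,r",
        [(0.6, 0.45, 0.83, 0.87), (0.7, 0.5, 0.9, 0.8), (0.55, 0.6, 0.75, 0.95)],
    )
    def test_matches_monte_carlo_oracle(self, a, v, d, r):
        mx, mn, _ = expected_bounds(a, v, d, r)
        assert mx == pytest.approx(mc_expected_bound(a, v, d, r, True), abs=0.01)
        assert mn == pytest.approx(mc_expected_bound(a, v, d, r, False), abs=0.01)

    @pytest.mark.parametrize(
        "a,v,d,r",
        [(0.6, 0.45, 0.83, 0.87), (0.7, 0.5, 0.9, 0.8), (0.55, 0.6, 0.75, 0.95)],
    )
    def test_report_conditioning_approximation_is_small(self, a, v, d, r):
        """The empirical consistency conditions per-class on the *reported*
        auditory percept; the closed form conditions on the true percept.
        The induced approximation error stays below 0.05 for realistic
        asymmetries and accuracies."""
        mx, mn, _ = expected_bounds(a, v, d, r)
        mx_obs = mc_expected_bound(a, v, d, r, True, condition="observed")
        mn_obs = mc_expected_bound(a, v, d, r, False, condition="observed")
        assert abs(mx - mx_obs) < 0.05
        assert abs(mn - mn_obs) < 0.05

    @settings(derandomize=True, max_examples=200)
    @given(
        a=st.floats(0.05, 0.95),
        v=st.floats(0.05, 0.95),
        d=st.floats(0.5, 1.0),
        r=st.floats(0.5, 1.0),
    )
    def test_bound_ordering(self, a, v, d, r):
        """theo_min <= exp_min <= 0.5 <= exp_max <= theo_max whenever the
        accuracies are at least chance."""
        mx_t, mn_t = theoretical_bounds(a, v)
        mx_e, mn_e, _ = expected_bounds(a, v, d, r)
        eps = 1e-12
        assert mn_t <= mn_e + eps
        assert mn_e <= 0.5 + eps
        assert 0.5 <= mx_e + eps
        assert mx_e <= mx_t + eps


class TestConsistency:
    def _model(self, w, b, d=4):
        dec = PerceptDecoder(cost=1.0)
        dec.coef_ = np.asarray(w, dtype=float)
        dec.intercept_ = float(b)
        dec.classes_ = np.array([INTEGRATED, SEGREGATED], dtype=np.int8)
        dec.n_features_in_ = d
        return DecoderModel(
            decoder=dec, cost=1.0, roles=RoleAssignment(0, 1, 2),
            stats=None, opt_accuracy=1.0,
        )

    def _block(self, y, d=4, seed=0):
        """Features whose first coordinate linearly encodes the label."""
        rng = np.random.default_rng(seed)
        n = len(y)
        X = rng.normal(0, 0.1, (n, d))
        X[:, 0] += np.where(y == SEGREGATED, 1.0, -1.0)
        return FeatureMatrix(
            t=np.arange(n) / 100.0, X=X,
            complete=np.ones(n, dtype=bool), lags=np.zeros(1),
        )

    def test_default_design_yields_48_cells(self):
        rng = np.random.default_rng(0)
        models = [self._model([1, 0, 0, 0], 0.0) for _ in range(6)]
        feats, labels = [], []
        for b in range(8):
            y = rng.choice([INTEGRATED, SEGREGATED], 500).astype(np.int8)
            feats.append(self._block(y, seed=b))
            labels.append(y)
        res = compute_consistency(models, feats, labels)
        assert res.matrix.shape == (6, 8)
        assert res.n_cells == 48
        assert res.n_defined == 48

    def test_identical_report_gives_unit_consistency(self):
        models = [self._model([1, 0, 0, 0], 0.0)]
        y = np.array([INTEGRATED, SEGREGATED] * 250, dtype=np.int8)
        res = compute_consistency(models, [self._block(y)], [y])
        assert res.mean == pytest.approx(1.0)

    def test_shuffled_labels_give_chance(self):
        """Mean consistency over shuffled auditory labels is 0.50 +- 0.02."""
        rng = np.random.default_rng(7)
        models = [self._model([1, 0, 0, 0], 0.0)]
        y = np.array([INTEGRATED, SEGREGATED] * 500, dtype=np.int8)
        fm = self._block(y)
        means = []
        for _ in range(100):
            y_shuf = rng.permutation(y)
            means.append(compute_consistency(models, [fm], [y_shuf]).mean)
        assert np.mean(means) == pytest.approx(0.5, abs=0.02)

    def test_single_class_block_flagged_undefined(self):
        models = [self._model([1, 0, 0, 0], 0.0)]
        y_good = np.array([INTEGRATED, SEGREGATED] * 100, dtype=np.int8)
        y_bad = np.full(200, SEGREGATED, dtype=np.int8)
        res = compute_consistency(
            models,
            [self._block(y_good), self._block(y_bad)],
            [y_good, y_bad],
        )
        assert res.n_defined == 1
        assert np.isnan(res.matrix[0, 1])
        assert res.mean == pytest.approx(res.matrix[0, 0])


class TestReportStatistics:
    def _rep(self, states, rate=100.0):
        return ReportTrace(rate=rate, states=np.asarray(states, dtype=np.int8))

    def test_all_segregated(self):
        rep = self._rep(np.full(100, SEGREGATED))
        assert percept_proportions(rep) == (1.0, 0.0, 1.0)

    def test_mixed_report_proportions(self):
        states = np.concatenate(
            [
                np.full(6000, SEGREGATED),
                np.full(4000, INTEGRATED),
                np.full(1000, NONE),
            ]
        )
        ps, pi, ex = percept_proportions(self._rep(states))
        assert ps == pytest.approx(0.6)
        assert pi == pytest.approx(0.4)
        assert ex == pytest.approx(100 / 110)
        assert ps + pi == pytest.approx(1.0)

    def test_no_exclusive_time_signals(self):
        with pytest.raises(ValueError):
            percept_proportions(self._rep(np.full(10, NONE)))

    def test_median_phase_duration_examples(self):
        states = np.concatenate(
            [
                np.full(200, INTEGRATED),   # 2 s
                np.full(400, SEGREGATED),   # 4 s
                np.full(900, INTEGRATED),   # 9 s
            ]
        )
        assert median_phase_duration(self._rep(states)) == pytest.approx(4.0)
        single = self._rep(np.full(700, SEGREGATED))
        assert median_phase_duration(single) == pytest.approx(7.0)

    def test_none_gap_splits_phases(self):
        states = np.concatenate(
            [
                np.full(300, INTEGRATED),
                np.full(100, NONE),
                np.full(300, INTEGRATED),
            ]
        )
        assert median_phase_duration(self._rep(states)) == pytest.approx(3.0)

    def test_simulated_phases_match_gamma_median(self):
        from okndecode.simulate import PerceptProcessParams, simulate_coupled_percepts
        from scipy.stats import gamma as gamma_dist

        p = PerceptProcessParams(mean_dom=8, shape=3, kappa=1.0, pi_seg=0.5)
        lat, _ = simulate_coupled_percepts(p, p, 10_000, seed=0, rate=100)
        rep = ReportTrace(rate=100.0, states=lat.states)
        med = median_phase_duration(rep)
        expected = gamma_dist.median(3, scale=8 / 3)
        assert med == pytest.approx(expected, rel=0.1)


class TestGroupStats:
    def test_values_at_reference_give_t0_p1(self):
        gs = group_tests(np.full(10, 0.5), 0.5)
        assert gs.statistic == 0.0
        assert gs.p_value == 1.0
        assert gs.df == 9

    def test_constant_shift_matches_closed_form(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 12)
        c = 0.7
        vals = 0.5 + c + (base - base.mean())
        gs = group_tests(vals, 0.5)
        expected_t = c * np.sqrt(12) / np.std(vals, ddof=1)
        assert gs.statistic == pytest.approx(expected_t, rel=1e-9)
        assert gs.df == 11

    def test_paired_identical_vectors(self):
        x = np.random.default_rng(1).normal(size=8)
        gs = paired_test(x, x.copy())
        assert gs.statistic == 0.0
        assert gs.p_value == 1.0

    def test_zero_variance_away_from_reference_signals(self):
        with pytest.raises(ValueError):
            group_tests(np.full(5, 0.8), 0.5)

    def test_correlation_of_linear_data(self):
        x = np.arange(10.0)
        gs = correlation(x, 2 * x + 1)
        assert gs.statistic == pytest.approx(1.0)
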