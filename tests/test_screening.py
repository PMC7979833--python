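import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import rhodoscreen as rs
from rhodoscreen.blasso import BlassoConfig, PosteriorSamples


def make_posterior(mu, beta, seed=0):
    mu = np.asarray(mu, dtype=float)
    beta = np.asarray(beta, dtype=float)
    T = len(mu)
    return PosteriorSamples(
        mu=mu,
        beta=beta,
        sigma2=np.ones(T),
        gamma2=np.ones(T),
        config=BlassoConfig(n_samples=T, burn_in=0, seed=seed),
    )


class TestPredictiveDraws:
    def test_null_coefficients_return_intercept_draws(self):
        mu = np.array([540.0, 545.0, 550.0])
        post = make_posterior(mu, np.zeros((3, 4)))
        x = rs.EncodedSample(id="c", x=np.ones(4))
        draws = rs.predictive_draws(post, x)
        np.testing.assert_array_equal(draws, mu)
        assert draws.std(ddof=1) == pytest.approx(mu.std(ddof=1))

    def test_single_draw_has_zero_predictive_sd(self):
        post = make_posterior([550.0], [[1.0, 2.0]])
        x = rs.EncodedSample(id="c", x=np.array([0.5, -0.5]))
        scores, _ = rs.score_candidates(
            post, [rs.EncodedSample(id="c", x=np.array([0.5, -0.5]),
                                    subfamily="PR")],
            {"PR": 520.0},
        )
        assert scores[0].pred_sd == 0.0
        assert scores[0].mc_standard_error == 0.0

    def test_hand_dot_products(self):
        mu = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        beta = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1],
                         [1, 1, 1], [2, -1, 0.5]], dtype=float)
        x = rs.EncodedSample(id="c", x=np.array([10.0, 20.0, 30.0]))
        expect = [1 + 10, 2 + 20, 3 + 30, 4 + 60, 5 + 20 - 20 + 15]
        np.testing.assert_allclose(
            rs.predictive_draws(make_posterior(mu, beta), x), expect
        )

    def test_standardizer_hash_mismatch_rejected(self, small_posterior):
        x = rs.EncodedSample(id="c", x=np.zeros(small_posterior.n_features),
                             standardizer_hash="not-the-right-one")
        with pytest.raises(ValueError, match="standardize"):
            rs.predictive_draws(small_posterior, x)


class TestExpectedGain:
    def test_fully_truncated(self):
        eg, prob, _ = rs.expected_gain(np.array([500.0, 510.0, 519.9]), 520.0)
        assert eg == 0.0 and prob == 0.0

    def test_deterministic_shift(self):
        eg, prob, se = rs.expected_gain(np.full(100, 532.0), 520.0)
        assert eg == pytest.approx(12.0)
        assert prob == 1.0
        assert se == 0.0

    def test_matches_closed_form_truncated_gaussian(self):
        m, s, b, T = 550.0, 10.0, 545.0, 200_000
        rng = np.random.default_rng(123)
        draws = rng.normal(m, s, T)
        eg, prob, se = rs.expected_gain(draws, b)
        z = (m - b) / s
        closed = s * stats.norm.pdf(z) + (m - b) * stats.norm.cdf(z)
        assert abs(eg - closed) < 3 * se
        assert prob == pytest.approx(stats.norm.cdf(z), abs=0.01)

    def test_jensen_bound_holds_exactly(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            draws = rng.normal(530, rng.uniform(0.5, 30), size=500)
            b = rng.uniform(500, 560)
            eg, _, _ = rs.expected_gain(draws, b)
            assert eg >= max(draws.mean() - b, 0.0) - 1e-12

    def test_monotone_in_base_wavelength(self):
        rng = np.random.default_rng(8)
        draws = rng.normal(540, 12, 300)
        bases = np.linspace(500, 580, 17)
        egs = [rs.expected_gain(draws, b)[0] for b in bases]
        probs = [rs.expected_gain(draws, b)[1] for b in bases]
        assert all(a >= b_ for a, b_ in zip(egs, egs[1:]))
        assert all(a >= b_ for a, b_ in zip(probs, probs[1:]))

    def test_exploration_prefers_wider_predictive_spread(self):
        # equal means just below base: the broader distribution wins
        rng = np.random.default_rng(9)
        base = 540.0
        narrow = rng.normal(538.0, 1.0, 50_000)
        wide = rng.normal(538.0, 15.0, 50_000)
        assert rs.expected_gain(wide, base)[0] > rs.expected_gain(narrow, base)[0]

    @settings(deadline=None, max_examples=50)
    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.floats(min_value=-30, max_value=30))
    def test_shift_equivariance(self, seed, c):
        rng = np.random.default_rng(seed)
        draws = rng.normal(540, 10, 200)
        b = 535.0
        eg0, p0, _ = rs.expected_gain(draws, b)
        eg1, p1, _ = rs.expected_gain(draws + c, b + c)
        assert eg1 == pytest.approx(eg0, abs=1e-9)
        assert p1 == p0

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            rs.expected_gain(np.array([]), 520.0)


def score(id_, eg, subfamily="PR", base=520.0):
    return rs.CandidateScore(
        id=id_, subfamily=subfamily, lambda_base=base,
        pred_mean=base + eg, pred_sd=1.0, expected_gain=eg,
        prob_positive_gain=1.0, mc_standard_error=0.01,
    )


class TestRankCandidates:
    def test_strict_threshold_semantics(self):
        scores = [score("a", 12.0), score("b", 9.0),
                  score("c", 10.0001), score("d", 30.0)]
        res = rs.rank_candidates(scores, threshold=10.0)
        assert [s.expected_gain for s in res.selected] == [30.0, 12.0, 10.0001]
        # exactly-at-threshold is excluded
        res10 = rs.rank_candidates([score("x", 10.0)], threshold=10.0)
        assert res10.selected == ()

    def test_empty_candidate_list(self):
        res = rs.rank_candidates([], threshold=10.0)
        assert res.ranked == () and res.selected == ()

    def test_ties_broken_by_id_ascending(self):
        scores = [score("zeta", 15.0), score("alpha", 15.0), score("mid", 15.0)]
        res = rs.rank_candidates(scores)
        assert [s.id for s in res.ranked] == ["alpha", "mid", "zeta"]

    def test_subfamily_whitelist_filters_selection_not_ranking(self):
        scores = [score("a", 20.0, subfamily="PR"),
                  score("b", 25.0, subfamily="NotAPump")]
        res = rs.rank_candidates(scores, threshold=10.0,
                                 subfamily_whitelist=["PR"])
        assert [s.id for s in res.ranked] == ["b", "a"]
        assert [s.id for s in res.selected] == ["a"]

    def test_unknown_subfamily_goes_unscored(self, small_posterior, small_sim):
        cands = list(small_sim.candidate_encoded)
        import dataclasses
        cands[0] = dataclasses.replace(cands[0], subfamily="mystery")
        scores, unscored = rs.score_candidates(
            small_posterior, cands, small_sim.base_wavelengths)
        assert unscored == [cands[0].id]
        assert len(scores) == len(cands) - 1

    def test_end_to_end_replay_of_estimator_and_filter(self, small_posterior,
                                                       small_sim):
        scores, unscored = rs.score_candidates(
            small_posterior, small_sim.candidate_encoded,
            small_sim.base_wavelengths)
        res = rs.rank_candidates(scores, threshold=5.0, unscored=unscored)
        # brute-force recomputation, independent of the scoring path
        mu, beta = small_posterior.mu, small_posterior.beta
        for s in res.ranked:
            cand = next(c for c in small_sim.candidate_encoded if c.id == s.id)
            draws = mu + beta @ cand.x
            eg = np.maximum(draws - s.lambda_base, 0).mean()
            assert s.expected_gain == pytest.approx(eg)
        expect_sel = sorted(
            [s.id for s in res.ranked if s.expected_gain > 5.0])
        assert sorted(s.id for s in res.selected) == expect_sel
        order = [(-s.expected_gain, s.id) for s in res.ranked]
        assert order == sorted(order)

    def test_training_duplicates_flagged(self, small_posterior, small_sim):
        train_strings = {s.pocket_string for s in small_sim.train_encoded}
        # a candidate sharing a training pocket string must be flagged
        import dataclasses
        dup = dataclasses.replace(
            small_sim.candidate_encoded[0],
            pocket_string=next(iter(train_strings)))
        scores, _ = rs.score_candidates(
            small_posterior, [dup], small_sim.base_wavelengths,
            training_pocket_strings=train_strings)
        assert scores[0].matches_training

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            rs.rank_candidates([], threshold=-1.0)
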