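import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rngxe import (
    GeneticCovariance,
    PosteriorSamples,
    additive_variance_at,
    assign_gradients,
    genetic_correlation,
    heritability_at,
)
from rngxe.posterior_summary import GradientLevel, SummaryError, summarize


def make_draws(G_draws, s2cg, s2pe, s2e, cg_ids=None, cg_mean=None):
    S = len(G_draws)
    cg_ids = cg_ids or ["c1", "c2"]
    cg_mean = cg_mean if cg_mean is not None else np.zeros(len(cg_ids))
    return PosteriorSamples(
        beta=np.zeros((S, 3)),
        cg=None, a=None, b=None, pm=None,
        G=np.asarray(G_draws, dtype=float),
        sigma2_cg=np.asarray(s2cg, dtype=float),
        sigma2_pe=np.asarray(s2pe, dtype=float),
        sigma2_e=np.asarray(s2e, dtype=float),
        animal_ids=[1], cg_ids=cg_ids, dam_ids=[],
        cg_mean=np.asarray(cg_mean, dtype=float),
        a_mean=np.zeros(1), b_mean=np.zeros(1), pm_mean=np.zeros(0),
    )


class TestAssignGradients:
    def test_forced_partition_of_ten(self):
        sols = {i: float(i) for i in range(1, 11)}
        levels = assign_gradients(sols, k=5)
        assert [lv.X for lv in levels] == [1.5, 3.5, 5.5, 7.5, 9.5]
        assert all(lv.n_cgs == 2 for lv in levels)

    def test_all_equal_solutions_still_partition(self):
        sols = {i: 1.0 for i in range(10)}
        levels = assign_gradients(sols, k=5)
        assert sum(lv.n_cgs for lv in levels) == 10
        assert all(lv.X == 1.0 for lv in levels)

    def test_23_cgs_match_brute_force_split(self):
        rng = np.random.default_rng(0)
        sols = {f"c{i}": float(v) for i, v in enumerate(rng.normal(size=23))}
        levels = assign_gradients(sols, k=5)
        assert [lv.n_cgs for lv in levels] == [5, 5, 5, 4, 4]
        # brute-force oracle: sort then slice
        ordered = sorted(sols.items(), key=lambda kv: (kv[1], str(kv[0])))
        start = 0
        for lv, sz in zip(levels, [5, 5, 5, 4, 4]):
            chunk = ordered[start : start + sz]
            start += sz
            assert lv.member_cgs == {c for c, _ in chunk}
            assert lv.X == pytest.approx(np.mean([v for _, v in chunk]))

    def test_levels_partition_and_x_nondecreasing(self):
        rng = np.random.default_rng(1)
        sols = {i: float(v) for i, v in enumerate(rng.normal(size=37))}
        levels = assign_gradients(sols, k=5)
        seen = set()
        for lv in levels:
            assert not (lv.member_cgs & seen)
            seen |= lv.member_cgs
        assert seen == set(sols)
        xs = [lv.X for lv in levels]
        assert xs == sorted(xs)

    def test_fewer_cgs_than_levels_is_error(self):
        with pytest.raises(SummaryError):
            assign_gradients({1: 0.0, 2: 1.0}, k=5)


class TestCovarianceFunction:
    def test_origin_returns_intercept_variance(self):
        G = GeneticCovariance(100, 25, 20)
        assert additive_variance_at(0.0, G) == 100.0

    def test_hand_evaluated_quadratic(self):
        G = GeneticCovariance(100, 25, 20)
        assert additive_variance_at(2.0, G) == pytest.approx(280.0, abs=1e-12)

    def test_singular_g_vanishes_at_minimum(self):
        G = GeneticCovariance(4, 1, 2)  # singular: minimum at X = -sigma_il/sigma2_l
        assert additive_variance_at(-2.0, G) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_for_random_psd_matrices(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            L = rng.normal(size=(2, 2))
            M = L @ L.T
            G = GeneticCovariance(M[0, 0], M[1, 1], M[0, 1])
            for X in np.linspace(-50, 50, 21):
                assert additive_variance_at(X, G) >= -1e-9


class TestGeneticCorrelation:
    def test_identical_environments_give_one(self):
        G = GeneticCovariance(100, 25, 20)
        assert genetic_correlation(1.3, 1.3, G) == 1.0

    def test_no_gxe_gives_one_everywhere(self):
        G = GeneticCovariance(100, 0, 0)
        for xx, xy in [(-3, 5), (0, 2), (10, -10)]:
            assert genetic_correlation(xx, xy, G) == 1.0

    def test_hand_evaluated_value(self):
        G = GeneticCovariance(100, 25, 0)
        r = genetic_correlation(0.0, 2.0, G)
        assert r == pytest.approx(100 / np.sqrt(100 * 200), abs=1e-12)

    def test_zero_variance_flags_degenerate(self):
        G = GeneticCovariance(4, 1, 2)
        with pytest.raises(SummaryError, match="degenerate"):
            genetic_correlation(-2.0, 1.0, G)

    @given(
        xx=st.floats(-20, 20), xy=st.floats(-20, 20),
        scale=st.floats(0.01, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_exchangeable_and_scale_invariant(self, xx, xy, scale):
        G = GeneticCovariance(100, 25, 20)
        Gs = GeneticCovariance(100 * scale, 25 * scale, 20 * scale)
        r1 = genetic_correlation(xx, xy, G)
        assert genetic_correlation(xy, xx, G) == pytest.approx(r1, abs=1e-12)
        assert genetic_correlation(xx, xy, Gs) == pytest.approx(r1, rel=1e-9)
        assert -1.0 <= r1 <= 1.0

    def test_monotone_separation_same_sign_environments(self):
        # correlation decays as environments separate (with Xx*Xy >= 0)
        G = GeneticCovariance(100, 25, 20)
        for base in (0.0, 1.0, 3.0):
            rs = [genetic_correlation(base, base + d, G) for d in np.linspace(0, 15, 40)]
            assert all(rs[i] >= rs[i + 1] - 1e-12 for i in range(len(rs) - 1))


class TestHeritability:
    def test_forced_ratio_single_draw(self):
        draws = make_draws([[100, 0, 0]], [0.0], [0.0], [100.0])
        lv = GradientLevel(level=1, X=0.0, member_cgs={"c1"})
        mean, sd = heritability_at(lv, draws)
        assert mean == 0.5 and sd == 0.0

    def test_identical_draws_have_zero_sd(self):
        draws = make_draws([[100, 25, 20]] * 50, [150] * 50, [30] * 50, [200] * 50)
        lv = GradientLevel(level=1, X=1.0, member_cgs={"c1"})
        _, sd = heritability_at(lv, draws)
        assert sd == 0.0

    def test_matches_per_draw_recomputation_oracle(self):
        rng = np.random.default_rng(3)
        S = 1000
        G = np.column_stack([
            rng.uniform(50, 150, S), rng.uniform(1, 30, S), rng.uniform(-5, 5, S)
        ])
        s2pe, s2e = rng.uniform(10, 50, S), rng.uniform(100, 300, S)
        draws = make_draws(G, np.full(S, 150.0), s2pe, s2e)
        lv = GradientLevel(level=2, X=1.7, member_cgs={"c1"})
        mean, sd = heritability_at(lv, draws)
        h2 = np.array([
            (g[0] + 1.7**2 * g[1] + 2 * 1.7 * g[2])
            / ((g[0] + 1.7**2 * g[1] + 2 * 1.7 * g[2]) + pe + e)
            for g, pe, e in zip(G, s2pe, s2e)
        ])
        assert mean == pytest.approx(h2.mean(), abs=1e-12)
        assert sd == pytest.approx(h2.std(), abs=1e-12)
        assert np.all((h2 >= 0) & (h2 <= 1))


class TestSummarize:
    def test_summary_structure_and_invariants(self):
        rng = np.random.default_rng(4)
        S, ncg = 200, 15
        G = np.column_stack([
            rng.uniform(80, 120, S), rng.uniform(5, 10, S), rng.uniform(5, 15, S)
        ])
        draws = make_draws(
            G, rng.uniform(100, 200, S), rng.uniform(20, 40, S), rng.uniform(150, 250, S),
            cg_ids=[f"c{i}" for i in range(ncg)],
            cg_mean=rng.normal(0, 3, ncg),
        )
        gs = summarize(draws, k=5)
        assert len(gs.levels) == 5
        np.testing.assert_allclose(gs.r_g, gs.r_g.T)
        np.testing.assert_allclose(np.diag(gs.r_g), 1.0)
        assert np.all(gs.r_g >= -1) and np.all(gs.r_g <= 1)
        assert all(v[0] >= 0 for v in gs.sigma2_a.values())
        assert all(0 <= v[0] <= 1 for v in gs.h2.values())
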