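import numpy as np
import pytest

from rngxe import (
    GeneticCovariance,
    ModelConfig,
    PosteriorSamples,
    SimulationConfig,
    fit,
    geweke_diagnostic,
    geweke_table,
    simulate,
)
from rngxe.rn_model import ModelError


@pytest.fixture(scope="module")
def fitted_small(small_simulation):
    cfg, ped, records, truth = small_simulation
    mc = ModelConfig(n_iterations=3000, burn_in=1000, thin=5, seed=77)
    return fit(records, ped, mc), ped, records


class TestModelConfig:
    def test_rejects_burn_in_past_iterations(self):
        with pytest.raises(ModelError):
            ModelConfig(n_iterations=100, burn_in=100).validate()

    def test_rejects_zero_thin(self):
        with pytest.raises(ModelError):
            ModelConfig(thin=0).validate()

    @pytest.mark.parametrize(
        "n_iter,burn,thin",
        [(1000, 200, 10), (1001, 200, 10), (999, 0, 7), (100, 99, 1), (200000, 20000, 10)],
    )
    def test_saved_draw_count_formula(self, n_iter, burn, thin):
        mc = ModelConfig(n_iterations=n_iter, burn_in=burn, thin=thin)
        assert mc.n_saved == (n_iter - burn) // thin


class TestFit:
    def test_draw_count_and_shapes(self, fitted_small):
        samples, ped, records = fitted_small
        assert samples.n_draws == (3000 - 1000) // 5
        assert samples.a.shape == (samples.n_draws, ped.n)
        assert samples.beta.shape[1] == 3
        assert len(samples.cg_ids) == len({r.cg for r in records})

    def test_every_saved_g_draw_positive_definite(self, fitted_small):
        samples, _, _ = fitted_small
        det = samples.G[:, 0] * samples.G[:, 1] - samples.G[:, 2] ** 2
        assert (samples.G[:, 0] > 0).all() and (det > 0).all()

    def test_seeded_determinism_bit_identical(self, small_simulation):
        _, ped, records, _ = small_simulation
        mc = ModelConfig(n_iterations=500, burn_in=100, thin=2, seed=5)
        s1 = fit(records, ped, mc)
        s2 = fit(records, ped, mc)
        np.testing.assert_array_equal(s1.G, s2.G)
        np.testing.assert_array_equal(s1.a, s2.a)
        np.testing.assert_array_equal(s1.sigma2_e, s2.sigma2_e)

    def test_unknown_animal_is_hard_error(self, small_simulation):
        _, ped, records, _ = small_simulation
        bad = records[:5]
        from dataclasses import replace

        bad = [replace(bad[0], animal=999999)] + list(records[1:5])
        with pytest.raises(ModelError, match="pedigree"):
            fit(bad, ped, ModelConfig(n_iterations=200, burn_in=50, thin=1))

    def test_single_cg_is_error(self, small_simulation):
        _, ped, records, _ = small_simulation
        one_cg = [r for r in records if r.cg == records[0].cg]
        with pytest.raises(ModelError, match="contemporary"):
            fit(one_cg, ped, ModelConfig(n_iterations=200, burn_in=50, thin=1))

    def test_update_order_does_not_change_posterior(self, small_simulation):
        # two fixed sweep orders target the same stationary distribution
        _, ped, records, _ = small_simulation
        mc_a = ModelConfig(n_iterations=6000, burn_in=2000, thin=4, seed=31)
        mc_b = ModelConfig(
            n_iterations=6000, burn_in=2000, thin=4, seed=32, update_order="alternate"
        )
        sa = fit(records, ped, mc_a)
        sb = fit(records, ped, mc_b)
        for col in ("sigma2_i", "sigma2_e", "sigma2_cg"):
            ca = sa.dispersion_frame()[col].to_numpy()
            cb = sb.dispersion_frame()[col].to_numpy()
            # Monte Carlo z on the difference of means with autocorrelation-
            # inflated standard errors (conservative factor)
            se = np.sqrt(ca.var() / len(ca) + cb.var() / len(cb)) * 4.0
            assert abs(ca.mean() - cb.mean()) < 5 * se

    def test_save_load_roundtrip(self, fitted_small, tmp_path):
        samples, _, _ = fitted_small
        samples.save(tmp_path)
        back = PosteriorSamples.load(tmp_path)
        np.testing.assert_allclose(back.G, samples.G)
        np.testing.assert_allclose(back.b_mean, samples.b_mean, atol=1e-12)
        assert back.cg_ids == [str(c) for c in samples.cg_ids] or back.cg_ids == samples.cg_ids


class TestReducedModel:
    def test_frozen_slopes_recover_standard_animal_model(self):
        """With slopes frozen the sampler is a plain additive animal model;
        REML on the dense likelihood is the independent oracle."""
        from oracles import reml_animal_model, tabular_a

        cfg = SimulationConfig(
            n_founders=120, n_generations=2, n_cgs=12, seed=99,
            true_G=GeneticCovariance(100.0, 0.0, 0.0),
        )
        ped, records, _ = simulate(cfg)
        mc = ModelConfig(n_iterations=12000, burn_in=3000, thin=5, seed=99, freeze_slopes=True)
        samples = fit(records, ped, mc)
        assert np.all(samples.G[:, 1] == 0) and np.all(samples.G[:, 2] == 0)
        df = samples.dispersion_frame()

        A = tabular_a(ped.sire_idx, ped.dam_idx)
        y = np.array([r.value for r in records])
        ages = np.array([r.cow_age for r in records])
        ac = ages - ages.mean()
        X = np.column_stack([np.ones(len(y)), ac, ac**2])
        cg_ids = sorted({r.cg for r in records}, key=str)
        cgi = {c: j for j, c in enumerate(cg_ids)}
        cg_index = np.array([cgi[r.cg] for r in records])
        z_animal = np.array([ped.id_index[r.animal] for r in records])
        dams = sorted({ped.id_index[r.dam] for r in records if r.dam is not None})
        dmi = {d: j for j, d in enumerate(dams)}
        pm_index = np.array(
            [dmi[ped.id_index[r.dam]] if r.dam is not None else -1 for r in records]
        )
        reml = reml_animal_model(y, X, A, z_animal, cg_index, pm_index)
        for key in ("sigma2_i", "sigma2_cg", "sigma2_pe", "sigma2_e"):
            lo, hi = np.quantile(df[key], [0.025, 0.975])
            rlo, rhi = reml["ci"][key]
            # overlapping 95% intervals (posterior vs asymptotic REML)
            assert max(lo, rlo) <= min(hi, rhi), (key, reml[key], (lo, hi), (rlo, rhi))


class TestGeweke:
    def test_constant_chain_degenerate(self):
        res = geweke_diagnostic(np.ones(1000))
        assert res.degenerate and not res.flagged and np.isnan(res.z)

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            geweke_diagnostic(np.arange(50.0))

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            geweke_diagnostic(np.random.default_rng(0).normal(size=200), 0.6, 0.6)

    def test_iid_chain_usually_passes(self):
        rng = np.random.default_rng(8)
        flags = [geweke_diagnostic(rng.standard_normal(5000)).flagged for _ in range(50)]
        assert sum(flags) <= 8

    def test_two_sd_trend_flagged(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(10000) + np.linspace(0, 2, 10000)
        res = geweke_diagnostic(x)
        assert res.flagged and abs(res.z) > 1.96

    def test_geweke_table_covers_all_dispersion_chains(self, fitted_small):
        samples, _, _ = fitted_small
        tbl = geweke_table(samples)
        assert set(tbl["parameter"]) == {
            "sigma2_i", "sigma2_l", "sigma_il", "sigma2_cg", "sigma2_pe", "sigma2_e"
        }
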