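"""Evolutionary predictions, EBV trends, drift null and bias metric."""

import numpy as np
import pytest

from wildqg.evolution import (
    bias_decomposition,
    breeders_equation,
    drift_null,
    ebv_trend,
    sts_prediction,
)
from wildqg.posterior import PosteriorSamples

from conftest import make_pedigree, random_pedigree


class TestBreedersEquation:
    def test_point_chains(self):
        r = breeders_equation(np.array([0.26]), np.array([0.23]))
        assert r[0] == pytest.approx(0.0598)

    def test_zero_beta_gives_zero_response(self):
        r = breeders_equation(np.full(100, 0.3), np.zeros(50))
        assert np.all(r == 0)

    def test_independent_product_mean(self):
        """E[V_A * beta] = E[V_A] E[beta] for independent posteriors."""
        rng = np.random.default_rng(1)
        va = rng.normal(0.25, 0.05, 100_000)
        beta = rng.normal(0.2, 0.05, 100_000)
        r = breeders_equation(va, beta, seed=2)
        assert r.mean() == pytest.approx(0.05, abs=1e-3)

    def test_pairing_seed_invariant_in_distribution(self):
        from scipy.stats import ks_2samp
        rng = np.random.default_rng(3)
        va = rng.gamma(4.0, 0.06, 5000)
        beta = rng.normal(0.2, 0.1, 4000)   # unequal lengths
        r1 = breeders_equation(va, beta, seed=4)
        r2 = breeders_equation(va, beta, seed=5)
        assert ks_2samp(r1, r2).pvalue > 0.01

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            breeders_equation(np.array([]), np.array([0.2]))


class TestSTS:
    def test_zero_cov_draws(self):
        s = PosteriorSamples(params={"cov_A": np.zeros(100)})
        assert np.all(sts_prediction(s) == 0)

    def test_missing_cov_rejected(self):
        with pytest.raises(ValueError):
            sts_prediction(PosteriorSamples(params={"V_A_t1": np.ones(10)}))

    def test_recovery_with_real_genetic_link(self):
        """Population with a direct size effect on fitness (true
        cov_A(w, z) = b_w V_A ~ 0.06): the R_STS HPD covers the truth.
        Identification is weak at this design, so coverage -- not point
        accuracy -- is the testable property."""
        from wildqg.animal_model import MCMCSettings, fit_bivariate_animal_model
        from wildqg.posterior import hpd_interval
        from wildqg.selection import standardize
        from wildqg.simulate import SimulationConfig, simulate_population

        pop = simulate_population(SimulationConfig(seed=3))
        fem = pop.phenotypes[pop.phenotypes.sex == "F"].reset_index(drop=True)
        trait = standardize(fem["size_cm"].to_numpy(), "F")
        biv = fit_bivariate_animal_model(
            fem.assign(size_z=trait.z), pop.ped,
            settings=MCMCSettings(burn_in=2000, n_iter=20000, thin=20, seed=5),
        )
        lo, hi = hpd_interval(sts_prediction(biv))
        truth = pop.truth["true_cov_A_wz"]
        assert lo <= truth <= hi


class TestEbvTrend:
    def test_exact_line(self):
        # cohort means exactly (0.0, 0.1, 0.2) over years 1, 2, 3
        ebv = np.array([[0.0, 0.0, 0.1, 0.1, 0.2, 0.2]])
        cohorts = np.array([1, 1, 2, 2, 3, 3])
        out = ebv_trend(ebv, cohorts, generation_time=4.0)
        assert out.slopes[0] == pytest.approx(0.1)
        assert out.haldanes[0] == pytest.approx(0.4)

    def test_haldane_conversion(self):
        """0.0005 PSD/yr at a 4-year generation = 0.002 Haldanes."""
        ebv = np.array([0.0, 0.0005, 0.001, 0.0015])[None, :]
        cohorts = np.array([0, 1, 2, 3])
        out = ebv_trend(ebv, cohorts, generation_time=4.0)
        assert out.slopes[0] == pytest.approx(0.0005)
        assert out.haldanes[0] == pytest.approx(0.002)

    def test_constant_ebvs_flagged(self):
        ebv = np.full((50, 6), 0.7)
        out = ebv_trend(ebv, np.array([1, 1, 2, 2, 3, 3]))
        assert np.all(out.slopes == 0)
        assert out.zero_variance

    def test_shift_equivariance(self):
        """Adding c per year to every EBV adds c to the slope."""
        rng = np.random.default_rng(6)
        cohorts = np.repeat([1990, 1991, 1992, 1993], 25)
        ebv = rng.standard_normal((40, 100))
        base = ebv_trend(ebv, cohorts).slopes
        shifted = ebv_trend(ebv + 0.3 * (cohorts - 1990), cohorts).slopes
        assert np.allclose(shifted - base, 0.3)

    def test_too_few_cohorts_rejected(self):
        with pytest.raises(ValueError):
            ebv_trend(np.zeros((5, 4)), np.array([1, 1, 2, 2]))


class TestDriftNull:
    def test_zero_va_degenerate(self, full_sib_family):
        obs = np.array([0.02, -0.01, 0.03])
        out = drift_null(
            full_sib_family, np.zeros(3), obs,
            full_sib_family.ids, [1, 1, 2, 2, 3], seed=1,
        )
        assert np.all(out.drift_slopes == 0)
        assert out.p_gt_drift == np.mean(obs > 0)

    def test_founder_pedigree_symmetric_null(self):
        """Exchangeable founders: drift slopes are symmetric about 0."""
        ped = random_pedigree(np.random.default_rng(7), 120, n_founders=120)
        cohorts = np.tile([0, 1, 2, 3], 30)
        out = drift_null(
            ped, np.ones(2000), np.zeros(2000), ped.ids, cohorts, seed=8,
        )
        s = out.drift_slopes
        assert abs(s.mean()) < 3 * s.std() / np.sqrt(s.size)
        assert 0.4 < np.mean(s > 0) < 0.6

    def test_calibrated_under_null(self):
        """Observed slopes drawn from the drift distribution itself:
        exceedance probability is ~1/2."""
        ped = random_pedigree(np.random.default_rng(9), 150, n_founders=40)
        cohorts = np.tile([0, 1, 2, 3, 4], 30)
        va = np.full(2000, 0.8)
        ref = drift_null(ped, va, np.zeros(2000), ped.ids, cohorts, seed=10)
        out = drift_null(ped, va, ref.drift_slopes, ped.ids, cohorts, seed=11)
        assert 0.45 < out.p_gt_drift < 0.55


class TestBiasDecomposition:
    @staticmethod
    def _samples(**kw):
        return PosteriorSamples(params={k: np.asarray(v, float) for k, v in kw.items()})

    def test_proportional_draws_give_zero_bias(self):
        """cov terms proportional to variances at ratio r: beta_G =
        beta_E = r and delta = 0 in every draw."""
        rng = np.random.default_rng(12)
        r = 0.4
        v = {t: rng.gamma(5, 0.1, 200) for t in ("A", "dam", "cohort", "resid")}
        s = self._samples(
            **{f"V_{t}_t1": v[t] for t in v},
            **{f"cov_{t}": r * v[t] for t in v},
        )
        out = bias_decomposition(s)
        assert np.allclose(out.beta_G, r)
        assert np.allclose(out.beta_E, r)
        assert np.allclose(out.delta_beta, 0.0)

    def test_identity_holds_per_draw(self):
        rng = np.random.default_rng(13)
        s = self._samples(
            **{f"V_{t}_t1": rng.gamma(3, 0.2, 500)
               for t in ("A", "dam", "cohort", "resid")},
            **{f"cov_{t}": rng.normal(0, 0.1, 500)
               for t in ("A", "dam", "cohort", "resid")},
        )
        out = bias_decomposition(s)
        assert np.allclose(out.delta_beta + out.beta_G, out.beta_E)

    def test_zero_denominator_draws_excluded(self):
        s = self._samples(
            V_A_t1=[1.0, 0.0], V_dam_t1=[0.1, 0.1], V_cohort_t1=[0.1, 0.1],
            V_resid_t1=[0.5, 0.5], cov_A=[0.2, 0.2], cov_dam=[0.0, 0.0],
            cov_cohort=[0.0, 0.0], cov_resid=[0.1, 0.1],
        )
        out = bias_decomposition(s)
        assert out.n_excluded == 1
        assert out.beta_G.size == 1
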