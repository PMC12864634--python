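import math

import numpy as np
import pytest
from scipy import stats

from metabf import (
    MetaInputError, ModelMarginals, PriorSpec, analyze_bayes,
    compute_marginals, interpret_bf, log_marginal_fe_alt, log_marginal_fe_null,
    log_marginal_re_alt, log_marginal_re_null, model_average, posterior_mu,
    savage_dickey_bf_fe, shrinkage_estimates,
)
from conftest import make_dataset

PRIOR = PriorSpec()


# ---------------------------------------------------------------------------
# brute-force oracles, independent of the quadrature path
# ---------------------------------------------------------------------------

def riemann_fe_alt(ds, prior=PRIOR, lo=-50.0, hi=50.0, n=1_000_001):
    mu = np.linspace(lo, hi, n)
    y, se = np.array(ds.y), np.array(ds.se)
    ll = np.sum(stats.norm.logpdf(y[None, :], mu[:, None], se[None, :]), axis=1)
    dens = stats.cauchy.pdf(mu, prior.cauchy_location, prior.cauchy_scale)
    return math.log(np.trapezoid(np.exp(ll) * dens, mu))


def riemann_re_null(ds, prior=PRIOR, n=400_001):
    lt = np.linspace(-20.0, 10.0, n)
    tau = np.exp(lt)
    y, se = np.array(ds.y), np.array(ds.se)
    sd = np.sqrt(se[None, :] ** 2 + tau[:, None] ** 2)
    ll = np.sum(stats.norm.logpdf(y[None, :], 0.0, sd), axis=1)
    logp = stats.invgamma.logpdf(tau, prior.ig_shape, scale=prior.ig_scale)
    return math.log(np.trapezoid(np.exp(ll + logp + lt), lt))


def grid_re_alt(ds, prior=PRIOR, n=2000):
    """2-D brute force: mu on a linear grid, tau on a log grid."""
    mu = np.linspace(-30.0, 30.0, n)
    lt = np.linspace(-12.0, 6.0, n)
    tau = np.exp(lt)
    y, se = np.array(ds.y), np.array(ds.se)
    v = se[None, :] ** 2 + tau[:, None] ** 2
    s0 = np.sum(1 / v, axis=1)
    s1 = np.sum(y / v, axis=1)
    s2 = np.sum(y ** 2 / v, axis=1)
    logdet = np.sum(np.log(2 * np.pi * v), axis=1)
    ll = -0.5 * (logdet[:, None] + s2[:, None] - 2 * mu[None, :] * s1[:, None]
                 + mu[None, :] ** 2 * s0[:, None])
    logp_mu = stats.cauchy.logpdf(mu, prior.cauchy_location, prior.cauchy_scale)
    logp_tau = stats.invgamma.logpdf(tau, prior.ig_shape, scale=prior.ig_scale)
    integrand = np.exp(ll + logp_mu[None, :] + (logp_tau + lt)[:, None])
    return math.log(np.trapezoid(np.trapezoid(integrand, mu, axis=1), lt))


class TestFeNull:
    def test_standard_normal_at_mode(self, single_study_dataset):
        assert log_marginal_fe_null(single_study_dataset) == \
            pytest.approx(math.log(1 / math.sqrt(2 * math.pi)), abs=1e-12)

    def test_unit_shift(self):
        ds = make_dataset([(1.0, 1.0)])
        assert log_marginal_fe_null(ds) == \
            pytest.approx(math.log(1 / math.sqrt(2 * math.pi)) - 0.5, abs=1e-12)

    def test_sums_over_independent_studies(self, five_study_dataset):
        total = sum(log_marginal_fe_null(make_dataset([(s.y, s.se)]))
                    for s in five_study_dataset)
        assert log_marginal_fe_null(five_study_dataset) == \
            pytest.approx(total, abs=1e-10)


class TestQuadratureVsOracles:
    def test_fe_alt_single_study(self, single_study_dataset):
        assert log_marginal_fe_alt(single_study_dataset, PRIOR) == \
            pytest.approx(riemann_fe_alt(single_study_dataset), abs=1e-6)

    def test_fe_alt_three_studies(self, three_study_dataset):
        assert log_marginal_fe_alt(three_study_dataset, PRIOR) == \
            pytest.approx(riemann_fe_alt(three_study_dataset), abs=1e-5)

    def test_re_null_single_study(self, single_study_dataset):
        assert log_marginal_re_null(single_study_dataset, PRIOR) == \
            pytest.approx(riemann_re_null(single_study_dataset), abs=1e-6)

    def test_re_null_three_studies(self, three_study_dataset):
        assert log_marginal_re_null(three_study_dataset, PRIOR) == \
            pytest.approx(riemann_re_null(three_study_dataset), abs=1e-5)

    def test_re_alt_two_studies(self):
        ds = make_dataset([(-0.5, 0.3), (-0.2, 0.25)])
        assert log_marginal_re_alt(ds, PRIOR) == \
            pytest.approx(grid_re_alt(ds), abs=1e-5)

    def test_re_null_dominated_variance_limit(self):
        """With huge se the tau contribution is negligible: closed form.

        The gap decays like the inverse-gamma tail P(tau > se) ~ 0.15/se,
        so se = 1000 is needed for agreement at 1e-3."""
        ds = make_dataset([(0.5, 1000.0), (-1.0, 1000.0)])
        assert log_marginal_re_null(ds, PRIOR) == \
            pytest.approx(log_marginal_fe_null(ds), abs=1e-3)

    def test_re_alt_degenerates_to_fe_alt_as_tau_prior_shrinks(
            self, three_study_dataset):
        tiny = PriorSpec(ig_scale=1e-6)
        assert log_marginal_re_alt(three_study_dataset, tiny) == \
            pytest.approx(log_marginal_fe_alt(three_study_dataset, PRIOR),
                          abs=1e-3)

    @pytest.mark.parametrize("fn", [log_marginal_fe_alt, log_marginal_re_null,
                                    log_marginal_re_alt])
    def test_symmetric_priors_ignore_sign(self, fn, three_study_dataset):
        neg = make_dataset([(-s.y, s.se) for s in three_study_dataset])
        assert fn(three_study_dataset, PRIOR) == \
            pytest.approx(fn(neg, PRIOR), abs=1e-8)


class TestModelAverage:
    def test_indifference(self):
        m = ModelMarginals(-3.0, -3.0, -3.0, -3.0)
        bf10, bf_rf, probs = model_average(m, PRIOR)
        assert bf10 == pytest.approx(1.0, abs=1e-12)
        assert bf_rf == pytest.approx(1.0, abs=1e-12)
        assert all(p == pytest.approx(0.25) for p in probs.values())

    def test_hand_set_marginals(self):
        m = ModelMarginals(math.log(1), math.log(2), math.log(3), math.log(4))
        bf10, bf_rf, probs = model_average(m, PRIOR)
        assert bf10 == pytest.approx((2 + 4) / (1 + 3), rel=1e-12)
        assert bf_rf == pytest.approx((3 + 4) / (1 + 2), rel=1e-12)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)
        assert probs["RE1"] == pytest.approx(0.4, rel=1e-12)

    def test_swapping_hypotheses_inverts_bf10(self, three_study_dataset):
        m = compute_marginals(three_study_dataset, PRIOR)
        swapped = ModelMarginals(m.logml_fe1, m.logml_fe0,
                                 m.logml_re1, m.logml_re0)
        bf, _, _ = model_average(m, PRIOR)
        bf_sw, _, _ = model_average(swapped, PRIOR)
        assert bf * bf_sw == pytest.approx(1.0, rel=1e-10)

    def test_zero_prior_on_a_whole_hypothesis_errors(self):
        m = ModelMarginals(-1.0, -1.0, -1.0, -1.0)
        prior = PriorSpec(model_prior=(0.5, 0.0, 0.5, 0.0))
        with pytest.raises(MetaInputError, match="zero mass"):
            model_average(m, prior)

    def test_nonuniform_model_prior_reweights(self):
        m = ModelMarginals(math.log(1), math.log(2), math.log(3), math.log(4))
        prior = PriorSpec(model_prior=(0.4, 0.4, 0.1, 0.1))
        bf10, _, _ = model_average(m, prior)
        # prior-weighted averages within each hypothesis
        expected = ((0.4 * 2 + 0.1 * 4) / 0.5) / ((0.4 * 1 + 0.1 * 3) / 0.5)
        assert bf10 == pytest.approx(expected, rel=1e-12)


class TestPosterior:
    def test_symmetric_single_study_has_median_zero(self, single_study_dataset):
        post = posterior_mu(single_study_dataset, PRIOR)
        assert post.mu_median == pytest.approx(0.0, abs=1e-3)
        assert post.cri_low == pytest.approx(-post.cri_high, abs=1e-3)

    def test_grid_integrates_to_one(self, three_study_dataset):
        post = posterior_mu(three_study_dataset, PRIOR)
        assert np.trapezoid(post.density, post.grid) == \
            pytest.approx(1.0, abs=1e-6)
        assert post.cri_low < post.mu_median < post.cri_high

    def test_likelihood_domination_with_tiny_se(self):
        ds = make_dataset([(-0.5, 1e-3), (-0.5, 1e-3), (-0.5, 1e-3)])
        post = posterior_mu(ds, PRIOR)
        assert post.mu_mean == pytest.approx(-0.5, abs=1e-3)
        assert post.cri_high - post.cri_low < 0.01

    def test_negating_effects_mirrors_posterior(self, three_study_dataset):
        neg = make_dataset([(-s.y, s.se) for s in three_study_dataset])
        a = posterior_mu(three_study_dataset, PRIOR)
        b = posterior_mu(neg, PRIOR)
        assert b.mu_mean == pytest.approx(-a.mu_mean, abs=1e-8)
        assert (b.cri_high - b.cri_low) == \
            pytest.approx(a.cri_high - a.cri_low, abs=1e-8)

    def test_spike_and_slab_averaging_keeps_null_mass(self, three_study_dataset):
        post = posterior_mu(three_study_dataset, PRIOR, include_null=True)
        _, _, probs = model_average(compute_marginals(three_study_dataset,
                                                      PRIOR), PRIOR)
        assert post.point_mass_at_zero == \
            pytest.approx(probs["FE0"] + probs["RE0"], abs=1e-10)

    def test_posterior_mean_against_grid_oracle(self):
        """K=2: posterior mean under RE1-dominated average vs brute force."""
        ds = make_dataset([(-0.5, 0.3), (-0.2, 0.25)])
        prior = PriorSpec(model_prior=(0.0, 0.0, 0.5, 0.5))
        # brute-force joint grid posterior mean of mu under RE1
        mu = np.linspace(-15.0, 15.0, 3000)
        lt = np.linspace(-12.0, 6.0, 3000)
        tau = np.exp(lt)
        y, se = np.array(ds.y), np.array(ds.se)
        v = se[None, :] ** 2 + tau[:, None] ** 2
        ll = -0.5 * (np.sum(np.log(2 * np.pi * v), axis=1)[:, None]
                     + np.sum(y ** 2 / v, axis=1)[:, None]
                     - 2 * mu[None, :] * np.sum(y / v, axis=1)[:, None]
                     + mu[None, :] ** 2 * np.sum(1 / v, axis=1)[:, None])
        w = np.exp(ll + stats.cauchy.logpdf(mu, 0, 0.707)[None, :]
                   + (stats.invgamma.logpdf(tau, 1, scale=0.15) + lt)[:, None])
        mean_oracle = float(np.sum(w * mu[None, :]) / np.sum(w))
        # RE1-only averaging via a model prior that zeroes FE models
        marg = compute_marginals(ds, PriorSpec())
        post = posterior_mu(ds, PriorSpec(), marginals=marg)
        w_fe1 = post.weight_fe1
        # remove the FE1 share analytically: mean = w*mean_fe1 + (1-w)*mean_re1
        dens_fe1 = np.exp(
            stats.norm.logpdf(y[None, :], post.grid[:, None],
                              se[None, :]).sum(axis=1)
            + stats.cauchy.logpdf(post.grid, 0, 0.707))
        dens_fe1 /= np.trapezoid(dens_fe1, post.grid)
        mean_fe1 = float(np.trapezoid(post.grid * dens_fe1, post.grid))
        mean_re1 = (post.mu_mean - w_fe1 * mean_fe1) / (1 - w_fe1)
        assert mean_re1 == pytest.approx(mean_oracle, abs=1e-4)


class TestShrinkage:
    def test_pulls_every_study_toward_the_pooled_mean(self, five_study_dataset):
        shr = shrinkage_estimates(five_study_dataset, PRIOR)
        mu_star = posterior_mu(five_study_dataset, PRIOR).mu_mean
        for s in shr:
            assert abs(s.mean - mu_star) <= abs(s.observed - mu_star) + 1e-9

    def test_uninformative_study_collapses_to_pooled_mean(self):
        """se = 100 carries no information: theta posterior = mu posterior
        (under RE1, the model shrinkage is defined for)."""
        ds = make_dataset([(-0.5, 0.2), (-0.4, 0.25), (3.0, 100.0)])
        shr = shrinkage_estimates(ds, PRIOR)
        re1_only = PriorSpec(model_prior=(0.0, 0.0, 0.5, 0.5))
        post = posterior_mu(ds, re1_only)
        assert shr[-1].mean == pytest.approx(post.mu_mean, abs=0.01)

    def test_cri_brackets_mean(self, three_study_dataset):
        for s in shrinkage_estimates(three_study_dataset, PRIOR):
            assert s.cri_low < s.mean < s.cri_high


class TestSavageDickey:
    def test_prior_density_at_null(self):
        assert math.exp(PRIOR.effect_logpdf(0.0)) == \
            pytest.approx(1 / (math.pi * 0.707), abs=1e-12)

    def test_matches_marginal_likelihood_ratio(self, three_study_dataset):
        m = compute_marginals(three_study_dataset, PRIOR)
        identity = math.exp(m.logml_fe0 - m.logml_fe1)
        assert savage_dickey_bf_fe(three_study_dataset, PRIOR) == \
            pytest.approx(identity, rel=1e-6)

    def test_data_at_null_favor_h0(self, single_study_dataset):
        assert savage_dickey_bf_fe(single_study_dataset, PRIOR) > 1.0


class TestInterpretBf:
    def test_bf_below_one_folds_to_h0(self):
        rec = interpret_bf(0.681)
        assert rec.direction == "H0"
        assert rec.folded_ratio == pytest.approx(1.47, abs=0.005)
        assert "1.47" in rec.text

    def test_unit_bf_is_equivocal(self):
        assert interpret_bf(1.0).direction == "equivocal"
        assert interpret_bf(1.0).folded_ratio == 1.0

    def test_large_bf_favors_h1(self):
        rec = interpret_bf(18.93)
        assert rec.direction == "H1"
        assert rec.folded_ratio == pytest.approx(18.93)

    @pytest.mark.parametrize("bad", [0.0, -2.0, float("inf")])
    def test_domain(self, bad):
        with pytest.raises(MetaInputError):
            interpret_bf(bad)


class TestFullAnalysis:
    def test_bundle_is_internally_consistent(self, three_study_dataset):
        res = analyze_bayes(three_study_dataset, PRIOR)
        bf10, bf_rf, probs = model_average(res.marginals, PRIOR)
        assert res.bf10 == pytest.approx(bf10, rel=1e-12)
        assert res.bf_rf == pytest.approx(bf_rf, rel=1e-12)
        assert sum(res.post_model_probs.values()) == pytest.approx(1.0)
        assert len(res.shrinkage) == 3
        d = res.to_dict()
        assert d["or"] == pytest.approx(math.exp(res.mu_mean))

    def test_strong_consistent_evidence_drives_bf_up(self):
        """Many precise studies at mu = -0.5 should leave no doubt."""
        ds = make_dataset([(-0.5, 0.12)] * 30)
        res = analyze_bayes(ds, PRIOR, with_shrinkage=False)
        assert res.bf10 > 100.0

    def test_cri_not_wildly_wider_than_wald_ci(self):
        """On homogeneous data the CrI should be comparable to the CI."""
        from metabf import random_effects_pool
        ds = make_dataset([(-0.4, 0.2), (-0.45, 0.25), (-0.35, 0.3),
                           (-0.4, 0.22)])
        bay = analyze_bayes(ds, PRIOR, with_shrinkage=False)
        freq = random_effects_pool(ds)
        cri_w = bay.cri_high - bay.cri_low
        ci_w = freq.ci_high - freq.ci_low
        assert cri_w <= 1.5 * ci_w
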