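"""Gamma-Poisson shrinkage and IC against independent numerical oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import faers_signals as fs
from faers_signals.bayes import (
    DUMOUCHEL_INIT,
    GammaPoissonShrinkage,
    ebgm,
    ebgm_quantile,
    expected_counts,
    ic,
    load_prior,
    save_prior,
)


# ---------------------------------------------------------------------------
# expected counts

class TestExpectedCounts:
    def test_margin_product(self):
        pairs = pd.DataFrame({
            "drug": ["d1", "d1", "d2", "d2"],
            "event": ["e1", "e2", "e1", "e2"],
            "n": [1, 99, 109, 9891],
        })
        out = expected_counts(pairs)
        target = out.query("drug=='d1' and event=='e1'")["e"].iloc[0]
        assert target == pytest.approx(100 * 110 / 10100, rel=1e-12)

    def test_uniform_grid_expectation_equals_count(self):
        pairs = pd.DataFrame({
            "drug": np.repeat([f"d{i}" for i in range(4)], 3),
            "event": np.tile([f"e{j}" for j in range(3)], 4),
            "n": 7,
        })
        out = expected_counts(pairs)
        assert np.allclose(out["e"], 7.0)

    def test_conservation(self):
        rng = np.random.default_rng(5)
        pairs = pd.DataFrame({
            "drug": np.repeat([f"d{i}" for i in range(6)], 5),
            "event": np.tile([f"e{j}" for j in range(5)], 6),
            "n": rng.integers(0, 50, 30),
        })
        out = expected_counts(pairs)
        assert out["e"].sum() == pytest.approx(out["n"].sum(), rel=1e-12)

    def test_stratified_expectations_sum_stratumwise(self):
        pairs = pd.DataFrame({
            "drug": ["d1", "d1", "d2", "d2"] * 2,
            "event": ["e1", "e2", "e1", "e2"] * 2,
            "stratum": ["s1"] * 4 + ["s2"] * 4,
            "n": [10, 30, 20, 40, 5, 5, 5, 5],
        })
        out = expected_counts(pairs, strata=["stratum"])
        row = out.query("drug=='d1' and event=='e1'").iloc[0]
        expected = 40 * 30 / 100 + 10 * 10 / 20
        assert row["e"] == pytest.approx(expected, rel=1e-12)
        assert row["n"] == 15

    def test_zero_grand_total_errors(self):
        pairs = pd.DataFrame({"drug": ["d"], "event": ["e"], "n": [0]})
        with pytest.raises(ValueError):
            expected_counts(pairs)


# ---------------------------------------------------------------------------
# information component

class TestIC:
    def test_closed_form_worked_example(self):
        point, _, _ = ic(10, 1.0891)
        assert point == pytest.approx(np.log2(10.5 / 1.5891), abs=1e-9)

    def test_n_equals_e_is_zero(self):
        assert ic(3, 3)[0] == 0.0

    def test_zero_count_closed_form(self):
        assert ic(0, 0.5)[0] == pytest.approx(-1.0, abs=1e-12)

    def test_credibility_bounds_from_gamma_posterior(self):
        point, lo, hi = ic(10, 1.0891)
        g = stats.gamma(a=10.5, scale=1 / 1.5891)
        assert lo == pytest.approx(np.log2(g.ppf(0.025)), rel=1e-12)
        assert hi == pytest.approx(np.log2(g.ppf(0.975)), rel=1e-12)
        assert lo < point < hi

    def test_monotone_in_n_and_e(self):
        ns = np.arange(0, 30)
        vals = ic(ns, 5.0)[0]
        assert np.all(np.diff(vals) > 0)
        es = np.linspace(0.5, 30, 40)
        vals = ic(10, es)[0]
        assert np.all(np.diff(vals) < 0)


# ---------------------------------------------------------------------------
# EBGM vs quadrature oracle

def _posterior_unnorm(lam, n, e, prior):
    prior_pdf = (
        prior.p * stats.gamma.pdf(lam, a=prior.alpha1, scale=1 / prior.beta1)
        + (1 - prior.p) * stats.gamma.pdf(lam, a=prior.alpha2, scale=1 / prior.beta2)
    )
    return prior_pdf * stats.poisson.pmf(n, lam * e)


def _support(n, e, prior):
    """Finite integration bracket covering the posterior's mass.

    The posterior components are Gamma(alpha_k + n, beta_k + e); extreme
    quantiles of both bracket the mixture's support for quadrature.
    """
    qs = [
        stats.gamma.ppf(q, a=a + n, scale=1 / (b + e))
        for q in (1e-14, 1 - 1e-14)
        for a, b in ((prior.alpha1, prior.beta1), (prior.alpha2, prior.beta2))
    ]
    return max(min(qs), 1e-300), max(qs)


def _ebgm_quadrature(n, e, prior):
    # integrate in u = ln(lambda): smooths the lambda -> 0 density singularity
    lo, hi = _support(n, e, prior)
    f = lambda u: _posterior_unnorm(np.exp(u), n, e, prior) * np.exp(u)
    norm, _ = integrate.quad(f, np.log(lo), np.log(hi), limit=400)
    mom, _ = integrate.quad(lambda u: u * f(u), np.log(lo), np.log(hi), limit=400)
    return np.exp(mom / norm)


def _posterior_cdf_quadrature(x, n, e, prior):
    lo, hi = _support(n, e, prior)
    f = lambda u: _posterior_unnorm(np.exp(u), n, e, prior) * np.exp(u)
    norm, _ = integrate.quad(f, np.log(lo), np.log(hi), limit=400,
                             epsabs=1e-13, epsrel=1e-11)
    mass, _ = integrate.quad(f, np.log(lo), np.log(min(x, hi)), limit=400,
                             epsabs=1e-13, epsrel=1e-11)
    return mass / norm


GRID_N = [0, 1, 5, 20, 100]
GRID_E = [0.5, 1.0, 2.5, 10.0, 40.0]


class TestEbgm:
    def test_matches_quadrature_on_grid(self):
        prior = DUMOUCHEL_INIT
        for n in GRID_N:
            for e in GRID_E:
                ours = float(ebgm(n, e, prior))
                oracle = _ebgm_quadrature(n, e, prior)
                assert ours == pytest.approx(oracle, abs=1e-4, rel=1e-5), (n, e)

    def test_quantiles_match_quadrature_on_grid(self):
        prior = DUMOUCHEL_INIT
        for n in GRID_N:
            for e in GRID_E:
                for q in (0.05, 0.95):
                    lam_q = float(ebgm_quantile(n, e, prior, q))
                    cdf = _posterior_cdf_quadrature(lam_q, n, e, prior)
                    assert cdf == pytest.approx(q, abs=1e-4), (n, e, q)

    def test_likelihood_dominance_limit(self):
        # n, e large with n/e = 3: the data overwhelm the prior
        val = float(ebgm(3_000_000, 1_000_000, DUMOUCHEL_INIT))
        assert val == pytest.approx(3.0, rel=1e-3)

    def test_shrinks_toward_prior_from_mle(self):
        prior = fs.GammaMixturePrior(2.0, 2.0, 2.0, 2.0, 0.5)  # single component
        gm = prior.geometric_mean
        for n, e in [(20, 5.0), (2, 10.0), (50, 50.0)]:
            est = float(ebgm(n, e, prior))
            mle = (n + 1e-9) / e
            assert abs(np.log(est) - np.log(gm)) <= abs(np.log(mle) - np.log(gm)) + 1e-9

    def test_quantiles_bracket_point_estimate(self):
        prior = DUMOUCHEL_INIT
        for n, e in [(5, 1.0), (0, 2.0), (100, 20.0)]:
            lo = float(ebgm_quantile(n, e, prior, 0.05))
            hi = float(ebgm_quantile(n, e, prior, 0.95))
            point = float(ebgm(n, e, prior))
            assert lo <= point <= hi


# ---------------------------------------------------------------------------
# hyperparameter fitting

def _simulate_mixture(rng, prior, m, e_low=-1.0, e_high=2.0):
    e = 10 ** rng.uniform(e_low, e_high, m)
    comp = rng.random(m) < prior.p
    lam = np.where(
        comp,
        rng.gamma(prior.alpha1, 1 / prior.beta1, m),
        rng.gamma(prior.alpha2, 1 / prior.beta2, m),
    )
    return rng.poisson(lam * e), e


def _aligned_max_rel_err(fit, truth):
    """Mixtures are identifiable only up to component relabeling."""
    f1 = (fit.alpha1, fit.beta1, fit.alpha2, fit.beta2, fit.p)
    f2 = (fit.alpha2, fit.beta2, fit.alpha1, fit.beta1, 1 - fit.p)
    t = (truth.alpha1, truth.beta1, truth.alpha2, truth.beta2, truth.p)
    err = lambda f: max(abs(a - b) / b for a, b in zip(f, t))
    return min(err(f1), err(f2))


class TestFit:
    def test_recovers_known_prior_within_20_percent(self):
        truth = fs.GammaMixturePrior(0.2, 0.1, 2.0, 4.0, 1 / 3)
        rng = np.random.default_rng(20240527)
        n, e = _simulate_mixture(rng, truth, 50_000)
        est = GammaPoissonShrinkage().fit(n, e)
        assert est.converged_
        assert _aligned_max_rel_err(est.prior_, truth) < 0.20

    def test_null_data_fit_concentrates_near_unity(self):
        rng = np.random.default_rng(9)
        e = 10 ** rng.uniform(-0.5, 1.5, 20_000)
        n = rng.poisson(e)
        est = GammaPoissonShrinkage().fit(n, e)
        assert 0.8 <= est.prior_.mixture_mean <= 1.25

    def test_degenerate_boundary_init_is_clipped(self):
        rng = np.random.default_rng(3)
        e = np.full(500, 2.0)
        n = rng.poisson(e)
        est = GammaPoissonShrinkage(p=1.0).fit(n, e)
        assert 0.0 < est.p_ < 1.0

    def test_requires_two_informative_pairs(self):
        with pytest.raises(ValueError):
            GammaPoissonShrinkage().fit([0, 0, 1], [1.0, 1.0, 1.0])

    def test_squashing_preserves_the_objective_exactly(self):
        # with e on a discrete set the (n, e-bin) aggregation is lossless:
        # the weighted log-likelihood equals the full sum at any parameters
        from faers_signals.bayes import _log_marginal, _squash
        rng = np.random.default_rng(17)
        e = rng.choice([0.5, 2.0, 8.0], 5000)
        n = rng.poisson(e)
        ns, es, w = _squash(n, e, bins=20)
        assert w.sum() == 5000
        for prior in (DUMOUCHEL_INIT, fs.GammaMixturePrior(1.0, 1.0, 3.0, 2.0, 0.7)):
            full = float(np.sum(_log_marginal(n, e, prior)))
            squashed = float(np.sum(_log_marginal(ns, es, prior, w)))
            assert squashed == pytest.approx(full, rel=1e-12)
        fitted = GammaPoissonShrinkage(squash_bins=20).fit(n, e)
        assert np.isfinite(fitted.loglik_)

    def test_estimator_params_protocol(self):
        est = GammaPoissonShrinkage(tol=1e-5)
        params = est.get_params()
        assert params["tol"] == 1e-5
        est.set_params(max_iter=123)
        assert est.max_iter == 123
        with pytest.raises(ValueError):
            est.set_params(bogus=1)

    def test_calibration_across_seeds(self):
        """Mean EBGM at an injected rr=10 pair stays within 20% of truth."""
        values = []
        for seed in range(1, 21):
            rng = np.random.default_rng(seed)
            wd = np.ones(200)
            wd[0] *= 2
            wd /= wd.sum()
            we = np.ones(100) / 100
            e = 200_000 * np.outer(wd, we)
            rr = np.ones_like(e)
            rr[0, 0] = 10.0
            n = rng.poisson(e * rr)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = GammaPoissonShrinkage().fit(n.ravel(), e.ravel())
            values.append(float(ebgm(n[0, 0], e[0, 0], est.prior_)))
        mean = float(np.mean(values))
        assert 8.0 <= mean <= 12.0


def test_prior_round_trips_through_flat_file(tmp_path):
    prior = fs.GammaMixturePrior(0.21, 0.11, 1.9, 3.8, 0.4, loglik=-12.5, converged=True)
    path = tmp_path / "prior.txt"
    save_prior(prior, path)
    back = load_prior(path)
    assert back == prior
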