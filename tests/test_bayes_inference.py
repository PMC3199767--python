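"""Priors, likelihood, proposals, sampler mechanics and summaries."""

import math

import numpy as np
import pytest
from scipy import stats

from korab import (
    Observations,
    Prior,
    default_priors,
    log_likelihood,
    lognormal_from_mode_cv,
    make_variant,
    mh_run,
    pairwise_correlation,
    propose,
    steady_state,
    make_mutant,
    summarize_posterior,
    joint_histogram,
    tune_acceptance,
)
from korab.bayes_inference import PosteriorChain, _lognormal_logpdf


def _chain_from_samples(samples, names=("k_A",), **kw):
    """Minimal PosteriorChain wrapper for summary-function tests."""
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
    n = samples.shape[0]
    defaults = dict(
        names=tuple(names), sampled=tuple(names), samples=samples,
        log_posterior=np.zeros(n), block_id=np.zeros(n, dtype=np.int8),
        accepted=np.ones(n, dtype=bool), seed=0, scales=(0.05, 0.08),
        priors={})
    defaults.update(kw)
    return PosteriorChain(**defaults)


# ---------------------------------------------------------------------------
# lognormal mode/cv parameterization
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("mode,cv", [(1600.0, 0.5), (12.9, 0.5), (0.001, 0.05)])
def test_lognormal_mode_and_cv_from_moments(mode, cv):
    mu, s = lognormal_from_mode_cv(mode, cv)
    assert math.exp(mu - s * s) == pytest.approx(mode, rel=1e-12)
    mean = math.exp(mu + s * s / 2)
    sd = mean * math.sqrt(math.expm1(s * s))
    assert sd / mean == pytest.approx(cv, rel=1e-12)
    assert s == pytest.approx(math.sqrt(math.log1p(cv * cv)), rel=1e-12)


def test_lognormal_collapses_at_tiny_cv():
    mu, s = lognormal_from_mode_cv(10.0, 1e-8)
    dist = stats.lognorm(s=s, scale=math.exp(mu))
    lo, hi = dist.ppf([0.001, 0.999])
    assert lo == pytest.approx(10.0, rel=1e-6)
    assert hi == pytest.approx(10.0, rel=1e-6)


def test_lognormal_empirical_mode_and_cv():
    rng = np.random.default_rng(42)
    mu, s = lognormal_from_mode_cv(12.9, 0.5)
    x = np.exp(rng.normal(mu, s, 200_000))
    assert np.std(x) / np.mean(x) == pytest.approx(0.5, rel=0.02)
    # independent density-mode oracle: fine histogram on the natural scale
    counts, edges = np.histogram(x, bins=250, range=(0.0, 60.0), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    assert centers[np.argmax(counts)] == pytest.approx(12.9, rel=0.08)


def test_lognormal_rejects_invalid_arguments():
    with pytest.raises(ValueError):
        lognormal_from_mode_cv(0.0, 0.5)
    with pytest.raises(ValueError):
        lognormal_from_mode_cv(1.0, -0.1)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


def test_lognormal_prior_density_matches_scipy():
    pr = Prior("lognormal", mode=12.9, cv=0.5)
    mu, s = lognormal_from_mode_cv(12.9, 0.5)
    ref = stats.lognorm(s=s, scale=math.exp(mu))
    for x in (0.5, 5.0, 12.9, 80.0):
        assert pr.logpdf(x) == pytest.approx(ref.logpdf(x), rel=1e-10)
        assert pr.cdf(x) == pytest.approx(ref.cdf(x), rel=1e-9)


def test_prior_samples_match_cdf():
    rng = np.random.default_rng(3)
    for pr in (Prior("lognormal", mode=4.5, cv=0.5),
               Prior("loguniform", bounds=(1e-5, 1e5)),
               Prior("uniform", bounds=(0.0, 1.0))):
        x = pr.sample(rng, 4000)
        res = stats.kstest(x, np.vectorize(pr.cdf))
        assert res.pvalue > 0.01


def test_default_prior_table_reflects_measured_modes():
    priors = default_priors()
    assert priors["k1"] == Prior("lognormal", mode=12.9, cv=0.5)
    assert priors["k2"] == Prior("lognormal", mode=9.3, cv=0.5)
    assert priors["gamma_P"] == Prior("lognormal", mode=0.0003875, cv=0.05)
    assert priors["pi_X"] == Prior("uniform", bounds=(0.0, 1.0))
    tight = default_priors(tight=True)
    assert tight["k1"].cv == 0.1
    assert tight["lambda_A"].cv == 0.05  # stays at its tighter value


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def test_likelihood_is_maximal_when_predictions_hit_the_data():
    """A parameter set whose steady states equal the measurements exactly
    attains the sum of the three mode-density values."""
    p = make_variant("uu")
    wt = steady_state(p)
    mut = steady_state(make_mutant(p))
    obs = Observations(A_tot_wt=wt.A_tot, B_tot_wt=wt.B_tot,
                       B_tot_mut=mut.B_tot, cv=0.5)
    expected = sum(_lognormal_logpdf(v, v, 0.5)
                   for v in (wt.A_tot, wt.B_tot, mut.B_tot))
    assert log_likelihood(p, obs) == pytest.approx(expected, rel=1e-9)


def test_likelihood_equals_independent_lognormal_oracle():
    p = make_variant("uu")
    wt = steady_state(p)
    mut = steady_state(make_mutant(p))
    obs = Observations()
    total = 0.0
    for pred, meas in ((wt.A_tot, obs.A_tot_wt), (wt.B_tot, obs.B_tot_wt),
                       (mut.B_tot, obs.B_tot_mut)):
        mu, s = lognormal_from_mode_cv(meas, obs.cv)
        total += stats.lognorm(s=s, scale=math.exp(mu)).logpdf(pred)
    assert log_likelihood(p, obs) == pytest.approx(total, rel=1e-9)


def test_each_likelihood_factor_decreases_away_from_the_mode():
    base = _lognormal_logpdf(1600.0, 1600.0, 0.5)
    offsets = np.array([1.1, 1.5, 3.0, 10.0])
    above = [_lognormal_logpdf(1600.0 * f, 1600.0, 0.5) for f in offsets]
    below = [_lognormal_logpdf(1600.0 / f, 1600.0, 0.5) for f in offsets]
    assert all(np.diff(above) < 0) and all(np.diff(below) < 0)
    assert max(above + below) < base


# ---------------------------------------------------------------------------
# proposals
# ---------------------------------------------------------------------------


def test_zero_scale_proposal_is_identity():
    rng = np.random.default_rng(0)
    cur = np.array([1.0, 2.0, 3.0])
    np.testing.assert_array_equal(propose("rates", cur, (0.0, 0.0), rng), cur)


def test_rate_proposals_stay_positive_and_match_log_sd():
    rng = np.random.default_rng(1)
    cur = np.full(100_000, 7.3)
    cand = propose("rates", cur, (0.05, 0.08), rng)
    assert np.all(cand > 0)
    assert np.std(np.log(cand / cur)) == pytest.approx(0.05, rel=0.02)


def test_pi_proposals_are_additive():
    rng = np.random.default_rng(2)
    cur = np.full(100_000, 0.5)
    cand = propose("pi_X", cur, (0.05, 0.08), rng)
    assert np.std(cand - cur) == pytest.approx(0.08, rel=0.02)
    with pytest.raises(ValueError):
        propose("nope", cur, (0.05, 0.08), rng)


# ---------------------------------------------------------------------------
# sampler mechanics
# ---------------------------------------------------------------------------


def test_chain_is_reproducible_from_seed():
    priors = default_priors()
    obs = Observations()
    a = mh_run(priors, obs, iterations=2000, seed=7)
    b = mh_run(priors, obs, iterations=2000, seed=7)
    np.testing.assert_array_equal(a.samples, b.samples)
    np.testing.assert_array_equal(a.accepted, b.accepted)
    c = mh_run(priors, obs, iterations=2000, seed=8)
    assert not np.array_equal(a.samples, c.samples)


def test_blocks_rotate_and_bookkeeping_is_consistent():
    chain = mh_run(default_priors(), None, iterations=3000, seed=1)
    assert len(chain) == 3000
    np.testing.assert_array_equal(chain.block_id[:6], [0, 1, 2, 0, 1, 2])
    # a rejected iteration repeats the previous sample exactly
    same = np.all(chain.samples[1:] == chain.samples[:-1], axis=1)
    np.testing.assert_array_equal(~same, chain.accepted[1:])


def test_posterior_support_is_respected():
    chain = mh_run(default_priors(), None, iterations=30_000, seed=11)
    for name in ("pi_X", "pi_Y"):
        x = chain.column(name)
        assert np.all((x >= 0.0) & (x <= 1.0))
    for name in ("k_A", "k1", "sigma_A", "lambda_B", "gamma_P", "D0"):
        assert np.all(chain.column(name) > 0)


def test_flat_likelihood_recovers_an_informative_prior_marginal():
    """Desk-scale invariant-distribution check on the tightest prior."""
    priors = default_priors()
    chain = mh_run(priors, None, iterations=400_000, seed=5)
    kept = chain.thinned(burn_in=0.1, thinning=1200)
    x = kept[:, chain.names.index("gamma_P")]
    assert stats.kstest(x, np.vectorize(priors["gamma_P"].cdf)).pvalue > 0.01


def test_missing_prior_is_rejected():
    priors = default_priors()
    del priors["gamma_P"]
    with pytest.raises(ValueError, match="gamma_P"):
        mh_run(priors, None, iterations=10, seed=0)


# ---------------------------------------------------------------------------
# summaries and diagnostics
# ---------------------------------------------------------------------------


def test_constant_chain_summarizes_to_point():
    chain = _chain_from_samples(np.full(300, 7.25))
    s = summarize_posterior(chain, burn_in=0.1, thinning=1)
    assert s.loc["k_A", "mode"] == pytest.approx(7.25)
    assert s.loc["k_A", "cv"] == 0.0


def test_summary_recovers_known_lognormal_mode_and_cv():
    rng = np.random.default_rng(9)
    mu, s_par = lognormal_from_mode_cv(11.5, 0.3)
    chain = _chain_from_samples(np.exp(rng.normal(mu, s_par, 100_000)))
    s = summarize_posterior(chain, burn_in=0.0, thinning=1)
    assert s.loc["k_A", "mode"] == pytest.approx(11.5, rel=0.05)
    assert s.loc["k_A", "cv"] == pytest.approx(0.3, rel=0.05)


def test_summary_requires_enough_samples():
    chain = _chain_from_samples(np.full(50, 1.0))
    with pytest.raises(ValueError):
        summarize_posterior(chain, burn_in=0.1, thinning=1)


def test_acceptance_rates_for_degenerate_chains():
    ones = _chain_from_samples(np.arange(1.0, 501.0))
    assert tune_acceptance(ones).loc["rates", "acceptance"] == 1.0
    rej = _chain_from_samples(np.full(500, 1.0),
                              accepted=np.zeros(500, dtype=bool))
    assert tune_acceptance(rej).loc["rates", "acceptance"] == 0.0


def test_joint_density_and_correlation_of_correlated_samples():
    rng = np.random.default_rng(13)
    z = rng.normal(size=5000)
    kA = np.exp(2.0 + z)
    kB = np.exp(1.0 + 0.9 * z + 0.3 * rng.normal(size=5000))
    chain = _chain_from_samples(np.column_stack([kA, kB]),
                                names=("k_A", "k_B"))
    corr = pairwise_correlation(chain, burn_in=0.0, thinning=1)
    assert corr.loc["k_A", "k_B"] > 0.8
    H, xe, ye = joint_histogram(chain, "k_A", "k_B", bins=25,
                                burn_in=0.0, thinning=1)
    assert H.shape == (25, 25)
    assert H.sum() > 0
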