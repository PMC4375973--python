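"""Likelihoods, posteriors, hybrid energies and MAP estimators."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, optimize, stats

from csisd import (
    DeviationSummary,
    DivergenceError,
    ModelSpec,
    SummaryOnlyError,
    TRAINING_SET_SIGMA,
    UncertaintyState,
    log_likelihood_cauchy,
    log_likelihood_gaussian,
    map_sigma_conjugate,
    map_sigma_jeffreys,
    neg_log_marginal_gaussian,
    neg_log_posterior_cauchy,
    neg_log_posterior_gaussian_conjugate,
    neg_log_posterior_gaussian_jeffreys,
    summary_from_scalars,
    total_hybrid_energy,
)


def dev_from(**per_class):
    return DeviationSummary.from_deviations(per_class)


# ---------------------------------------------------------------------------
# Gaussian likelihood
# ---------------------------------------------------------------------------


def test_gaussian_loglik_single_zero_deviation_unit_scale():
    val = log_likelihood_gaussian(dev_from(CA=[0.0]), UncertaintyState({"CA": 1.0}))
    assert val == pytest.approx(-0.5 * math.log(2 * math.pi), rel=1e-12)


def test_gaussian_loglik_empty_data_is_zero():
    assert log_likelihood_gaussian(dev_from(), UncertaintyState({})) == 0.0


def test_gaussian_loglik_summary_matches_per_term_oracle(protein_g_ca_summary, rng):
    # independent oracle: sum scipy normal logpdfs over an explicit deviation
    # vector with the same n and chi-square
    d = rng.normal(0, 1.1, 54)
    d *= math.sqrt(69.7 / np.sum(d * d))
    sigma = TRAINING_SET_SIGMA["CA"]
    oracle = float(np.sum(stats.norm.logpdf(d, scale=sigma)))
    val = log_likelihood_gaussian(protein_g_ca_summary, UncertaintyState({"CA": sigma}))
    assert val == pytest.approx(oracle, rel=1e-10)


def test_gaussian_loglik_rejects_nonpositive_scale():
    with pytest.raises(ValueError):
        log_likelihood_gaussian(dev_from(CA=[0.1]), UncertaintyState({"CA": 0.0}))


# ---------------------------------------------------------------------------
# Jeffreys posterior and MAP
# ---------------------------------------------------------------------------


def test_jeffreys_energy_at_map_matches_direct_evaluation(protein_g_ca_summary):
    sigma = math.sqrt(69.7 / 55)
    expected = 55 * math.log(sigma) + 69.7 / (2 * sigma**2)
    val = neg_log_posterior_gaussian_jeffreys(
        protein_g_ca_summary, UncertaintyState({"CA": sigma})
    )
    assert val == pytest.approx(expected, rel=1e-12)
    assert val == pytest.approx(34.014, abs=5e-3)


def test_jeffreys_energy_zero_misfit_unit_scale_is_zero():
    dev = summary_from_scalars({"CA": (54, 0.0)})
    assert neg_log_posterior_gaussian_jeffreys(dev, UncertaintyState({"CA": 1.0})) == 0.0


def test_physical_energy_is_additive():
    dev = dev_from(CA=[0.5, -0.3])
    theta = UncertaintyState({"CA": 0.8})
    base = neg_log_posterior_gaussian_jeffreys(dev, theta)
    assert neg_log_posterior_gaussian_jeffreys(dev, theta, e_phys=5.0) == pytest.approx(base + 5.0)
    assert neg_log_posterior_gaussian_conjugate(dev, theta, e_phys=5.0) == pytest.approx(
        neg_log_posterior_gaussian_conjugate(dev, theta) + 5.0
    )
    c = dev_from(CA=[0.5, -0.3])
    assert neg_log_posterior_cauchy(c, theta, e_phys=5.0) == pytest.approx(
        neg_log_posterior_cauchy(c, theta) + 5.0
    )


def test_map_jeffreys_on_printed_summary(protein_g_ca_summary):
    theta = map_sigma_jeffreys(protein_g_ca_summary)
    assert theta["CA"] ** 2 == pytest.approx(69.7 / 55, rel=1e-12)
    assert theta["CA"] == pytest.approx(1.12573, abs=1e-5)


def test_map_jeffreys_zero_chi_square_degenerates_with_warning():
    dev = summary_from_scalars({"CA": (54, 0.0)})
    with pytest.warns(RuntimeWarning):
        theta = map_sigma_jeffreys(dev)
    assert theta["CA"] == 0.0


def test_map_jeffreys_scale_equivariance(rng):
    d = rng.normal(0, 1.0, 30)
    s1 = map_sigma_jeffreys(dev_from(CA=d))["CA"]
    s2 = map_sigma_jeffreys(dev_from(CA=2.0 * d))["CA"]
    assert s2 == pytest.approx(2.0 * s1, rel=1e-12)


# ---------------------------------------------------------------------------
# Conjugate posterior and MAP
# ---------------------------------------------------------------------------


def test_conjugate_exponent_exceeds_jeffreys_by_one_log_sigma():
    # with alpha = beta -> 0 the conjugate energy exceeds the Jeffreys energy
    # by exactly one ln(sigma) per populated class
    dev = dev_from(CA=[0.4, -1.1, 0.9], HA=[0.1])
    for sigma in (0.5, 1.0, 2.3):
        theta = UncertaintyState({"CA": sigma, "HA": sigma})
        eps = 1e-12
        conj = neg_log_posterior_gaussian_conjugate(dev, theta, alpha=eps, beta=eps)
        jeff = neg_log_posterior_gaussian_jeffreys(dev, theta)
        assert conj - jeff == pytest.approx(2 * math.log(sigma), abs=1e-8)


def test_conjugate_stationary_point_matches_printed_map(protein_g_ca_summary):
    var = (2 * 1e-3 + 69.7) / (2 * 1e-3 + 2 + 54)
    assert var == pytest.approx(1.24464, abs=1e-5)
    res = optimize.minimize_scalar(
        lambda s: neg_log_posterior_gaussian_conjugate(
            protein_g_ca_summary, UncertaintyState({"CA": s})
        ),
        bounds=(0.2, 5.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    assert res.x**2 == pytest.approx(var, rel=1e-6)


def test_conjugate_map_strictly_positive_at_zero_misfit():
    dev = summary_from_scalars({"CA": (54, 0.0)})
    theta = map_sigma_conjugate(dev)
    assert theta["CA"] ** 2 == pytest.approx(0.002 / 56.002, rel=1e-9)
    assert theta["CA"] > 0


def test_conjugate_map_on_printed_summary(protein_g_ca_summary):
    assert map_sigma_conjugate(protein_g_ca_summary)["CA"] == pytest.approx(1.11563, abs=1e-5)


def test_conjugate_map_limit_is_jeffreys_with_n_plus_two():
    dev = dev_from(CA=[1.0, -0.5, 0.25, 2.0])
    chi2, n = dev.chi_square("CA"), dev.n("CA")
    tiny = map_sigma_conjugate(dev, alpha=1e-12, beta=1e-12)["CA"]
    assert tiny**2 == pytest.approx(chi2 / (n + 2), rel=1e-9)


# ---------------------------------------------------------------------------
# Marginal likelihood
# ---------------------------------------------------------------------------


def test_marginal_energy_on_printed_summary(protein_g_ca_summary):
    val = neg_log_marginal_gaussian(protein_g_ca_summary)
    assert val == pytest.approx(27 * math.log(69.7), rel=1e-12)


def test_marginal_energy_unit_chi_square_is_zero():
    assert neg_log_marginal_gaussian(summary_from_scalars({"CA": (2, 1.0)})) == 0.0


def test_marginal_energy_rejects_zero_chi_square():
    with pytest.raises(DivergenceError):
        neg_log_marginal_gaussian(summary_from_scalars({"CA": (5, 0.0)}))


def neg_log_sigma_integral(n, chi2):
    """-ln ∫ likelihood(σ)·(1/σ) dσ by quadrature in u = ln σ.

    The peak value is factored out so the integrand stays O(1), and the
    window scales with the posterior width 1/√n.
    """
    dev = summary_from_scalars({"CA": (n, chi2)})
    u0 = 0.5 * math.log(chi2 / n)
    w = 25.0 / math.sqrt(n)
    ll0 = log_likelihood_gaussian(dev, UncertaintyState({"CA": math.exp(u0)}))

    def g(u):
        return math.exp(
            log_likelihood_gaussian(dev, UncertaintyState({"CA": math.exp(u)})) - ll0
        )

    q, _ = integrate.quad(g, u0 - w, u0 + w, limit=400)
    return -(math.log(q) + ll0)


@pytest.mark.parametrize("n,chi2", [(3, 0.7), (10, 4.2), (25, 30.0), (54, 69.7), (120, 95.0)])
def test_marginal_energy_matches_quadrature_oracle(n, chi2):
    # -ln of int_0^inf likelihood(sigma) * (1/sigma) dsigma, full constants,
    # equals the marginal energy plus a closed-form n-dependent constant
    q = neg_log_sigma_integral(n, chi2)
    dev = summary_from_scalars({"CA": (n, chi2)})
    const = 0.5 * n * math.log(2 * math.pi) + math.log(2) \
        - 0.5 * n * math.log(2) - math.lgamma(n / 2)
    assert q == pytest.approx(neg_log_marginal_gaussian(dev) + const, rel=1e-6)


# ---------------------------------------------------------------------------
# Cauchy family
# ---------------------------------------------------------------------------


def test_cauchy_loglik_examples():
    assert log_likelihood_cauchy(
        dev_from(CA=[0.0]), UncertaintyState({"CA": 1.0})
    ) == pytest.approx(-math.log(math.pi), rel=1e-12)
    assert log_likelihood_cauchy(
        dev_from(CA=[1.0]), UncertaintyState({"CA": 1.0})
    ) == pytest.approx(-math.log(math.pi) - math.log(2), rel=1e-12)


def test_cauchy_loglik_is_even_in_deviations(rng):
    d = rng.standard_cauchy(40)
    theta = UncertaintyState({"CA": 0.7})
    assert log_likelihood_cauchy(dev_from(CA=d), theta) == pytest.approx(
        log_likelihood_cauchy(dev_from(CA=-d), theta), rel=1e-12
    )


def test_cauchy_rejects_summary_only(protein_g_ca_summary):
    with pytest.raises(SummaryOnlyError):
        log_likelihood_cauchy(protein_g_ca_summary, UncertaintyState({"CA": 1.0}))
    with pytest.raises(SummaryOnlyError):
        neg_log_posterior_cauchy(protein_g_ca_summary, UncertaintyState({"CA": 1.0}))


def test_cauchy_posterior_examples():
    assert neg_log_posterior_cauchy(dev_from(CA=[0.0]), UncertaintyState({"CA": 1.0})) == 0.0
    assert neg_log_posterior_cauchy(
        dev_from(CA=[1.0]), UncertaintyState({"CA": 1.0})
    ) == pytest.approx(math.log(2), rel=1e-12)


def test_cauchy_posterior_has_interior_minimum(rng):
    d = rng.standard_cauchy(25) * 0.8
    dev = dev_from(CA=d)

    def f(g):
        return neg_log_posterior_cauchy(dev, UncertaintyState({"CA": g}))

    gs = np.geomspace(1e-3, 1e3, 400)
    vals = np.array([f(g) for g in gs])
    imin = vals.argmin()
    assert 0 < imin < len(gs) - 1       # interior
    diffs = np.sign(np.diff(vals))
    # derivative changes sign exactly once: negative then positive
    assert (diffs[: imin] <= 0).all() and (diffs[imin:] >= 0).all()


# ---------------------------------------------------------------------------
# Normalisation and posterior-consistency invariants
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("family,scale", [("gaussian", 0.26), ("gaussian", 2.78), ("cauchy", 0.19), ("cauchy", 1.87)])
def test_single_shift_likelihood_integrates_to_one(family, scale):
    pred = 55.0

    def density(x):
        dev = dev_from(CA=[pred - x])
        theta = UncertaintyState({"CA": scale})
        ll = (
            log_likelihood_gaussian(dev, theta)
            if family == "gaussian"
            else log_likelihood_cauchy(dev, theta)
        )
        return math.exp(ll)

    if family == "gaussian":
        total, _ = integrate.quad(density, pred - 40 * scale, pred + 40 * scale, limit=400)
    else:
        # heavy tails: integrate the far wings too
        total, _ = integrate.quad(density, pred - 20 * scale, pred + 20 * scale, limit=400)
        for lo, hi in [(-np.inf, pred - 20 * scale), (pred + 20 * scale, np.inf)]:
            total += integrate.quad(density, lo, hi, limit=400)[0]
    assert total == pytest.approx(1.0, abs=1e-8)


def test_exp_neg_energy_proportional_to_likelihood_times_prior(rng):
    # ratio posterior / (likelihood * prior) is state-independent
    d = rng.normal(0, 1.2, 20)
    dev = dev_from(CA=d)
    ratios = []
    for _ in range(20):
        s = float(rng.uniform(0.3, 4.0))
        theta = UncertaintyState({"CA": s})
        log_post = -neg_log_posterior_gaussian_jeffreys(dev, theta)
        log_lik_prior = log_likelihood_gaussian(dev, theta) - math.log(s)
        ratios.append(log_post - log_lik_prior)
    assert np.ptp(ratios) < 1e-10
    ratios = []
    for _ in range(20):
        s = float(rng.uniform(0.3, 4.0))
        theta = UncertaintyState({"CA": s})
        log_post = -neg_log_posterior_cauchy(dev, theta)
        log_lik_prior = log_likelihood_cauchy(dev, theta) - math.log(s)
        ratios.append(log_post - log_lik_prior)
    assert np.ptp(ratios) < 1e-10


def test_map_estimators_minimize_their_posteriors(rng):
    d = rng.normal(0, 0.9, 40)
    dev = dev_from(CA=d)
    for fn, map_fn in [
        (neg_log_posterior_gaussian_jeffreys, map_sigma_jeffreys),
        (neg_log_posterior_gaussian_conjugate, map_sigma_conjugate),
    ]:
        res = optimize.minimize_scalar(
            lambda s: fn(dev, UncertaintyState({"CA": s})),
            bounds=(0.05, 10.0),
            method="bounded",
            options={"xatol": 1e-12},
        )
        assert res.x == pytest.approx(map_fn(dev)["CA"], rel=1e-6)


def test_cauchy_outlier_penalty_is_much_smaller_than_gaussian():
    base = [0.0] * 9
    theta = UncertaintyState({"CA": 1.0})
    with_out = base + [10.0]
    gauss_pen = neg_log_posterior_gaussian_jeffreys(
        dev_from(CA=with_out), theta
    ) - neg_log_posterior_gaussian_jeffreys(dev_from(CA=base + [0.0]), theta)
    cauchy_pen = neg_log_posterior_cauchy(
        dev_from(CA=with_out), theta
    ) - neg_log_posterior_cauchy(dev_from(CA=base + [0.0]), theta)
    assert gauss_pen == pytest.approx(50.0, rel=1e-12)
    assert cauchy_pen == pytest.approx(math.log(101), rel=1e-12)
    assert cauchy_pen < gauss_pen


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------


def test_dispatch_matches_family_functions(rng):
    d = rng.normal(0, 1.0, 15)
    dev = dev_from(CA=d)
    theta = UncertaintyState({"CA": 1.3})
    assert total_hybrid_energy(dev, theta, ModelSpec("gaussian_jeffreys")) == (
        neg_log_posterior_gaussian_jeffreys(dev, theta)
    )
    assert total_hybrid_energy(dev, theta, ModelSpec("gaussian_conjugate")) == (
        neg_log_posterior_gaussian_conjugate(dev, theta)
    )
    assert total_hybrid_energy(dev, theta, ModelSpec("cauchy_jeffreys")) == (
        neg_log_posterior_cauchy(dev, theta)
    )
    assert total_hybrid_energy(dev, None, ModelSpec("gaussian_marginal")) == (
        neg_log_marginal_gaussian(dev)
    )


def test_dispatch_fixed_weights_equal_energy_at_packaged_scales(rng):
    d = rng.normal(0, 1.2, 25)
    dev = dev_from(CA=d)
    model = ModelSpec.with_preset("gaussian_jeffreys", "camshift-trainingset-gaussian")
    fixed = total_hybrid_energy(dev, None, model)
    explicit = neg_log_posterior_gaussian_jeffreys(
        dev, UncertaintyState(TRAINING_SET_SIGMA)
    )
    assert fixed == pytest.approx(explicit, rel=1e-14)


def test_dispatch_rejects_theta_mismatch(rng):
    dev = dev_from(CA=rng.normal(0, 1, 5))
    with pytest.raises(ValueError):
        total_hybrid_energy(dev, UncertaintyState({"CA": 1.0}), ModelSpec("gaussian_marginal"))
    with pytest.raises(ValueError):
        total_hybrid_energy(dev, None, ModelSpec("gaussian_jeffreys"))
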