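"""Observer core: densities, error maps, optimal actions, response stats."""

import warnings

import numpy as np
import pytest
from scipy import stats

from chronobayes.distributions import (make_block_distribution,
                                       make_candidate_prior)
from chronobayes.observer import (LossSpec, NoiseModel, ObserverModel,
                                  bias_sd_curves, decision_rule, error_map,
                                  expected_loss, loss_value, motor_density,
                                  response_distribution, sensory_density,
                                  simulate_responses)


def make_observer(prior, loss="standard", w_s=0.1, w_m=0.1,
                  sensory_kind="scalar", motor_kind="scalar", **kw):
    return ObserverModel(NoiseModel(sensory_kind, w_s),
                         NoiseModel(motor_kind, w_m),
                         prior, LossSpec(loss) if isinstance(loss, str) else loss,
                         **kw)


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------

def test_scalar_sensory_density_is_gaussian_in_the_interval():
    n = NoiseModel("scalar", 0.1)
    xm = np.linspace(500, 1100, 7)
    assert sensory_density(xm, 800.0, n) == pytest.approx(
        stats.norm.pdf(xm, 800.0, 80.0))


def test_constant_noise_sd_is_interval_independent():
    n = NoiseModel("constant", 0.1)
    assert n.sd(np.array([300.0, 900.0])) == pytest.approx([78.75, 78.75])
    assert motor_density(700.0, 700.0, n) == pytest.approx(
        stats.norm.pdf(0.0, 0.0, 78.75))


def test_sensory_density_normalizes_on_the_grid(grid5):
    n = NoiseModel("scalar", 0.15)
    dens = sensory_density(grid5, 750.0, n)
    assert np.trapezoid(dens, grid5) == pytest.approx(1.0, abs=1e-5)


def test_scalar_noise_rejects_nonpositive_interval():
    with pytest.raises(ValueError):
        NoiseModel("scalar", 0.1).sd(np.array([-5.0]))


# ---------------------------------------------------------------------------
# Error maps
# ---------------------------------------------------------------------------

def test_error_map_values():
    assert error_map(900.0, 800.0, LossSpec("standard")) == pytest.approx(100.0)
    assert error_map(900.0, 800.0, LossSpec("fractional")) == pytest.approx(100.0 / 800.0)
    assert error_map(900.0, 800.0, LossSpec("skewed")) == pytest.approx(100.0 / 900.0)


@pytest.mark.parametrize("kind", ["standard", "fractional", "skewed"])
def test_zero_error_on_the_diagonal(kind):
    assert error_map(750.0, 750.0, LossSpec(kind)) == 0.0
    assert loss_value(750.0, 750.0, LossSpec(kind, 1.7)) == 0.0


def test_skewed_map_rejects_nonpositive_response():
    with pytest.raises(ValueError):
        error_map(0.0, 700.0, LossSpec("skewed"))


def test_fractional_squared_loss_approximates_log_loss():
    """[(r-x)/x]^2 ~ [log(r/x)]^2 for small relative errors, the sense in
    which the fractional map matches a logarithmic internal representation
    of time.  Taylor oracle: the squared ratio is 1 + eps + O(eps^2), so
    the relative gap at a 5% error is ~5%, shrinking linearly with eps."""
    x = 800.0
    for eps in (0.05, 0.005):
        r = x * (1 + eps)
        frac = loss_value(r, x, LossSpec("fractional"))
        assert frac == pytest.approx(np.log(r / x) ** 2, rel=1.2 * eps)
        assert frac > np.log(r / x) ** 2


# ---------------------------------------------------------------------------
# Expected loss and decision rule
# ---------------------------------------------------------------------------

def test_expected_loss_minimized_at_conjugate_posterior_mean(grid5):
    """Gaussian prior + constant sensory noise + quadratic standard loss:
    the optimal action is the conjugate-Gaussian posterior mean."""
    from chronobayes.distributions import ContinuousPrior

    mu_p, sd_p, sd_s = 780.0, 110.0, 70.0
    prior = ContinuousPrior.from_unnormalized(
        grid5, stats.norm.pdf(grid5, mu_p, sd_p))
    m = make_observer(prior, sensory_kind="constant", w_s=sd_s / 787.5,
                      motor_kind="constant", w_m=0.03)
    x_m = 900.0
    expected = (sd_p ** 2 * x_m + sd_s ** 2 * mu_p) / (sd_p ** 2 + sd_s ** 2)
    rule = decision_rule(m, xm_grid=np.array([x_m]), grid=grid5)
    assert rule.u_star[0] == pytest.approx(expected, abs=0.5)
    # and the expected-loss surface itself dips there
    us = expected + np.array([-40.0, 0.0, 40.0])
    losses = [expected_loss(u, x_m, m, grid=grid5) for u in us]
    assert losses[1] < losses[0] and losses[1] < losses[2]


def test_noiseless_observer_reproduces_the_measurement(grid5):
    prior = make_candidate_prior("e", "medium_uniform", grid5)
    m = make_observer(prior, w_s=1e-6, w_m=1e-6)
    xm = np.arange(620.0, 960.0, 20.0)
    rule = decision_rule(m, xm_grid=xm, grid=grid5)
    assert np.max(np.abs(rule.u_star - xm)) < 0.1


def test_central_tendency_between_measurement_and_prior_mean(grid5):
    prior = make_candidate_prior("b", "medium_uniform", grid5)
    m = make_observer(prior, motor_kind="constant", w_m=0.05)
    xm = np.array([600.0, 650.0, 900.0, 975.0])
    rule = decision_rule(m, xm_grid=xm, grid=grid5)
    for x_m, u in zip(xm, rule.u_star):
        lo, hi = sorted((x_m, 787.5))
        assert lo < u < hi


@pytest.mark.parametrize("loss", ["standard", "fractional"])
@pytest.mark.parametrize("motor_kind", ["constant", "scalar"])
def test_analytic_and_numeric_rules_agree(loss, motor_kind, grid5):
    prior = make_candidate_prior("b", "medium_uniform", grid5)
    m = make_observer(prior, loss=loss, motor_kind=motor_kind, w_m=0.12)
    a = decision_rule(m, method="analytic", grid=grid5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        n = decision_rule(m, method="numeric", grid=grid5)
    assert np.max(np.abs(a.u_star - n.u_star)) < 0.5


def test_rule_monotone_for_standard_loss_constant_noise(grid5):
    prior = make_candidate_prior("c", "medium_peaked", grid5)
    m = make_observer(prior, sensory_kind="constant", motor_kind="constant")
    rule = decision_rule(m, grid=grid5)
    assert np.all(np.diff(rule.u_star) >= -1e-9)


def test_skewed_rule_overshoots_quadratic_rule(grid5):
    """The response-denominated skewed loss penalizes undershoot more, so
    its optimal actions exceed the standard-loss actions."""
    prior = make_candidate_prior("e", "medium_uniform", grid5)
    std = decision_rule(make_observer(prior, "standard"), grid=grid5)
    ske = decision_rule(make_observer(prior, "skewed"), grid=grid5)
    mid = (std.xm_grid > 600) & (std.xm_grid < 975)
    assert np.all(ske.u_star[mid] > std.u_star[mid])


# ---------------------------------------------------------------------------
# Response distribution and bias/sd curves
# ---------------------------------------------------------------------------

def test_response_distribution_normalizes(grid5, gaussian_observer):
    p = response_distribution(750.0, gaussian_observer, r_grid=grid5)
    assert np.trapezoid(p.density, p.grid) == pytest.approx(1.0, abs=1e-6)


def test_lapse_mixture_composition(grid5, gaussian_observer, medium_design):
    base = response_distribution(750.0, gaussian_observer, r_grid=grid5)
    lapser = ObserverModel(gaussian_observer.sensory, gaussian_observer.motor,
                           gaussian_observer.prior, gaussian_observer.loss,
                           lapse_rate=0.5,
                           lapse_range=medium_design.allowed_window)
    mixed = response_distribution(750.0, lapser, r_grid=grid5)
    a, b = medium_design.allowed_window
    uniform = np.where((grid5 >= a) & (grid5 <= b), 1.0 / (b - a), 0.0)
    uniform /= np.trapezoid(uniform, grid5)  # grid-truncated lapse density
    assert mixed.density == pytest.approx(0.5 * base.density + 0.5 * uniform,
                                          abs=1e-9)


def test_quadrature_density_matches_forward_simulation(grid5, gaussian_observer):
    """Chi-square agreement between the marginal response density and a
    direct simulation of the generative chain (one observer; the
    multi-observer version runs in the acceptance suite)."""
    x = 750.0
    rule = decision_rule(gaussian_observer, grid=grid5)
    p = response_distribution(x, gaussian_observer, r_grid=grid5, rule=rule)
    rng = np.random.default_rng(5)
    r, _ = simulate_responses(gaussian_observer, np.full(200_000, x), rng,
                              rule=rule)
    cdf = np.concatenate([[0.0], np.cumsum(
        0.5 * (p.density[1:] + p.density[:-1]) * np.diff(p.grid))])
    cdf /= cdf[-1]
    qs = np.linspace(0.0, 1.0, 31)
    edges = np.interp(qs, cdf, p.grid)
    counts, _ = np.histogram(r, bins=edges)
    stat = ((counts - len(r) / 30) ** 2 / (len(r) / 30)).sum()
    assert stats.chi2.sf(stat, 29) > 0.01


def test_bias_antisymmetric_for_flat_prior_constant_noise(grid5):
    prior = make_candidate_prior("e", "medium_uniform", grid5)
    m = make_observer(prior, sensory_kind="constant", motor_kind="constant")
    curves = bias_sd_curves(m, make_block_distribution("medium_uniform"),
                            grid=grid5)
    b = curves["bias"].to_numpy()
    assert b == pytest.approx(-b[::-1], abs=0.25)
    assert b[0] > 0 > b[-1]  # central tendency


def test_bias_small_at_prior_mean(grid5, gaussian_observer):
    """Zero bias at the prior mean holds exactly under symmetric (constant)
    noise; under scalar noise it is only approximate."""
    prior = gaussian_observer.prior
    sym = make_observer(prior, sensory_kind="constant", motor_kind="constant")
    dist = make_block_distribution("medium_uniform")
    curves = bias_sd_curves(sym, dist, grid=grid5)
    assert abs(np.interp(787.5, curves["x"], curves["bias"])) < 0.5
    curves = bias_sd_curves(gaussian_observer, dist, grid=grid5)
    assert abs(np.interp(787.5, curves["x"], curves["bias"])) < 6.0


def test_peaked_prior_reduces_sd_near_peak(grid5):
    dist = make_block_distribution("medium_peaked")
    flat = make_observer(make_candidate_prior("e", "medium_peaked", grid5))
    peaked = make_observer(make_candidate_prior("c", "medium_peaked", grid5))
    c_flat = bias_sd_curves(flat, dist, grid=grid5)
    c_peak = bias_sd_curves(peaked, dist, grid=grid5)
    assert c_peak["sd"][1] < c_flat["sd"][1]  # at the 675-ms peak


def test_quadrature_moments_match_simulation(grid5, gaussian_observer):
    x = 675.0
    rule = decision_rule(gaussian_observer, grid=grid5)
    curves = bias_sd_curves(gaussian_observer,
                            make_block_distribution("medium_uniform"),
                            grid=grid5, rule=rule)
    n = 100_000
    rng = np.random.default_rng(9)
    r, _ = simulate_responses(gaussian_observer, np.full(n, x), rng, rule=rule)
    row = curves[curves["x"] == x].iloc[0]
    se_mean = r.std() / np.sqrt(n)
    assert r.mean() - x == pytest.approx(row["bias"], abs=3 * se_mean)
    se_sd = r.std() / np.sqrt(2 * (n - 1))
    assert r.std(ddof=1) == pytest.approx(row["sd"], abs=3 * se_sd)
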