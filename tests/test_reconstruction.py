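"""GP interpolation, control-point posterior, slice sampler, prior moments."""

import numpy as np
import pytest

from chronobayes.distributions import duration_grid
from chronobayes.reconstruction import (ControlPointPrior, GPInterpolator,
                                        PriorReconstruction,
                                        _slice_coordinate,
                                        control_points_for_block,
                                        has_spurious_multimodality,
                                        interpolate_prior,
                                        summarize_prior_moments)


@pytest.fixture(scope="module")
def recon(medium_trials, gaussian_observer):
    return PriorReconstruction(medium_trials, gaussian_observer, grid_step=5.0)


# ---------------------------------------------------------------------------
# Control points and GP interpolation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("block,n,lo,hi", [
    ("short_uniform", 10, 300.0, 975.0),
    ("medium_uniform", 10, 450.0, 1125.0),
    ("long_uniform", 10, 600.0, 1275.0),
    ("wide_bimodal", 14, 300.0, 1275.0),
])
def test_control_points_extend_the_block_range(block, n, lo, hi):
    cp = control_points_for_block(block)
    assert len(cp) == n
    assert cp[0] == lo and cp[-1] == hi
    assert np.allclose(np.diff(cp), 75.0)


def test_interpolant_passes_through_control_values():
    cps = control_points_for_block("medium_uniform")
    rng = np.random.default_rng(1)
    lv = rng.normal(0.0, 1.0, len(cps))
    gp = GPInterpolator(jitter=1e-8)
    grid = duration_grid(step=5.0)  # control times lie on the 5-ms grid
    w = gp.interp_matrix(cps, grid)
    from chronobayes.reconstruction import _interp_log_density
    logf = _interp_log_density(w, lv, gp.mean_log)
    at_cp = logf[np.searchsorted(grid, cps)]
    assert np.max(np.abs(at_cp - lv)) < 1e-6


def test_constant_log_values_give_flat_density_with_decayed_tails():
    cps = control_points_for_block("medium_uniform")
    cp = ControlPointPrior(cps, np.full(len(cps), 2.0))
    p = interpolate_prior(cp, GPInterpolator(), duration_grid(step=2.0))
    inside = (p.grid >= cps[0]) & (p.grid <= cps[-1])
    d_in = p.density[inside]
    assert d_in.max() / d_in.min() < 1.25  # near-flat over the control span
    far = p.density[p.grid > cps[-1] + 300]
    assert far.max() < 1e-3 * d_in.max()   # tails decay fast outside


def test_grid_refinement_leaves_the_density_unchanged():
    cps = control_points_for_block("medium_uniform")
    rng = np.random.default_rng(2)
    cp = ControlPointPrior(cps, rng.normal(0.0, 1.0, len(cps)))
    gp = GPInterpolator()
    coarse = interpolate_prior(cp, gp, duration_grid(step=2.0))
    fine = interpolate_prior(cp, gp, duration_grid(step=1.0))
    on_coarse = fine.density[::2]
    assert np.max(np.abs(on_coarse - coarse.density)) < 1e-4


def test_singular_covariance_suggests_jitter():
    gp = GPInterpolator(jitter=0.0, length_scale=5000.0)
    with pytest.raises(ValueError, match="jitter"):
        gp.interp_matrix(control_points_for_block("medium_uniform"),
                         duration_grid(step=5.0))


# ---------------------------------------------------------------------------
# Log posterior
# ---------------------------------------------------------------------------

def test_log_posterior_shift_invariant(recon):
    y = np.random.default_rng(3).normal(0.0, 1.0, 10)
    assert recon.log_posterior(y) == pytest.approx(recon.log_posterior(y + 4.0),
                                                   abs=1e-9)


def test_generative_control_points_beat_random_perturbations(recon):
    """The control vector of the generative Gaussian prior scores higher
    than random sd-1 perturbations of itself on the synthetic data."""
    cps = recon.control_times
    y_true = -0.5 * ((cps - 787.5) / 128.086) ** 2
    base = recon.log_posterior(y_true)
    rng = np.random.default_rng(4)
    worse = sum(recon.log_posterior(y_true + rng.normal(0.0, 1.0, len(cps))) < base
                for _ in range(100))
    assert worse >= 97


def test_log_posterior_stable_under_grid_refinement(medium_trials,
                                                    gaussian_observer):
    """Per-trial densities re-evaluated on a much finer quadrature agree:
    the coarse grid is converged."""
    coarse = PriorReconstruction(medium_trials, gaussian_observer, grid_step=5.0)
    fine = PriorReconstruction(medium_trials, gaussian_observer, grid_step=0.5)
    y = np.random.default_rng(5).normal(0.0, 0.5, 10)
    n = int(medium_trials["retained"].sum())
    assert abs(coarse.log_posterior(y) - fine.log_posterior(y)) / n < 1e-3


def test_cap_blocks_extreme_relative_log_values(recon):
    y = np.zeros(10)
    y[3] = 45.0
    assert recon.log_posterior(y) == -np.inf


# ---------------------------------------------------------------------------
# Slice sampler
# ---------------------------------------------------------------------------

def test_slice_sampler_recovers_a_gaussian_target():
    """Sampler-correctness oracle: bypass the data and target a known
    2-D Gaussian; sample moments must match within Monte-Carlo error."""
    mu = np.array([1.0, -2.0])
    sd = np.array([0.7, 1.4])

    def logf(y):
        return float(-0.5 * np.sum(((y - mu) / sd) ** 2))

    rng = np.random.default_rng(6)
    y = np.zeros(2)
    fy = logf(y)
    draws = []
    for it in range(2500):
        for i in range(2):
            _, fy, _ = _slice_coordinate(logf, y, i, fy, rng, width=2.0,
                                         max_steps=10)
        if it >= 500:
            draws.append(y.copy())
    draws = np.asarray(draws)
    n_eff = len(draws) / 5  # generous autocorrelation allowance
    for k in range(2):
        assert draws[:, k].mean() == pytest.approx(
            mu[k], abs=4 * sd[k] / np.sqrt(n_eff))
        assert draws[:, k].std() == pytest.approx(sd[k], rel=0.15)


def test_fit_deterministic_under_seed(recon):
    r1 = recon.fit(chains=1, burn=10, draws=10, seed=21)
    r2 = recon.fit(chains=1, burn=10, draws=10, seed=21)
    assert np.array_equal(r1.samples, r2.samples)
    r3 = recon.fit(chains=1, burn=10, draws=10, seed=22)
    assert not np.array_equal(r1.samples, r3.samples)


# ---------------------------------------------------------------------------
# Moment summaries
# ---------------------------------------------------------------------------

def test_identical_samples_have_zero_moment_spread():
    mom = np.tile([700.0, 120.0, 0.1, -0.5], (50, 1))
    s = summarize_prior_moments(mom)
    assert np.all(s["sd"] < 1e-12)
    assert s.loc["mean", "mean"] == 700.0


def test_average_of_moments_not_moments_of_average(recon):
    """Averaging the sampled densities and then taking moments misstates
    tail weight (a mixture of two near-Gaussian densities has a very
    different kurtosis from either component); the reported summary is
    the average of per-sample moments instead."""
    cps = recon.control_times
    y1 = -0.5 * ((cps - 650.0) / 60.0) ** 2
    y2 = -0.5 * ((cps - 900.0) / 60.0) ** 2
    d1 = recon.density_from_log_values(y1)
    d2 = recon.density_from_log_values(y2)
    grid = recon.grid

    def mom4(d):
        m = np.trapezoid(grid * d, grid)
        mu2 = np.trapezoid((grid - m) ** 2 * d, grid)
        mu4 = np.trapezoid((grid - m) ** 4 * d, grid)
        return np.array([m, np.sqrt(mu2), 0.0, mu4 / mu2 ** 2 - 3.0])

    per_sample = np.vstack([mom4(d1), mom4(d2)])
    pooled = summarize_prior_moments(per_sample)
    avg_of_moments = pooled.loc["excess_kurtosis", "mean"]
    # the operation returns the average of per-sample moments ...
    assert avg_of_moments == pytest.approx(per_sample[:, 3].mean())
    # ... which differs decisively from the moments of the average density
    moments_of_avg = mom4(0.5 * (d1 + d2))[3]
    assert abs(avg_of_moments - moments_of_avg) > 0.5
    # pooling a list of per-subject arrays concatenates them
    assert summarize_prior_moments([per_sample, per_sample]).loc[
        "mean", "mean"] == pytest.approx(pooled.loc["mean", "mean"])


def test_multimodality_detector():
    smooth = np.array([0.1, 0.5, 1.0, 1.3, 1.4, 1.3, 1.0, 0.5, 0.2, 0.1])
    comb = np.array([0.1, 0.9, 0.2, 1.0, 0.3, 1.1, 0.2, 0.8, 0.2, 0.1])
    assert not has_spurious_multimodality(smooth)
    assert has_spurious_multimodality(comb)


def test_short_reconstruction_smoke(recon):
    """End-to-end smoke at token chain length: valid densities, archive
    frame shape, finite diagnostics."""
    res = recon.fit(chains=2, burn=15, draws=20, seed=8)
    dens = res.mean_density()
    assert np.all(dens.density >= 0)
    assert np.trapezoid(dens.density, dens.grid) == pytest.approx(1.0, abs=1e-8)
    frame = res.to_frame()
    assert len(frame) == 2 * 20
    assert {"chain", "iteration", "mean", "sd"} <= set(frame.columns)
    assert np.isfinite(res.rhat())
    mom = res.sample_moments()
    assert np.all((mom[:, 0] > 450) & (mom[:, 0] < 1150))
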