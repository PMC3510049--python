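"""Nonparametric reconstruction of subjective priors.

Rather than choosing among a fixed set of candidate priors, the prior is
freed to vary over a broad class of smooth densities: its log is
parameterized by the values at 10 control points (14 for the Wide range)
spaced 75 ms apart over the block's interval range extended by two steps
on each side, and interpolated onto the duration grid with a squared-
exponential Gaussian-process posterior mean (the GP is an interpolator
only, not part of the inference).  With the observer's noise and loss
components fixed (at values inferred by the model comparison), control-
point vectors are sampled from the posterior over priors, which is
proportional to the trial likelihood, using coordinate-wise slice
sampling with stepping-out.  Moments are computed per sampled prior and
then averaged across samples - never the moments of the averaged
density, which would understate tail weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .distributions import (ContinuousPrior, _trapz_weights, duration_grid,
                            make_block_distribution)
from .observer import (ACTION_BOUNDS, ObserverModel, _motor_matrix, _norm_pdf,
                       _parabolic_refine, _trunc_normalizer, loss_value,
                       sensory_density)

__all__ = [
    "ControlPointPrior",
    "GPInterpolator",
    "PriorReconstruction",
    "PriorReconstructionResults",
    "control_points_for_block",
    "interpolate_prior",
    "slice_sample_priors",
    "summarize_prior_moments",
    "has_spurious_multimodality",
]

#: Hard cap on |log prior value - mean log value| at control points, for
#: numerical safety.  Only relative log values matter (normalization
#: absorbs any common offset), so the cap is applied in the centred gauge.
LOG_VALUE_CAP = 20.0


def control_points_for_block(block_name: str) -> np.ndarray:
    """Control-point times: the block's interval support extended by two
    75-ms steps on each side (10 points for 6-interval blocks, 14 for
    Wide), allowing tails or shifts beyond the range."""
    d = make_block_distribution(block_name)
    lo, hi = d.support[0] - 150.0, d.support[-1] + 150.0
    return np.arange(lo, hi + 1e-9, 75.0)


@dataclass
class ControlPointPrior:
    """Log-prior values at the control points."""

    control_times: np.ndarray
    log_values: np.ndarray

    def __post_init__(self):
        self.control_times = np.asarray(self.control_times, float)
        self.log_values = np.asarray(self.log_values, float)
        if self.control_times.shape != self.log_values.shape:
            raise ValueError("control_times and log_values must match")


@dataclass
class GPInterpolator:
    """Squared-exponential GP posterior-mean interpolation of the log prior.

    length_scale (ms) is of the order of the 75-ms control spacing so the
    interpolant is smooth without oscillating; signal_scale is in
    log-density units; jitter is the small noise term that keeps the
    covariance well conditioned.  Extrapolation beyond the control points
    decays to ``mean_log`` log-density units *below the average control
    value* (anchoring the extrapolation level to the control mean makes
    the induced density exactly invariant to adding a constant to all
    control values), so tails vanish within about one control spacing
    outside the range.
    """

    length_scale: float = 100.0
    signal_scale: float = 2.0
    jitter: float = 1e-6
    mean_log: float = -10.0

    def _kernel(self, s, t):
        d = (np.asarray(s, float)[:, None] - np.asarray(t, float)[None, :])
        return self.signal_scale ** 2 * np.exp(-0.5 * (d / self.length_scale) ** 2)

    def interp_matrix(self, control_times, grid) -> np.ndarray:
        """W such that log f(grid) = mean_log + W @ (y - mean_log)."""
        kcc = self._kernel(control_times, control_times)
        kcc[np.diag_indices_from(kcc)] += self.jitter
        try:
            cho = linalg.cho_factor(kcc)
        except linalg.LinAlgError as err:
            raise ValueError("control-point covariance not positive definite; "
                             "increase the jitter term") from err
        kgc = self._kernel(grid, control_times)
        return linalg.cho_solve(cho, kgc.T).T


def _interp_log_density(w, log_values, mean_log):
    base = float(np.mean(log_values)) + mean_log
    return base + w @ (np.asarray(log_values, float) - base)


def interpolate_prior(cp: ControlPointPrior, gp: GPInterpolator,
                      grid) -> ContinuousPrior:
    """GP-interpolate the control-point log prior onto ``grid``,
    exponentiate and renormalize."""
    grid = np.asarray(grid, float)
    w = gp.interp_matrix(cp.control_times, grid)
    logf = _interp_log_density(w, cp.log_values, gp.mean_log)
    return ContinuousPrior.from_unnormalized(grid, np.exp(logf),
                                             label="interpolated")


def has_spurious_multimodality(density_at_controls, ratio: float = 1.5) -> bool:
    """True when some interior control point is a local maximum exceeding
    ``ratio`` times the density at both adjacent control points - the
    signature of a spurious mode at the 75-ms control resolution."""
    d = np.asarray(density_at_controls, float)
    for i in range(1, len(d) - 1):
        if d[i] > ratio * d[i - 1] and d[i] > ratio * d[i + 1]:
            return True
    return False


# ---------------------------------------------------------------------------
# Fixed-observer likelihood engine (prior varies, noise/loss fixed)
# ---------------------------------------------------------------------------

class _FixedObserverEngine:
    """Trial log likelihood as a function of the prior density alone.

    Everything that does not depend on the prior - the sensory kernel
    over the measurement grid, the per-target sensory weights, and for
    the skewed loss the truncated-Gaussian 1/r moments - is precomputed,
    so a log-posterior evaluation costs two matrix-vector products plus
    the motor densities at the observed responses.
    """

    def __init__(self, x, r, observer: ObserverModel, grid,
                 bounds=ACTION_BOUNDS, xm_step: float = 10.0):
        self.grid = np.asarray(grid, float)
        self.obs = observer
        self.wq = _trapz_weights(self.grid)
        x = np.asarray(x, float)
        r = np.asarray(r, float)
        sens, motor = observer.sensory, observer.motor

        # Measurement grid: only where some target has non-negligible
        # sensory mass, at its own (coarser) resolution - the integrand is
        # a Gaussian mixture with sds of at least ~30 ms, so ~10-ms
        # quadrature is ample.
        ux = np.unique(x)
        sd_x = sens.sd(ux)
        lo = max(self.grid[0], float((ux - 6.0 * sd_x).min()))
        hi = min(self.grid[-1], float((ux + 6.0 * sd_x).max()))
        step = max(float(self.grid[1] - self.grid[0]), xm_step)
        self.xm = np.arange(lo, hi + 0.5 * step, step)

        # Sensory kernel over (x_m, x): prior-independent posterior factor.
        sd_grid = sens.sd(self.grid)
        self.k_s = _norm_pdf(self.xm[:, None], self.grid[None, :],
                             sd_grid[None, :])

        # Per-target sensory weight rows, truncated to each target's own
        # effective measurement support.
        wq_xm = _trapz_weights(self.xm)
        self.groups = []
        for xv in ux:
            ws = sensory_density(self.xm, float(xv), sens) * wq_xm
            ws /= ws.sum()
            nz = np.flatnonzero(ws > 1e-14)
            sl = slice(int(nz[0]), int(nz[-1]) + 1)
            rv = r[x == xv]
            self.groups.append((rv, ws[sl] / ws[sl].sum(), sl,
                                np.empty((len(rv), sl.stop - sl.start))))
        self.n_trials = len(x)

        # Action grid and loss-specific precomputations.
        self.u_grid = self.grid[(self.grid >= bounds[0]) & (self.grid <= bounds[1])]
        loss = observer.loss
        self.c_motor = 1.0 + motor.w ** 2 if motor.kind == "scalar" else 1.0
        self.loss_kind = loss.map_kind if loss.exponent == 2.0 else "generic"
        if self.loss_kind == "skewed":
            mker = _motor_matrix(self.u_grid, self.grid, motor) * self.wq[None, :]
            self.a_u = mker @ (1.0 / self.grid)
            self.b_u = mker @ (1.0 / self.grid ** 2)
        elif self.loss_kind == "generic":
            mker = _motor_matrix(self.u_grid, self.grid, motor) * self.wq[None, :]
            lmat = loss_value(self.grid[None, :], self.grid[:, None], loss)
            self.c_mat = mker @ lmat.T  # (n_u, n_x)

    def _decision(self, prior_density):
        pw = prior_density * self.wq
        num = self.k_s * pw[None, :]
        z = num.sum(axis=1, keepdims=True)
        p = num / np.maximum(z, 1e-300)
        kind = self.loss_kind
        if kind == "standard":
            return (p @ self.grid) / self.c_motor
        if kind == "fractional":
            return (p @ (1.0 / self.grid)) / (self.c_motor * (p @ self.grid ** -2))
        if kind == "skewed":
            m1 = p @ self.grid
            m2 = p @ self.grid ** 2
            g = -2.0 * np.outer(m1, self.a_u) + np.outer(m2, self.b_u)
        else:
            g = p @ self.c_mat.T
        return _parabolic_refine(self.u_grid, g, np.argmin(g, axis=1))

    def loglik(self, prior_density) -> float:
        u = self._decision(prior_density)
        motor = self.obs.motor
        sd = motor.sd(u)
        z = np.maximum(_trunc_normalizer(u, sd, self.grid[0], self.grid[-1]),
                       1e-300)
        # motor Gaussian at every (trial, x_m) pair, built in-place
        norm = 1.0 / (sd * np.sqrt(2.0 * np.pi) * z)
        lam = self.obs.lapse_rate
        a, b = self.obs.lapse_range
        total = 0.0
        for rv, ws, sl, buf in self.groups:
            np.subtract(rv[:, None], u[None, sl], out=buf)
            buf /= sd[None, sl]
            np.multiply(buf, buf, out=buf)
            buf *= -0.5
            np.exp(buf, out=buf)
            dens = buf @ (ws * norm[sl])
            if lam > 0:
                lap = ((rv >= a) & (rv <= b)) / (b - a)
                dens = (1.0 - lam) * dens + lam * lap
            if np.any(dens <= 0):
                return -np.inf
            total += float(np.log(dens).sum())
        return total


# ---------------------------------------------------------------------------
# Slice sampler
# ---------------------------------------------------------------------------

def _slice_coordinate(logf, y, i, fy, rng, width=1.0, max_steps=10,
                      lo=-LOG_VALUE_CAP, hi=LOG_VALUE_CAP):
    """One univariate slice-sampling update of coordinate ``i`` with
    stepping-out (Neal 2003).  Returns (new value, new log density,
    number of log-density evaluations)."""
    level = fy + np.log(rng.random())
    x0 = y[i]
    left = x0 - width * rng.random()
    right = left + width
    j = int(np.floor(max_steps * rng.random()))
    k = max_steps - 1 - j
    n_eval = 0

    def f_at(v):
        nonlocal n_eval
        y[i] = v
        n_eval += 1
        return logf(y)

    while j > 0 and left > lo and f_at(left) > level:
        left -= width
        j -= 1
    while k > 0 and right < hi and f_at(right) > level:
        right += width
        k -= 1
    left, right = max(left, lo), min(right, hi)
    for _ in range(10_000):
        v = left + (right - left) * rng.random()
        fv = f_at(v)
        if fv > level:
            return v, fv, n_eval
        if v < x0:
            left = v
        else:
            right = v
    raise RuntimeError("slice shrinkage failed to accept; the log density "
                       "is likely inconsistent with the current state")


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class PriorReconstruction:
    """Posterior over nonparametric priors for one block's trials.

    Parameters
    ----------
    trials : DataFrame
        Trial table for a single block; only retained trials are used.
    observer : ObserverModel
        Carries the *fixed* components (sensory/motor noise kinds and
        coefficients, loss, lapse); its own prior is ignored.
    block : str, optional
        Block name (inferred from the table when unique); sets the
        control points.
    gp : GPInterpolator
    grid_step : float
        Duration-grid resolution (ms).
    """

    def __init__(self, trials: pd.DataFrame, observer: ObserverModel,
                 block: str = None, gp: GPInterpolator = None,
                 grid_step: float = 1.0, control_times=None):
        if "retained" in trials.columns:
            trials = trials[trials["retained"]]
        if block is None:
            blocks = trials["block"].unique()
            if len(blocks) != 1:
                raise ValueError("trials span several blocks; pass block=")
            block = str(blocks[0])
        else:
            trials = trials[trials["block"] == block]
        if len(trials) == 0:
            raise ValueError("no retained trials for the requested block")
        self.block = block
        self.gp = gp or GPInterpolator()
        self.grid = duration_grid(step=grid_step)
        self.control_times = (np.asarray(control_times, float)
                              if control_times is not None
                              else control_points_for_block(block))
        if (self.control_times[0] < self.grid[0]
                or self.control_times[-1] > self.grid[-1]):
            raise ValueError("control points must lie inside the grid")
        self.w_interp = self.gp.interp_matrix(self.control_times, self.grid)
        self.engine = _FixedObserverEngine(trials["target_ms"].to_numpy(),
                                           trials["response_ms"].to_numpy(),
                                           observer, self.grid)
        self.observer = observer
        self.trials = trials

    # -- posterior ----------------------------------------------------------

    def density_from_log_values(self, log_values) -> np.ndarray:
        logf = _interp_log_density(self.w_interp, log_values, self.gp.mean_log)
        f = np.exp(logf)
        return f / np.trapezoid(f, self.grid)

    def log_posterior(self, log_values) -> float:
        """log Pr(data | prior) with a flat (capped) hyperprior over the
        control-point log values; invariant to adding a constant to all
        log values, which normalization absorbs."""
        lv = np.asarray(log_values, float)
        if np.any(np.abs(lv - lv.mean()) > LOG_VALUE_CAP):
            return -np.inf
        return self.engine.loglik(self.density_from_log_values(lv))

    def _initial_points(self, rng, chains):
        """Dispersed initialization around a Gaussian matched to the
        empirical target moments."""
        x = self.trials["target_ms"].to_numpy()
        mu, sd = float(x.mean()), float(x.std() + 30.0)
        base = -0.5 * ((self.control_times - mu) / sd) ** 2
        base = np.maximum(base - base.max(), -8.0)
        return [base + rng.normal(0.0, 0.5, size=base.shape)
                for _ in range(chains)]

    def fit(self, chains: int = 10, burn: int = 3000, draws: int = 1500,
            seed=None, width: float = 1.0, max_steps: int = 10,
            verbose: bool = False) -> "PriorReconstructionResults":
        """Slice-sample the posterior over control-point priors.

        Defaults follow the full protocol (10 chains x 3000 burn-in
        + 1500 saved = 15000 priors); smaller chain configurations give
        quick approximate reconstructions.
        """
        master = np.random.default_rng(seed)
        chain_rngs = master.spawn(chains)
        n_cp = len(self.control_times)
        samples = np.empty((chains, draws, n_cp))
        logposts = np.empty((chains, draws))
        inits = self._initial_points(master, chains)
        for c, rng in enumerate(chain_rngs):
            y = inits[c].copy()
            fy = self.log_posterior(y)
            if not np.isfinite(fy):
                raise ValueError("non-finite log posterior at initialization")
            # Per-coordinate slice widths, adapted to the typical accepted
            # move during burn-in and frozen afterwards (adaptation during
            # sampling would break detailed balance).
            widths = np.full(n_cp, width)
            move_ema = np.full(n_cp, width / 3.0)
            for it in range(burn + draws):
                for i in range(n_cp):
                    old = y[i]
                    v, fy, _ = _slice_coordinate(self.log_posterior, y, i, fy,
                                                 rng, widths[i], max_steps)
                    if it < burn:
                        move_ema[i] = 0.9 * move_ema[i] + 0.1 * abs(v - old)
                        widths[i] = np.clip(3.0 * move_ema[i], 0.02, 5.0)
                # Gauge fixing: the posterior is invariant to adding a
                # constant to all log values, so recentre to mean zero to
                # keep the chain off that flat ridge.
                y -= y.mean()
                if it >= burn:
                    samples[c, it - burn] = y
                    logposts[c, it - burn] = fy
            if verbose:
                print(f"chain {c + 1}/{chains} done (logpost {fy:.1f})")
        return PriorReconstructionResults(self, samples, logposts)


class PriorReconstructionResults:
    """Sampled priors, their moments, and convergence diagnostics."""

    def __init__(self, model: PriorReconstruction, samples, logposts):
        self.model = model
        self.samples = np.asarray(samples)   # (chains, draws, n_cp)
        self.logposts = np.asarray(logposts)
        self._moments = None

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0] * self.samples.shape[1]

    def _densities(self, flat_samples) -> np.ndarray:
        g = self.model
        base = flat_samples.mean(axis=1, keepdims=True) + g.gp.mean_log
        logf = base + (flat_samples - base) @ g.w_interp.T
        f = np.exp(logf)
        z = np.trapezoid(f, g.grid, axis=1)
        return f / z[:, None]

    def sample_moments(self) -> np.ndarray:
        """First four moments (mean, sd, skewness, excess kurtosis) of each
        sampled prior; computed in batches, cached."""
        if self._moments is None:
            flat = self.samples.reshape(-1, self.samples.shape[-1])
            g = self.model.grid
            wq = _trapz_weights(g)
            out = np.empty((len(flat), 4))
            for s in range(0, len(flat), 2000):
                d = self._densities(flat[s:s + 2000]) * wq[None, :]
                m = d @ g
                dev = g[None, :] - m[:, None]
                mu2 = np.einsum("ij,ij->i", d, dev ** 2)
                mu3 = np.einsum("ij,ij->i", d, dev ** 3)
                mu4 = np.einsum("ij,ij->i", d, dev ** 4)
                sd = np.sqrt(mu2)
                out[s:s + 2000] = np.column_stack(
                    [m, sd, mu3 / sd ** 3, mu4 / mu2 ** 2 - 3.0])
            self._moments = out
        return self._moments

    def moment_summary(self) -> pd.DataFrame:
        """Mean and sd of each moment across the sampled priors (moments
        first, averaging second)."""
        return summarize_prior_moments(self.sample_moments())

    def mean_density(self) -> ContinuousPrior:
        """Average of the sampled normalized densities (for display and
        multimodality checks; moments are *not* taken from this)."""
        flat = self.samples.reshape(-1, self.samples.shape[-1])
        dens = np.zeros(len(self.model.grid))
        for s in range(0, len(flat), 2000):
            dens += self._densities(flat[s:s + 2000]).sum(axis=0)
        dens /= len(flat)
        return ContinuousPrior.from_unnormalized(self.model.grid, dens,
                                                 label=f"{self.model.block}:reconstructed")

    def density_at_controls(self) -> np.ndarray:
        d = self.mean_density()
        return np.interp(self.model.control_times, d.grid, d.density)

    def rhat(self, on: str = "moments") -> float:
        """Largest split-R-hat across monitored quantities.

        By default convergence is monitored on the per-sample prior
        moments, which are identifiable; raw control-point values carry a
        flat shift direction and weakly likelihood-constrained tails, so
        their R-hat stays pessimistic long after the induced densities
        have converged (``on='control_points'`` reports it anyway).
        """
        import arviz as az
        if on == "moments":
            chains, draws, _ = self.samples.shape
            data = self.sample_moments().reshape(chains, draws, 4)
        else:
            data = self.samples
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r = az.rhat(az.convert_to_dataset(data))
        return float(np.max(r.to_array().values))

    def to_frame(self) -> pd.DataFrame:
        """Sample archive: chain, iteration, control values, four moments."""
        chains, draws, n_cp = self.samples.shape
        flat = self.samples.reshape(-1, n_cp)
        mom = self.sample_moments()
        df = pd.DataFrame(flat, columns=[f"cp_{int(t)}" for t in
                                         self.model.control_times])
        df.insert(0, "iteration", np.tile(np.arange(draws), chains))
        df.insert(0, "chain", np.repeat(np.arange(chains), draws))
        for k, name in enumerate(["mean", "sd", "skewness", "excess_kurtosis"]):
            df[name] = mom[:, k]
        return df

    def summary(self) -> str:
        ms = self.moment_summary()
        lines = [f"Nonparametric prior reconstruction - block {self.model.block}",
                 f"  chains x draws: {self.samples.shape[0]} x {self.samples.shape[1]}"
                 f"   trials: {self.model.engine.n_trials}",
                 f"  split-R-hat (max over prior moments): {self.rhat():.3f}",
                 "", ms.to_string(float_format=lambda v: f"{v:.2f}")]
        return "\n".join(lines)


def slice_sample_priors(trials, observer: ObserverModel, block: str = None,
                        chains: int = 10, burn: int = 3000, draws: int = 1500,
                        seed=None, gp: GPInterpolator = None,
                        grid_step: float = 1.0) -> PriorReconstructionResults:
    """Functional wrapper: build a :class:`PriorReconstruction` and sample."""
    model = PriorReconstruction(trials, observer, block=block, gp=gp,
                                grid_step=grid_step)
    return model.fit(chains=chains, burn=burn, draws=draws, seed=seed)


def summarize_prior_moments(moments) -> pd.DataFrame:
    """Mean +/- sd of the first four moments across sampled priors.

    ``moments`` is an (n_samples, 4) array, or a sequence of such arrays
    (e.g. one per subject), which are pooled.  Averaging per-sample
    moments preserves tail weight that the moments of the averaged
    density would misstate.
    """
    if isinstance(moments, (list, tuple)):
        moments = np.concatenate([np.asarray(m) for m in moments], axis=0)
    moments = np.asarray(moments)
    names = ["mean", "sd", "skewness", "excess_kurtosis"]
    return pd.DataFrame({"mean": moments.mean(axis=0),
                         "sd": moments.std(axis=0, ddof=0)}, index=names)
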