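"""Bayesian ideal observer-actor for interval reproduction.

A single observer is specified by four components: a sensory noise model
(Gaussian measurement noise, constant or scalar), a motor noise model
(same two choices), a subjective prior over interval durations, and a
loss function (a squared subjective error map, with an optional
non-quadratic exponent).  Given a noisy internal measurement ``x_m`` of
the target interval ``x``, the observer presses for the duration ``u``
that minimizes the subjectively expected loss

    u*(x_m) = argmin_u  E_{x ~ post(.|x_m)} E_{r ~ motor(.|u)} |f(r, x)|^k

and the observed response is the chosen action corrupted by motor noise.
Marginalizing the hidden measurement yields the response distribution

    p(r | x) = integral  p_s(x_m | x) p_m(r | u*(x_m)) dx_m ,

optionally mixed with a uniform lapse component.  The predicted response
bias ``E[r|x] - x`` and response sd follow by quadrature.

All quadratures run on a regular 1-ms duration grid by default; scalar
noise is truncated to the grid and renormalized.  Durations in ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .distributions import (ContinuousPrior, IntervalDistribution,
                            REFERENCE_INTERVAL, duration_grid,
                            make_candidate_prior, _trapz_weights)

__all__ = [
    "NoiseModel",
    "LossSpec",
    "ObserverModel",
    "DecisionRule",
    "sensory_density",
    "motor_density",
    "error_map",
    "loss_value",
    "expected_loss",
    "decision_rule",
    "response_distribution",
    "bias_sd_curves",
    "simulate_responses",
]

#: Action optimization bounds (ms): a superset of every block's
#: allowed-response window, so no admissible optimum is clipped.
ACTION_BOUNDS = (150.0, 1800.0)

LOSS_KINDS = ("standard", "fractional", "skewed")
NOISE_KINDS = ("constant", "scalar")


@dataclass
class NoiseModel:
    """Gaussian timing noise with coefficient of variation ``w``.

    kind='scalar' : sd grows linearly with the interval, sd = w * t
        (the scalar property of interval timing).
    kind='constant' : sd is interval-independent, sd = w * reference,
        with the reference fixed at 787.5 ms.
    """

    kind: str
    w: float
    reference: float = REFERENCE_INTERVAL

    def __post_init__(self):
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"noise kind must be one of {NOISE_KINDS}")
        if not self.w > 0:
            raise ValueError("coefficient of variation w must be > 0")

    def sd(self, t):
        t = np.asarray(t, dtype=float)
        if self.kind == "scalar":
            if np.any(t <= 0):
                raise ValueError("scalar noise undefined for nonpositive durations")
            return self.w * t
        return np.broadcast_to(self.w * self.reference, t.shape).copy()

    def to_dict(self):
        return {"kind": self.kind, "w": float(self.w), "reference": float(self.reference)}

    @classmethod
    def from_dict(cls, d):
        return cls(d["kind"], d["w"], d.get("reference", REFERENCE_INTERVAL))


@dataclass
class LossSpec:
    """Loss = |subjective error map|^exponent.

    map_kind='standard'   : f(r, x) = r - x
    map_kind='fractional' : f(r, x) = (r - x) / x
    map_kind='skewed'     : f(r, x) = (r - x) / r  (response-denominated,
        producing a response-dependent asymmetry)

    The basic model uses exponent 2; other exponents force the numeric
    minimization path.
    """

    map_kind: str
    exponent: float = 2.0

    def __post_init__(self):
        if self.map_kind not in LOSS_KINDS:
            raise ValueError(f"loss map kind must be one of {LOSS_KINDS}")
        if not self.exponent > 0:
            raise ValueError("loss exponent must be > 0")

    def to_dict(self):
        return {"map_kind": self.map_kind, "exponent": float(self.exponent)}

    @classmethod
    def from_dict(cls, d):
        return cls(d["map_kind"], d.get("exponent", 2.0))


@dataclass
class ObserverModel:
    """A fully specified Bayesian observer-actor.

    ``prior`` may be an :class:`IntervalDistribution` (discrete atoms) or
    a :class:`ContinuousPrior` (density on a grid).  ``lapse_rate`` is the
    probability of a lapse trial, on which the response is uniform over
    ``lapse_range``.
    """

    sensory: NoiseModel
    motor: NoiseModel
    prior: object
    loss: LossSpec
    lapse_rate: float = 0.0
    lapse_range: tuple = (300.0, 1462.0)

    def __post_init__(self):
        if not (0.0 <= self.lapse_rate < 1.0):
            raise ValueError("lapse_rate must lie in [0, 1)")
        if not isinstance(self.prior, (IntervalDistribution, ContinuousPrior)):
            raise TypeError("prior must be an IntervalDistribution or ContinuousPrior")
        a, b = self.lapse_range
        if not b > a:
            raise ValueError("lapse_range must be an increasing interval")

    def to_dict(self):
        if isinstance(self.prior, IntervalDistribution):
            prior = {"type": "discrete", **self.prior.to_dict()}
        else:
            prior = {"type": "continuous", "label": self.prior.label,
                     "grid": [float(g) for g in self.prior.grid],
                     "density": [float(d) for d in self.prior.density]}
        return {"sensory": self.sensory.to_dict(), "motor": self.motor.to_dict(),
                "prior": prior, "loss": self.loss.to_dict(),
                "lapse_rate": float(self.lapse_rate),
                "lapse_range": [float(v) for v in self.lapse_range]}

    @classmethod
    def from_dict(cls, d):
        p = d["prior"]
        if "scheme" in p:
            prior = make_candidate_prior(p["scheme"], p["block"])
        elif p.get("type") == "discrete" or "support" in p:
            prior = IntervalDistribution.from_dict(p)
        else:
            prior = ContinuousPrior(np.asarray(p["grid"], float),
                                    np.asarray(p["density"], float),
                                    p.get("label", ""))
        return cls(sensory=NoiseModel.from_dict(d["sensory"]),
                   motor=NoiseModel.from_dict(d["motor"]),
                   prior=prior, loss=LossSpec.from_dict(d["loss"]),
                   lapse_rate=d.get("lapse_rate", 0.0),
                   lapse_range=tuple(d.get("lapse_range", (300.0, 1462.0))))


@dataclass
class DecisionRule:
    """Tabulated optimal action u*(x_m) on a measurement grid."""

    xm_grid: np.ndarray
    u_star: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.u_star)):
            raise ValueError("optimal actions must be finite")

    def __call__(self, x_m):
        return np.interp(x_m, self.xm_grid, self.u_star)


# ---------------------------------------------------------------------------
# Densities and error maps
# ---------------------------------------------------------------------------

def _norm_pdf(x, mu, sd):
    z = (np.asarray(x, float) - mu) / sd
    return np.exp(-0.5 * z * z) / (sd * np.sqrt(2.0 * np.pi))


def sensory_density(x_m, x, noise: NoiseModel):
    """Sensory likelihood p_s(x_m | x): Gaussian centred on the interval."""
    return _norm_pdf(x_m, np.asarray(x, float), noise.sd(x))


def motor_density(r, u, noise: NoiseModel):
    """Motor likelihood p_m(r | u): Gaussian centred on the action."""
    return _norm_pdf(r, np.asarray(u, float), noise.sd(u))


def error_map(r, x, loss: LossSpec):
    """Signed subjective error f(r, x) for the loss's map kind."""
    r = np.asarray(r, dtype=float)
    x = np.asarray(x, dtype=float)
    if loss.map_kind == "standard":
        return r - x
    if loss.map_kind == "fractional":
        if np.any(x <= 0):
            raise ValueError("fractional error undefined for x <= 0")
        return (r - x) / x
    if np.any(r <= 0):
        raise ValueError("skewed error undefined for r <= 0")
    return (r - x) / r


def loss_value(r, x, loss: LossSpec):
    """Loss |f(r, x)|^exponent."""
    return np.abs(error_map(r, x, loss)) ** loss.exponent


# ---------------------------------------------------------------------------
# Internal quadrature helpers
# ---------------------------------------------------------------------------

def prior_atoms(prior, grid=None):
    """Represent a prior as weighted support points (xs, pw), pw summing 1.

    Discrete priors keep their exact atoms; continuous priors become their
    grid with trapezoid quadrature weights folded in.
    """
    if isinstance(prior, IntervalDistribution):
        return prior.support.copy(), prior.probs.copy()
    pw = prior.density * _trapz_weights(prior.grid)
    z = pw.sum()
    if z <= 0:
        raise ValueError("prior has zero mass on the grid")
    return prior.grid.copy(), pw / z


def _posterior_matrix(xm, xs, pw, sensory: NoiseModel):
    """Row-normalized posterior over prior support per measurement.

    P[i, j] proportional to p_s(xm_i | xs_j) * pw_j, computed in log space
    so that measurements far from the support stay well-defined.
    """
    sd = sensory.sd(xs)
    with np.errstate(divide="ignore"):
        logw = np.log(pw)
    z = (xm[:, None] - xs[None, :]) / sd[None, :]
    logk = -0.5 * z * z - np.log(sd)[None, :] + logw[None, :]
    m = logk.max(axis=1, keepdims=True)
    p = np.exp(logk - m)
    p /= p.sum(axis=1, keepdims=True)
    return p


def _trunc_normalizer(u, sd, lo, hi):
    """Gaussian mass of N(u, sd^2) inside [lo, hi]."""
    return ndtr((hi - u) / sd) - ndtr((lo - u) / sd)


def _motor_matrix(u_vec, r_grid, motor: NoiseModel):
    """Motor kernel M[i, k] = p_m(r_k | u_i), truncated-renormalized to
    the r grid."""
    sd = motor.sd(u_vec)
    m = _norm_pdf(r_grid[None, :], u_vec[:, None], sd[:, None])
    z = _trunc_normalizer(u_vec, sd, r_grid[0], r_grid[-1])
    return m / np.maximum(z, 1e-300)[:, None]


def _parabolic_refine(u_grid, g, idx):
    """Refine grid argmins by fitting a parabola through each minimum's
    neighbourhood; interior points only."""
    u = u_grid[idx].astype(float)
    inner = (idx > 0) & (idx < len(u_grid) - 1)
    i = idx[inner]
    g0, g1, g2 = g[inner, i - 1], g[inner, i], g[inner, i + 1]
    denom = g0 - 2.0 * g1 + g2
    ok = denom > 0
    step = np.zeros_like(g1)
    step[ok] = 0.5 * (g0[ok] - g2[ok]) / denom[ok]
    h = u_grid[i + 1] - u_grid[i]
    u[inner] = u_grid[i] + np.clip(step, -1.0, 1.0) * h
    return u


# ---------------------------------------------------------------------------
# Expected loss and optimal action
# ---------------------------------------------------------------------------

def expected_loss(u, x_m, model: ObserverModel, grid=None):
    """Subjectively expected loss of action ``u`` given measurement ``x_m``.

    Double quadrature of loss x motor density x normalized posterior over
    the duration grid.  Used directly for testing and by the generic
    numeric minimization; the analytic decision-rule paths bypass it.
    """
    if grid is None:
        grid = _model_grid(model)
    xs, pw = prior_atoms(model.prior, grid)
    post = _posterior_matrix(np.atleast_1d(float(x_m)), xs, pw, model.sensory)[0]
    if not np.any(post > 0):
        raise ValueError("prior carries no mass near the measurement")
    wq = _trapz_weights(grid)
    mrow = _motor_matrix(np.atleast_1d(float(u)), grid, model.motor)[0]
    lmat = loss_value(grid[None, :], xs[:, None], model.loss)
    return float(post @ (lmat @ (mrow * wq)))


def _model_grid(model_or_prior):
    prior = getattr(model_or_prior, "prior", model_or_prior)
    if isinstance(prior, ContinuousPrior):
        step = prior.grid[1] - prior.grid[0]
        return duration_grid(step=float(step))
    return duration_grid()


def _analytic_rule(model, P, xs):
    """Closed-form optimal actions for quadratic standard/fractional loss.

    Standard:   u* = E[x | x_m] / c
    Fractional: u* = E[1/x | x_m] / (c E[1/x^2 | x_m])
    with c = 1 + w_m^2 for scalar motor noise and c = 1 otherwise.
    """
    c = 1.0 + model.motor.w ** 2 if model.motor.kind == "scalar" else 1.0
    if model.loss.map_kind == "standard":
        return (P @ xs) / c
    q1 = P @ (1.0 / xs)
    q2 = P @ (1.0 / xs ** 2)
    return q1 / (c * q2)


def _extended_grid(grid, motor, bounds):
    """Response-quadrature grid padded by 6 motor sds beyond the bounds, so
    that no Gaussian mass is lost where the loss integral runs over the
    whole real line (standard/fractional maps)."""
    step = grid[1] - grid[0]
    pad = 6.0 * float(np.max(motor.sd(np.asarray(bounds))))
    n_lo = int(np.ceil(pad / step))
    lo = grid[0] - step * np.arange(n_lo, 0, -1)
    hi = grid[-1] + step * np.arange(1, n_lo + 1)
    return np.concatenate([lo, grid, hi])


def _numeric_rule(model, P, xs, grid, bounds):
    """Grid-scan + parabolic refinement of the expected-loss minimum."""
    lo, hi = bounds
    u_grid = grid[(grid >= lo) & (grid <= hi)]
    if model.loss.map_kind == "skewed":
        # The 1/r moments diverge as r -> 0; the grid's positive domain is
        # the regularizer (sub-150-ms responses are effectively never
        # produced), so use the truncated-renormalized kernel.
        r_quad = grid
        mker = _motor_matrix(u_grid, r_quad, model.motor)
    else:
        r_quad = _extended_grid(grid, model.motor, bounds)
        sd = model.motor.sd(u_grid)
        mker = _norm_pdf(r_quad[None, :], u_grid[:, None], sd[:, None])
    mker = mker * _trapz_weights(r_quad)[None, :]
    if model.loss.map_kind == "skewed" and model.loss.exponent == 2.0:
        # E[(1 - x/r)^2] = 1 - 2 E[x] A(u) + E[x^2] B(u), with A, B the
        # truncated-Gaussian moments of 1/r and 1/r^2.
        a = mker @ (1.0 / r_quad)
        b = mker @ (1.0 / r_quad ** 2)
        m1 = P @ xs
        m2 = P @ xs ** 2
        g = -2.0 * np.outer(m1, a) + np.outer(m2, b)
    else:
        lmat = loss_value(r_quad[None, :], xs[:, None], model.loss)
        c = mker @ lmat.T          # (n_u, n_xs)
        g = P @ c.T                # (n_xm, n_u)
    idx = np.argmin(g, axis=1)
    if np.any(idx == 0) or np.any(idx == len(u_grid) - 1):
        warnings.warn("optimal action at an optimization bound; "
                      "bounds are likely too tight", RuntimeWarning)
    return _parabolic_refine(u_grid, g, idx)


def decision_rule(model: ObserverModel, xm_grid=None, method: str = "auto",
                  grid=None, bounds=ACTION_BOUNDS) -> DecisionRule:
    """Tabulate the optimal action u*(x_m) over a measurement grid.

    method='auto' uses the closed form for quadratic standard/fractional
    losses and bounded numeric minimization otherwise; 'analytic' and
    'numeric' force one path (both agree within 0.5 ms where both apply).
    """
    if grid is None:
        grid = _model_grid(model)
    grid = np.asarray(grid, float)
    if xm_grid is None:
        xm_grid = grid
    xm_grid = np.asarray(xm_grid, float)
    xs, pw = prior_atoms(model.prior, grid)
    P = _posterior_matrix(xm_grid, xs, pw, model.sensory)

    analytic_ok = (model.loss.exponent == 2.0
                   and model.loss.map_kind in ("standard", "fractional"))
    if method == "analytic" and not analytic_ok:
        raise ValueError("no closed form for this loss; use method='numeric'")
    if method == "auto":
        method = "analytic" if analytic_ok else "numeric"
    if method == "analytic":
        u = np.clip(_analytic_rule(model, P, xs), bounds[0], bounds[1])
    elif method == "numeric":
        u = _numeric_rule(model, P, xs, grid, bounds)
    else:
        raise ValueError(f"unknown method {method!r}")
    return DecisionRule(xm_grid=xm_grid, u_star=u)


# ---------------------------------------------------------------------------
# Response distribution and predicted statistics
# ---------------------------------------------------------------------------

def _sensory_weights(x, grid, sensory: NoiseModel, warn_truncation=True):
    w = sensory_density(grid, x, sensory) * _trapz_weights(grid)
    z = w.sum()
    if warn_truncation and abs(1.0 - z) > 1e-4:
        warnings.warn(f"sensory density mass truncated by the grid at x={x}",
                      RuntimeWarning)
    return w / z


def _lapse_density(r_grid, lapse_range):
    a, b = lapse_range
    return np.where((r_grid >= a) & (r_grid <= b), 1.0 / (b - a), 0.0)


def response_distribution(x, model: ObserverModel, r_grid=None,
                          rule: DecisionRule = None) -> ContinuousPrior:
    """Marginal response density p(r | x) on a grid of responses.

    Integrates the motor likelihood of the optimal action over the hidden
    measurement, then mixes in the uniform lapse component:
    (1 - lambda) p(r|x) + lambda Uniform(lapse_range).
    """
    if r_grid is None:
        r_grid = _model_grid(model)
    r_grid = np.asarray(r_grid, float)
    if rule is None:
        rule = decision_rule(model, grid=r_grid)
    ws = _sensory_weights(float(x), rule.xm_grid, model.sensory)
    sd = model.motor.sd(rule.u_star)
    z = _trunc_normalizer(rule.u_star, sd, r_grid[0], r_grid[-1])
    if float(ws @ (1.0 - z)) > 1e-4:
        warnings.warn("response grid too narrow: >1e-4 density mass truncated",
                      RuntimeWarning)
    mker = _norm_pdf(r_grid[None, :], rule.u_star[:, None], sd[:, None])
    mker /= np.maximum(z, 1e-300)[:, None]
    dens = ws @ mker
    dens /= np.trapezoid(dens, r_grid)
    lam = model.lapse_rate
    if lam > 0:
        lap = _lapse_density(r_grid, model.lapse_range)
        lap /= np.trapezoid(lap, r_grid)
        dens = (1.0 - lam) * dens + lam * lap
    return ContinuousPrior.from_unnormalized(r_grid, dens, label=f"p(r|x={x:g})")


def bias_sd_curves(model: ObserverModel, dist: IntervalDistribution,
                   grid=None, rule: DecisionRule = None):
    """Predicted per-interval response bias and sd.

    bias(x) = E[r | x] - x and sd(x) = Std[r | x], by quadrature over the
    response grid for each support point of ``dist``.

    Returns
    -------
    pandas.DataFrame with columns x, bias, sd.
    """
    import pandas as pd

    if grid is None:
        grid = _model_grid(model)
    grid = np.asarray(grid, float)
    if rule is None:
        rule = decision_rule(model, grid=grid)
    rows = []
    for x in dist.support:
        p = response_distribution(float(x), model, r_grid=grid, rule=rule)
        m = p.mean()
        rows.append((float(x), m - float(x), p.sd()))
    return pd.DataFrame(rows, columns=["x", "bias", "sd"])


def simulate_responses(model: ObserverModel, x, rng: np.random.Generator,
                       rule: DecisionRule = None, grid=None):
    """Draw responses from the generative chain for targets ``x``.

    Per trial: x_m ~ sensory likelihood; u = u*(x_m) by interpolation of
    the tabulated rule; r ~ motor likelihood, or uniform over the lapse
    range with probability lapse_rate.

    Returns
    -------
    (responses, lapse_flags) : arrays matching ``x``.
    """
    x = np.asarray(x, dtype=float)
    if rule is None:
        rule = decision_rule(model, grid=grid)
    x_m = rng.normal(x, model.sensory.sd(x))
    u = rule(x_m)
    r = rng.normal(u, model.motor.sd(u))
    lapse = rng.random(x.shape) < model.lapse_rate
    if np.any(lapse):
        a, b = model.lapse_range
        r = np.where(lapse, rng.uniform(a, b, size=x.shape), r)
    return r, lapse
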