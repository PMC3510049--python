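"""Bayesian model comparison over the observer family.

Each candidate observer is a discrete choice of sensory noise kind,
motor noise kind, prior approximation scheme and loss map, leaving only
the two coefficients of variation (w_s, w_m) as continuous parameters.
For every candidate the marginal likelihood

    Pr(data | model) = integral L(data | w_s, w_m) p(w_s) p(w_m) dw dw

is computed both by two-dimensional quadrature on a log-spaced parameter
grid and by a Laplace approximation around the MAP, under independent
Beta(1.3, 2.6) priors on the parameters.  Posterior model probabilities,
per-component posteriors (obtained by fixing one component and summing
over the others) and Bayesian-model-averaged bias/SD predictions follow.

The public surface is the ``ObserverComparison`` model class and its
``fit`` -> ``ObserverComparisonResults`` pair.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from .distributions import (_trapz_weights, block_range, duration_grid,
                            make_candidate_prior)
from .observer import (LossSpec, NoiseModel, ObserverModel, _lapse_density,
                       _norm_pdf, _sensory_weights, _trunc_normalizer,
                       bias_sd_curves, decision_rule, prior_atoms)
from .synthetic import ALLOWED_WINDOWS, BlockDesign

__all__ = [
    "ParameterPrior",
    "ModelTemplate",
    "ModelSpace",
    "ModelEvidence",
    "ObserverComparison",
    "ObserverComparisonResults",
    "log_likelihood",
    "marginal_likelihood",
    "component_posteriors",
]

COMPONENTS = ("sensory", "motor", "prior_scheme", "loss")
# Tie-break order: simpler levels first.
_LEVEL_ORDER = {
    "sensory": ("constant", "scalar"),
    "motor": ("constant", "scalar"),
    "loss": ("standard", "fractional", "skewed"),
    "prior_scheme": ("a", "b", "c", "d", "e", "f", "g"),
}


@dataclass
class ParameterPrior:
    """Independent Beta(1.3, 2.6) priors on w_s and w_m.

    The quadrature runs on ``n_grid`` log-spaced nodes over
    [w_min, w_max] (the plausible Weber-fraction region); the Beta
    density is renormalized over that window so that a constant
    likelihood integrates to itself.
    """

    a: float = 1.3
    b: float = 2.6
    w_min: float = 0.01
    w_max: float = 0.6
    n_grid: int = 60

    def __post_init__(self):
        d = stats.beta(self.a, self.b)
        self._log_z = np.log(d.cdf(self.w_max) - d.cdf(self.w_min))
        self._dist = d

    def logpdf(self, w):
        w = np.asarray(w, float)
        out = np.where((w >= self.w_min) & (w <= self.w_max),
                       self._dist.logpdf(np.clip(w, self.w_min, self.w_max))
                       - self._log_z, -np.inf)
        return out

    def nodes(self) -> np.ndarray:
        return np.geomspace(self.w_min, self.w_max, self.n_grid)

    def log_quad_weights(self) -> np.ndarray:
        """log of trapezoid weights x prior density at the nodes."""
        nodes = self.nodes()
        return np.log(_trapz_weights(nodes)) + self.logpdf(nodes)


@dataclass(frozen=True)
class ModelTemplate:
    """One member of the discrete model family, with (w_s, w_m) free."""

    sensory: str
    motor: str
    prior_scheme: str
    loss: str
    lapse_rate: float = 0.0

    @property
    def label(self) -> str:
        s = f"{self.sensory[:5]}-{self.motor[:5]}-{self.prior_scheme}-{self.loss}"
        if self.lapse_rate:
            s += f"-lapse{self.lapse_rate:g}"
        return s

    def loss_spec(self) -> LossSpec:
        return LossSpec(self.loss)

    def observer(self, prior, w_s: float, w_m: float,
                 lapse_range=(300.0, 1462.0)) -> ObserverModel:
        return ObserverModel(NoiseModel(self.sensory, w_s),
                             NoiseModel(self.motor, w_m),
                             prior, self.loss_spec(),
                             lapse_rate=self.lapse_rate,
                             lapse_range=lapse_range)


class ModelSpace:
    """Cartesian product of component levels, with optional restrictions.

    Prior schemes are instantiated per block, so a template's scheme is
    shared across blocks ("consistent approximation scheme"), while the
    induced prior differs per block.
    """

    def __init__(self, templates):
        self.templates = list(templates)
        if not self.templates:
            raise ValueError("model space is empty")

    @classmethod
    def full(cls, sensory=("constant", "scalar"), motor=("constant", "scalar"),
             prior_schemes=("a", "b", "c", "d", "e"),
             losses=("standard", "fractional", "skewed"),
             lapse_rates=(0.0,)) -> "ModelSpace":
        tpl = [ModelTemplate(s, m, p, l, lr)
               for s, m, p, l, lr in itertools.product(
                   sensory, motor, prior_schemes, losses, lapse_rates)]
        return cls(tpl)

    def restrict(self, sensory=None, motor=None, prior_scheme=None,
                 loss=None) -> "ModelSpace":
        def keep(t):
            return ((sensory is None or t.sensory in sensory)
                    and (motor is None or t.motor in motor)
                    and (prior_scheme is None or t.prior_scheme in prior_scheme)
                    and (loss is None or t.loss in loss))
        kept = [t for t in self.templates if keep(t)]
        if not kept:
            raise ValueError("restriction eliminates every model")
        return ModelSpace(kept)

    def __len__(self):
        return len(self.templates)

    def __iter__(self):
        return iter(self.templates)


# ---------------------------------------------------------------------------
# Likelihood engine
# ---------------------------------------------------------------------------

class _BlockEngine:
    """Per-block trial likelihood for one template, fast in (w_s, w_m).

    Precomputes the prior atoms and trial grouping; each ``loglik`` call
    rebuilds only the noise-dependent kernels.
    """

    def __init__(self, x, r, prior, loss: LossSpec, sensory_kind, motor_kind,
                 lapse_range, grid):
        self.grid = np.asarray(grid, float)
        self.xs, self.pw = prior_atoms(prior, self.grid)
        self.prior = prior
        self.loss = loss
        self.sensory_kind = sensory_kind
        self.motor_kind = motor_kind
        self.lapse_range = lapse_range
        x = np.asarray(x, float)
        r = np.asarray(r, float)
        self.groups = []
        for xv in np.unique(x):
            self.groups.append((float(xv), r[x == xv]))
        self.n_trials = len(x)
        self._wq = _trapz_weights(self.grid)

    def _dummy_model(self, w_s, w_m):
        return ObserverModel(NoiseModel(self.sensory_kind, w_s),
                             NoiseModel(self.motor_kind, w_m),
                             self.prior, self.loss, lapse_rate=0.0,
                             lapse_range=self.lapse_range)

    def per_trial_density(self, w_s, w_m):
        """Lapse-free densities p(r_i | x_i) and the matching r values."""
        model = self._dummy_model(w_s, w_m)
        with warnings.catch_warnings():
            # extreme parameter nodes push edge-of-grid actions onto the
            # optimization bounds; harmless during evidence integration
            warnings.simplefilter("ignore", RuntimeWarning)
            rule = decision_rule(model, grid=self.grid)
        sd = model.motor.sd(rule.u_star)
        z = np.maximum(_trunc_normalizer(rule.u_star, sd,
                                         self.grid[0], self.grid[-1]), 1e-300)
        dens_parts, r_parts = [], []
        for xv, rv in self.groups:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                ws = _sensory_weights(xv, self.grid, model.sensory)
            m = _norm_pdf(rv[None, :], rule.u_star[:, None], sd[:, None])
            dens_parts.append(ws @ (m / z[:, None]))
            r_parts.append(rv)
        return np.concatenate(dens_parts), np.concatenate(r_parts)

    def loglik(self, w_s, w_m, lapse_rates=(0.0,), on_zero: str = "-inf"):
        """Sum of log p(r_i | x_i); one value per lapse rate.

        A response with zero density either raises (``on_zero='raise'``,
        the single-observer contract) or yields -inf (the evidence
        integrators, where extreme parameter nodes legitimately assign
        vanishing density).
        """
        dens, rv = self.per_trial_density(w_s, w_m)
        lap = _lapse_density(rv, self.lapse_range)
        out = np.empty(len(lapse_rates))
        for k, lam in enumerate(lapse_rates):
            d = (1.0 - lam) * dens + lam * lap
            if np.any(d <= 0):
                if on_zero == "raise":
                    i = int(np.argmin(d))
                    raise ValueError(
                        f"zero response density at trial with r={rv[i]:.1f} ms "
                        "(grid/window mismatch or response outside model support)")
                out[k] = -np.inf
                continue
            out[k] = np.log(d).sum()
        return out


def _make_engines(trials: pd.DataFrame, template: ModelTemplate, designs,
                  grid) -> list:
    engines = []
    for block, sub in trials.groupby("block"):
        block = str(block)
        design = designs.get(block) if designs else None
        dist = design.distribution if design else None
        prior = make_candidate_prior(template.prior_scheme, block, grid)
        window = (design.allowed_window if design
                  else ALLOWED_WINDOWS[block_range(block)])
        engines.append(_BlockEngine(sub["target_ms"].to_numpy(),
                                    sub["response_ms"].to_numpy(),
                                    prior, template.loss_spec(),
                                    template.sensory, template.motor,
                                    window, grid))
    return engines


def _retained(trials: pd.DataFrame) -> pd.DataFrame:
    if "retained" in trials.columns:
        return trials[trials["retained"]]
    return trials


def log_likelihood(trials: pd.DataFrame, observer: ObserverModel,
                   w_s: float = None, w_m: float = None,
                   grid=None) -> float:
    """Trial-set log likelihood under one fully specified observer.

    ``w_s``/``w_m`` override the observer's own coefficients when given.
    The trial table must already be filtered to retained trials (rows with
    a ``retained`` column set to False are ignored).  An empty set scores
    0 (an empty product).
    """
    trials = _retained(trials)
    if len(trials) == 0:
        return 0.0
    if grid is None:
        grid = duration_grid()
    total = 0.0
    for block, sub in trials.groupby("block"):
        eng = _BlockEngine(sub["target_ms"].to_numpy(),
                           sub["response_ms"].to_numpy(),
                           observer.prior, observer.loss,
                           observer.sensory.kind, observer.motor.kind,
                           observer.lapse_range, grid)
        total += float(eng.loglik(w_s if w_s is not None else observer.sensory.w,
                                  w_m if w_m is not None else observer.motor.w,
                                  (observer.lapse_rate,), on_zero="raise")[0])
    return total


# ---------------------------------------------------------------------------
# Evidence
# ---------------------------------------------------------------------------

@dataclass
class ModelEvidence:
    template: ModelTemplate
    log_evidence_grid: float = np.nan
    log_evidence_laplace: float = np.nan
    map_w_s: float = np.nan
    map_w_m: float = np.nan
    map_on_boundary: bool = False
    loglik_grid: np.ndarray = None  # (n_nodes, n_nodes), lapse-averaged

    def log_evidence(self, prefer: str = "grid") -> float:
        g, l = self.log_evidence_grid, self.log_evidence_laplace
        if prefer == "grid":
            return g if np.isfinite(g) else l
        return l if np.isfinite(l) else g


def _grid_evidence(engines, param_prior: ParameterPrior, lapse_grid):
    nodes = param_prior.nodes()
    lw = param_prior.log_quad_weights()
    n = len(nodes)
    n_lam = len(lapse_grid)
    ll = np.empty((n, n, n_lam))
    for i, ws_ in enumerate(nodes):
        for j, wm_ in enumerate(nodes):
            ll[i, j] = sum(e.loglik(ws_, wm_, lapse_grid) for e in engines)
    # lapse marginalized uniformly over its small grid
    ll_marg = logsumexp(ll, axis=2) - np.log(n_lam)
    log_z = logsumexp(ll_marg + lw[:, None] + lw[None, :])
    return float(log_z), ll_marg


def _laplace_evidence(engines, param_prior: ParameterPrior, lapse_grid,
                      x0=None):
    """Laplace approximation around the MAP of the (w_s, w_m) posterior,
    computed in log-parameter coordinates for conditioning."""
    n_lam = len(lapse_grid)

    def neg_logpost(z):
        w = np.exp(z)
        if np.any(w < param_prior.w_min) or np.any(w > param_prior.w_max):
            return 1e12
        ll = logsumexp(sum(e.loglik(w[0], w[1], lapse_grid) for e in engines)) \
            - np.log(n_lam)
        lp = param_prior.logpdf(w).sum() + z.sum()  # + Jacobian
        out = -(ll + lp)
        return out if np.isfinite(out) else 1e12

    if x0 is None:
        x0 = np.array([0.12, 0.12])
    res = optimize.minimize(neg_logpost, np.log(np.asarray(x0)),
                            method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-6})
    z_map = res.x
    f_map = -res.fun
    w_map = np.exp(z_map)
    eps = 1e-3
    h = np.zeros((2, 2))
    for i in range(2):
        for j in range(i, 2):
            zi, zj = np.zeros(2), np.zeros(2)
            zi[i] = eps
            zj[j] = eps
            fpp = neg_logpost(z_map + zi + zj)
            fpm = neg_logpost(z_map + zi - zj)
            fmp = neg_logpost(z_map - zi + zj)
            fmm = neg_logpost(z_map - zi - zj)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    sign, logdet = np.linalg.slogdet(h)
    boundary = bool(np.any(np.abs(np.log(w_map)
                                  - np.log([param_prior.w_min, param_prior.w_max])[:, None])
                           .min(axis=0) < 0.02))
    if sign <= 0:
        warnings.warn("non-positive-definite Hessian at the MAP; Laplace "
                      "evidence unreliable", RuntimeWarning)
        logdet = np.inf
    if boundary:
        warnings.warn("MAP on the parameter-space boundary; Laplace evidence "
                      "flagged unreliable", RuntimeWarning)
    log_z = f_map + np.log(2 * np.pi) - 0.5 * logdet
    return float(log_z), float(w_map[0]), float(w_map[1]), boundary


def marginal_likelihood(trials: pd.DataFrame, template: ModelTemplate,
                        designs=None, param_prior: ParameterPrior = None,
                        grid=None, method: str = "both",
                        lapse_grid=(0.0,)) -> ModelEvidence:
    """Log marginal likelihood of one model template for a trial set.

    method='grid', 'laplace' or 'both'.  The grid variant integrates the
    likelihood x Beta prior over the log-spaced (w_s, w_m) quadrature; the
    Laplace variant expands around the MAP (flagged when the MAP sits on
    the parameter boundary).
    """
    if param_prior is None:
        param_prior = ParameterPrior()
    if grid is None:
        grid = duration_grid()
    trials = _retained(trials)
    engines = _make_engines(trials, template, designs, grid)
    ev = ModelEvidence(template=template)
    if method in ("grid", "both"):
        ev.log_evidence_grid, ev.loglik_grid = _grid_evidence(
            engines, param_prior, lapse_grid)
    if method in ("laplace", "both"):
        x0 = None
        if ev.loglik_grid is not None:
            nodes = param_prior.nodes()
            i, j = np.unravel_index(np.argmax(ev.loglik_grid
                                              + param_prior.logpdf(nodes)[:, None]
                                              + param_prior.logpdf(nodes)[None, :]),
                                    ev.loglik_grid.shape)
            x0 = np.array([nodes[i], nodes[j]])
        (ev.log_evidence_laplace, ev.map_w_s, ev.map_w_m,
         ev.map_on_boundary) = _laplace_evidence(engines, param_prior,
                                                 lapse_grid, x0=x0)
    return ev


def component_posteriors(evidences, prefer: str = "grid") -> dict:
    """Posterior probability of each component level, by fixing one
    component and summing model posteriors over the others."""
    log_ev = np.array([e.log_evidence(prefer) for e in evidences])
    post = np.exp(log_ev - logsumexp(log_ev))
    out = {}
    for comp in COMPONENTS:
        attr = "prior_scheme" if comp == "prior_scheme" else comp
        levels = []
        for e in evidences:
            lv = getattr(e.template, attr)
            if lv not in levels:
                levels.append(lv)
        order = [lv for lv in _LEVEL_ORDER[comp] if lv in levels]
        order += [lv for lv in levels if lv not in order]
        probs = pd.Series(
            {lv: float(post[[getattr(e.template, attr) == lv
                             for e in evidences]].sum()) for lv in order})
        out[comp] = probs
    return out


def modal_components(evidences, prefer: str = "grid") -> dict:
    """Most probable level per component; ties break toward the simpler
    level (the first in canonical order)."""
    cp = component_posteriors(evidences, prefer)
    return {comp: probs.index[int(np.argmax(probs.to_numpy()))]
            for comp, probs in cp.items()}


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class ObserverComparison:
    """Bayesian comparison of observer models on a trial table.

    Parameters
    ----------
    trials : DataFrame
        Trial table (synthetic or real); only retained trials enter the
        likelihood.
    model_space : ModelSpace, optional
        Defaults to the full constant/scalar x scheme (a-e) x three-loss
        product.
    designs : dict, optional
        block name -> BlockDesign, for allowed windows and lapse ranges.
    param_prior : ParameterPrior
    grid_step : float
        Duration-grid resolution in ms for all quadratures.
    lapse_grid : tuple of float
        Lapse rates marginalized uniformly (the lapse model variant);
        (0.0,) recovers the basic lapse-free observer family.
    """

    def __init__(self, trials: pd.DataFrame, model_space: ModelSpace = None,
                 designs: dict = None, param_prior: ParameterPrior = None,
                 grid_step: float = 1.0, lapse_grid=(0.0,)):
        self.trials = _retained(trials).reset_index(drop=True)
        if len(self.trials) == 0:
            raise ValueError("no retained trials")
        self.model_space = model_space or ModelSpace.full()
        self.designs = designs or {
            str(b): BlockDesign(str(b)) for b in self.trials["block"].unique()}
        self.param_prior = param_prior or ParameterPrior()
        self.grid = duration_grid(step=grid_step)
        self.lapse_grid = tuple(lapse_grid)

    def fit(self, method: str = "both", verbose: bool = False
            ) -> "ObserverComparisonResults":
        evidences = []
        for t in self.model_space:
            ev = marginal_likelihood(self.trials, t, designs=self.designs,
                                     param_prior=self.param_prior,
                                     grid=self.grid, method=method,
                                     lapse_grid=self.lapse_grid)
            if verbose:
                print(f"  {t.label}: grid={ev.log_evidence_grid:.2f} "
                      f"laplace={ev.log_evidence_laplace:.2f}")
            evidences.append(ev)
        prefer = "laplace" if method == "laplace" else "grid"
        return ObserverComparisonResults(self, evidences, prefer)


class ObserverComparisonResults:
    """Evidences, posteriors and model-averaged predictions."""

    def __init__(self, model: ObserverComparison, evidences, prefer="grid"):
        self.model = model
        self.evidences = evidences
        self.prefer = prefer
        log_ev = np.array([e.log_evidence(prefer) for e in evidences])
        self.posterior = np.exp(log_ev - logsumexp(log_ev))

    @property
    def best_template(self) -> ModelTemplate:
        return self.evidences[int(np.argmax(self.posterior))].template

    def map_params(self, template: ModelTemplate = None):
        t = template or self.best_template
        for e in self.evidences:
            if e.template == t:
                if np.isfinite(e.map_w_s):
                    return e.map_w_s, e.map_w_m
                if e.loglik_grid is not None:
                    nodes = self.model.param_prior.nodes()
                    lp = self.model.param_prior.logpdf(nodes)
                    i, j = np.unravel_index(
                        np.argmax(e.loglik_grid + lp[:, None] + lp[None, :]),
                        e.loglik_grid.shape)
                    return float(nodes[i]), float(nodes[j])
        raise KeyError("template not in the fitted space")

    def component_posteriors(self) -> dict:
        return component_posteriors(self.evidences, self.prefer)

    def modal_components(self) -> dict:
        return modal_components(self.evidences, self.prefer)

    def evidence_table(self) -> pd.DataFrame:
        rows = []
        for e, p in zip(self.evidences, self.posterior):
            t = e.template
            rows.append({"model": t.label, "sensory": t.sensory,
                         "motor": t.motor, "prior_scheme": t.prior_scheme,
                         "loss": t.loss,
                         "log_evidence_grid": e.log_evidence_grid,
                         "log_evidence_laplace": e.log_evidence_laplace,
                         "posterior": p,
                         "map_w_s": e.map_w_s, "map_w_m": e.map_w_m,
                         "map_on_boundary": e.map_on_boundary})
        return pd.DataFrame(rows).sort_values("posterior", ascending=False,
                                              ignore_index=True)

    def _parameter_posterior_nodes(self, evidence: ModelEvidence,
                                   top_mass: float = 0.995):
        """(w_s, w_m, weight) nodes covering ``top_mass`` of the parameter
        posterior for one model; falls back to the MAP point when no grid
        was computed."""
        if evidence.loglik_grid is None:
            ws, wm = self.map_params(evidence.template)
            return [(ws, wm, 1.0)]
        lw = self.model.param_prior.log_quad_weights()
        lp = evidence.loglik_grid + lw[:, None] + lw[None, :]
        p = np.exp(lp - logsumexp(lp)).ravel()
        order = np.argsort(p)[::-1]
        csum = np.cumsum(p[order])
        keep = order[:int(np.searchsorted(csum, top_mass)) + 1]
        nodes = self.model.param_prior.nodes()
        n = len(nodes)
        out = []
        w_norm = p[keep].sum()
        for flat in keep:
            i, j = divmod(flat, n)
            out.append((float(nodes[i]), float(nodes[j]),
                        float(p[flat] / w_norm)))
        return out

    def model_average_curves(self, block: str, top_mass: float = 0.995,
                             min_model_weight: float = 1e-4) -> pd.DataFrame:
        """Bayesian-model-averaged bias and sd per interval for one block.

        The average runs over models (posterior weights) and, within each
        model, over the (w_s, w_m) posterior quadrature - no parameter is
        point-fitted.
        """
        design = self.model.designs[block]
        dist = design.distribution
        acc = None
        for e, mp in zip(self.evidences, self.posterior):
            if mp < min_model_weight:
                continue
            prior = make_candidate_prior(e.template.prior_scheme, block,
                                         self.model.grid)
            part = None
            for ws, wm, w in self._parameter_posterior_nodes(e, top_mass):
                obs = e.template.observer(prior, ws, wm,
                                          lapse_range=design.allowed_window)
                cur = bias_sd_curves(obs, dist, grid=self.model.grid)
                v = w * cur[["bias", "sd"]].to_numpy()
                part = v if part is None else part + v
            acc = mp * part if acc is None else acc + mp * part
        out = pd.DataFrame(acc, columns=["bias", "sd"])
        out.insert(0, "x", dist.support)
        return out

    def summary(self) -> str:
        tab = self.evidence_table()
        cp = self.component_posteriors()
        lines = ["Bayesian observer model comparison",
                 f"  trials: {len(self.model.trials)}   models: {len(self.evidences)}"
                 f"   evidence: {self.prefer}",
                 "",
                 tab.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
                 "", "Component posteriors:"]
        for comp, probs in cp.items():
            body = "  ".join(f"{lv}={pv:.3f}" for lv, pv in probs.items())
            lines.append(f"  {comp:13s} {body}")
        return "\n".join(lines)
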