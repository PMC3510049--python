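"""Experimental interval distributions and candidate subjective priors.

The interval-reproduction task draws target durations from discrete,
block-dependent distributions over a handful of intervals spaced 75 ms
apart.  An ideal observer, however, need not represent the experimental
distribution exactly: its *subjective prior* may be the true discrete
distribution, a moment-matched Gaussian, a smoothed mixture, a flat
density over the range, or a sparse Gaussian mixture built around the
over-represented ("peak") intervals.  This module constructs both the
objective block distributions and that family of candidate priors, and
computes their first four moments.

Durations are in milliseconds throughout.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import yaml

__all__ = [
    "IntervalDistribution",
    "ContinuousPrior",
    "MomentSummary",
    "duration_grid",
    "make_block_distribution",
    "make_candidate_prior",
    "moments",
    "block_names",
    "block_registry",
    "register_block",
    "save_block_registry",
    "load_block_registry",
    "PRIOR_SCHEMES",
]

#: Default evaluation grid bounds and step (ms).  The grid spans every
#: block's allowed-response window, so truncating continuous priors to it
#: loses only negligible tail mass.
GRID_MIN = 150.0
GRID_MAX = 1800.0
GRID_STEP = 1.0

#: Spacing between adjacent target intervals in all standard blocks (ms).
INTERVAL_STEP = 75.0

#: Reference duration: the centre of the Medium/Wide ranges (ms).
REFERENCE_INTERVAL = 787.5

PRIOR_SCHEMES = ("a", "b", "c", "d", "e", "f", "g")


def duration_grid(t_min: float = GRID_MIN, t_max: float = GRID_MAX,
                  step: float = GRID_STEP) -> np.ndarray:
    """Regular duration grid in ms, inclusive of both endpoints."""
    n = int(round((t_max - t_min) / step))
    return t_min + step * np.arange(n + 1)


def _trapz_weights(grid: np.ndarray) -> np.ndarray:
    w = np.empty_like(grid)
    w[1:-1] = 0.5 * (grid[2:] - grid[:-2])
    w[0] = 0.5 * (grid[1] - grid[0])
    w[-1] = 0.5 * (grid[-1] - grid[-2])
    return w


@dataclass
class IntervalDistribution:
    """Discrete distribution over target interval durations.

    Parameters
    ----------
    support : array of float
        Strictly increasing durations (ms).
    probs : array of float
        Probabilities, nonnegative and summing to one.
    label : str
        Identifier, e.g. ``"medium_high_peaked"``.
    """

    support: np.ndarray
    probs: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.support = np.asarray(self.support, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.support.ndim != 1 or self.support.shape != self.probs.shape:
            raise ValueError("support and probs must be 1-D arrays of equal length")
        if np.any(np.diff(self.support) <= 0):
            raise ValueError("support must be strictly increasing")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1 within 1e-12")

    @property
    def n(self) -> int:
        return len(self.support)

    def mean(self) -> float:
        return float(self.probs @ self.support)

    def var(self) -> float:
        m = self.mean()
        return float(self.probs @ (self.support - m) ** 2)

    def sd(self) -> float:
        return float(np.sqrt(self.var()))

    def to_dict(self) -> dict:
        return {"label": self.label,
                "support": [float(s) for s in self.support],
                "probs": [float(p) for p in self.probs]}

    @classmethod
    def from_dict(cls, d: dict) -> "IntervalDistribution":
        return cls(np.asarray(d["support"], float), np.asarray(d["probs"], float),
                   d.get("label", ""))


@dataclass
class ContinuousPrior:
    """Density on a regular duration grid, normalized by the trapezoid rule."""

    grid: np.ndarray
    density: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.shape != self.density.shape or self.grid.ndim != 1:
            raise ValueError("grid and density must be 1-D arrays of equal length")
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")
        z = np.trapezoid(self.density, self.grid)
        if abs(z - 1.0) > 1e-8:
            raise ValueError(f"density must integrate to 1 (got {z:.3e})")

    @classmethod
    def from_unnormalized(cls, grid, density, label: str = "") -> "ContinuousPrior":
        grid = np.asarray(grid, float)
        density = np.clip(np.asarray(density, float), 0.0, None)
        z = np.trapezoid(density, grid)
        if not np.isfinite(z) or z <= 0:
            raise ValueError("density has zero or non-finite mass on the grid")
        return cls(grid, density / z, label)

    def mean(self) -> float:
        return float(np.trapezoid(self.grid * self.density, self.grid))

    def sd(self) -> float:
        m = self.mean()
        return float(np.sqrt(np.trapezoid((self.grid - m) ** 2 * self.density, self.grid)))


@dataclass
class MomentSummary:
    """First four moments: mean and sd in ms, skewness and excess kurtosis
    dimensionless (excess kurtosis = kurtosis - 3)."""

    mean: float
    sd: float
    skewness: float
    excess_kurtosis: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mean, self.sd, self.skewness, self.excess_kurtosis])


def moments(dist) -> MomentSummary:
    """Moments of a discrete :class:`IntervalDistribution` (exact
    probability-weighted sums) or a :class:`ContinuousPrior` (trapezoid
    quadrature).

    Raises
    ------
    ValueError
        If the distribution is degenerate (zero variance), where skewness
        and kurtosis are undefined.
    """
    if isinstance(dist, IntervalDistribution):
        x, w = dist.support, dist.probs
        def ev(f):
            return float(w @ f)
    elif isinstance(dist, ContinuousPrior):
        x = dist.grid
        dens = dist.density
        def ev(f):
            return float(np.trapezoid(f * dens, x))
    else:
        raise TypeError(f"unsupported distribution type: {type(dist)!r}")
    m = ev(x)
    mu2 = ev((x - m) ** 2)
    if mu2 <= 0:
        raise ValueError("degenerate (single-point) distribution: "
                         "skewness and kurtosis are undefined")
    sd = np.sqrt(mu2)
    mu3 = ev((x - m) ** 3)
    mu4 = ev((x - m) ** 4)
    return MomentSummary(mean=m, sd=float(sd),
                         skewness=float(mu3 / sd ** 3),
                         excess_kurtosis=float(mu4 / mu2 ** 2 - 3.0))


# ---------------------------------------------------------------------------
# Block registry
# ---------------------------------------------------------------------------

def _steps(first: int, n: int) -> list:
    return [first + int(INTERVAL_STEP) * i for i in range(n)]


def _uniform(n: int) -> list:
    return [Fraction(1, n)] * n


# Named experimental blocks.  Probabilities are exact rationals; peak
# intervals carry the stated extra mass (e.g. 7/12 at 675 ms for Peaked).
_BLOCKS: dict = {
    "short_uniform": (_steps(450, 6), _uniform(6)),
    "medium_uniform": (_steps(600, 6), _uniform(6)),
    "long_uniform": (_steps(750, 6), _uniform(6)),
    "wide_uniform": (_steps(450, 10), _uniform(10)),
    "medium_peaked": (_steps(600, 6),
                      [Fraction(1, 12), Fraction(7, 12)] + [Fraction(1, 12)] * 4),
    "medium_high_peaked": (_steps(600, 6),
                           [Fraction(1, 24), Fraction(19, 24)] + [Fraction(1, 24)] * 4),
    "medium_bimodal": (_steps(600, 6),
                       [Fraction(1, 3)] + [Fraction(1, 12)] * 4 + [Fraction(1, 3)]),
    "wide_bimodal": (_steps(450, 10),
                     [Fraction(1, 7)] * 3 + [Fraction(1, 28)] * 4 + [Fraction(1, 7)] * 3),
}

#: Interval range (ms) of each named range, and the block -> range map.
RANGES = {"short": (450.0, 825.0), "medium": (600.0, 975.0),
          "long": (750.0, 1125.0), "wide": (450.0, 1125.0)}

_CUSTOM_BLOCKS: dict = {}


def block_names() -> list:
    return list(_BLOCKS) + list(_CUSTOM_BLOCKS)


def block_range(block_name: str) -> str:
    """Range family ('short', 'medium', 'long', 'wide') of a named block."""
    head = block_name.split("_", 1)[0]
    if head not in RANGES:
        raise ValueError(f"cannot infer range for block {block_name!r}")
    return head


def make_block_distribution(block_name: str) -> IntervalDistribution:
    """Construct the exact discrete distribution of a named block.

    Valid names: short/medium/long/wide_uniform, medium_peaked,
    medium_high_peaked, medium_bimodal, wide_bimodal, plus any block added
    through :func:`register_block`.
    """
    if block_name in _BLOCKS:
        support, probs = _BLOCKS[block_name]
        d = IntervalDistribution(np.array(support, float),
                                 np.array([float(p) for p in probs]),
                                 label=block_name)
        if np.any(np.abs(np.diff(d.support) - INTERVAL_STEP) > 1e-9):
            raise AssertionError("named blocks must use 75-ms spacing")
        return d
    if block_name in _CUSTOM_BLOCKS:
        return copy.deepcopy(_CUSTOM_BLOCKS[block_name])
    raise ValueError(f"unknown block {block_name!r}; valid blocks: "
                     + ", ".join(block_names()))


def register_block(dist: IntervalDistribution) -> None:
    """Add a custom distribution to the registry under its label."""
    if not dist.label:
        raise ValueError("distribution must carry a label to be registered")
    _CUSTOM_BLOCKS[dist.label] = copy.deepcopy(dist)


def block_registry() -> dict:
    """All registered blocks as a name -> IntervalDistribution mapping."""
    return {name: make_block_distribution(name) for name in block_names()}


def save_block_registry(path) -> None:
    data = {name: d.to_dict() for name, d in block_registry().items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_block_registry(path) -> dict:
    """Load blocks from a YAML file, registering any non-builtin ones."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    out = {}
    for name, d in data.items():
        dist = IntervalDistribution.from_dict({**d, "label": name})
        if name not in _BLOCKS:
            register_block(dist)
        out[name] = dist
    return out


# ---------------------------------------------------------------------------
# Candidate subjective priors (approximation schemes a-g)
# ---------------------------------------------------------------------------

# Mixture weight of one emerging peak in schemes (f)/(g): the probability
# mass of the peak in excess of the uniform background, stored as exact
# rationals.  E.g. Peaked: 7/12 - 1/12 = 1/2.
_PEAK_EMERGENCE = {
    "medium_uniform": Fraction(0),
    "medium_peaked": Fraction(1, 2),
    "medium_high_peaked": Fraction(3, 4),
    "medium_bimodal": Fraction(1, 4),       # per peak: 1/3 - 1/12
    "wide_bimodal": Fraction(9, 28),        # per peak: 3 * (1/7 - 1/28)
}

# Background component of schemes (f)/(g): Gaussian centred on the range
# midpoint with the sd quoted for the uniform background (ms).
_BACKGROUND_SD = {"medium": 128.7, "wide": 251.6}

# Small sd of the peak components (ms); scheme (g) doubles it.  For the
# Wide range, 75*sqrt(2/3) is the population sd of three intervals 75 ms
# apart.
_PEAK_SD_SMALL = {"medium": 37.5, "wide": 75.0 * np.sqrt(2.0 / 3.0)}

# Peak centres for the bimodal (f)/(g) schemes (ms).
_BIMODAL_CENTRES = {"medium_bimodal": (600.0, 975.0),
                    "wide_bimodal": (525.0, 1050.0)}


def _norm_pdf(x, mu, sd):
    z = (np.asarray(x, float) - mu) / sd
    return np.exp(-0.5 * z * z) / (sd * np.sqrt(2.0 * np.pi))


def _mixture_density(grid, centres, sds, weights):
    dens = np.zeros_like(grid)
    for c, s, w in zip(centres, sds, weights):
        dens += w * _norm_pdf(grid, c, s)
    return dens


def make_candidate_prior(scheme: str, block_name: str, grid=None):
    """Build candidate subjective prior `scheme` for `block_name`.

    Schemes
    -------
    a : the true discrete distribution (returned as IntervalDistribution).
    b : single Gaussian matched to the true mean and variance.
    c : mixture of Gaussians (sd 37.5 ms) at the true intervals, weighted
        by the true probabilities.
    d : as (c) with sd 75 ms.
    e : continuous uniform from the shortest to the longest interval.
    f : peak-plus-background Gaussian mixture with a narrow peak component
        (two components for peaked blocks, three for bimodal ones); the
        peak weight is the probability mass emerging above the uniform
        background.  Reduces to a single Gaussian for Medium Uniform.
    g : as (f) with doubled peak sd.

    Continuous schemes are truncated to `grid` and renormalized.
    """
    if scheme not in PRIOR_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; valid: {PRIOR_SCHEMES}")
    dist = make_block_distribution(block_name)
    if scheme == "a":
        return dist
    if grid is None:
        grid = duration_grid()
    grid = np.asarray(grid, float)
    label = f"{block_name}:{scheme}"

    if scheme == "b":
        dens = _norm_pdf(grid, dist.mean(), dist.sd())
    elif scheme in ("c", "d"):
        sd = 37.5 if scheme == "c" else 75.0
        dens = _mixture_density(grid, dist.support, [sd] * dist.n, dist.probs)
    elif scheme == "e":
        lo, hi = dist.support[0], dist.support[-1]
        dens = np.where((grid >= lo) & (grid <= hi), 1.0 / (hi - lo), 0.0)
    else:  # f, g
        if block_name not in _PEAK_EMERGENCE:
            raise ValueError(
                f"scheme {scheme!r} is defined only for the Medium Uniform, "
                f"Peaked, High-Peaked and Bimodal blocks, not {block_name!r}")
        rng = block_range(block_name)
        pi0 = float(_PEAK_EMERGENCE[block_name])
        small = _PEAK_SD_SMALL[rng]
        peak_sd = small if scheme == "f" else 2.0 * small
        bg = (REFERENCE_INTERVAL, _BACKGROUND_SD[rng])
        if block_name in _BIMODAL_CENTRES:
            c1, c2 = _BIMODAL_CENTRES[block_name]
            centres = [c1, c2, bg[0]]
            sds = [peak_sd, peak_sd, bg[1]]
            weights = [pi0, pi0, 1.0 - 2.0 * pi0]
        else:
            centres = [675.0, bg[0]]
            sds = [peak_sd, bg[1]]
            weights = [pi0, 1.0 - pi0]
        dens = _mixture_density(grid, centres, sds, weights)
    return ContinuousPrior.from_unnormalized(grid, dens, label)
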