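"""Diagnostic figures: bias/SD curves and reconstructed priors."""

from __future__ import annotations

import numpy as np


def plot_bias_sd(curves, data=None, ax=None, label=None, color=None):
    """Plot predicted bias and sd per interval (two stacked axes).

    ``curves`` is a DataFrame with columns x, bias, sd (as returned by
    :func:`chronobayes.bias_sd_curves` or BMA curves); ``data`` an
    optional trial table whose empirical per-interval bias/sd are drawn
    as points.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(2, 1, sharex=True, figsize=(5, 6))
    ax[0].plot(curves["x"], curves["bias"], "-", color=color, label=label)
    ax[1].plot(curves["x"], curves["sd"], "-", color=color, label=label)
    if data is not None:
        kept = data[data["retained"]] if "retained" in data.columns else data
        g = kept.groupby("target_ms")["response_ms"]
        x = np.array(sorted(g.groups))
        ax[0].plot(x, g.mean().loc[x] - x, "o", color=color)
        ax[1].plot(x, g.std(ddof=1).loc[x], "o", color=color)
    ax[0].axhline(0.0, lw=0.5, color="k")
    ax[0].set_ylabel("bias (ms)")
    ax[1].set_ylabel("response sd (ms)")
    ax[1].set_xlabel("target interval (ms)")
    if label:
        ax[0].legend(frameon=False)
    return ax


def plot_reconstructed_prior(results, truth=None, ax=None, color="C0"):
    """Mean reconstructed prior density with a sample-density band.

    ``results`` is a :class:`PriorReconstructionResults`; ``truth`` an
    optional generative prior (ContinuousPrior or IntervalDistribution)
    drawn for comparison.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    grid = results.model.grid
    flat = results.samples.reshape(-1, results.samples.shape[-1])
    idx = np.linspace(0, len(flat) - 1, min(len(flat), 400)).astype(int)
    dens = results._densities(flat[idx])
    lo, hi = np.percentile(dens, [16, 84], axis=0)
    ax.fill_between(grid, lo, hi, alpha=0.25, color=color, lw=0)
    ax.plot(grid, results.mean_density().density, color=color,
            label="reconstructed")
    if truth is not None:
        if hasattr(truth, "density"):
            ax.plot(truth.grid, truth.density, "k--", label="generative")
        else:
            ax.stem(truth.support, truth.probs / 75.0, basefmt=" ",
                    linefmt="k-", markerfmt="ko", label="generative")
    ax.set_xlabel("interval (ms)")
    ax.set_ylabel("density (1/ms)")
    ax.set_xlim(results.model.control_times[0] - 75,
                results.model.control_times[-1] + 75)
    ax.legend(frameon=False)
    return ax
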