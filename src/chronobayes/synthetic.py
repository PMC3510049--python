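"""Synthetic subjects: run construction, trial simulation, retention rules.

The original behavioural datasets are not deposited, so every analysis
stage is exercised on simulated subjects whose trial tables carry the
same statistical structure as the study design: runs of 84-96 trials in
which each interval appears exactly in proportion to the block
distribution (with the High-Peaked ordering constraint that every rare
interval is immediately preceded by 3-5 peak intervals), responses
generated by a ground-truth Bayesian observer with optional lapses, a
block-dependent allowed-response window for trial retention, and random
balanced subsampling of over-represented intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import (IntervalDistribution, block_range,
                            make_block_distribution)
from .observer import DecisionRule, ObserverModel, decision_rule, simulate_responses

__all__ = [
    "BlockDesign",
    "ALLOWED_WINDOWS",
    "TRIAL_COLUMNS",
    "build_run",
    "simulate_trials",
    "filter_trials",
    "subsample_balanced",
    "write_trials",
    "read_trials",
]

#: Allowed response windows (ms, inclusive) per interval range; responses
#: outside the window are discarded from analysis.
ALLOWED_WINDOWS = {
    "short": (225.0, 1237.0),
    "medium": (300.0, 1462.0),
    "long": (375.0, 1687.0),
    "wide": (225.0, 1687.0),
}

TRIAL_COLUMNS = ["subject_id", "block", "session", "run", "trial_index",
                 "target_ms", "response_ms", "retained", "lapse"]

# Default run lengths: the smallest value in 84-96 for which every
# interval count is integral (96 for High-Peaked, whose probabilities
# have denominator 24; 90 for Wide Uniform).
_DEFAULT_RUN_LENGTH = {"medium_high_peaked": 96, "wide_uniform": 90}


@dataclass
class BlockDesign:
    """One experimental block: distribution, feedback regime, run layout."""

    block_name: str
    feedback: str = "standard"
    run_length: int = 0
    n_sessions: int = 2
    runs_per_session: int = 6
    distribution: IntervalDistribution = None
    allowed_window: tuple = None

    def __post_init__(self):
        if self.feedback not in ("skewed", "standard"):
            raise ValueError("feedback must be 'skewed' or 'standard'")
        if self.distribution is None:
            self.distribution = make_block_distribution(self.block_name)
        if self.run_length == 0:
            self.run_length = _DEFAULT_RUN_LENGTH.get(self.block_name, 84)
        if not (84 <= self.run_length <= 96):
            raise ValueError("run_length must lie in 84-96")
        if self.allowed_window is None:
            self.allowed_window = ALLOWED_WINDOWS[block_range(self.block_name)]
        self.interval_counts()  # validate integrality early

    def interval_counts(self) -> np.ndarray:
        """Exact per-interval counts within one run."""
        counts = self.distribution.probs * self.run_length
        rounded = np.rint(counts)
        if np.any(np.abs(counts - rounded) > 1e-9):
            good = [n for n in range(84, 97)
                    if np.allclose(self.distribution.probs * n,
                                   np.rint(self.distribution.probs * n), atol=1e-9)]
            raise ValueError(
                f"run_length {self.run_length} does not yield integer interval "
                f"counts for {self.block_name!r}; compatible lengths in 84-96: {good}")
        return rounded.astype(int)

    def to_dict(self):
        return {"block_name": self.block_name, "feedback": self.feedback,
                "run_length": int(self.run_length),
                "n_sessions": int(self.n_sessions),
                "runs_per_session": int(self.runs_per_session)}

    @classmethod
    def from_dict(cls, d):
        return cls(**d)


def _is_high_peaked(dist: IntervalDistribution) -> bool:
    return dist.probs.max() > 0.75


def build_run(design: BlockDesign, seed) -> np.ndarray:
    """One run of target durations with exact per-interval counts.

    The order is randomized, except for High-Peaked designs where every
    rare (non-peak) target is immediately preceded by 3-5 consecutive
    peak targets, as in the study's run construction.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dist = design.distribution
    counts = design.interval_counts()
    if not _is_high_peaked(dist):
        targets = np.repeat(dist.support, counts)
        return rng.permutation(targets)

    # High-Peaked: lay the run out as [k_1 peaks, rare_1, k_2 peaks,
    # rare_2, ...] with k_i in {3, 4, 5} summing to the peak count.
    peak_idx = int(np.argmax(dist.probs))
    peak = dist.support[peak_idx]
    rare = np.repeat(np.delete(dist.support, peak_idx),
                     np.delete(counts, peak_idx))
    n_rare, n_peak = len(rare), int(counts[peak_idx])
    if n_peak < 3 * n_rare:
        raise ValueError("too few peak targets to precede every rare target "
                         "with 3-5 peaks; choose a compatible run_length")
    k = np.full(n_rare, 3)
    spare = min(n_peak - 3 * n_rare, 2 * n_rare)
    while spare > 0:
        room = np.flatnonzero(k < 5)
        i = rng.choice(room)
        k[i] += 1
        spare -= 1
    rng.shuffle(rare)
    out = []
    for ki, x in zip(k, rare):
        out.extend([peak] * ki)
        out.append(x)
    out.extend([peak] * (n_peak - int(k.sum())))  # trailing peaks, if any
    return np.asarray(out, dtype=float)


def simulate_trials(design: BlockDesign, truth: ObserverModel,
                    n_trials: int = None, seed=None, subject_id: str = "syn01",
                    rule: DecisionRule = None, grid=None) -> pd.DataFrame:
    """Simulate a trial table for one synthetic subject and block.

    Targets follow the exact-proportion run structure; responses are drawn
    from the ground-truth observer's generative chain (sensory noise ->
    optimal action -> motor noise, or a uniform lapse).  Deterministic
    under ``seed``.  ``n_trials`` defaults to the design's full session
    layout and is otherwise met by truncating the final run.
    """
    rng = np.random.default_rng(seed)
    if rule is None:
        rule = decision_rule(truth, grid=grid)
    if n_trials is None:
        n_trials = design.run_length * design.runs_per_session * design.n_sessions
    runs_per_session = design.runs_per_session
    frames = []
    produced = 0
    run_counter = 0
    while produced < n_trials:
        targets = build_run(design, rng)
        take = min(len(targets), n_trials - produced)
        targets = targets[:take]
        r, lapse = simulate_responses(truth, targets, rng, rule=rule)
        frames.append(pd.DataFrame({
            "subject_id": subject_id,
            "block": design.block_name,
            "session": run_counter // runs_per_session + 1,
            "run": run_counter + 1,
            "trial_index": np.arange(take) + 1,
            "target_ms": targets,
            "response_ms": r,
            "retained": True,
            "lapse": lapse,
        }))
        produced += take
        run_counter += 1
    trials = pd.concat(frames, ignore_index=True)
    return filter_trials(trials, design)


def _window_for(block: str, design: BlockDesign = None):
    if design is not None and design.block_name == block:
        return design.allowed_window
    return ALLOWED_WINDOWS[block_range(block)]


def filter_trials(trials: pd.DataFrame, design: BlockDesign = None) -> pd.DataFrame:
    """Flag trial retention: responses inside the block's allowed window
    (boundaries inclusive) are retained; discarded trials stay in the
    table with ``retained=False``."""
    trials = trials.copy()
    for block, idx in trials.groupby("block").groups.items():
        lo, hi = _window_for(str(block), design)
        r = trials.loc[idx, "response_ms"]
        trials.loc[idx, "retained"] = (r >= lo) & (r <= hi)
    return trials


def subsample_balanced(trials: pd.DataFrame, seed=None) -> pd.DataFrame:
    """Balanced random subsample of retained trials for non-uniform blocks.

    Downsamples every interval's retained trials to the minimum retained
    per-interval count, so all intervals contribute equally to the model
    comparison.  Not applicable to the Wide Bimodal block (too few trials
    per interval, as in the original analysis).
    """
    if (trials["block"] == "wide_bimodal").any():
        raise ValueError("balanced subsampling is not applied to the Wide "
                         "Bimodal block (too few trials per interval)")
    rng = np.random.default_rng(seed)
    out = trials.copy()
    for block, sub in trials.groupby("block"):
        kept = sub[sub["retained"]]
        counts = kept.groupby("target_ms").size()
        n_min = int(counts.min())
        for x, grp in kept.groupby("target_ms"):
            if len(grp) > n_min:
                drop = rng.choice(grp.index.to_numpy(), size=len(grp) - n_min,
                                  replace=False)
                out.loc[drop, "retained"] = False
    return out


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as tab-delimited text with the standard header."""
    trials.to_csv(path, sep="\t", index=False, columns=TRIAL_COLUMNS)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    df["retained"] = df["retained"].astype(bool)
    df["lapse"] = df["lapse"].astype(bool)
    return df
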