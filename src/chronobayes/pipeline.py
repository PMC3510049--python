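"""Pipeline orchestration: simulate -> compare -> reconstruct -> report.

A :class:`RunConfig` (YAML-serializable) names the block designs, the
ground-truth observers for synthetic runs, any model-space restrictions,
the chain configuration and the master seed.  ``run_pipeline`` executes
the requested stages into an artifact directory of plain delimited text
plus a JSON manifest (config hash, seeds, package version), and stages
are resumable from prior outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparison import (ModelSpace, ObserverComparison, ParameterPrior)
from .distributions import make_candidate_prior
from .observer import LossSpec, NoiseModel, ObserverModel
from .reconstruction import PriorReconstruction
from .synthetic import (BlockDesign, read_trials, simulate_trials,
                        subsample_balanced, write_trials)

__all__ = ["RunConfig", "run_pipeline", "restrict_model_space"]

STAGES = ("simulate", "compare", "reconstruct", "report")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    stages: list = field(default_factory=lambda: list(STAGES))
    designs: list = field(default_factory=list)      # BlockDesign dicts
    truth: dict = field(default_factory=dict)        # ObserverModel spec
    n_trials_per_block: int = 500
    model_space: dict = field(default_factory=dict)  # levels per component
    restrict: dict = field(default_factory=dict)     # component -> levels
    grid_step: float = 2.0
    n_param_grid: int = 20
    evidence_method: str = "both"
    balanced_subsample: bool = True
    chains: int = 2
    burn: int = 300
    draws: int = 300
    seed: int = 0
    out_dir: str = "chronobayes_run"

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- derived objects ----------------------------------------------------

    def block_designs(self) -> dict:
        if not self.designs:
            raise ValueError("config lists no block designs")
        out = {}
        for d in self.designs:
            bd = BlockDesign.from_dict(dict(d))
            out[bd.block_name] = bd
        return out

    def truth_observer(self, block: str) -> ObserverModel:
        t = dict(self.truth) if self.truth else {}
        scheme = t.get("prior_scheme", "a")
        prior = make_candidate_prior(scheme, block)
        design = self.block_designs()[block]
        return ObserverModel(
            NoiseModel(t.get("sensory_kind", "scalar"), t.get("w_s", 0.1)),
            NoiseModel(t.get("motor_kind", "scalar"), t.get("w_m", 0.1)),
            prior, LossSpec(t.get("loss", "standard"),
                            t.get("loss_exponent", 2.0)),
            lapse_rate=t.get("lapse_rate", 0.0),
            lapse_range=design.allowed_window)


def restrict_model_space(config: RunConfig) -> ModelSpace:
    """Model space after the config's restrictions (e.g. Standard-loss-only
    comparisons, or scalar/scalar noise with free prior scheme)."""
    kw = {}
    for key in ("sensory", "motor", "prior_schemes", "losses"):
        if key in config.model_space:
            kw[key] = tuple(config.model_space[key])
    space = ModelSpace.full(**kw)
    r = {k: tuple(v) for k, v in config.restrict.items()}
    if r:
        space = space.restrict(sensory=r.get("sensory"), motor=r.get("motor"),
                               prior_scheme=r.get("prior_scheme"),
                               loss=r.get("loss"))
    return space


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path.name}; run the '{stage}' stage first")
    return path


def run_pipeline(config: RunConfig, verbose: bool = False) -> Path:
    """Execute the configured stages; returns the artifact directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    designs = config.block_designs()
    rng = np.random.default_rng(config.seed)
    manifest = {"config": config.to_dict(), "config_hash": config.config_hash(),
                "version": __version__, "seeds": {}, "stages_run": []}
    trials_path = out / "trials.tsv"

    if "simulate" in config.stages:
        frames = []
        for block, design in designs.items():
            seed = int(rng.integers(2 ** 31))
            manifest["seeds"][f"simulate:{block}"] = seed
            truth = config.truth_observer(block)
            tr = simulate_trials(design, truth, n_trials=config.n_trials_per_block,
                                 seed=seed)
            if config.balanced_subsample and block != "wide_bimodal" \
                    and design.distribution.probs.max() > design.distribution.probs.min():
                sub_seed = int(rng.integers(2 ** 31))
                manifest["seeds"][f"subsample:{block}"] = sub_seed
                tr = subsample_balanced(tr, seed=sub_seed)
            frames.append(tr)
        trials = pd.concat(frames, ignore_index=True)
        write_trials(trials, trials_path)
        manifest["stages_run"].append("simulate")
        if verbose:
            print(f"simulate: {len(trials)} trials "
                  f"({int(trials['retained'].sum())} retained) -> {trials_path}")

    results = None
    if "compare" in config.stages:
        trials = read_trials(_require(trials_path, "simulate"))
        space = restrict_model_space(config)
        comp = ObserverComparison(
            trials, space, designs=designs,
            param_prior=ParameterPrior(n_grid=config.n_param_grid),
            grid_step=config.grid_step)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            results = comp.fit(method=config.evidence_method, verbose=verbose)
        results.evidence_table().to_csv(out / "evidence.tsv", sep="\t", index=False)
        cp = results.component_posteriors()
        rows = [{"component": comp_name, "level": lv, "posterior": pv}
                for comp_name, probs in cp.items() for lv, pv in probs.items()]
        pd.DataFrame(rows).to_csv(out / "component_posteriors.tsv", sep="\t",
                                  index=False)
        curves = []
        for block in designs:
            c = results.model_average_curves(block)
            c.insert(0, "block", block)
            curves.append(c)
        pd.concat(curves, ignore_index=True).to_csv(out / "bma_curves.tsv",
                                                    sep="\t", index=False)
        manifest["stages_run"].append("compare")
        if verbose:
            print(f"compare: best model {results.best_template.label}")

    if "reconstruct" in config.stages:
        trials = read_trials(_require(trials_path, "simulate"))
        if results is None:
            ev_path = _require(out / "evidence.tsv", "compare")
            best = pd.read_csv(ev_path, sep="\t").iloc[0]
            fixed = {"sensory": str(best["sensory"]), "motor": str(best["motor"]),
                     "loss": str(best["loss"]),
                     "w_s": float(best["map_w_s"]), "w_m": float(best["map_w_m"])}
        else:
            t = results.best_template
            ws, wm = results.map_params()
            fixed = {"sensory": t.sensory, "motor": t.motor, "loss": t.loss,
                     "w_s": ws, "w_m": wm}
        samples_frames, moment_rows = [], []
        for block, design in designs.items():
            sub = trials[trials["block"] == block]
            observer = ObserverModel(
                NoiseModel(fixed["sensory"], fixed["w_s"]),
                NoiseModel(fixed["motor"], fixed["w_m"]),
                make_candidate_prior("e", block),  # placeholder; replaced by sampling
                LossSpec(fixed["loss"]), lapse_range=design.allowed_window)
            seed = int(rng.integers(2 ** 31))
            manifest["seeds"][f"reconstruct:{block}"] = seed
            rec = PriorReconstruction(sub, observer, block=block,
                                      grid_step=config.grid_step)
            res = rec.fit(chains=config.chains, burn=config.burn,
                          draws=config.draws, seed=seed, verbose=verbose)
            frame = res.to_frame()
            frame.insert(0, "block", block)
            samples_frames.append(frame)
            ms = res.moment_summary()
            for name, row in ms.iterrows():
                moment_rows.append({"block": block, "moment": name,
                                    "mean": row["mean"], "sd": row["sd"]})
        pd.concat(samples_frames, ignore_index=True).to_csv(
            out / "prior_samples.tsv", sep="\t", index=False)
        pd.DataFrame(moment_rows).to_csv(out / "prior_moments.tsv", sep="\t",
                                         index=False)
        manifest["stages_run"].append("reconstruct")

    if "report" in config.stages:
        lines = [f"chronobayes {__version__} run {manifest['config_hash']}"]
        if trials_path.exists():
            tr = read_trials(trials_path)
            lines.append(f"trials: {len(tr)} total, {int(tr['retained'].sum())} retained")
            counts = tr[tr["retained"]].groupby("block").size()
            lines += [f"  {b}: {n}" for b, n in counts.items()]
        for name in ("evidence.tsv", "component_posteriors.tsv", "prior_moments.tsv"):
            p = out / name
            if p.exists():
                lines.append("")
                lines.append(f"== {name} ==")
                lines.append(pd.read_csv(p, sep="\t").to_string(index=False))
        (out / "report.txt").write_text("\n".join(lines) + "\n")
        manifest["stages_run"].append("report")
        if verbose:
            print((out / "report.txt").read_text())

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
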