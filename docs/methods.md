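# Methods

This note documents the model, the numerical choices and the synthetic
study conditions implemented in `chronobayes`, and what the test suite
does and does not establish.

## Observer–actor model

A trial presents a target interval `x` drawn from a discrete block
distribution; the observer forms a noisy measurement `x_m`, selects the
action `u*(x_m)` minimizing its subjectively expected loss, and produces
a response `r` corrupted by motor noise.  The response distribution
marginalizes the unobserved measurement:

    p(r | x) = ∫ p_s(x_m | x) · p_m(r | u*(x_m)) dx_m,
    u*(x_m)  = argmin_u ∫∫ |f̃(r, x)|^κ p_m(r | u) post(x | x_m) dx dr,

with `post(x | x_m) ∝ p_s(x_m | x) π(x)`.  Both likelihoods are
Gaussian; a *scalar* noise component has sd `w·t` (constant coefficient
of variation, the Weber fraction of interval timing), a *constant* one
has sd `w·787.5 ms` regardless of `t`, so that `w` is comparable across
kinds.  The generative and internal models share `(w_s, w_m)` — the
basic model assumes the observer knows its own noise.

Error maps: standard `r − x`, fractional `(r − x)/x`, skewed
`(r − x)/r`.  The loss is the squared map (`κ = 2`) in the basic model;
`LossSpec(..., exponent=κ)` implements the sub-/super-quadratic
extension, which forces the numeric minimization path and is excluded
from the default comparison family.  For small relative errors the
squared fractional loss approximates a squared logarithmic loss
(relative gap ≈ the relative error itself), which is why it stands in
for a logarithmic internal representation of time.

### Optimal actions

For the quadratic standard and fractional losses the minimization is
closed-form (posterior mean, scaled by `1/(1 + w_m²)` under scalar motor
noise; the ratio `E[1/x]/E[1/x²]` analogue for fractional).  The skewed
loss is minimized numerically: the expected loss factorizes as
`1 − 2·E[x|x_m]·A(u) + E[x²|x_m]·B(u)` where `A, B` are the
truncated-Gaussian moments of `1/r` and `1/r²`, evaluated on an action
grid and refined by parabolic interpolation.  Both paths agree within
0.5 ms where both apply (tested).

One regularization is intrinsic: `E[1/r²]` under an untruncated Gaussian
motor likelihood diverges, so the skewed-loss quadrature runs on the
positive response grid `[150, 1800] ms`.  Responses below 150 ms are
essentially never produced by the modelled observers, and such trials
are discarded by the retention windows in any case.  For the standard
and fractional losses the numeric path integrates on a grid extended by
six motor sds so that no Gaussian mass is clipped, which is what makes
the closed-form/numeric agreement exact rather than approximate.

### Grids and quadrature

All duration quadratures run on a regular grid spanning `[150, 1800]`
ms — a superset of every allowed-response window — with trapezoid
weights.  The default step is 1 ms; the heavy fitting stages (model
comparison, prior reconstruction) use a 5-ms step, and the reconstruction
engine integrates over the measurement at a 10-ms step, both verified
against 0.5-ms re-evaluation to well under 1e-3 per-trial log-density
error (noise sds are ≥ 30 ms everywhere, so these integrands are
smooth).  Scalar-noise Gaussians are truncated to the grid and
renormalized; the truncation masses involved are ≤ 1e-6 except at the
extreme grid edges, which carry no data.

## Experimental distributions and candidate priors

The block registry reproduces the study designs exactly as rationals:
Uniform blocks (1/6 per interval; 1/10 for Wide), Peaked (7/12 at
675 ms), High-Peaked (19/24), Medium Bimodal (1/3 at each of 600 and
975 ms), Wide Bimodal (1/7 at each of six extremal intervals, 1/28 at
the four middle ones).  Candidate subjective priors: (a) the true
discrete distribution; (b) a moment-matched Gaussian; (c)/(d) Gaussian
mixtures at the true intervals with sd 37.5/75 ms; (e) a continuous
uniform over the range; (f)/(g) sparse peak-plus-background mixtures
whose peak weight is the probability mass emerging above the uniform
background (1/2 Peaked, 3/4 High-Peaked, 1/4 per mode Medium Bimodal,
9/28 per mode Wide Bimodal), with narrow (37.5 ms; 61.2 ms for Wide)
or doubled peak sds and a background Gaussian at 787.5 ms with sd
128.7 ms (251.6 ms for Wide).  A kurtosis note: the High-Peaked
distribution's excess kurtosis is +4.27 by direct computation — any
value below `skewness² − 2 = 3.06` would be mathematically impossible
given its skewness of 2.25.

## Synthetic subjects

The generator reproduces the protocol's statistical structure, and its
defaults are the study conditions, not tuning knobs:

- runs of 84–96 trials with *exact* per-interval counts (84 default; 96
  for High-Peaked, 90 for Wide Uniform — the smallest compatible
  lengths), order randomized, and every rare High-Peaked target preceded
  by 3–5 consecutive peak targets;
- two test sessions of six runs per block (~1000 trials per block),
  matching the analysed test-trial counts; non-uniform blocks are
  balanced-subsampled to the minimum per-interval count before model
  comparison (~500 trials for Peaked), except Wide Bimodal;
- allowed response windows 225–1237 (Short), 300–1462 (Medium), 375–1687
  (Long), 225–1687 ms (Wide), boundaries inclusive (the convention is
  immaterial at these widths but fixed); discarded trials stay in the
  table with `retained=False`;
- ground-truth Weber fractions default to `w_s = w_m = 0.1`, mid-range
  for human interval timing; lapses are off by default and modelled as
  uniform responses over the allowed window when enabled;
- hardware artifacts (timestamp errors, inter-trial timing, the 250-ms
  reproduction delay) are not simulated — they do not affect the
  `(x, r)` statistics under the model.

What passing tests on these subjects do **not** show: real observers may
have non-Gaussian (heavier-tailed) likelihoods, non-quadratic losses,
sequential (trial-to-trial) dependencies, or learning dynamics — none of
which the generator emulates.  Recovery results here certify the
inference machinery, not those modelling assumptions.

## Model comparison

Marginal likelihoods integrate the trial likelihood against independent
Beta(1.3, 2.6) priors on `(w_s, w_m)`, truncated and renormalized on
`[0.01, 0.6]` (the plausible Weber-fraction region; the renormalization
makes a constant likelihood integrate to itself exactly).  Two routes
are computed and compared:

- **grid**: 60×60 log-spaced nodes with trapezoid weights.  The node
  count matters: at ~500 trials the `w` posterior has sd ≈ 0.003, and
  the 60-node grid spaces nodes ≈ 2.4 posterior sds apart near
  `w = 0.1`, which Gaussian-quadrature behaviour makes accurate to a few
  hundredths of a log unit; 20 nodes produce ~1-log-unit quadrature
  error.  Scaled-down grids are therefore used only where the evidence
  *difference* between models (typically ≫ 1 log unit) is what matters.
- **Laplace**: Nelder-Mead MAP search in log-`w` coordinates,
  finite-difference Hessian, flagged unreliable when the MAP sits on the
  parameter boundary.

Component posteriors fix one component and sum model posteriors over the
others; ties break toward the simpler level (constant before scalar,
standard before fractional before skewed).  Bayesian model averaging of
bias/SD curves weights each model's parameter-posterior-averaged curve
by its posterior probability (top 99.5% of parameter mass; no point
fitting).  The optional lapse variant marginalizes λ uniformly over the
small grid {0, 0.01, 0.03, 0.1}.

The scaled-down confusion study (acceptance suite) uses Laplace
evidences, a 5-ms grid, and a model space restricted to
{3 losses} × {2 sensory kinds} with scalar motor noise and the true
discrete prior: 6 truth configurations × 10 seeds, each subject carrying
~1000 Medium Uniform + ~500 balanced Medium Peaked trials.  Loss
recovery is essentially perfect at this size; sensory-kind recovery runs
at ~90–100% per configuration.  At half the trial counts the sensory
kind is only ~75% recoverable — the likelihood at the *true* parameters
then often favours the wrong noise kind, an information limit of the
Medium-range design (constant and scalar noise coincide at 787.5 ms and
differ only through the sd slope across 600–975 ms), not an inference
failure; quadrupling the data restores near-certain recovery.

## Nonparametric prior reconstruction

The log prior is parameterized by its values at control points spaced
75 ms apart spanning the block's interval range extended by two steps on
each side (10 points; 14 for Wide).  A squared-exponential GP
(length scale 100 ms, signal scale 2 log-density units, jitter 1e-6)
interpolates the log density onto the duration grid — interpolation
only, not part of the inference.  The extrapolation level is anchored
10 log units *below the mean control value*, which (i) makes the induced
density exactly invariant to adding a constant to all control values,
the gauge freedom the normalization absorbs, and (ii) sends tails to
zero within about one control spacing outside the range.  The
length-scale choice is a compromise — of the order of the control
spacing, smooth without oscillation — and results are verified robust to
halving/doubling it.

Sampling is coordinate-wise slice sampling with stepping-out (Neal
2003): initial width 1.0 in log-density, up to 10 step-outs, per-
coordinate widths adapted to the typical accepted move during burn-in
and frozen afterwards (adaptation during sampling would break detailed
balance).  After each sweep the control vector is recentred to mean zero
(pure gauge fixing along the exactly flat direction).  A hard cap of
±20 on *centred* log values guards numerics.  Chains start dispersed
around a Gaussian matched to the empirical target moments.  The full
protocol is 10 chains × (3000 burn-in + 1500 saved) = 15000 sampled
priors; the acceptance suite runs a 2 × (250 + 300) smoke version, which
the moment-level split-R-hat (≈ 1.01–1.06) shows is converged on the
quantities reported.  Raw control-point R-hat stays high much longer —
the tail coordinates outside the data range are only weakly likelihood-
constrained — which is why convergence is monitored on the per-sample
prior moments, the identifiable quantities.

Fixed observer components (noise kinds, `w` values, loss) come from the
model-comparison stage; the MAP `(w_s, w_m)` is used rather than
re-marginalizing (a switchable choice).  Moments are computed per
sampled prior and then averaged across samples; taking moments of the
averaged density instead would misstate tail weight (a mixture of
near-Gaussian densities can be strongly platy- or leptokurtic), and the
package deliberately reports the average-of-moments.  Spurious
multimodality is flagged when an interior control point of the
posterior-mean density exceeds 1.5× the density at both neighbours.

At 1000 trials the reconstruction recovers the mean, sd and skewness of
Gaussian, smoothed-discrete and flat generative priors within two
posterior sds (posterior sd of the mean is ~40–50 ms at this size); the
posterior over flexible priors sits a few log units above the generative
control vector — the expected ~k/2 overfitting headroom of 10 free
parameters — so point-identification of the prior is soft even when its
moments are well determined.

## Pipeline

`RunConfig` (YAML) → `run_pipeline`: simulate → compare → reconstruct →
report, writing tab-delimited artifacts plus a JSON manifest (config
hash, derived seeds, package version).  Every stochastic stage draws its
seed from the master seed, so a rerun is byte-identical for
deterministic stages and statistically reproducible for MCMC.  The
`chronobayes` CLI exposes the stages with `--restrict` model-space
filters (e.g. `loss=standard` for the constrained comparisons used with
sparse designs).

## Known limitations

- The skewed-loss expected value depends (weakly) on the 150-ms lower
  quadrature bound; this is a modelling choice, documented above.
- Constant-vs-scalar noise attribution is weakly identified from
  Medium-range data alone; designs spanning multiple ranges identify it
  far better.
- The reconstruction's tail control points are prior-dominated; only
  quantities robust to them (moments, the density over the data range)
  should be interpreted.
- No sequential effects, learning dynamics, non-Gaussian likelihoods or
  free loss exponents in the default comparison family.
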