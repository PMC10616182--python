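# Methods

## Design

The emulated experiment fully crosses 6 reference orientations (15°–165° in
30° steps; 0° is vertical), 13 stimulus-mean offsets (−18° to +18° in 3°
steps) and 2 ensemble noise levels (all 24 bars identical, or bar
orientations drawn N(mean, 9°)), giving 156-trial blocks; a session is 5
single-task blocks followed by 5 dual-task blocks (1560 trials; the
explicit discrimination instruction appears only after all single-task
blocks). Randomisation within a block is a seeded Fisher–Yates shuffle of
the enumerated factorial, so trial tables are byte-reproducible from one
integer. The *nominal* ensemble mean (reference + offset, mod 180°) is the
stimulus value used by the model; ensemble variability is absorbed into the
high-noise measurement SD. Realised bar draws can be attached for
sensitivity analyses (`design.attach_ensembles`) but are not used by the
fit. Practice blocks, response time-outs and trial-repeat mechanics are not
simulated — the synthetic observer always responds.

Published descriptions of this paradigm vary in the number of fixed
reference values used (six versus eight); the default here is six, and the
reference set is a configuration parameter rather than a constant, so
either variant can be generated.

## Observer model

Measurement: m ~ N(μ, σ²) with σ_l (low noise) and σ_h (high noise); σ is a
standard deviation in degrees throughout. Decoding multiplies the
measurement density by the weighting function

f(ω) = ½ g(ω; α, θ, δ) + ½ g(−ω; α, θ, δ),

a mixture of a shifted Gamma density and its reflection about the
reference. An alternative parameterisation translates the second component
by −δ instead of reflecting it (½ g(ω; δ) + ½ g(ω; −δ)); that variant is a
pure translation of g and is not symmetric about the reference, so the
reflected form — which makes the weighting profile exactly even and
bimodal, as a reference-centred re-weighting should be — is the default,
with the translated variant kept behind `form="literal_shift"` for
comparison. At the (measure-zero)
support boundaries ±δ of an α = 1 component, f takes the average of its
one-sided limits so that it is exactly even; each component g keeps the
right-continuous convention (g(δ) = 1/θ).

Each task condition has its own (α, θ, δ); the motor bias ε is one constant
shared across all conditions and is applied as a translation of the final
estimate axis after re-weighting. The dual-task CW/CCW choice is the sign
of the *pre-bias* internal sample, ties broken CW — one shared sample per
trial drives both responses, the minimal rule consistent with
self-consistency between discrimination and reproduction; an optional lapse
rate (default 0) can flip choices. Single-task trials use the single-task
weighting even though no explicit choice is made.

## Likelihood and fitting

The likelihood is evaluated analytically on a uniform grid of offsets
(default [−90°, 90°], 0.1° spacing): each trial contributes the log of the
normalised product-density mass in the grid cell nearest its relative
estimate, floored at 1e−12 per trial (estimates outside the grid count at
the floor). A Monte-Carlo alternative (`fitting.sampled_log_likelihood`,
500 draws per design cell binned at 2°) is provided as a cross-check; the
analytic objective is deterministic and is the default. The sampler
(`observer.simulate_session`) draws by inverse CDF on the same grid with
uniform smoothing inside each 0.1° cell, and agrees with the analytic
density to multinomial accuracy (tested at a total-variation threshold of
0.05 against a 10× finer grid, ~3× the expected multinomial noise for 1e5
draws in 2° bins).

Fitting is Nelder–Mead on an unconstrained internal scale — log(σ), log(α),
log(θ), softplus(δ) (so δ ≥ 0), identity for ε — with a data-driven
starting point (within-cell SDs for σ, the |estimate| histogram peak near
alignment for the weighting location) and jittered multi-start (default 8
starts, SD 0.3 on the internal scale; convergence at objective change
< 1e−6, simplex size < 1e−4, ≤ 5000 iterations per start). The reported
optimum is the best across starts and is never worse than the
initialisation. Parameters whose conditions are absent from the data (e.g.
dual-task weights when only single-task trials are supplied) are held at
the initialisation and flagged. Uncertainty comes from a nonparametric
bootstrap (default 100 replicates) stratified by task × noise × offset
cell, so every replicate retains the complete design; replicates are
refitted from the full-data solution with 2 starts. A likelihood profile in
δ (0–20° grid) at the fitted point serves as an identifiability guard.

Model predictions draw 500 estimates per design cell through the observer
and are analysed exactly like measured data (selection, bias curves, dip
tests), closing the loop between the generative and descriptive layers.

## Descriptive statistics

Relative estimate: Δω = ω̄ − ω_ref wrapped to (−90°, 90°] (mod 180°).

Psychometric fit: P(CW|x) = guess + (1 − guess − lapse)·Φ((x − pse)/s) by
maximum likelihood, lapse and guess bounded in [0, 0.1] (the common
convention of the standard psychometric toolboxes); the PSE standard error
uses a 200-replicate parametric bootstrap.
The discrimination threshold is identified with s, the SD of the cumulative
Gaussian (reciprocal slope).

Dip test: the dip statistic is the minimal sup-norm distance between the
ECDF and any unimodal CDF, computed exactly by the iterative greatest-
convex-minorant / least-concave-majorant algorithm; tied observations are
separated by a deterministic 1e−11 relative spread, under which the
statistic is continuous. The implementation is verified in the test suite
against an independent exact oracle (one linear program per candidate mode
location). P-values are Monte-Carlo against the uniform null (default 2000
null samples of the same n, null tables cached per sample size); type-I
error at α = .05 calibrates to ≈ 0.05–0.06 at n = 200.

Gamma-mixture histogram fit: estimates are binned (default 2° bins over
(−45°, 45°]), density-normalised and
fitted by non-linear least squares with multi-start. The default model is
the unshifted symmetric mixture (δ = 0; bimodality is carried by α > 1),
matching the descriptive model of "two identical Gamma density functions";
the shifted variant is available via `fit_delta=True`. The spread summary
is the per-component variance αθ²; 95% CIs use a residual bootstrap.

Implicit-correctness selection classifies a trial as correct when the
estimate falls on the same CW/CCW side of the reference as the true offset
— by estimates in *both* task conditions (a flag switches dual-task
classification to the explicit responses). Zero-offset trials have no
defined correct side; the default keeps them with the side taken from the
estimate's sign (their bias is then |estimate| ≥ 0), since bias at
alignment is a reported quantity; dropping them is a config option.
Repulsive bias is sign(offset)·(estimate − offset), cell means ± SEM
(SD/√n) by |offset| × task × noise. SD summaries subtract per-offset cell
means before pooling so the design spread does not inflate them.

## Synthetic observer defaults

The generator's defaults define the emulated experimental conditions, set
to the regime pooled human data in this paradigm occupy:
σ_l = 5.0°, σ_h = 6.5° (the scale of pooled discrimination thresholds),
weighting profiles peaking at ±7° in both tasks, the dual profile far more
concentrated than the single one, and ε = 0.5°:

- single: α = 1.1, θ = 70°, δ = 0 (broad, shallow central notch),
- dual: α = 4, θ = 1°, δ = 4° (narrow, hard central gap).

The single-task concentration is only loosely constrained by the reported
profile figures; it was calibrated once so that the emulated single-task
pooled estimates are unimodal by the dip test while the dual-task ones are
strongly bimodal — the reported pattern — and then frozen. With these
defaults the synthetic data reproduce the direction-of-effect findings
end-to-end: repulsion ≈ 7° at alignment in the dual task (≈ 4–5° single),
attraction (negative bias) at large offsets that is stronger under the dual
task, SD(single) > SD(dual), and ~93% implicit-correctness retention.

What the generator does not emulate: sequential effects (serial dependence,
learning across blocks), reaction times, memory decay over the response
interval, motor noise beyond the constant bias, and between-subject
heterogeneity (pooled-scale datasets are five independent sessions from
*one* parameter set). Passing tests therefore show that the pipeline
recovers what the model family can express under the stated design — not
that real data satisfy the model.

## Problem sizes and numerical choices

Parameter recovery runs 20 replicates of 7800 trials (five sessions, the
pooled scale) with 2 Nelder–Mead starts per fit; medians over replicates
summarise recovery (σ within ~1%, δ within ~0.1°, ε bias ~0.1° in the
default regime). The broad single-task profile leaves θ_s only weakly
identified on a bounded grid (its likelihood is nearly flat towards the
flat-weighting limit); this is expected and documented rather than
penalised — the scientifically meaningful quantities (σ_l, σ_h, δ_s, δ_d,
ε, and the dual concentration) recover tightly. Sampler checks use 1e5
draws at three parameter regimes. Dip calibration uses 500 simulations at
n = 200 against a cached 2000-sample null table. Degenerate inputs are
handled explicitly: an all-equal sample is flagged as a point mass (dip 0),
a zero-overlap measurement × weighting product raises a degenerate-readout
error, and single-class psychometric data raise a degenerate-data error.

## Known limitations

- The dip statistic's tie handling is exact only to ~1e−10 (the
  deterministic spread); irrelevant for continuous estimates.
- θ_s is weakly identified when the true single-task weighting is nearly
  flat over the grid (see above).
- The bootstrap resamples within design cells; it does not model
  between-session or between-subject variance components.
- No hierarchical model: pooled fits concatenate trials, per-subject fits
  subset them.
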