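# refrep

Encoding-decoding analysis of **reference repulsion** in ensemble-orientation
reproduction.

When observers reproduce the mean orientation of an ensemble of tilted bars
after a reference orientation is shown, their reports are biased *away* from
the reference — most strongly when stimulus and reference nearly coincide —
and the bias changes when an explicit clockwise/counter-clockwise (CW/CCW)
discrimination against the reference precedes the reproduction (dual task)
rather than being absent (single task). `refrep` implements the full analysis
pipeline for this paradigm: factorial design generation, a generative
observer model, maximum-likelihood model fitting with bootstrap, and the
descriptive behavioural statistics, for psychophysicists studying
decision-stage biases in perception.

## The model

Orientations are axial (mod 180°) and expressed relative to the reference.
On each trial the observer encodes the stimulus offset μ as a noisy
measurement

    m ~ N(μ, σ²),   σ ∈ {σ_l, σ_h}  (low / high ensemble noise)

and, at decoding, multiplies the measurement distribution by a weighting
function centred on the reference — a symmetric mixture of two shifted Gamma
densities,

    f(ω) = ½ g(ω; α, θ, δ) + ½ g(−ω; α, θ, δ),
    g(ω; α, θ, δ) = (ω−δ)^(α−1) e^(−(ω−δ)/θ) / (θ^α Γ(α)),  ω > δ,

with separate (α, θ, δ) for the single-task and the dual-task condition.
The normalised product is the readout density of the reproduced offset; a
constant motor bias ε translates the final estimate. Nine parameters in all:
σ_l, σ_h, (α_s, θ_s, δ_s), (α_d, θ_d, δ_d), ε. The same internal sample that
drives reproduction also determines the dual-task CW/CCW choice (its sign,
pre-ε), keeping discrimination and reproduction self-consistent.

The descriptive layer provides relative estimates Δω = ω̄ − ω_ref wrapped to
(−90°, 90°], cumulative-Gaussian psychometric fits with lapse/guess rates,
Hartigan's dip test of unimodality (exact GCM/LCM statistic, Monte-Carlo
uniform null), symmetric Gamma-mixture histogram fits (variance summary
αθ²), implicit-correctness trial selection, and repulsive-bias curves
(bias = sign(offset)·(estimate − offset), positive = repulsion).

## Worked example

```python
import refrep as rr
from refrep.stats import dip_test, repulsive_bias_curve, select_correct_trials

trials = rr.generate_session(5, 5, seed=1)           # 1560-trial session
data = rr.simulate_session(trials, rr.DEFAULT_OBSERVER, seed=2)

dual = data[data.task == "dual"]
print("dual-task dip:", dip_test(dual.estimate_rel_deg, seed=0))

bias = repulsive_bias_curve(select_correct_trials(data))
aligned = bias[bias.abs_offset_deg == 0]
print(aligned[["task", "noise_level", "mean_bias_deg", "sem_deg", "n"]].to_string(index=False))

fit = rr.fit_model(data, n_restarts=2, random_state=0)
print("sigma_low:", round(fit.params_hat.sigma_low, 2),
      "sigma_high:", round(fit.params_hat.sigma_high, 2),
      "delta_dual:", round(fit.params_hat.weighting_dual.delta, 2))
```

prints

```
dual-task dip: DipResult(statistic=0.13486703484913004, p_value=0.0004997501249375312, n=780, degenerate=False)
  task noise_level  mean_bias_deg  sem_deg  n
  dual        high       8.117889 0.316959 30
  dual         low       7.114835 0.342509 30
single        high       4.875180 0.678342 30
single         low       4.431420 0.690357 30
sigma_low: 5.17 sigma_high: 6.4 delta_dual: 3.93
```

The dual-task estimate distribution is bimodal (dip p ≈ .0005: estimates
cluster on either side of the reference), the repulsive bias at alignment is
about 7–8° in the dual task versus 4–5° in the single task, and refitting
the model to its own simulated session recovers the generating measurement
SDs (5.0, 6.5) and dual weighting shift (4.0) closely.

The same pipeline is available from the shell:

```sh
refrep design  --out run --seed 1
refrep simulate --out run
refrep analyze --out run          # psychfit.json, dip.json, gammamix.json,
refrep report  --out run          # bias_curve.csv, sd_summary.csv, figures
```

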