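# erpdecon

Overlap-corrected regression estimates of event-related responses from
continuous multichannel time series.

## The problem

Event-related responses (ERPs and their analogues in pupillometry, EMG,
fNIRS, …) are classically estimated by cutting the continuous recording
into epochs around event onsets and averaging. When the response to one
event has not decayed before the next event arrives — fast stimulus
streams, stimulus–response pairs, eye-movement-locked analyses — the
epochs contain superpositions of neighbouring responses and the average
is biased in ways that can mimic or mask real effects.

Because the recorded signal is (to good approximation) the *sum* of the
individual responses, the fix is linear: model the whole continuous
recording at once and let overlapping responses explain the signal
jointly. `erpdecon` builds that model, solves it, and turns the
coefficients back into interpretable waveforms.

## The model

For channel data $y(t)$ sampled at rate $f_s$, events $i$ with onsets
$o_i$, predictors $x_{i,c}$ (from a Wilkinson formula such as
`y ~ 1 + cat(condition) + spl(luminance, 5)`), and a local-time window
$\tau \in [\tau_{\min}, \tau_{\max}]$:

$$y(t) \;=\; \sum_i \sum_c x_{i,c}\, \beta_c(t - o_i) \;+\; \varepsilon(t)$$

Each predictor gets a full coefficient *time-course* $\beta_c(\tau)$ —
a regression ERP. Discretizing $\tau$ (stick/FIR basis, optionally
compressed through a spline or truncated Fourier basis) makes this one
sparse linear model over all samples: the time-expanded design matrix
$X_{dc}$ has one row per sample and one column per (predictor, local
time) pair, with overlapping windows summing in shared cells. Solving
least squares on $X_{dc}$ *is* the deconvolution. Non-linear covariate
effects enter as cubic B-spline bases (GAM terms) with quantile-spaced
knots; circular predictors use periodic splines; artifacts are handled
by blanking rows rather than cutting the recording.

## Worked example

Nineteen auditory-like responses, each lasting 0.6 s, packed into a 5 s
recording (mean inter-event interval 0.25 s) — every sample is a
superposition of two or three responses:

```python
import numpy as np
import erpdecon as ed
from erpdecon.formula import ModelSpec
from erpdecon.timeexpand import TemporalBasis

# --- Part 1: exact recovery under heavy overlap (noise-free) -----------
scenario = ed.preset("fig10_erp")      # 5 s at 100 Hz, ISI ~ N(0.25 s, 0.05 s)
data, events, truth = ed.simulate(scenario, seed=1)
print(f"{len(events)} events in {data.shape[1]} samples "
      f"(kernel lasts {truth['stim']['kernel_duration']:g} s -> heavy overlap)")

spec = ModelSpec("y ~ 1", window=(0.0, 0.6))
design = ed.build_design(events, spec)
window = ed.local_window(0.0, 0.6, scenario.srate)
onsets = ed.onsets_to_samples(events["onset"], scenario.srate)
expanded = ed.time_expand(design, onsets, window, TemporalBasis("stick"),
                          data.shape[1], "stim", scenario.srate)
fit = ed.fit_lsmr(expanded, data)

kernel = truth["stim"]["intercept_kernel"]
naive = ed.cut_epochs(data, onsets, window)[0][0].mean(axis=0)
print(f"deconvolution max error: {np.abs(fit.coefficients[0] - kernel).max():.2e}")
print(f"naive epoch average max error: {np.abs(naive - kernel).max():.2f}")

# --- Part 2: collinear covariates, ridge shrinkage ---------------------
scenario = ed.preset("fig7")           # 38 events, noise sd 1, covariates r = 0.85
data, events, _ = ed.simulate(scenario, seed=1)
spec = ModelSpec("y ~ 1 + covariate + random_covariate", window=(0.0, 0.6))
design = ed.build_design(events, spec)
onsets = ed.onsets_to_samples(events["onset"], scenario.srate)
expanded = ed.time_expand(design, onsets, window, TemporalBasis("stick"),
                          data.shape[1], "stim", scenario.srate)

ols = ed.fit_lsmr(expanded, data)
ridge = ed.fit_elasticnet(expanded, data, alpha=0.0)   # lambda by block CV
null_cols = expanded.columns_for("stim", "random_covariate")
print(f"null-covariate course variance: OLS {np.var(ols.coefficients[0, null_cols]):.3f}, "
      f"ridge {np.var(ridge.coefficients[0, null_cols]):.4f}")
```

Output:

```
19 events in 500 samples (kernel lasts 0.6 s -> heavy overlap)
deconvolution max error: 1.18e-09
naive epoch average max error: 1.30
null-covariate course variance: OLS 0.184, ridge 0.0050
```

The deconvolved waveform matches the generating kernel to nine decimal
places while the naive average is off by more than the response
amplitude; with two correlated covariates of which only one drives the
signal, cross-validated ridge suppresses the spurious time-course that
ordinary least squares hallucinates for the null covariate.

The same pipeline is available from the command line:

```bash
erpdecon simulate --preset fig10_erp --seed 1 --out data/
erpdecon fit analysis.json          # JSON config: recording, events, models
erpdecon massuni analysis.json      # mass-univariate (no deconvolution) twin
erpdecon export out/rerps.csv --out wide/
```

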