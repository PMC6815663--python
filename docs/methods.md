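# Methods

This note defines the statistical model implemented by `erpdecon`, the
assumptions it rests on, every user-facing parameter with its default
and rationale, what the bundled simulator does and does not emulate,
and the numerical choices that matter for reproducing results.

## 1. Model

### 1.1 Continuous-time regression with overlap correction

Let $y(t)$ be one channel of a continuous recording sampled at
$f_s$ Hz, and let events $i = 1..N$ of one or more types occur at
onsets $o_i$ (seconds). Each event carries predictor values
$x_{i,c}$, $c = 1..C$, obtained from a model formula (section 1.3).
The signal is modeled as a linear superposition of event-locked
responses plus noise:

$$y(t) = \sum_{i} \sum_{c} x_{i,c}\,\beta_c(t - o_i) + \varepsilon(t),$$

where $\beta_c(\tau)$ is the coefficient time-course of predictor $c$
over local time $\tau \in [\tau_{\min}, \tau_{\max}]$ and is zero
outside that window. Discretizing $\tau$ on the sample grid turns this
into a single sparse least-squares problem

$$y = X_{dc}\,\beta + \varepsilon,$$

where the time-expanded design matrix $X_{dc}$ has one row per
continuous-time sample and one column per (predictor, local-time basis
function) pair. Row $t$ receives the entry
$x_{i,c}\,T_{k,b}$ in column $(c, b)$ for every event $i$ and local
sample $k$ with $o_i + k = t$; entries from overlapping windows **sum**
in shared cells. Solving the least-squares problem therefore
deconvolves the overlapping responses: where windows overlap, the rows
constrain sums of coefficients, and variability in the inter-event
intervals makes the individual curves identifiable.

Assumptions: responses superpose linearly; the response shape does not
depend on the local overlap context (no refractoriness/adaptation
beyond what covariates encode); noise is zero-mean and uncorrelated
with the event structure. Estimation is per channel; channels share the
design.

### 1.2 Temporal bases

The local-time transform $T$ ($n_{\text{local}} \times n_b$) is one of:

- **stick** (default): identity; one free coefficient per local sample
  (FIR basis). Unbiased, maximal variance.
- **spline**: clamped cubic B-splines on $n_{\text{basis}} - 2$ equally
  spaced breakpoints spanning the window (boundary knots repeated to
  multiplicity 4). A smoothness constraint; no column is dropped because
  local time carries no separate intercept. Requires
  $n_{\text{basis}} \ge 4$.
- **fourier**: a constant column $1/\sqrt{n}$ plus $\cos$/$\sin$ pairs
  at integer frequencies $1..K$ cycles per window, all columns
  $\ell_2$-normalized and pairwise orthogonal. Acts as an exact
  low-pass: fitted courses carry no spectral energy above harmonic $K$.

### 1.3 Formulas and instance-level design

Model formulas use Wilkinson notation: `y ~ 1 + cat(cond) + luminance`,
with `a*b = a + b + a:b`, `0 +` to suppress the intercept, and three
spline term functions: `spl(x, n)` (cubic B-splines, quantile knots),
`circspl(x, n, lo, hi)` (periodic cubic splines on `[lo, hi]`), and
`2dspl(a, b, n)` (tensor product, $n^2$ columns). Spline terms cannot
appear inside interactions. Categorical predictors use treatment coding
by default (alphabetically first level as reference unless overridden),
so the intercept course is the reference-condition waveform and other
courses are difference waves; effects (sum-to-zero) coding is available.

**Quantile knots.** For `spl(x, n)` the breakpoints are the
$n - 2$ empirical quantiles of $x$ at levels `linspace(0, 1, n-2)`
(including min and max), with boundary knots repeated to multiplicity
4: `len(knots) = n + 4` and the basis satisfies the partition of unity
on `[min(x), max(x)]`. Quantile placement spends resolution where the
data are. Out-of-range evaluation clamps to the boundary. Requires
$n \ge 4$ and a non-degenerate predictor.

**Identifiability.** A B-spline basis sums to one everywhere, so with
an intercept in the model one spline column is redundant. The column
whose basis function peaks nearest the predictor's median is dropped
(for tensor terms, the product column nearest the two medians). Spline
effects are therefore relative to the response at that reference point.

**Cyclic splines.** `circspl` builds cubic B-splines on uniform knots
over the cycle and folds the three wrap-around columns back onto the
first basis functions, yielding an exactly periodic, shift-invariant
basis ($n \ge 3$).

## 2. Estimation

- **`fit_lsmr`** (default): sparse iterative least squares (LSMR), one
  solve per channel, stopping tolerances `atol = btol = tol` with
  default `1e-10` (far below any scientific tolerance; raise for
  speed on very large problems). The iteration cap defaults to
  `10 * n_columns + 100`; hitting it raises a warning and flags the fit
  as non-converged in the metadata.
- **`fit_elasticnet`**: penalized estimates minimizing
  $\tfrac{1}{2n}\lVert y - X\beta\rVert^2 + \lambda(\alpha\lVert\beta\rVert_1 + \tfrac{1-\alpha}{2}\lVert\beta\rVert^2)$.
  `alpha` is the L1 mixing ratio (0 = ridge, 1 = lasso). $\lambda$ is
  chosen per channel by $K$-fold cross-validation (default 5) over a
  log-spaced path (default 20 values down to $10^{-3}\lambda_{\max}$);
  folds are **contiguous temporal blocks**, because samples of a
  continuous recording are autocorrelated and shuffled folds would leak
  information. Pure ridge uses an exact damped LSMR solve; mixed
  penalties use coordinate descent.
- **`fit_mass_univariate`**: the comparison twin without overlap
  correction — per-local-sample OLS on epoched data, organized exactly
  like a stick-basis fit so conversion and export are shared. With
  non-overlapping events it coincides with the deconvolution estimate;
  with overlap it shows the bias the deconvolution removes.

**Artifacts.** Contaminated stretches are detected by a moving-window
peak-to-peak threshold (window length `winlen` seconds, step
`winlen/2` by default, flagged on any channel) and stored as merged
half-open sample intervals. Fitting then zeroes the affected design
rows **and** the response at those samples: contaminated samples carry
no leverage, clean parts of every trial still contribute, and the
residual-based noise estimate `sigma` is computed over unblanked rows
only so it stays interpretable as the noise scale.

## 3. Parameters (defaults and units)

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `window` | — (required) | s | Analysis window in local time; inclusive of both rounded endpoints. |
| temporal basis | `stick` | — | Unbiased FIR estimate; compress only when undersampled. |
| `spl` basis size | — (required) | count | ≥ 4; quantile knots. |
| coding | `treatment` | — | Reference-condition intercept; difference waves. |
| solver `tol` | `1e-10` | — | Effectively exact; see §2. |
| elastic-net `alpha` | `0.0` | — | Ridge: collinearity-driven variance is the usual failure mode. |
| CV folds | `5` | count | Contiguous blocks. |
| artifact `winlen` | `2.0` | s | Pipeline default for slow drifts; set per modality. |
| artifact `step` | `winlen/2` | s | Half-overlapping windows cover boundary-straddling artifacts. |
| imputation | `drop`/`mean`/`median`/`marginal` | — | `marginal` requires a seed; `drop` warns that remaining-overlap correction is lost for dropped events. |

## 4. Simulator

`erpdecon.simulate` generates ground-truth recordings for validation:
event trains with truncated-normal inter-event intervals (floored at 2
samples), covariates with uniform/normal/choice marginals optionally
correlated through a Gaussian copula, per-event responses as gain ×
kernel with constant, linear, logarithmic, or indicator gains, and
i.i.d. Gaussian noise. Kernels: boxcar, Dirac impulse, a three-Gaussian
auditory-ERP shape, seeded 1/f ("pink") noise normalized to unit peak,
or custom samples. A trial specification links a response event to each
stimulus through per-condition normal reaction times. Presets cover the
standard validation scenarios (`fig10_*`: 5 s, ISI ~ N(0.25 s,
0.05 s), noise-free, one kernel each; `fig7`: 38 events, an effective
covariate plus an r = 0.85-correlated null covariate, noise sd 1;
`fig1`: a face/house experiment with luminance, N170 face effect, and
motor responses). Identical scenario and seed give bitwise-identical
output (events and noise use independent seeded streams).

The simulator emulates linear superposition only. It does **not**
emulate non-linear overlap interactions, autocorrelated or non-Gaussian
noise, drifting baselines, channel covariance structure (multichannel
data share the clean signal with independent noise), or latency jitter
of the response shape itself.

## 5. Numerical choices

- **Onset rounding:** onsets map to samples by `rint` (half-to-even);
  local windows include both rounded endpoints; local sample $k$ has
  time $k / f_s$. Kernels have `round(duration*srate) + 1` samples to
  align with inclusive windows.
- **Sparse accumulation:** the expansion is assembled in COO form and
  converted to CSR, which sums duplicate (row, column) entries — this
  conversion *is* the overlap summation. Out-of-range local samples are
  truncated (partial windows at recording edges).
- **Spline evaluation** uses `scipy.interpolate.BSpline.design_matrix`
  with input clamping; the test suite checks it against an independent
  Cox–de Boor recursion to 1e-10.
- **Degenerate designs:** all-zero predictor columns warn; NaNs in the
  design raise (impute first); more columns than samples warns
  (underdetermined); LSMR then returns the minimum-norm solution.
- **Export precision:** long-format CSV uses 12 significant digits,
  sufficient for float round-trips at the tested tolerances.

## 6. Limitations

- Linear superposition is assumed, not tested; strong refractoriness or
  adaptation violates it (covariates can absorb known modulations).
- Deconvolution needs ISI variability; near-constant ISIs make the
  design ill-conditioned, and regularization then biases the shape.
- Cross-validated $\lambda$ minimizes prediction error, which is not
  the same as unbiased effect estimation; ridge estimates are shrunk.
- Per-channel independent fitting ignores spatial structure.
- The mass-univariate twin requires complete epochs and silently drops
  boundary events (reported in its keep mask).
- Statistical inference (standard errors, cluster tests) is out of
  scope; the package estimates waveforms and residual scale only.
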