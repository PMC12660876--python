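# Methods

## Task process

Each session is a sequence of `T = 420` binary stimuli drawn
`s_t ~ Bernoulli(h_t)`. The hidden probability `h_t` is piecewise constant:
at each step it changes with hazard `λ = 1/75`, and a change is forced when
a run reaches 300 trials (run lengths are drawn geometrically and capped,
which is equivalent to per-step hazard with a cap). At the start and at
every change point, `h` is redrawn uniformly on [0.1, 0.9], rejected until
the odds `h/(1−h)` change by a factor of at least 4 in either direction
(always satisfiable on this support). Report periods interrupt the stream
after trial intervals of `22 + U{−3..3}`; each period lasts 10 s (two 5-s
response screens, probability then confidence). Stimuli last 1 s with an
SOA of 1.3 s, so a session runs ≈ 12.5 min including a 16-s rest tail;
stimulus timing, hazard, support, odds factor, and report spacing are the
printed design parameters, while screen durations are a package choice.

## Ideal observer

The observer knows the generative process and runs a grid filter
(default: 100 equally spaced points spanning the generative support, which
keeps posterior summaries within ~1e−8 of a 1000-point reference for these
smooth posteriors):

    p(h_{t+1} | s_{1:t+1}) ∝ p(s_{t+1} | h_{t+1}) ·
        [(1 − λ) p(h_t | s_{1:t}) + λ π(h_{t+1})]

with `π` the resampling prior, by default uniform on the support. The
transition kernel is this two-component mixture only; it does not model the
odds-factor or max-run constraints. Scalar read-outs per trial:

- probability estimate `p̂_t`: mean of the distribution,
- confidence `c_t = −log SD` (natural log; log precision up to a factor 2),
- Shannon surprise `−log p(s_t)` and outcome entropy, both from the
  predictive probability of the trial's stimulus.

**Timing convention.** By default `p̂_t` and `c_t` are read from the
*predictive* distribution held before observing `s_t` — the same quantity
that defines the surprise of `s_t` — with the post-update (filtered)
convention available as an option. The filtered posterior is used for the
values shown/reported at report screens.

An exact oracle computes the posterior by summing over all `2^(T−1)`
change-point configurations (feasible to T = 12); the filter is tested
against it exhaustively for all sequences up to length 8.

## Encoding models

A unit's activity is modeled as a function of the estimate `x` (probability
or confidence): linear `ŷ = wx`, or versatile `ŷ = Σᵢ wᵢ fᵢ(x)` with
K = 10 basis functions whose centers sit at `a + i(b−a)/(K+1)`. Gaussian
widths are σ = 0.04 on the probability domain [0, 1] and σ = 0.06 on the
confidence domain [1.1, 2.6]; for other K the width scales with the center
spacing so the basis sum stays approximately flat (translation invariance).
Basis amplitude is 1 (scale is absorbed by the regression). Confidence
values outside the domain are clamped to the boundary with a logged count.
A posterior-expectation variant replaces `fᵢ(x)` with `∫fᵢ(x)p(x)dx` under
the trial's (predictive) posterior, computed as a grid sum; it applies to
probability only, since the posterior is over the hidden probability.

Regressors are built by placing each modulator as an impulse at the
stimulus onset on a 0.1-s grid, convolving with a canonical double-gamma
HRF (peak 6 s, undershoot 16 s, unit dispersions, ratio 1/6, 32-s support;
all configurable), and sampling at TR = 2 s. No-interest regressors:
stimulus constant, surprise, entropy (dropped when entropy is itself the
modeled estimate), report-screen constant/normative value/reported value,
and optional motion confounds. Scans per session = ceil(session duration /
TR).

**Temporal preprocessing**, applied identically to data and regressors:
per-session linear detrend; high-pass at 1/128 Hz implemented as projection
on an orthonormal DCT drift basis (components with frequency below the
cutoff); z-scoring across the concatenated sessions; per-session
demeaning. Columns reduced to float-epsilon residue (e.g. constant input)
are zeroed rather than amplified by the z-scoring.

## Fitting and the z-R² score

Weights are fitted by closed-form ridge regression without intercept
(`w = (XᵀX + λI)⁻¹ Xᵀy`), one shared penalty across units; the default
λ = 1 on the z-scored regressors was retained after a simulation grid
search over {1, 10, 100, 1000} (larger penalties raised matched scores
slightly but raised cross-estimate leakage more; a grid-search utility is
provided). Evaluation is leave-one-session-out: fit on three sessions, and
on the held-out session predict using the interest regressors only (the
no-interest regressors are session-demeaned, so this equals replacing them
by their session mean). The score is the sums-of-squares R² (which may be
negative), standardized against a null distribution obtained by rebuilding
the interest regressors from 100 replacement sequences drawn from the same
task process: `z-R² = (R² − μ₀)/σ₀`, averaged over folds.

Null details: the 100 sequences are drawn once per evaluation and shared
across folds and units; the true session supplies stimulus timing and
report schedule (only the stimulus values, hence the estimates, are
replaced); null columns are preprocessed like the true ones with the
z-scoring scale frozen from the true design, keeping predictions on one
scale. Units whose null distribution degenerates (σ₀ = 0) are flagged and
excluded with a warning.

## Synthetic experiments and model recovery

A simulated voxel is `y = X_interest w + ε`, with the generative model's
interest weights drawn uniformly in [−0.5, 0.5] (per voxel, constant across
sessions) and Gaussian white noise of power `noise_ratio = 9` times the
signal (10% signal). Signals are built from the preprocessed regressors;
the noisy series then passes through the same preprocessing during
evaluation (idempotent for the signal part). Simulated reports (needed only
as no-interest regressors) are the normative value plus Gaussian noise
(sd 0.1 on the unit scale), discretized to the 3- or 5-range probability
scale (chosen at random per period) and the 5-level confidence scale.

The recovery analysis crosses generative models (linear/versatile ×
probability/confidence, optionally + linear entropy) with fitted models
through the full z-R² pipeline and reports the generative × fitted mean
z-R² matrix and the fraction of experiments each fitted model scored best.
Desk-scale default: 10 experiments × 20 voxels (the headline simulation in
the field runs 100 × 100; scale is configurable). Designs and null columns
are shared across generative models within an experiment — they depend
only on the session data — which keeps the desk scale at ~40 s on one CPU.

**Known limitation — cross-estimate leakage.** Probability and confidence
time courses of the *same* sequence are intrinsically coupled (extreme
estimates co-occur with high confidence), and the sequence-replacement
null removes only sequence-generic structure. A wrong-estimate model can
therefore retain a small fraction of a null-SD of genuine predictive power
at desk scale: in the default recovery run, cross-estimate cells sit
within ±0.1–0.3 z units of zero while matched cells reach 1.8–2.5 and the
best-fitting model equals the generative one in 95% of runs. The
surprise/entropy no-interest covariates absorb most, not all, of the
coupling.

## Tuning-curve characterization

Curves are reconstructed as `f(x) = Σᵢ wᵢ fᵢ(x)` on a 201-point grid over
the domain (resolution is a package choice). Measures:

- argmax location, classed *non-extreme* when at least 20% of the span
  from both bounds (ties resolve to the lowest x);
- non-monotonicity `n(f) = 1 − |f(b) − f(a)|/(f_max − f_min)`; `m = 1 − n`
  equals 1 for every monotonic curve (necessary, not sufficient);
- nonlinearity `ν(f) = 1 − R²` of an ordinary least-squares line;
- peak count on the min-max-normalized curve with height ≥ 0.7 and
  topographic prominence ≥ 0.125 (`scipy.signal.find_peaks`, verified
  against an exhaustive prominence oracle).

Constant curves are flagged degenerate with `n = ν = 0` by convention and
excluded from group summaries. Units of interest are selected by converting
R² scores to empirical-null p-values, `p = (1 + #{null ≥ obs})/(1 + N)`,
against R² of the same pipeline on white noise (default N = 10,000;
1,000,000 is used at full scale), followed by Benjamini–Hochberg FDR at
0.05. Split-half reliability refits the versatile weights on sessions
{1,2} vs {3,4} and correlates them over selected units.

## Decoding and RDM geometry

Patterns are the versatile-model weights refitted with 5 basis functions:
per leave-one-session-out fold, one joint fit on the three training
sessions and a separate fit on the test session, restricted to the top 100
units by z-R² estimated from the training sessions only (inner
leave-one-session-out among the three; when fewer units are available, all
are used). The decoder assigns test bin j the training bin k minimizing the
correlation distance `D(j,k) = 1 − r`, ties to the lowest k. A stimulus
falls in bin j when `fⱼ(x)` exceeds 10% of that function's maximum; bins
with fewer than 5% of the test session's stimuli are dropped from that
fold's accuracy. Chance level is 0.2.

RDMs (asymmetric, nonzero diagonal, since rows come from the test fit and
columns from the training fit) are averaged over folds (invalid rows
ignored) and regressed, over all cells of valid rows including the
diagonal, on two z-scored model RDMs: identity `1[j≠k]` (non-monotonic
code) and graded `|j−k|` (monotonic code; `(j−k)²` available), with an
intercept. The larger coefficient classifies the code. Group helpers run
per-region t-tests of accuracy against chance with BH-FDR and test the
per-participant fraction of "graded" regions against 0.5.

## What the synthetic data do and do not show

The generator reproduces the task statistics, the HRF-convolved signal
chain, and white measurement noise. It does not simulate spatial structure,
physiological/temporally correlated noise, motion, inter-individual
variability in HRF or learning, or real report behavior. Passing tests
therefore establish that the pipeline is *correct and well calibrated*
(unbiased decoder at chance, z-R² centered under noise, generative models
recovered, RDM geometry identified at 10% signal) — not that any particular
brain region encodes probability; that claim needs real data, for which the
entry points accept per-unit time-series matrices, BIDS-style events
tables, confound TSVs, and NIfTI volumes.

## Numerical and design choices

- Grid integrals are plain grid sums; posterior rows normalize to 1 within
  1e−10, and a fully zeroed row raises a numerical error with the trial
  index.
- The enumeration oracle refuses T > 12 (combinatorial explosion).
- Ridge solves use a Cholesky factorization of the Gram matrix; non-finite
  inputs are rejected.
- Argmin/argmax ties always break toward the lower index/value for
  determinism.
- All randomness flows through `numpy.random.Generator`s seeded from a
  single per-run seed; identical seeds give bit-identical sequences,
  experiments, and output files (manifests record config, seed, version).
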