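# Methods

## Observer model

The dynamic Bayesian observer treats the stop rate `r` as a first-order
Markov process: with probability `α` it persists across trials, with
probability `1 − α` it is resampled from a fixed beta prior `π(r)` with mean
`pm` and concentration `sc` (`beta(pm·sc, (1−pm)·sc)`).  The predictive
belief for trial `k` is the mixture `α · posterior_{k−1} + (1−α) · π`, and
the Bernoulli likelihood of the observed trial type updates it.  P(stop) on
trial `k` is read off the predictive distribution *before* the outcome is
seen; trial 1 reads the generic prior (the natural convention for an
observer with no history).  On stop trials the prediction error is
`1 − P(stop)`.

**Belief representation.**  The `α`-mixture destroys beta conjugacy, so
beliefs live on a fixed midpoint grid over (0, 1) with `grid_size` cells
(default 200; Riemann masses, renormalized after every step).  At `α = 1`
the model reduces to exact beta-Bernoulli updating, giving a closed-form
check: the predictive mean must equal `(a + Σs)/(sc + k − 1)` at every
trial, and the 200-cell grid tracks both that closed form and a 4000-cell
oracle to better than 1e-3 under the mean readout.

**Readout.**  `P(stop)` may be the predictive mean (the exact predictive
probability) or the MAP point; the default is MAP, with ties resolved to the
lowest grid point.  One consequence worth knowing: the mixture predictive is
often bimodal (a data-driven bump plus the prior mode), and the argmax of a
bimodal density is a discontinuous functional.  Refining the grid therefore
cannot make the MAP trace converge uniformly — on ~1–2% of trials of a long
random sequence the 200- and 4000-cell argmaxes sit on different modes
(jumps ~0.1) while all remaining trials agree to within half a grid cell.
The mean readout has no such discontinuity; tests assert strict fine-grid
equivalence for the mean and the mode-flip-tolerant form for MAP.

**Fitting.**  Per subject, every `(α, pm)` pair on the published grid
(49 × 25 points, `sc = 10`) is run over the full go/stop sequence and the
P(stop) trace is Pearson-correlated with RT over successful go trials only
— stop trials inform the observer but contribute no usable RT, and
premature/omitted responses are excluded.  Argmax ties resolve to the larger
`α`, then the larger `pm` (deterministic; exact ties arise only in
degenerate data).  The search is vectorized over the whole grid at once;
a test pins it to the scalar path.  Group analyses reuse the arithmetic mean
of the fitted `α` and `pm` across subjects to recompute every subject's
trace.

## Behavioral generator and its calibration

The simulated responder runs the observer online and races a go process
against a stop process:

    T_go  = rt_base + slowing_slope · P(stop) + N(0, rt_noise_sd)   [ms]
    stop succeeds  iff  SSD + SSRT_true < T_go  (or no press in the window)

with defaults `rt_base = 345`, `slowing_slope = 300`, `rt_noise_sd = 60`,
`SSRT_true = 216`, a 1000 ms response window, 25% stop trials, 1–3 s uniform
foreperiods, and the one-up-one-down SSD staircase (start 200 ms, ±64 ms,
clipped to [0, window]).  Cohorts add a 30 ms-sd between-subject offset to
the go-RT base.  Go omissions arise only from window truncation (no
independent lapse process), so at these defaults the simulated go success
rate is ~100%.

Achieved calibration (pilot, 18 × 400 trials, MAP readout): stop-success
rate 49.5%, mean within-subject sequential-effect r = 0.30, recovered SSRT
218 ms, mean failed-stop RT 341 ms, mean go-RT 379 ms.  The slowing
calibration (345 + 300·P(stop)) and the MAP readout jointly fix the go-RT
scale: the MAP trace averages ~0.10, so mean go-RT sits near 380 ms rather
than ~405 ms, and the failed-stop mean (the fast tail selected by the race)
lands near 341 ms rather than ~360 ms.  Raising mean P(stop) to ~0.2 (the
mean readout) recenters both RT summaries but halves the sequential-effect
correlation to ~0.21; the default calibration keeps the sequential effect —
the quantity the model exists to capture — at its target.

**Critical SSD and SSRT.**  The inhibition function
P(stop success | SSD) is fitted by maximizing the Bernoulli likelihood over
all staircase-generated SSDs under a cumulative-Gaussian family
(Nelder-Mead on (θ, log σ); success probability *decreases* with SSD, 50%
point θ).  A logistic family is available behind a flag and agrees within
10 ms on simulated data.  SSRT is the median successful-go RT minus θ.  The
estimator needs ≥ 20 stop trials, ≥ 3 distinct SSDs and mixed outcomes;
staircase data satisfy this comfortably.  The P(stop)-binned group curves
average within subject per 0.01-wide bin, then across subjects, and drop
bins carried by ≤ 2 subjects.

## EEG generator

Each epoch is 1/f background noise (spectral shaping of white noise,
exponent 1.0, 15 µV RMS) plus one Gaussian-windowed sinusoidal burst with
uniform random phase whose **amplitude** is `max(0, base + gain · z(cov))` —
linear in the z-scored covariate so every monotone power measure preserves
the planted rank correlation.  Placements mirror the three effects under
study: fixation-locked 4 Hz at 100 ± 50 ms (covariate P(stop), gain +2 µV),
go-locked 4 Hz at 450 ± 120 ms (covariate RT, gain −1.6 µV), stop-locked
16 Hz at 350 ± 25 ms (covariate PE, gain +4 µV), base 6 µV.  Epochs carry
1 s of padding beyond the −0.5…1.0 s analysis window; artifact trials
(rate 0.05) get a 200 µV square pulse to exercise the 150 µV peak-to-peak
rejection rule.  Single channel only: the statistics under study are
channel-local, so a montage would add nothing the tests could see.

**Why these gains.**  The planted single-trial Spearman correlation is
~0.08 per subject — deliberately in the weak regime typical of within-
subject EEG-behavior coupling.  The choice is a genuine trade-off: group
detection needs `z̄ ≈ ρ√n_trials` large, while the *null* pairs (P(stop) on
go-locked power, RT on fixation-locked power) inherit a leaked correlation
of `r(pstop, RT) × ρ ≈ 0.3ρ` that must stay below the cluster-forming
threshold.  At ρ ≈ 0.08 the planted pairs reach p_perm ≈ 0.001–0.04 and the
dissociation pattern holds in ~5/6 of replicate cohorts; materially stronger
gains provably break the dissociation, materially weaker ones lose
detection.  A corollary: the emergent across-trial correlation between the
P(stop)- and RT-cluster powers is only ≈ −0.3ρ², a few thousandths, so the
pipeline's Wilcoxon on those coefficients is usually null on synthetic
cohorts; the mechanism itself is tested separately with an explicit shared
latent factor.  What passing tests show is that the *analysis machinery*
detects and dissociates weak planted effects at realistic sizes — not that
real EEG looks like 1/f noise plus one burst; phase-locked components,
multichannel structure and non-stationary artifacts are all absent by
design.

## Time-frequency decomposition

Complex Morlet convolution per frequency bin (default 59 log-spaced bins,
2–50 Hz) on the padded epoch, cropped to the analysis window afterwards so
wavelet edges never touch it (validated by a white-noise flatness test).
The envelope FWHM is specified in periods — 1 at the lowest bin to 4 at the
highest, interpolated linearly across *bin index* (equivalently log
frequency; linear-in-Hz is available behind a flag) — and converted to the
Gaussian sd via `sd = FWHM / (2√(2 ln 2))`.  Wavelets are truncated at ±4 sd
and amplitude-normalized so a unit sinusoid yields peak power 1 at its bin
regardless of frequency; an independent cross-check against MNE's Morlet
implementation (widths matched through `n_cycles = FWHM_periods·2π/(2√(2 ln 2))`)
agrees to r > 0.97 on log power.  Baseline correction divides by
(`P/B − 1`, default) or subtracts the mean −300…−100 ms power per trial and
frequency; a second application raises an error, and zero baseline power is
rejected rather than propagated.

## Cluster statistics

Within subject, Spearman correlations are computed as Pearson correlations
of midranks, vectorized over all bins; the null shuffles the covariate
across retained (post-rejection) trials, each of the 1000 permutations an
independent uniform draw.  `z = (ρ_obs − mean_null)/sd_null`; bins with
degenerate nulls are flagged NaN rather than silently zeroed.

At the group level a two-tailed one-sample t test marks suprathreshold bins
(p < 0.02, 0.005 or 0.001), 4-neighbor adjacency groups them (8-neighbor
behind a flag), positive and negative clusters form separately, and the
cluster statistic is the summed t.  The permutation null flips the sign of
whole subject z-maps — the exchangeability argument for a one-sample test
against zero — and records the largest suprathreshold |Σt| across both signs
per iteration (two-tailed family-wise control).  The sign-flip t statistics
are computed in closed form from the flip matrix (the per-bin sum of squares
is flip-invariant), so 2000 iterations cost one matrix product plus
labeling.  `p_perm = max(1, #{null ≥ |Σt|})/n_iter`, quantized in 1/n_iter
steps with attainable minimum 1/n_iter.  Empirical family-wise error on null
maps (18 subjects, 40 × 50 bins, 200 simulations) stays within [0.02, 0.09]
at nominal 0.05 for all three thresholds.  Observed power re-runs the test
with fresh null draws on fixed data and reports the fraction with
p_perm < 0.05.

The cluster-power correlation aligns two locks through their trial indices,
correlates the clusters' mean power across common trials per subject, and
tests the coefficients against zero with a two-tailed Wilcoxon signed-rank
test (a Lilliefors normality p-value is reported alongside, as the choice of
a rank test presumes non-normality).  PE analyses can first residualize
stop-locked power against the stop-success/stop-error condition means,
which exactly removes any outcome-confounded component while preserving
condition-independent covariate correlations.

## Pipeline and problem sizes

`run_study` chains the stages with one master seed (per-subject and
per-stage generators derived from it) and writes trial tables, cluster
tables and a JSON summary.  Defaults follow the reference conditions: 18
subjects, 400 trials, 59 frequency bins at 250 Hz sampling, 1000
within-subject permutations, 2000 group iterations, analysis windows
0–500 ms (fixation- and stop-locked) and 0–800 ms (go-locked).  The test
suite and the worked example run a reduced grid (20 log bins 2–30 Hz, 20 ms
time steps, 300 permutations, 1000 iterations) — chosen as the smallest
setting at which the planted band is well resolved and the permutation
calibration is unchanged — so a full replicate study completes in about half
a minute and the whole suite in minutes.

## Known limitations

* The MAP readout's mode flips (above) make P(stop) piecewise-constant and
  occasionally discontinuous in the grid resolution; analyses that need a
  smooth trace should use the mean readout.
* The go-RT scale of the generator sits ~25 ms below the human reference
  values at the default calibration (see the trade-off discussion above).
* The EEG generator plants one burst per lock and no phase-locked (ERP)
  component; conclusions about mixed evoked/induced regimes need a richer
  generator.
* Stop-locked analyses rest on ~100 trials per subject; the PE effect is
  correspondingly the least reliably detected, as in the reference data.
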