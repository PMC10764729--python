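# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Preprocessing chain

The cleaning chain runs in a fixed order — blink interpolation, sliding
mean, session z-transform, missingness QC, gaze-window QC — and a run
manifest records every threshold.

**Blink interpolation** (`pad_ms = 100`). A blink is any contiguous run
of invalid samples. The pupil values from the last valid sample at
least 100 ms before the gap to the first valid sample at least 100 ms
after it are replaced by the straight line between those two anchors
(touching expansions merge; gaps without an anchor on one side stay
missing). Overwritten samples carry an `interpolated` flag distinct
from raw validity: they are *usable* for the z-transform and feature
windows but count as *missing* for rejection, so interpolation can
never rescue a trial from the missingness rule. Whether interpolated
samples count as missing is a config switch
(`count_interpolated_as_missing`, default true); the stricter reading
was chosen because interpolation fabricates data.

**Smoothing** (`window_ms = 200`). Each pupil value becomes the mean of
all usable samples within ±100 ms, truncated at the session edges (no
padding or reflection — the simplest contract for "the mean of that
window"). At 250 Hz the interior window holds 51 samples.

**Z-transform.** Pupil is standardized over the session's usable
samples with the sample SD (n−1 denominator, used consistently
throughout the package). This removes between-participant differences
in average pupil size and measurement units.

**Missingness rejection.** A trial is dropped when strictly more than
50% of its 6-s anticipation window is missing; a session is dropped
when strictly more than 15% of all samples are missing. Strict
inequalities implement "more than 50%" / "exceeded 15%"; a trial at
exactly the threshold survives. The trial rule is evaluated on the
anticipation window (the analysis window) by default; a `trial`
alternative using the whole trial is a config switch, since the
original protocol is ambiguous on this point.

**Gaze window.** Per participant, the window center is the median gaze
(x, y) over all anticipation samples; the half-widths are shared across
the cohort: 3.3 × the cohort mean of the per-participant gaze SDs.
Trials with gaze outside the rectangle for (cumulatively, over valid
samples) more than 1 s are dropped. Cumulative-vs-consecutive is a
config switch (`gaze_outside_mode`); cumulative is the stricter default.

## Dilation features

"Pupil dilation" is a rate: the mean first difference of the cleaned
trace divided by the sample period, over an analysis window — which
telescopes to (last − first) / elapsed time on a gap-free window, an
identity the tests assert to 1e-10. Dilations are computed per trial
and then averaged within condition × phase cells over surviving trials
only, so QC acts at trial resolution; the differential score is the
exact difference of cell means. Phases: anticipation (cue onset →
offset, 6 s), fixation (fixation onset → cue onset), consumption (the
1.5-s feedback display, successful reward/neutral trials only).
Unrecovered gaps inside a window simply drop their adjacent first
differences.

Split-half reliability: per participant, the differential score is
formed separately from trials 1–5 and 6–10 (position within condition,
dropped trials excluded from the means but not from the numbering) and
the two halves are correlated across participants. No Spearman–Brown
step-up is applied: the half-based value is itself the plug-in the
uncertainty model uses, which makes the measurement-noise correction
slightly conservative-to-neutral (see "Known limitations").

Clinical derivations: anhedonia score = BDI items 4 + 12 + 21;
"acutely depressed" = diagnosed group with ≥ 5 current symptoms.

## The latent correlation model

Latent pairs (ξᵢ, ηᵢ) are bivariate normal with uniform priors on
(μₓ, σₓ, μᵧ, σᵧ, ρ); observed values add independent Gaussian noise
with fixed SDs `SD·√(1−R)`. Because one noise SD applies per
instrument, the per-pair latents are marginalized analytically: the
observations are bivariate normal with covariance
[[σₓ²+seₓ², ρσₓσᵧ], [ρσₓσᵧ, σᵧ²+seᵧ²]], which reduces the likelihood
to five sufficient statistics and makes each evaluation O(1) in n. The
data type still carries per-observation SEs so heteroscedastic
extensions fall back to the per-observation likelihood. Symptom counts
enter the Gaussian model as continuous values (a deliberate
simplification; see limitations). If data fall outside the prior
support the location/scale bounds widen with a warning rather than
silently truncating the fit.

**Sampler.** The posterior is sampled in transformed coordinates
(μ, log σ, atanh ρ) with the Jacobian keeping the priors uniform on the
original scale. The engine is a whitened random-direction slice sampler:
each update slices along a direction drawn through a whitening matrix
that is re-estimated once mid-warm-up from the warm-up draws
(stepping-out plus shrinkage; no step-size tuning). Slice sampling was
chosen after ensemble-move MCMC demonstrably failed to equilibrate the
curved ρ tails of the small-n posterior: against three independent
integration oracles (two grid discretizations and prior-box importance
sampling) the ensemble sampler's 95% interval was systematically
0.03–0.04 too narrow at n = 10 regardless of chain length, while the
slice sampler converges to the oracle. Defaults: 4 independent chains,
5000 kept draws per chain after 1000 warm-up iterations; split R-hat
(arviz, rank-normalized) above 1.01 first earns up to two chain
doublings and then raises an error carrying the diagnostics. All chains
are seeded; a fit is bit-reproducible from (data, settings, seed).

**Directional Bayes factor.** BF₍₋₎ = (draws below zero)/(draws above
zero), the posterior counting rule under the symmetric uniform prior
(prior odds 1:1), not a Savage–Dickey density estimate. When no draw
crosses zero the total draw count is reported with a lower-bound flag.

**Default Bayes factors.** The correlation BF integrates the exact
reduced likelihood of r given ρ (via the Gaussian hypergeometric
function) against a stretched-beta prior of width κ (κ = 1, the flat
default, matching the conventional software default; κ is a parameter).
The two-sample BF integrates the noncentral-t density of the observed
statistic against a Cauchy(0, √2/2) prior on the standardized effect.
Both are checked against independent fine-grid quadratures in different
parameterizations and against `pingouin`'s closed forms to < 1%.
Degenerate inputs (|r| = 1) return a capped value (1e12) with a flag.

## The synthetic-study generator

The generator emulates the study design the pipeline targets: 30 trials
(10 per condition, pseudo-randomized with no 3 alike in a row), each
fixation (uniform 2–4 s; the protocol does not state its jitter) → 6-s
cue → 0.5-s flash/response → 1.5-s feedback (reward and neutral only),
sampled at 250 Hz with gaze and validity streams.

Latent structure:

* Arousal trait a ~ N(0,1). Anticipation ramps are linear with
  per-condition slopes 0.30/0.20/0.10 z/s whose contrast against
  control scales with the trait (sensitivity 0.5, floored so slope
  ordering holds); linearity suffices because the analysis consumes
  only the mean derivative. The control slope is trait-free, so only
  reward (strongly) and neutral (weakly) per-stimulus dilations couple
  to symptoms.
* The symptom latent is a Gaussian copula of the trait with correlation
  −|true_rho|, divided by the discretization attenuation corr(w, g(w))
  (computed by quadrature) so the planted correlation survives the
  mapping to a 0–20 count exactly. The count margin mixes a healthy
  zero mass with a negative-binomial-shaped severity distribution;
  observation noise at `symptom_reliability` (default 0.78) separates
  the latent from the reported count, matching the inference model's
  plug-in.
* BDI items are 0–3 ordinal readouts of the symptom latent; a
  configurable subset (default 4, 15, 21 — loss of pleasure, loss of
  energy, loss of sexual interest) loads additionally on (low) arousal,
  giving the item screen its specificity pattern.
* Trial-to-trial slope jitter is set through the Spearman–Brown
  relation for a 5-trial half so the *pipeline-measured* split-half
  reliability converges to `reliability_target` (default 0.87). Two
  one-time calibration constants enter this mapping, measured on the
  default design (n = 300, five seeds, jitter off): the session
  z-transform shrinks the between-participant differential variance to
  ≈ 0.81 of its raw value, and the slow drift leaves a residual
  differential half-score noise of (0.0136 · drift_sd)². These
  constants are part of the generator's definition; changing the task
  geometry or drift spectrum materially would require re-measuring them.
* Slow 1/f-like pupil drift (three sinusoids, periods 240/160/104 s,
  amplitude² ∝ period, random phases, total SD 1.5 z) dominates session
  variance, as spontaneous arousal fluctuations do in real recordings —
  without it the z-transform would divide out the very signal under
  study. Each session's drift is normalized to the exact target SD: a
  handful of sinusoids does not self-average the way a true 1/f process
  does over a session, and the phase-dependent realized variance would
  otherwise reappear as spurious between-participant scale noise after
  z-scoring. Drift slope is nearly constant within a trial and largely
  cancels in the differential score.

Artifacts are planted and recorded: Poisson blinks (8/min, 100–400 ms),
whole-trial missing runs covering 62% of the anticipation window
(guaranteed past the 50% rule), and gaze excursions in two duration
bands (0.3–0.8 s and 1.2–2.5 s) straddling the 1-s rule, placed in
blink-free spans so QC decisions are exactly predictable from the
ground truth.

What the generator does **not** emulate: pupillary light reflexes,
saccadic or oculomotor dynamics, luminance effects, realistic blink
envelopes (gaps are rectangular), or the empirical group structure of
clinical cohorts — in particular, the zero-symptom healthy margin sits
at the top of the simulated arousal continuum, so simulated group
contrasts and item screens come out stronger than in typical clinical
cohorts, where the coupling lives mostly within patients. Passing
tests therefore demonstrate the correctness of the pipeline and the
statistics under the stated generative assumptions, not the clinical
effect sizes themselves.

## Numerical choices and degenerate inputs

* Sample SD (n−1) everywhere; windows include both boundary samples;
  event times snap to the sample grid.
* A fully invalid series, zero pupil variance, a gaze window with zero
  half-width, and fewer than 3 complete participants for a reliability
  or correlation are hard errors, never silent NaNs.
* Cells with no surviving trial are NaN with `n_trials_used = 0` and
  drop out of correlations; session-dropped participants are omitted
  from the feature table entirely.
* Readers of the TSV contracts validate on load and name the offending
  participant/row; writers emit `%.17g` floats and reads use the
  round-trip parser, so write→read is bit-exact.

## Problem sizes used by the test suite

Simulation-based checks run at the design points of the study they
mirror: parameter recovery uses 100 replicates of n = 70 at latent
correlation −0.4 with reliabilities 0.87/0.78; sign recovery uses 20
replicates at −0.3; the specificity screen uses 5 replicates of the
combined design (n = 136); generator invariants use 500 participants
(in memory-friendly chunks of 100) for the reliability target and large
cohort draws (2·10⁴–4·10⁴) for the copula targets. Replicate fits use
a lighter sampler preset (4 × 2500 draws); grid-oracle comparisons use
4 × 12000 draws because tail quantiles of the n = 10 posterior converge
slowly.

## Known limitations

* Symptom counts are modelled as continuous Gaussian latents; the
  discrete, zero-inflated margin is handled in the generator but not in
  the inference model (faithful to the analysis being implemented).
* The half-based reliability plug-in (no Spearman–Brown step-up)
  slightly overstates the noise of the 10-trial score; in recovery
  simulations this inflates |ρ̂| by ≈ 3%, visible only as a small
  conservative margin in the bias checks.
* The uncertainty model assumes one SE per instrument; per-observation
  SEs are carried through the data type but default to uniform.
* The gaze window inflates when planted excursions inflate the
  per-participant gaze SDs (as real artifacts would); excursion offsets
  are placed far enough out (8 × 3.3 × gaze noise SD) that detection is
  unambiguous at the default artifact rates.
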