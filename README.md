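# pupilbayes

Reward-anticipation pupillometry analysis for depression research:
trial-structured pupil/gaze preprocessing, derivative-based dilation
features, and Bayesian estimation of the dilation–symptom correlation
with measurement uncertainty propagated into the posterior.

## The problem

Pupil dilation while a participant waits for a reward-predicting cue to
resolve is a peripheral readout of noradrenergic arousal. In depressed
patients, a blunted dilation during this anticipation window tracks the
number of current depressive symptoms — a candidate physiological marker
of anhedonia. Testing that association properly requires (a) a careful
cleaning chain for pupillometry (blinks, smoothing, gaze control,
missing-data rejection), (b) a scalar dilation readout per participant,
and (c) a correlation estimate that does not pretend either measurement
is noise-free.

`pupilbayes` implements that workflow end to end, together with a
synthetic-study generator with known ground truth, so every stage is
testable without access to clinical data. Real recordings can enter at
any stage through plain TSV contracts.

## The model

**Dilation** is the mean first derivative of the cleaned, session
z-scored pupil trace over the 6-s anticipation window (units z/s); the
analysis variable is the differential score
`x_i = dilation(reward) − dilation(control)` for participant *i*, and
`y_i` is the current depressive-symptom count (0–20).

**Latent correlation with measurement error.** Latent pairs
(ξᵢ, ηᵢ) follow a bivariate normal with parameters
(μₓ, μᵧ, σₓ, σᵧ, ρ); observations add independent Gaussian noise with
known standard deviations

    xᵢ ~ N(ξᵢ, SDₓ·√(1−R_pupil)),   yᵢ ~ N(ηᵢ, SDᵧ·√(1−R_symptom)),

where the reliabilities are plug-ins: R_pupil = 0.87 (split-half of the
differential score, trials 1–5 vs 6–10; 0.70 as a conservative
alternative) and R_symptom = 0.78 (interview test–retest). All five
parameters carry uniform priors — (−2, 2), (0, 20), (0, 2), (0, 10) and
(−1, 1) for ρ. The posterior is sampled by four independent
slice-sampling chains (5000 kept draws each after 1000 warm-up; split
R-hat > 1.01 raises an error). The directional Bayes factor

    BF₍₋₎ = #{ρ draws < 0} / #{ρ draws > 0}

uses the posterior counting rule under the symmetric prior; if no draw
crosses zero the draw count is reported as a lower bound. Default
two-sided Bayes factors (stretched-beta prior for Pearson correlations,
JZS Cauchy(0.707) for two-sample contrasts) cover the item, phase and
group screens.

## A worked example

```python
import numpy as np
from pupilbayes import (SimConfig, simulate_study, preprocess_study,
                        NoisyPairData, fit_latent_correlation, measurement_se)
from pupilbayes.features import aggregate_features

study = simulate_study(SimConfig(n_participants=70, true_rho=-0.4, seed=33))
cleaned, qc, _ = preprocess_study(study.session_pairs())
features, _ = aggregate_features(cleaned, study.events, qc)
merged = features.merge(study.clinical, on="participant_id")
x = merged["diff_reward_minus_control"].to_numpy()
y = merged["symptom_count"].to_numpy(dtype=float)
data = NoisyPairData(x=x, y=y,
                     se_x=measurement_se(np.std(x, ddof=1), 0.87),
                     se_y=measurement_se(np.std(y, ddof=1), 0.78))
post = fit_latent_correlation(data, seed=0)
print(post.raw_pearson_r, post.rho_mean, post.rho_ci95, post.bf_minus)
```

Running this (it is `examples/03_latent_correlation.py`) prints

```
raw Pearson r (noisy)      : -0.191
posterior mean rho         : -0.225
95% credible interval      : [-0.480, +0.046]
BF(-) for rho < 0          : 18.0
```

The raw correlation (−0.19) is attenuated by measurement noise; the
model's posterior mean (−0.23) is larger in magnitude because the known
noise is integrated out, and the data favour a negative correlation by
18 : 1. The other scripts in `examples/` walk through QC on planted
artifacts, feature extraction with split-half reliability, and the
Bayes-factor screens.

A thin CLI mirrors the stages for shell use
(`pupilbayes simulate | preprocess | features | correlate | items |
report`), reading and writing the TSV contracts and a run manifest.

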