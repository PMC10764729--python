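"""Estimate the dilation-symptom correlation with measurement error.

Builds a full simulated study with a known latent correlation of -0.4,
runs the pipeline, and fits the latent bivariate-Gaussian model in
which each observed pair is a noisy version of a true score (noise SD =
SD * sqrt(1 - reliability); 0.87 for the pupil score, 0.78 for the
symptom count). Prints the raw Pearson r, the disattenuated posterior,
and the directional Bayes factor from the posterior counting rule.
"""

import numpy as np

from pupilbayes import (
    McmcSettings,
    NoisyPairData,
    SimConfig,
    fit_latent_correlation,
    measurement_se,
    preprocess_study,
    simulate_study,
)
from pupilbayes.features import aggregate_features

study = simulate_study(SimConfig(n_participants=70, true_rho=-0.4, seed=33))
cleaned, qc, _ = preprocess_study(study.session_pairs())
features, _ = aggregate_features(cleaned, study.events, qc)
merged = features.merge(study.clinical, on="participant_id")
sub = merged[["diff_reward_minus_control", "symptom_count"]].dropna()
x = sub.iloc[:, 0].to_numpy()
y = sub.iloc[:, 1].to_numpy()

data = NoisyPairData(
    x=x,
    y=y,
    se_x=measurement_se(float(np.std(x, ddof=1)), 0.87),
    se_y=measurement_se(float(np.std(y, ddof=1)), 0.78),
)
post = fit_latent_correlation(data, settings=McmcSettings(), seed=0)

print(f"planted latent correlation : -0.40")
print(f"raw Pearson r (noisy)      : {post.raw_pearson_r:+.3f}")
print(f"posterior mean rho         : {post.rho_mean:+.3f}")
print(f"95% credible interval      : [{post.rho_ci95[0]:+.3f}, {post.rho_ci95[1]:+.3f}]")
bound = " (lower bound)" if post.bf_is_lower_bound else ""
print(f"BF(-) for rho < 0          : {post.bf_minus:.1f}{bound}")
print(f"max split R-hat            : {max(post.rhat.values()):.4f}")
# The model recovers a correlation larger in magnitude than the raw r
# (disattenuation): the raw estimate is biased toward zero by the known
# measurement noise the model integrates out.
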