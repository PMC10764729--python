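"""Default Bayes-factor screens: BDI items, task phases, groups.

On a combined-design simulated sample (136 participants, 81 depressed)
this runs the screens the analysis reports: correlation of the
differential dilation with each BDI item (flagging moderate evidence,
BF10 > 3), the phase-specificity checks (fixation and consumption
should stay silent), and the JZS group comparison of healthy controls
versus acutely depressed participants (>= 5 current symptoms).
"""

from pupilbayes import SimConfig, bf10_pearson, bf10_ttest, preprocess_study, simulate_study
from pupilbayes.features import aggregate_features, derive_clinical
from pupilbayes.inference import run_item_screen

study = simulate_study(
    SimConfig(n_participants=136, prop_depressed=81 / 136, true_rho=-0.4, seed=17)
)
cleaned, qc, _ = preprocess_study(study.session_pairs())
features, _ = aggregate_features(cleaned, study.events, qc)
clinical = derive_clinical(study.clinical)
merged = features.merge(clinical, on="participant_id")

screen = run_item_screen(features, clinical)
print("BDI item screen, rows with BF10 > 3:")
for row in screen[screen["moderate"]].itertuples(index=False):
    print(f"  {row.label:40s} r = {row.r:+.2f}  BF10 = {row.bf10:8.1f}")

print("\nphase specificity (vs symptom count):")
for label, col in [
    ("anticipation diff (reward-control)", "diff_reward_minus_control"),
    ("fixation (all conditions)", "dilation_fixation_all"),
    ("consumption (reward)", "dilation_consumption_reward"),
]:
    sub = merged[[col, "symptom_count"]].dropna()
    res = bf10_pearson(sub.iloc[:, 0].to_numpy(), sub.iloc[:, 1].to_numpy())
    print(f"  {label:36s} r = {res.statistic:+.2f}  BF10 = {res.bf10:8.1f} ({res.evidence})")

hc = merged.loc[merged["group"] == "HC", "diff_reward_minus_control"].dropna()
acute = merged.loc[merged["acute"], "diff_reward_minus_control"].dropna()
res = bf10_ttest(hc.to_numpy(), acute.to_numpy())
print(f"\nHC (n={len(hc)}) vs acutely depressed (n={len(acute)}): "
      f"t = {res.statistic:.2f}, BF10 = {res.bf10:.2f} ({res.evidence})")
# Only the anticipation-phase differential carries evidence; fixation
# and consumption dilations are uncoupled from symptoms by design, and
# the screens confirm it. Note the simulator places the zero-symptom
# healthy margin at the top of the arousal continuum, which makes the
# item and group contrasts stronger than in typical clinical cohorts,
# where the coupling lives mostly within patients.
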