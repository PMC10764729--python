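"""Per-participant dilation features and clinical derivations.

"Pupil dilation" here is a rate: the mean first derivative of the
(cleaned, z-scored) pupil trace over an analysis window, in z/s. For a
uniformly sampled window this equals (last - first) / elapsed time by
telescoping, an identity the tests exploit. Trial dilations are computed
per trial and then averaged within condition/phase cells, so trial-level
QC decisions carry through directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .preprocess import CONDITIONS, QCReport, SampleSeries

__all__ = [
    "compute_dilation",
    "trial_dilations",
    "aggregate_features",
    "split_half_reliability",
    "derive_clinical",
    "ANHEDONIA_ITEMS",
    "ACUTE_SYMPTOM_THRESHOLD",
]

ANHEDONIA_ITEMS = (4, 12, 21)  # loss of pleasure, loss of interest, loss of sexual interest
ACUTE_SYMPTOM_THRESHOLD = 5

FEATURE_COLUMNS = [
    "dilation_reward",
    "dilation_neutral",
    "dilation_control",
    "diff_reward_minus_control",
    "diff_reward_minus_neutral",
    "dilation_fixation_reward",
    "dilation_fixation_neutral",
    "dilation_fixation_control",
    "dilation_fixation_all",
    "diff_fixation_reward_minus_control",
    "dilation_consumption_reward",
    "dilation_consumption_neutral",
]


def compute_dilation(segment: np.ndarray, sampling_rate: float) -> float:
    """Mean first derivative of a pupil segment, in z/s.

    NaN samples (unrecovered gaps) simply drop their adjacent first
    differences from the mean.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size < 2:
        raise ValueError("dilation needs a segment of at least 2 samples")
    d = np.diff(segment) * sampling_rate
    d = d[np.isfinite(d)]
    if d.size == 0:
        return float("nan")
    return float(np.mean(d))


def _window_slice(series: SampleSeries, t0: float, t1: float) -> np.ndarray:
    """Pupil samples with t0 <= t <= t1 (both boundary samples included)."""
    i0 = int(np.searchsorted(series.time_s, t0 - 1e-9, side="left"))
    i1 = int(np.searchsorted(series.time_s, t1 + 1e-9, side="right"))
    return series.pupil[i0:i1]


def trial_dilations(
    series: SampleSeries, events: pd.DataFrame, feedback_s: float = 1.5
) -> pd.DataFrame:
    """Per-trial dilations for the anticipation, fixation and (where a
    successful feedback exists) consumption phases of one session."""
    rows = []
    fb_onset = events["feedback_onset_s"].to_numpy(dtype=float)
    for trial_index, condition, fix_on, cue_on, cue_off, success, fb_on in zip(
        events["trial_index"].to_numpy(),
        events["condition"].to_numpy(),
        events["fixation_onset_s"].to_numpy(dtype=float),
        events["cue_onset_s"].to_numpy(dtype=float),
        events["cue_offset_s"].to_numpy(dtype=float),
        events["feedback_success"].to_numpy(),
        fb_onset,
    ):
        anticipation = compute_dilation(
            _window_slice(series, cue_on, cue_off), series.sampling_rate_hz
        )
        fixation = compute_dilation(
            _window_slice(series, fix_on, cue_on), series.sampling_rate_hz
        )
        consumption = np.nan
        if isinstance(success, (bool, np.bool_)) and success and np.isfinite(fb_on):
            consumption = compute_dilation(
                _window_slice(series, fb_on, fb_on + feedback_s), series.sampling_rate_hz
            )
        rows.append(
            {
                "participant_id": series.participant_id,
                "trial_index": int(trial_index),
                "condition": condition,
                "dilation": anticipation,
                "dilation_fixation": fixation,
                "dilation_consumption": consumption,
            }
        )
    return pd.DataFrame(rows)


def _cell_mean(values: np.ndarray) -> Tuple[float, int]:
    values = values[np.isfinite(values)]
    if values.size == 0:
        return float("nan"), 0
    return float(np.mean(values)), int(values.size)


def aggregate_features(
    cleaned: Mapping[str, SampleSeries],
    events: Mapping[str, pd.DataFrame],
    qc: Mapping[str, QCReport],
    feedback_s: float = 1.5,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse surviving trials into one feature row per participant.

    Returns ``(features, trials)`` where ``trials`` holds the per-trial
    dilations (with QC flags) that the split-half reliability needs.
    Session-dropped participants are omitted entirely; cells with no
    surviving trial are NaN with ``n_trials_used`` 0.
    """
    feature_rows = []
    trial_frames = []
    for pid in cleaned:
        report = qc[pid]
        if report.session_dropped:
            continue
        trials = trial_dilations(cleaned[pid], events[pid], feedback_s=feedback_s)
        trials = trials.merge(
            report.trials[["trial_index", "dropped", "drop_reason"]], on="trial_index"
        )
        trial_frames.append(trials)
        kept = trials[~trials["dropped"]]
        row: Dict[str, object] = {"participant_id": pid}
        for cond in CONDITIONS:
            sub = kept[kept["condition"] == cond]
            mean, n = _cell_mean(sub["dilation"].to_numpy())
            row[f"dilation_{cond}"] = mean
            row[f"n_trials_{cond}"] = n
            fmean, fn = _cell_mean(sub["dilation_fixation"].to_numpy())
            row[f"dilation_fixation_{cond}"] = fmean
            row[f"n_trials_fixation_{cond}"] = fn
        amean, an = _cell_mean(kept["dilation_fixation"].to_numpy())
        row["dilation_fixation_all"] = amean
        row["n_trials_fixation_all"] = an
        for cond in ("reward", "neutral"):
            sub = kept[kept["condition"] == cond]
            cmean, cn = _cell_mean(sub["dilation_consumption"].to_numpy())
            row[f"dilation_consumption_{cond}"] = cmean
            row[f"n_trials_consumption_{cond}"] = cn
        row["diff_reward_minus_control"] = row["dilation_reward"] - row["dilation_control"]
        row["diff_reward_minus_neutral"] = row["dilation_reward"] - row["dilation_neutral"]
        row["diff_fixation_reward_minus_control"] = (
            row["dilation_fixation_reward"] - row["dilation_fixation_control"]
        )
        feature_rows.append(row)
    features = pd.DataFrame(feature_rows)
    trials = (
        pd.concat(trial_frames, ignore_index=True) if trial_frames else pd.DataFrame()
    )
    return features, trials


def split_half_reliability(
    trials: pd.DataFrame,
    condition_a: str = "reward",
    condition_b: str = "control",
) -> float:
    """Split-half reliability of the differential dilation score.

    Per participant, the differential score (condition_a minus
    condition_b trial means) is computed separately from trials 1-5 and
    6-10 (numbering within condition, surviving trials only); returned
    is the Pearson correlation of the two halves across participants,
    uncorrected (the plug-in convention the uncertainty model uses).
    """
    halves = []
    for _, sub in trials.groupby("participant_id", sort=True):
        vals = {}
        for cond in (condition_a, condition_b):
            csub = sub[sub["condition"] == cond].sort_values("trial_index")
            rank = np.arange(1, len(csub) + 1)  # position within condition, incl. dropped
            keep = (~csub["dropped"]).to_numpy() & np.isfinite(csub["dilation"].to_numpy())
            d = csub["dilation"].to_numpy()
            n_half = len(csub) // 2
            first = d[keep & (rank <= n_half)]
            second = d[keep & (rank > n_half)]
            if first.size == 0 or second.size == 0:
                break
            vals[cond] = (float(np.mean(first)), float(np.mean(second)))
        else:
            halves.append(
                (
                    vals[condition_a][0] - vals[condition_b][0],
                    vals[condition_a][1] - vals[condition_b][1],
                )
            )
    if len(halves) < 3:
        raise ValueError("split-half reliability needs >= 3 complete participants")
    arr = np.asarray(halves)
    return float(pearsonr(arr[:, 0], arr[:, 1])[0])


def derive_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Add the anhedonia sum score (BDI items 4+12+21) and the acute flag
    (depressed with >= 5 current symptoms)."""
    out = clinical.copy()
    item_cols = [f"bdi_item_{j:02d}" for j in ANHEDONIA_ITEMS]
    out["anhedonia_score"] = out[item_cols].sum(axis=1)
    out["acute"] = (out["group"] == "MDD") & (out["symptom_count"] >= ACUTE_SYMPTOM_THRESHOLD)
    return out
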