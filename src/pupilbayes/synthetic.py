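"""Simulated reward-anticipation pupillometry studies with known ground truth.

The generator emulates the study design the analysis pipeline targets:
each participant performs 30 trials (10 reward, 10 neutral, 10 control,
pseudo-randomized with no 3 identical conditions in a row). A trial is
fixation -> 6-s cue/anticipation -> flash/response -> 1.5-s feedback
(reward and neutral only). Pupil diameter is sampled at 250 Hz together
with gaze position and a validity flag; blinks appear as invalid gaps.

The latent structure is what the downstream statistics estimate:

* each participant carries an arousal trait ``a ~ N(0, 1)``;
* anticipation-phase pupil ramps linearly with per-condition slopes
  scaled by the trait, so the differential dilation (reward - control)
  is a linear readout of ``a``;
* the symptom latent is a Gaussian copula of ``a`` with correlation
  ``-|true_rho|``, observed through measurement noise matching
  ``symptom_reliability`` and discretized to a 0-20 count (healthy
  controls are the zero-count margin);
* trial-to-trial slope jitter is calibrated through the Spearman-Brown
  relation for a 5-trial half so the split-half reliability of the
  differential score converges to ``reliability_target``;
* BDI-style items are 0-3 ordinal readouts of the symptom latent, with
  a configurable subset loading additionally on the arousal trait.

Artifacts (blinks, whole-trial missing runs, out-of-window gaze
episodes) are planted explicitly and recorded in :class:`GroundTruth`
so QC decisions can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy.stats import nbinom, norm

from .preprocess import CONDITIONS, SampleSeries

__all__ = ["SimConfig", "GroundTruth", "SimulatedStudy", "simulate_condition_order", "simulate_study"]

# Post-cue geometry (seconds): hold at peak (pupil response latency),
# relax back to baseline, settle before the feedback window. Keeps the
# 200 ms smoothing window from leaking anticipation peaks into the
# fixation or consumption windows.
_HOLD_S = 0.2
_FALL_S = 0.2
_SETTLE_S = 0.1
_RETURN_S = 0.3
_POST_FB_FLAT_S = 0.2
_LEAD_S = 1.0

# One-time calibration constants of the default design (see docs):
# the session z-transform couples the scale to the trait and shrinks the
# between-participant differential-slope variance to ~_K2_CAL of its raw
# value; the slow drift leaves (_D_COEF * drift_sd)^2 of half-score noise
# in the differential despite cancelling to first order.
_K2_CAL = 0.81
_D_COEF = 0.0136


@dataclass
class SimConfig:
    """Study-design constants and noise levels of the simulator."""

    n_participants: int = 70
    prop_depressed: float = 0.57
    true_rho: float = -0.4
    sampling_rate: float = 250.0
    n_trials_per_condition: int = 10
    anticipation_s: float = 6.0
    feedback_s: float = 1.5
    response_s: float = 0.5
    fixation_s_range: Tuple[float, float] = (2.0, 4.0)
    blink_rate: float = 8.0  # blinks per minute
    blink_dur_ms_range: Tuple[float, float] = (100.0, 400.0)
    gaze_noise_sd: float = 15.0  # px
    gaze_excursion_prob: float = 0.05
    missing_trial_prob: float = 0.0
    trial_noise_sd: float = 0.1  # per-sample pupil noise, z-units
    reliability_target: float = 0.87
    symptom_reliability: float = 0.78
    seed: int = 0
    # latent-structure constants
    base_slopes: Tuple[float, float, float] = (0.30, 0.20, 0.10)  # reward, neutral, control (z/s)
    slope_sensitivity: float = 0.5  # trait scaling of all condition slopes
    consumption_slope_mean: float = 0.15
    consumption_slope_sd: float = 0.05
    gaze_center: Tuple[float, float] = (512.0, 384.0)
    baseline_range: Tuple[float, float] = (3.0, 6.0)  # arbitrary units, removed by z-scoring
    # slow trait-independent pupil fluctuations; they dominate session
    # variance (as spontaneous arousal drifts do in real recordings), so
    # the session z-transform does not divide out the task effect. Their
    # slope is nearly constant over a trial and cancels in differential scores.
    drift_sd: float = 1.5
    drift_periods_s: Tuple[float, ...] = (240.0, 160.0, 104.0)
    loaded_items: Tuple[int, ...] = (4, 15, 21)  # 1-based BDI items coupled to the trait

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2 (correlation undefined below)")
        for name in ("sampling_rate", "anticipation_s", "feedback_s", "response_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("prop_depressed", "gaze_excursion_prob", "missing_trial_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if abs(self.true_rho) > 1.0:
            raise ValueError("|true_rho| must be <= 1")
        if not 0.0 < self.reliability_target <= 1.0:
            raise ValueError("reliability_target must lie in (0, 1]")
        if not 0.0 < self.symptom_reliability <= 1.0:
            raise ValueError("symptom_reliability must lie in (0, 1]")
        if self.blink_rate < 0 or self.trial_noise_sd < 0 or self.gaze_noise_sd < 0:
            raise ValueError("rates and noise SDs must be non-negative")
        if self.drift_sd < 0 or any(p <= 0 for p in self.drift_periods_s):
            raise ValueError("drift_sd must be >= 0 and drift periods positive")
        if not self.fixation_s_range[0] <= self.fixation_s_range[1] or self.fixation_s_range[0] <= 0:
            raise ValueError("fixation_s_range must be a positive interval")
        if not 0 < self.blink_dur_ms_range[0] <= self.blink_dur_ms_range[1]:
            raise ValueError("blink_dur_ms_range must be a positive interval")
        if any(not 1 <= j <= 21 for j in self.loaded_items):
            raise ValueError("loaded_items must be 1-based BDI item numbers")

    @property
    def n_trials(self) -> int:
        return 3 * self.n_trials_per_condition

    @property
    def diff_true_mean(self) -> float:
        return self.base_slopes[0] - self.base_slopes[2]

    @property
    def diff_true_sd(self) -> float:
        return abs(self.diff_true_mean) * self.slope_sensitivity

    @property
    def trial_slope_sd(self) -> float:
        """Per-trial slope jitter implied by the split-half reliability target.

        For a 5-trial half the differential half-score carries noise
        variance 2*sigma^2/5, so R = V / (V + 2*sigma^2/5 + D) with V the
        between-participant variance of the differential score as the
        pipeline measures it and D the residual half-score noise the slow
        drift leaves in the differential. Both enter through calibration
        constants of the default design: the session z-transform shrinks
        the raw slope variance by ``_K2_CAL`` and the drift contributes
        ``(_D_COEF * drift_sd)^2``.
        """
        r = self.reliability_target
        if r >= 1.0:
            return 0.0
        v_eff = _K2_CAL * self.diff_true_sd**2
        d = (_D_COEF * self.drift_sd) ** 2
        return float(np.sqrt(max(2.5 * (v_eff * (1.0 - r) / r - d), 0.0)))


@dataclass
class GroundTruth:
    """Everything the generator planted, for exact downstream checks."""

    participants: pd.DataFrame  # participant_id, trait, factor, slope_*, diff_true,
    #                             symptom_latent, symptom_count, group, baseline
    trial_slopes: pd.DataFrame  # participant_id, trial_index, condition, slope,
    #                             consumption_slope, feedback_success
    blinks: pd.DataFrame  # participant_id, onset_s, offset_s
    excursions: pd.DataFrame  # participant_id, trial_index, onset_s, duration_s
    missing_trials: pd.DataFrame  # participant_id, trial_index
    config: SimConfig

    def __post_init__(self) -> None:
        counts = self.participants["symptom_count"]
        if ((counts < 0) | (counts > 20)).any():
            raise ValueError("symptom counts must lie in [0, 20]")
        valid_trials = set(
            zip(self.trial_slopes["participant_id"], self.trial_slopes["trial_index"])
        )
        for name, df in (("excursions", self.excursions), ("missing_trials", self.missing_trials)):
            for pid, tr in zip(df["participant_id"], df["trial_index"]):
                if (pid, tr) not in valid_trials:
                    raise ValueError(f"{name} references unknown trial ({pid}, {tr})")

    def expected_dropped(self) -> Dict[str, set]:
        """Trials the QC chain must drop: planted missing runs plus gaze
        excursions longer than one second."""
        out: Dict[str, set] = {str(p): set() for p in self.participants["participant_id"]}
        for pid, tr in zip(self.missing_trials["participant_id"], self.missing_trials["trial_index"]):
            out[str(pid)].add(int(tr))
        long = self.excursions[self.excursions["duration_s"] > 1.0]
        for pid, tr in zip(long["participant_id"], long["trial_index"]):
            out[str(pid)].add(int(tr))
        return out


@dataclass
class SimulatedStudy:
    sessions: Dict[str, SampleSeries]
    events: Dict[str, pd.DataFrame]
    clinical: pd.DataFrame
    truth: GroundTruth

    def session_pairs(self) -> Dict[str, Tuple[SampleSeries, pd.DataFrame]]:
        return {pid: (self.sessions[pid], self.events[pid]) for pid in self.sessions}


def simulate_condition_order(
    n_trials: int, n_conditions: int, seed: int | np.random.Generator = 0
) -> List[str]:
    """Balanced pseudo-random condition sequence with no 3 identical in a row."""
    if n_conditions < 1 or n_trials < 1:
        raise ValueError("n_trials and n_conditions must be positive")
    if n_trials % n_conditions != 0:
        raise ValueError("n_trials must be divisible by n_conditions")
    if n_conditions == 1 and n_trials >= 3:
        raise ValueError("cannot avoid runs of 3 with a single condition")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = list(CONDITIONS) if n_conditions == 3 else [f"cond{i + 1}" for i in range(n_conditions)]
    remaining = [n_trials // n_conditions] * n_conditions
    seq: List[int] = []

    def feasible(rem: List[int]) -> bool:
        # pruning bound: m copies in pairs need a separator after each pair
        slots = sum(rem)
        return all(m <= 2 * (slots - m) + 2 for m in rem)

    def backtrack() -> bool:
        if len(seq) == n_trials:
            return True
        last_two = seq[-1] if len(seq) >= 2 and seq[-1] == seq[-2] else None
        choices = [i for i in range(n_conditions) if remaining[i] > 0 and i != last_two]
        rng.shuffle(choices)
        # try the most constrained (largest remaining) early to prune dead ends
        choices.sort(key=lambda i: -remaining[i])
        for i in choices:
            remaining[i] -= 1
            seq.append(i)
            if feasible(remaining) and backtrack():
                return True
            seq.pop()
            remaining[i] += 1
        return False

    if not backtrack():
        raise ValueError("no balanced sequence without runs of 3 exists for these counts")
    return [labels[i] for i in seq]


def _symptom_count_pmf(prop_depressed: float) -> np.ndarray:
    """Marginal over counts 0-20: healthy zero-count mass plus a
    negative-binomial-shaped severity distribution for the depressed."""
    pmf = np.zeros(21)
    pmf[0] = 1.0 - prop_depressed
    body = nbinom.pmf(np.arange(20), 3, 0.35)
    pmf[1:] = prop_depressed * body / body.sum()
    return pmf


_ITEM_CUM = np.array([0.4, 0.7, 0.9])  # item-score margins P(0),P(<=1),P(<=2) among depressed


def _discretization_attenuation(pmf: np.ndarray) -> float:
    """corr(w, g(w)) for w ~ N(0,1) mapped through the count quantile map
    g; the copula correlation is divided by this so the planted
    correlation survives discretization exactly."""
    cum = np.cumsum(pmf)
    w = np.linspace(-8.0, 8.0, 40001)
    pw = norm.pdf(w)
    pw /= pw.sum()
    g = np.minimum(np.searchsorted(cum, norm.cdf(w), side="right"), len(pmf) - 1).astype(float)
    mean_g = float(np.sum(pw * g))
    var_g = float(np.sum(pw * (g - mean_g) ** 2))
    cov_wg = float(np.sum(pw * w * (g - mean_g)))
    return cov_wg / np.sqrt(var_g)


def draw_cohort(config: SimConfig, rng: np.random.Generator) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw traits, symptom latents, counts, groups and BDI items.

    Returns (participants ground-truth frame, clinical table). Split out
    from :func:`simulate_study` so latent-structure properties can be
    checked at large n without synthesizing time series.
    """
    n = config.n_participants
    pids = [f"P{i + 1:03d}" for i in range(n)]
    a = rng.standard_normal(n)
    pmf = _symptom_count_pmf(config.prop_depressed)
    c0 = _discretization_attenuation(pmf)
    # inflate the copula correlation so corr(trait, count) comes out at
    # -|true_rho| * sqrt(symptom_reliability) after discretization
    r0 = min(abs(config.true_rho) / c0, 0.999)
    eta = -r0 * a + np.sqrt(1.0 - r0**2) * rng.standard_normal(n)
    ry = config.symptom_reliability
    w = np.sqrt(ry) * eta + np.sqrt(1.0 - ry) * rng.standard_normal(n)
    cum = np.cumsum(pmf)
    counts = np.minimum(np.searchsorted(cum, norm.cdf(w), side="right"), 20).astype(int)
    groups = np.where(counts >= 1, "MDD", "HC")

    # trait gain scales each condition's contrast against control, so the
    # control slope is trait-free (its per-stimulus correlation with
    # symptoms is null) while the differential is 0.2 * factor
    factor = np.maximum(1.0 + config.slope_sensitivity * a, 0.05)
    base = np.asarray(config.base_slopes)
    slopes = base[None, :] + np.outer(factor - 1.0, base - base[2])
    baseline = rng.uniform(*config.baseline_range, size=n)

    # BDI items: ordinal readouts of the symptom latent; the loaded
    # subset additionally tracks (low) arousal, mirroring the anhedonia /
    # loss-of-energy specificity the item screen is meant to detect.
    items = np.zeros((n, 21), dtype=int)
    mdd = counts >= 1
    thresholds = norm.ppf(_ITEM_CUM)
    for j in range(21):
        if (j + 1) in config.loaded_items:
            alpha, beta = 0.30, 0.25
        else:
            alpha, beta = 0.35, 0.0
        resid = 1.0 - alpha**2 - beta**2 - 2.0 * alpha * beta * r0
        u = alpha * eta + beta * (-a) + np.sqrt(max(resid, 1e-12)) * rng.standard_normal(n)
        items[:, j] = np.searchsorted(thresholds, u, side="right")
    items[~mdd] = 0

    participants = pd.DataFrame(
        {
            "participant_id": pids,
            "trait": a,
            "factor": factor,
            "slope_reward": slopes[:, 0],
            "slope_neutral": slopes[:, 1],
            "slope_control": slopes[:, 2],
            "diff_true": slopes[:, 0] - slopes[:, 2],
            "symptom_latent": eta,
            "symptom_count": counts,
            "group": groups,
            "baseline": baseline,
        }
    )
    clinical = pd.DataFrame({"participant_id": pids, "group": groups, "symptom_count": counts})
    for j in range(21):
        clinical[f"bdi_item_{j + 1:02d}"] = items[:, j]
    return participants, clinical


def _find_clear_span(
    valid: np.ndarray, lo: int, hi: int, dur_n: int, rng: np.random.Generator, tries: int = 30
) -> int | None:
    """A start index in [lo, hi - dur_n] whose span contains no invalid sample."""
    if hi - dur_n <= lo:
        return None
    for _ in range(tries):
        start = int(rng.integers(lo, hi - dur_n))
        if valid[start : start + dur_n].all():
            return start
    return None


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate a complete simulated study; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    dt = 1.0 / fs
    participants, clinical = draw_cohort(config, rng)

    n_ant = int(round(config.anticipation_s * fs))
    n_hold = int(round(_HOLD_S * fs))
    n_fall = int(round(_FALL_S * fs))
    n_settle = int(round(_SETTLE_S * fs))
    n_fb = int(round(config.feedback_s * fs))
    n_ret = int(round(_RETURN_S * fs))
    n_postflat = int(round(_POST_FB_FLAT_S * fs))
    n_lead = int(round(_LEAD_S * fs))
    n_resp = n_hold + n_fall + n_settle
    if abs(n_resp * dt - config.response_s) > 1e-9:
        n_settle += int(round(config.response_s * fs)) - n_resp
        n_resp = n_hold + n_fall + n_settle
    excursion_offset_px = 8.0 * 3.3 * config.gaze_noise_sd

    sessions: Dict[str, SampleSeries] = {}
    events_by_pid: Dict[str, pd.DataFrame] = {}
    trial_rows: List[dict] = []
    blink_rows: List[dict] = []
    excursion_rows: List[dict] = []
    missing_rows: List[dict] = []

    sigma_trial = config.trial_slope_sd
    for row in participants.itertuples(index=False):
        pid = row.participant_id
        order = simulate_condition_order(config.n_trials, 3, rng)
        fix_n = rng.integers(
            int(round(config.fixation_s_range[0] * fs)),
            int(round(config.fixation_s_range[1] * fs)) + 1,
            size=config.n_trials,
        )
        slopes_by_cond = {
            "reward": row.slope_reward,
            "neutral": row.slope_neutral,
            "control": row.slope_control,
        }

        # --- timeline layout (all in samples) -------------------------------
        cursor = n_lead
        ev_rows = []
        seg_fill: List[Tuple[int, int, float, float]] = []  # start, stop, v0, v1 (linear)
        for k, cond in enumerate(order):
            trial_index = k + 1
            slope = slopes_by_cond[cond] + (rng.normal(0.0, sigma_trial) if sigma_trial > 0 else 0.0)
            fixation_onset = cursor
            cue_onset = fixation_onset + int(fix_n[k])
            cue_offset = cue_onset + n_ant
            peak = slope * config.anticipation_s
            seg_fill.append((cue_onset, cue_offset, 0.0, peak - slope * dt))
            seg_fill.append((cue_offset, cue_offset + n_hold, peak, peak))
            seg_fill.append((cue_offset + n_hold, cue_offset + n_hold + n_fall, peak, 0.0))
            cursor = cue_offset + n_resp
            cons_slope = np.nan
            feedback_success = np.nan
            feedback_onset = np.nan
            if cond in ("reward", "neutral"):
                cons_slope = rng.normal(config.consumption_slope_mean, config.consumption_slope_sd)
                feedback_success = bool(rng.random() < 0.5)
                feedback_onset = cursor
                fb_end_val = cons_slope * config.feedback_s
                seg_fill.append((cursor, cursor + n_fb, 0.0, fb_end_val - cons_slope * dt))
                seg_fill.append((cursor + n_fb, cursor + n_fb + n_ret, fb_end_val, 0.0))
                cursor = cursor + n_fb + n_ret + n_postflat
            ev_rows.append(
                {
                    "participant_id": pid,
                    "trial_index": trial_index,
                    "condition": cond,
                    "fixation_onset_s": fixation_onset * dt,
                    "cue_onset_s": cue_onset * dt,
                    "cue_offset_s": cue_offset * dt,
                    "feedback_onset_s": feedback_onset * dt if np.isfinite(feedback_onset) else np.nan,
                    "feedback_success": feedback_success,
                }
            )
            trial_rows.append(
                {
                    "participant_id": pid,
                    "trial_index": trial_index,
                    "condition": cond,
                    "slope": slope,
                    "consumption_slope": cons_slope,
                    "feedback_success": feedback_success,
                }
            )
        total = cursor + n_lead
        time_s = np.arange(total) * dt
        signal = np.zeros(total)
        for start, stop, v0, v1 in seg_fill:
            m = stop - start
            if m <= 0:
                continue
            signal[start:stop] = np.linspace(v0, v1, m) if v0 != v1 else v0

        pupil = row.baseline + signal
        if config.drift_sd > 0:
            periods = np.asarray(config.drift_periods_s, dtype=float)
            # 1/f-like spectrum: amplitude^2 proportional to the period
            weights = np.sqrt(2.0 * periods / periods.sum())
            phases = rng.uniform(0.0, 2.0 * np.pi, size=periods.size)
            drift = np.zeros(total)
            for w_i, period, phi in zip(weights, periods, phases):
                drift += w_i * np.sin(2.0 * np.pi * time_s / period + phi)
            # normalize to the exact target SD: a handful of sinusoids
            # self-averages far less than a real 1/f process over one
            # session, and the phase-dependent realized variance would
            # otherwise reappear as spurious between-participant scale
            # differences after the session z-transform
            drift -= drift.mean()
            drift *= config.drift_sd / drift.std()
            pupil = pupil + drift
        if config.trial_noise_sd > 0:
            pupil = pupil + rng.normal(0.0, config.trial_noise_sd, total)
        valid = np.ones(total, dtype=bool)

        # --- blinks ---------------------------------------------------------
        session_minutes = total * dt / 60.0
        n_blinks = rng.poisson(config.blink_rate * session_minutes)
        margin = int(round(0.5 * fs))
        for _ in range(n_blinks):
            dur_n = int(round(rng.uniform(*config.blink_dur_ms_range) / 1000.0 * fs))
            start = int(rng.integers(margin, total - margin - dur_n))
            valid[start : start + dur_n] = False
            blink_rows.append(
                {"participant_id": pid, "onset_s": start * dt, "offset_s": (start + dur_n) * dt}
            )

        events = pd.DataFrame(ev_rows)

        # --- planted whole-trial missing runs (62% of the 6-s window) -------
        for ev in events.itertuples(index=False):
            if rng.random() >= config.missing_trial_prob:
                continue
            i0 = int(round(ev.cue_onset_s * fs)) + int(round(0.19 * n_ant))
            valid[i0 : i0 + int(round(0.62 * n_ant))] = False
            missing_rows.append({"participant_id": pid, "trial_index": int(ev.trial_index)})
        planted_missing = {m["trial_index"] for m in missing_rows if m["participant_id"] == pid}

        # --- gaze -----------------------------------------------------------
        gaze_x = config.gaze_center[0] + rng.normal(0.0, config.gaze_noise_sd, total)
        gaze_y = config.gaze_center[1] + rng.normal(0.0, config.gaze_noise_sd, total)
        for ev in events.itertuples(index=False):
            if int(ev.trial_index) in planted_missing:
                continue
            if rng.random() >= config.gaze_excursion_prob:
                continue
            if rng.random() < 0.5:
                dur_s = rng.uniform(0.3, 0.8)  # below the 1-s rule: must be kept
            else:
                dur_s = rng.uniform(1.2, 2.5)  # above the 1-s rule: must be dropped
            dur_n = int(round(dur_s * fs))
            lo = int(round(ev.cue_onset_s * fs)) + int(round(0.05 * fs))
            hi = int(round(ev.cue_offset_s * fs)) - int(round(0.05 * fs))
            start = _find_clear_span(valid, lo, hi, dur_n, rng)
            if start is None:
                continue
            sign = 1.0 if rng.random() < 0.5 else -1.0
            gaze_x[start : start + dur_n] += sign * excursion_offset_px
            excursion_rows.append(
                {
                    "participant_id": pid,
                    "trial_index": int(ev.trial_index),
                    "onset_s": start * dt,
                    "duration_s": dur_n * dt,
                }
            )

        pupil = pupil.copy()
        pupil[~valid] = np.nan
        gaze_x[~valid] = np.nan
        gaze_y[~valid] = np.nan
        sessions[pid] = SampleSeries(
            participant_id=pid,
            time_s=time_s,
            pupil=pupil,
            gaze_x_px=gaze_x,
            gaze_y_px=gaze_y,
            valid=valid,
            sampling_rate_hz=fs,
        )
        events_by_pid[pid] = events

    truth = GroundTruth(
        participants=participants,
        trial_slopes=pd.DataFrame(trial_rows),
        blinks=pd.DataFrame(blink_rows, columns=["participant_id", "onset_s", "offset_s"]),
        excursions=pd.DataFrame(
            excursion_rows, columns=["participant_id", "trial_index", "onset_s", "duration_s"]
        ),
        missing_trials=pd.DataFrame(missing_rows, columns=["participant_id", "trial_index"]),
        config=config,
    )
    return SimulatedStudy(sessions=sessions, events=events_by_pid, clinical=clinical, truth=truth)
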