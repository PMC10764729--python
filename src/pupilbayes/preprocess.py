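"""Pupil-trace cleaning and quality control.

The cleaning chain reproduces a standard eye-tracker workflow for
task-based pupillometry, applied in a fixed order:

1. linear blink interpolation with a padding margin around each gap,
2. sliding-window mean smoothing against non-biological outliers,
3. per-session z-transform of pupil diameter,
4. trial/session rejection by missing-data fractions,
5. trial rejection by time spent outside a rectangular gaze window.

Missing samples are represented by ``valid == False``; samples whose
values were overwritten by blink interpolation (including the padding
margin) carry a separate ``interpolated`` flag so that missingness
accounting can treat them as missing while the z-transform and feature
extraction can still use their values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "SampleSeries",
    "QCReport",
    "GazeWindow",
    "PreprocessParams",
    "interpolate_blinks",
    "smooth_sliding_mean",
    "zscore_session",
    "reject_missing",
    "fit_gaze_window",
    "reject_gaze",
    "preprocess_session",
    "preprocess_study",
]

CONDITIONS = ("reward", "neutral", "control")


@dataclass
class SampleSeries:
    """One participant's uniformly sampled pupil/gaze stream.

    ``pupil`` is NaN wherever the sample is neither valid nor
    interpolated. ``valid`` always reflects the *raw* tracker validity;
    interpolation never rewrites it.
    """

    participant_id: str
    time_s: np.ndarray
    pupil: np.ndarray
    gaze_x_px: np.ndarray
    gaze_y_px: np.ndarray
    valid: np.ndarray
    sampling_rate_hz: float
    interpolated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.gaze_x_px = np.asarray(self.gaze_x_px, dtype=float)
        self.gaze_y_px = np.asarray(self.gaze_y_px, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.interpolated is None:
            self.interpolated = np.zeros(self.time_s.shape, dtype=bool)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        n = self.time_s.size
        if n < 2:
            raise ValueError(f"{self.participant_id}: series needs at least 2 samples")
        for name in ("pupil", "gaze_x_px", "gaze_y_px", "valid", "interpolated"):
            if getattr(self, name).size != n:
                raise ValueError(f"{self.participant_id}: column {name} has wrong length")
        dt = np.diff(self.time_s)
        if np.any(dt <= 0):
            raise ValueError(f"{self.participant_id}: time_s must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / self.sampling_rate_hz)) > 1e-6:
            raise ValueError(f"{self.participant_id}: sampling interval is not uniform")

    @property
    def usable(self) -> np.ndarray:
        """Samples carrying a meaningful pupil value (valid or interpolated)."""
        return self.valid | self.interpolated

    @property
    def missing(self) -> np.ndarray:
        """Samples counted as missing for QC (raw-invalid or overwritten)."""
        return (~self.valid) | self.interpolated

    def copy(self) -> "SampleSeries":
        # bypass __init__: the arrays were already validated on construction
        new = object.__new__(SampleSeries)
        new.participant_id = self.participant_id
        new.sampling_rate_hz = self.sampling_rate_hz
        new.time_s = self.time_s.copy()
        new.pupil = self.pupil.copy()
        new.gaze_x_px = self.gaze_x_px.copy()
        new.gaze_y_px = self.gaze_y_px.copy()
        new.valid = self.valid.copy()
        new.interpolated = self.interpolated.copy()
        return new


@dataclass
class GazeWindow:
    """Per-participant rectangular fixation-control window.

    The center is the participant's own median gaze during the
    anticipation windows; the half-widths are shared across the cohort
    (multiplier x the cohort mean of per-participant gaze SDs).
    """

    center_x_px: float
    center_y_px: float
    half_width_x_px: float
    half_height_y_px: float


@dataclass
class QCReport:
    """Missingness and gaze QC outcome for one session."""

    participant_id: str
    session_missing_fraction: float
    session_dropped: bool
    trials: pd.DataFrame  # trial_index, condition, trial_missing_fraction,
    #                       out_of_window_s, dropped, drop_reason

    def __post_init__(self) -> None:
        if not 0.0 <= self.session_missing_fraction <= 1.0:
            raise ValueError("session_missing_fraction outside [0, 1]")
        bad = self.trials["dropped"] & (self.trials["drop_reason"] == "none")
        if bad.any():
            raise ValueError("dropped trials must carry a drop_reason")

    @property
    def kept_trials(self) -> np.ndarray:
        return self.trials.loc[~self.trials["dropped"], "trial_index"].to_numpy()

    @property
    def dropped_trials(self) -> np.ndarray:
        return self.trials.loc[self.trials["dropped"], "trial_index"].to_numpy()


@dataclass
class PreprocessParams:
    """Thresholds of the cleaning chain (defaults follow the protocol)."""

    pad_ms: float = 100.0
    window_ms: float = 200.0
    trial_missing_threshold: float = 0.5
    session_missing_threshold: float = 0.15
    gaze_sd_multiplier: float = 3.3
    max_outside_s: float = 1.0
    # the three protocol ambiguities, exposed as switches:
    count_interpolated_as_missing: bool = True
    gaze_outside_mode: str = "cumulative"  # or "consecutive"
    trial_missing_window: str = "anticipation"  # or "trial"

    def __post_init__(self) -> None:
        if self.pad_ms < 0 or self.window_ms <= 0:
            raise ValueError("pad_ms must be >= 0 and window_ms > 0")
        for t in (self.trial_missing_threshold, self.session_missing_threshold):
            if not 0.0 < t < 1.0:
                raise ValueError("missingness thresholds must lie in (0, 1)")
        if self.gaze_outside_mode not in ("cumulative", "consecutive"):
            raise ValueError("gaze_outside_mode must be 'cumulative' or 'consecutive'")
        if self.trial_missing_window not in ("anticipation", "trial"):
            raise ValueError("trial_missing_window must be 'anticipation' or 'trial'")


def _runs(mask: np.ndarray) -> Iterable[Tuple[int, int]]:
    """Yield [start, stop) index pairs of maximal True runs."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for start, stop in zip(edges[::2], edges[1::2]):
        yield int(start), int(stop)


def interpolate_blinks(series: SampleSeries, pad_ms: float = 100.0) -> SampleSeries:
    """Linearly bridge blink gaps, padding ``pad_ms`` on both sides.

    A blink is any contiguous run of invalid samples. The replaced span
    runs between the last valid sample at least ``pad_ms`` before the
    gap and the first valid sample at least ``pad_ms`` after it; those
    two anchors keep their own values. Gaps without such anchors (at the
    session boundary, typically) are left missing. All overwritten
    samples are flagged ``interpolated``.
    """
    if pad_ms < 0:
        raise ValueError("pad_ms must be >= 0")
    out = series.copy()
    invalid = ~out.valid
    if invalid.all():
        raise ValueError(f"{series.participant_id}: entire series is invalid")
    pad_n = int(round(pad_ms / 1000.0 * series.sampling_rate_hz))
    n = out.time_s.size
    # expanding each gap by pad_n - 1 leaves the two pad_ms-distant
    # anchors in place; touching expansions merge into one bridged span
    expand = max(pad_n - 1, 0)
    spans: list[tuple[int, int]] = []
    for start, stop in _runs(invalid):
        start, stop = start - expand, stop + expand
        if spans and start <= spans[-1][1]:
            spans[-1] = (spans[-1][0], max(spans[-1][1], stop))
        else:
            spans.append((start, stop))
    for start, stop in spans:
        if start <= 0 or stop >= n:
            continue  # no anchor on one side: leave the gap missing
        left, right = start - 1, stop
        t0, t1 = out.time_s[left], out.time_s[right]
        v0, v1 = out.pupil[left], out.pupil[right]
        out.pupil[start:stop] = v0 + (out.time_s[start:stop] - t0) * (v1 - v0) / (t1 - t0)
        out.interpolated[start:stop] = True
    out.pupil[~out.usable] = np.nan
    return out


def smooth_sliding_mean(series: SampleSeries, window_ms: float = 200.0) -> SampleSeries:
    """Replace each pupil value with the mean of its +-window_ms/2 neighbourhood.

    The window is truncated at the series edges; only usable samples
    enter the mean, and samples without a value stay NaN. Gaze and
    validity flags are untouched.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be > 0")
    out = series.copy()
    h = int(np.floor(window_ms / 2.0 * series.sampling_rate_hz / 1000.0 + 1e-9))
    usable = out.usable
    if h == 0:
        return out
    n = out.pupil.size

    def windowed_sum(values: np.ndarray) -> np.ndarray:
        c = np.concatenate(([0.0], np.cumsum(values)))
        s = np.empty(n)
        s[h : n - h] = c[2 * h + 1 :] - c[: n - 2 * h]  # full windows
        head = np.arange(min(h, n))
        s[head] = c[np.minimum(head + h + 1, n)]
        tail = np.arange(max(n - h, 0), n)
        s[tail] = c[n] - c[np.maximum(tail - h, 0)]
        return s

    if usable.all():
        cnt = windowed_sum(np.ones(n))
        tot = windowed_sum(out.pupil)
    else:
        cnt = windowed_sum(usable.astype(float))
        tot = windowed_sum(np.where(usable, out.pupil, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = tot / cnt
    smoothed[cnt == 0] = np.nan
    smoothed[~usable] = np.nan
    out.pupil = smoothed
    return out


def zscore_session(series: SampleSeries) -> SampleSeries:
    """Z-transform pupil over the session's usable samples (sample SD, n-1)."""
    out = series.copy()
    usable = out.usable
    vals = out.pupil[usable]
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError(f"{series.participant_id}: need >= 2 usable samples to z-score")
    sd = float(np.std(vals, ddof=1))
    if sd == 0.0:
        raise ValueError(f"{series.participant_id}: zero pupil variance, cannot z-score")
    out.pupil = (out.pupil - float(np.mean(vals))) / sd
    return out


def _trial_slice(series: SampleSeries, t0: float, t1: float) -> slice:
    if t0 < series.time_s[0] - 1e-9 or t1 > series.time_s[-1] + 1e-9:
        raise ValueError(
            f"{series.participant_id}: event window [{t0}, {t1}] outside recorded session"
        )
    i0 = int(np.searchsorted(series.time_s, t0 - 1e-9, side="left"))
    i1 = int(np.searchsorted(series.time_s, t1 - 1e-9, side="left"))
    return slice(i0, i1)


def reject_missing(
    series: SampleSeries,
    events: pd.DataFrame,
    trial_threshold: float = 0.5,
    session_threshold: float = 0.15,
    params: PreprocessParams | None = None,
) -> QCReport:
    """Flag trials (>trial_threshold missing in the analysis window) and
    sessions (>session_threshold missing overall). Both comparisons are
    strict, so fractions exactly at threshold are kept.
    """
    params = params or PreprocessParams(
        trial_missing_threshold=trial_threshold,
        session_missing_threshold=session_threshold,
    )
    missing = series.missing if params.count_interpolated_as_missing else ~series.valid
    session_frac = float(np.mean(missing))
    rows = []
    cols = events[
        ["trial_index", "condition", "fixation_onset_s", "cue_onset_s", "cue_offset_s"]
    ].to_numpy(dtype=object).T
    fb_onset = events["feedback_onset_s"].to_numpy(dtype=float)
    for (trial_index, condition, fix_on, cue_on, cue_off), fb_on in zip(zip(*cols), fb_onset):
        if params.trial_missing_window == "anticipation":
            sl = _trial_slice(series, cue_on, cue_off)
        else:
            t_end = max(cue_off, fb_on) if np.isfinite(fb_on) else cue_off
            sl = _trial_slice(series, fix_on, t_end)
        frac = float(np.mean(missing[sl]))
        dropped = frac > params.trial_missing_threshold
        rows.append(
            {
                "trial_index": int(trial_index),
                "condition": condition,
                "trial_missing_fraction": frac,
                "out_of_window_s": 0.0,
                "dropped": dropped,
                "drop_reason": "missing" if dropped else "none",
            }
        )
    columns = [
        "trial_index", "condition", "trial_missing_fraction", "out_of_window_s",
        "dropped", "drop_reason",
    ]
    return QCReport(
        participant_id=series.participant_id,
        session_missing_fraction=session_frac,
        session_dropped=session_frac > params.session_missing_threshold,
        trials=pd.DataFrame(rows, columns=columns),
    )


def fit_gaze_window(
    sessions: Mapping[str, Tuple[SampleSeries, pd.DataFrame]],
    sd_multiplier: float = 3.3,
) -> Dict[str, GazeWindow]:
    """Per-participant gaze-window centers with cohort-level half-widths.

    Centers are each participant's median gaze over all anticipation
    windows (raw-valid samples); half-widths are ``sd_multiplier`` times
    the cohort mean of the per-participant gaze SDs.
    """
    if len(sessions) < 2:
        raise ValueError("fit_gaze_window needs at least 2 participants")
    centers: Dict[str, Tuple[float, float]] = {}
    sds_x, sds_y = [], []
    for pid, (series, events) in sessions.items():
        xs, ys = [], []
        for cue_on, cue_off in zip(
            events["cue_onset_s"].to_numpy(), events["cue_offset_s"].to_numpy()
        ):
            sl = _trial_slice(series, cue_on, cue_off)
            ok = series.valid[sl]
            xs.append(series.gaze_x_px[sl][ok])
            ys.append(series.gaze_y_px[sl][ok])
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        if x.size == 0:
            raise ValueError(f"{pid}: no valid anticipation-window gaze samples")
        centers[pid] = (float(np.median(x)), float(np.median(y)))
        sds_x.append(float(np.std(x, ddof=1)) if x.size > 1 else 0.0)
        sds_y.append(float(np.std(y, ddof=1)) if y.size > 1 else 0.0)
    half_x = sd_multiplier * float(np.mean(sds_x))
    half_y = sd_multiplier * float(np.mean(sds_y))
    return {
        pid: GazeWindow(cx, cy, half_x, half_y) for pid, (cx, cy) in centers.items()
    }


def reject_gaze(
    series: SampleSeries,
    events: pd.DataFrame,
    window: GazeWindow,
    qc: QCReport,
    max_outside_s: float = 1.0,
    mode: str = "cumulative",
) -> QCReport:
    """Drop trials whose gaze stays outside the window for more than
    ``max_outside_s`` (strict), counted over valid samples of the
    anticipation window, cumulatively by default.
    """
    if window.half_width_x_px <= 0 or window.half_height_y_px <= 0:
        raise ValueError("gaze window has non-positive half-widths")
    trials = qc.trials.copy()
    dt = 1.0 / series.sampling_rate_hz
    out_of_window = []
    for cue_on, cue_off in zip(
        events["cue_onset_s"].to_numpy(), events["cue_offset_s"].to_numpy()
    ):
        sl = _trial_slice(series, cue_on, cue_off)
        ok = series.valid[sl]
        outside = ok & (
            (np.abs(series.gaze_x_px[sl] - window.center_x_px) > window.half_width_x_px)
            | (np.abs(series.gaze_y_px[sl] - window.center_y_px) > window.half_height_y_px)
        )
        if mode == "cumulative":
            t_out = float(np.sum(outside)) * dt
        else:
            t_out = max((stop - start for start, stop in _runs(outside)), default=0) * dt
        out_of_window.append(t_out)
    trials["out_of_window_s"] = out_of_window
    gaze_drop = (trials["out_of_window_s"] > max_outside_s) & ~trials["dropped"]
    trials.loc[gaze_drop, "dropped"] = True
    trials.loc[gaze_drop, "drop_reason"] = "gaze"
    return QCReport(
        participant_id=qc.participant_id,
        session_missing_fraction=qc.session_missing_fraction,
        session_dropped=qc.session_dropped,
        trials=trials,
    )


def preprocess_session(
    series: SampleSeries,
    events: pd.DataFrame,
    params: PreprocessParams | None = None,
) -> Tuple[SampleSeries, QCReport]:
    """Run interpolate -> smooth -> z-transform -> missingness QC for one session."""
    params = params or PreprocessParams()
    clean = interpolate_blinks(series, pad_ms=params.pad_ms)
    clean = smooth_sliding_mean(clean, window_ms=params.window_ms)
    clean = zscore_session(clean)
    qc = reject_missing(
        clean,
        events,
        trial_threshold=params.trial_missing_threshold,
        session_threshold=params.session_missing_threshold,
        params=params,
    )
    return clean, qc


def preprocess_study(
    sessions: Mapping[str, Tuple[SampleSeries, pd.DataFrame]],
    params: PreprocessParams | None = None,
) -> Tuple[Dict[str, SampleSeries], Dict[str, QCReport], Dict[str, GazeWindow]]:
    """Apply the full cleaning chain to a cohort, including the
    cohort-level gaze window (which needs all participants at once)."""
    params = params or PreprocessParams()
    cleaned: Dict[str, SampleSeries] = {}
    reports: Dict[str, QCReport] = {}
    for pid, (series, events) in sessions.items():
        clean, qc = preprocess_session(series, events, params)
        cleaned[pid] = clean
        reports[pid] = qc
    windows = fit_gaze_window(sessions, sd_multiplier=params.gaze_sd_multiplier)
    for pid, (series, events) in sessions.items():
        reports[pid] = reject_gaze(
            cleaned[pid],
            events,
            windows[pid],
            reports[pid],
            max_outside_s=params.max_outside_s,
            mode=params.gaze_outside_mode,
        )
    return cleaned, reports, windows
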