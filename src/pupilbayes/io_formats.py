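"""Tabular data contracts: plain TSV, UTF-8, "." decimal.

Readers validate on load and reject malformed input with errors naming
the offending participant or row; writers emit files their paired
reader accepts unchanged (full float precision round-trip). Missing
samples are encoded as ``valid = false`` with the pupil value left
empty (an ignored value is also accepted).
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

from .preprocess import CONDITIONS, QCReport, SampleSeries

__all__ = [
    "read_samples",
    "write_samples",
    "read_events",
    "write_events",
    "read_clinical",
    "write_clinical",
    "read_features",
    "write_features",
    "read_posterior_summary",
    "write_posterior_summary",
    "write_qc_report",
    "read_config",
    "write_config",
    "samples_to_series",
    "series_to_samples",
    "write_ground_truth",
    "read_table",
    "write_table",
]

_FLOAT_FMT = "%.17g"

SAMPLE_COLUMNS = ["participant_id", "time_s", "pupil", "gaze_x_px", "gaze_y_px", "valid"]
EVENT_COLUMNS = [
    "participant_id",
    "trial_index",
    "condition",
    "fixation_onset_s",
    "cue_onset_s",
    "cue_offset_s",
    "feedback_onset_s",
    "feedback_success",
]
CLINICAL_COLUMNS = ["participant_id", "group", "symptom_count"] + [
    f"bdi_item_{j:02d}" for j in range(1, 22)
]


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _bool_series(s: pd.Series, path: str, col: str) -> pd.Series:
    def conv(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        if pd.isna(v) or v == "":
            return np.nan
        text = str(v).strip().lower()
        if text in ("true", "1"):
            return True
        if text in ("false", "0"):
            return False
        raise ValueError(f"{path}: column {col} has non-boolean value {v!r}")

    return s.map(conv)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    if not Path(path).exists():
        raise FileNotFoundError(path)
    # round_trip parser: %.17g output must reparse to the identical double
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


# --------------------------------------------------------------------------
# samples


def read_samples(path) -> pd.DataFrame:
    df = read_table(path)
    _require_columns(df, SAMPLE_COLUMNS, path)
    df["valid"] = _bool_series(df["valid"], str(path), "valid").astype(bool)
    for pid, sub in df.groupby("participant_id", sort=False):
        t = sub["time_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError(f"{path}: participant {pid}: time_s not strictly increasing")
        if dt.size and np.max(np.abs(dt - np.median(dt))) > 1e-6:
            raise ValueError(f"{path}: participant {pid}: non-uniform sampling interval")
    return df


def write_samples(sessions: Mapping[str, SampleSeries] | pd.DataFrame, path) -> None:
    if isinstance(sessions, pd.DataFrame):
        df = sessions
    else:
        df = series_to_samples(sessions)
    write_table(df, path)


def samples_to_series(df: pd.DataFrame, sampling_rate_hz: float | None = None) -> Dict[str, SampleSeries]:
    out: Dict[str, SampleSeries] = {}
    for pid, sub in df.groupby("participant_id", sort=False):
        t = sub["time_s"].to_numpy(dtype=float)
        fs = sampling_rate_hz or 1.0 / float(np.median(np.diff(t)))
        out[str(pid)] = SampleSeries(
            participant_id=str(pid),
            time_s=t,
            pupil=sub["pupil"].to_numpy(dtype=float),
            gaze_x_px=sub["gaze_x_px"].to_numpy(dtype=float),
            gaze_y_px=sub["gaze_y_px"].to_numpy(dtype=float),
            valid=sub["valid"].to_numpy(dtype=bool),
            sampling_rate_hz=fs,
        )
    return out


def series_to_samples(sessions: Mapping[str, SampleSeries]) -> pd.DataFrame:
    frames = []
    for pid, s in sessions.items():
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "time_s": s.time_s,
                    "pupil": s.pupil,
                    "gaze_x_px": s.gaze_x_px,
                    "gaze_y_px": s.gaze_y_px,
                    "valid": s.valid,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# events


def read_events(
    path, anticipation_s: float = 6.0, sample_period_s: float = 1.0 / 250.0
) -> pd.DataFrame:
    df = read_table(path)
    _require_columns(df, EVENT_COLUMNS, path)
    df["feedback_success"] = _bool_series(df["feedback_success"], str(path), "feedback_success")
    bad_cond = ~df["condition"].isin(CONDITIONS)
    if bad_cond.any():
        row = df.index[bad_cond][0]
        raise ValueError(f"{path}: row {row}: unknown condition {df.loc[row, 'condition']!r}")
    dur = df["cue_offset_s"] - df["cue_onset_s"]
    off = np.abs(dur - anticipation_s) > sample_period_s + 1e-9
    if off.any():
        row = df.index[off][0]
        raise ValueError(
            f"{path}: participant {df.loc[row, 'participant_id']} trial "
            f"{df.loc[row, 'trial_index']}: cue window {dur[row]:.4f}s does not match the "
            f"{anticipation_s}s contract"
        )
    for pid, sub in df.groupby("participant_id", sort=False):
        t = sub[["fixation_onset_s", "cue_onset_s", "cue_offset_s"]].to_numpy(dtype=float)
        if np.any(np.diff(t, axis=1) <= 0):
            raise ValueError(f"{path}: participant {pid}: trial phases out of order")
        fb = sub["feedback_onset_s"].to_numpy(dtype=float)
        late = np.isfinite(fb) & (fb < t[:, 2])
        if late.any():
            raise ValueError(f"{path}: participant {pid}: feedback before cue offset")
        starts = t[:, 0]
        ends = np.where(np.isfinite(fb), fb, t[:, 2])
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{path}: participant {pid}: overlapping trials")
    return df


def write_events(events: Mapping[str, pd.DataFrame] | pd.DataFrame, path) -> None:
    if not isinstance(events, pd.DataFrame):
        events = pd.concat(list(events.values()), ignore_index=True)
    write_table(events, path)


# --------------------------------------------------------------------------
# clinical


def read_clinical(path) -> pd.DataFrame:
    df = read_table(path)
    _require_columns(df, CLINICAL_COLUMNS, path)
    bad_group = ~df["group"].isin(("HC", "MDD"))
    if bad_group.any():
        row = df.index[bad_group][0]
        raise ValueError(f"{path}: row {row}: unknown group {df.loc[row, 'group']!r}")
    counts = df["symptom_count"]
    bad = (counts < 0) | (counts > 20) | (counts != counts.astype(int))
    if bad.any():
        row = df.index[bad][0]
        raise ValueError(
            f"{path}: participant {df.loc[row, 'participant_id']}: symptom_count "
            f"{counts[row]} outside 0-20"
        )
    hc_bad = (df["group"] == "HC") & (counts != 0)
    if hc_bad.any():
        row = df.index[hc_bad][0]
        raise ValueError(
            f"{path}: participant {df.loc[row, 'participant_id']}: healthy controls must "
            "report zero symptoms"
        )
    for j in range(1, 22):
        col = f"bdi_item_{j:02d}"
        vals = df[col]
        bad = (vals < 0) | (vals > 3) | (vals != vals.astype(int))
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(
                f"{path}: participant {df.loc[row, 'participant_id']} row {row}: {col} = "
                f"{vals[row]} outside the 0-3 item range"
            )
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    write_table(df, path)


# --------------------------------------------------------------------------
# features / posterior / qc


def read_features(path) -> pd.DataFrame:
    df = read_table(path)
    _require_columns(df, ["participant_id"], path)
    return df


def write_features(df: pd.DataFrame, path) -> None:
    write_table(df, path)


def write_posterior_summary(summary, path) -> None:
    """Write posterior summaries (a LatentCorrPosterior or a plain dict)
    as a two-column key/value TSV."""
    if hasattr(summary, "summary_dict"):
        summary = summary.summary_dict()
    values = [float(v) if isinstance(v, (bool, np.bool_)) else v for v in summary.values()]
    rows = pd.DataFrame({"key": list(summary.keys()), "value": values})
    write_table(rows, path)


def read_posterior_summary(path) -> Dict[str, float]:
    df = read_table(path)
    _require_columns(df, ["key", "value"], path)
    out: Dict[str, float] = {}
    for k, v in zip(df["key"], df["value"]):
        out[str(k)] = float(v)
    if "bf_is_lower_bound" in out:
        out["bf_is_lower_bound"] = bool(out["bf_is_lower_bound"])
    return out


def write_qc_report(reports: Mapping[str, QCReport], path) -> None:
    """One row per trial plus a per-participant session summary row."""
    frames = []
    for pid, rep in reports.items():
        trials = rep.trials.copy()
        trials.insert(0, "participant_id", pid)
        trials["row_type"] = "trial"
        trials["session_missing_fraction"] = rep.session_missing_fraction
        trials["session_dropped"] = rep.session_dropped
        summary = pd.DataFrame(
            [
                {
                    "participant_id": pid,
                    "row_type": "session",
                    "session_missing_fraction": rep.session_missing_fraction,
                    "session_dropped": rep.session_dropped,
                }
            ]
        )
        frames.extend([trials, summary])
    write_table(pd.concat(frames, ignore_index=True), path)


def write_ground_truth(truth, path) -> None:
    """Per-participant sidecar table of planted latent values."""
    write_table(truth.participants, path)


# --------------------------------------------------------------------------
# flat key = value run configuration


def write_config(config: Mapping[str, object], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in config.items():
            if isinstance(value, (tuple, list)):
                value = ",".join(str(v) for v in value)
            fh.write(f"{key} = {value}\n")


def read_config(path) -> Dict[str, str]:
    out: Dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
    return out
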