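"""Stage-wise analysis pipeline over the TSV contracts.

Each stage reads the previous stage's files from ``out_dir`` and writes
its own, so real (non-simulated) recordings can enter at any stage by
providing files in the same formats. Every run writes a manifest with
the seed, version, a config hash and every threshold, making outputs
reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .features import aggregate_features, derive_clinical
from .inference import (
    BFResult,
    LatentCorrPosterior,
    McmcSettings,
    NoisyPairData,
    PriorSpec,
    bf10_pearson,
    bf10_ttest,
    evidence_label,
    fit_latent_correlation,
    measurement_se,
    run_item_screen,
)
from .io_formats import (
    read_clinical,
    read_events,
    read_features,
    read_samples,
    read_table,
    samples_to_series,
    series_to_samples,
    write_config,
    write_features,
    write_posterior_summary,
    write_qc_report,
    write_table,
)
from .preprocess import PreprocessParams, QCReport, preprocess_study
from .synthetic import SimConfig, simulate_study

__all__ = ["RunConfig", "CONTRASTS", "stage_simulate", "stage_preprocess", "stage_features",
           "stage_correlate", "stage_items", "stage_report"]

CONTRASTS = {
    "reward-control": "diff_reward_minus_control",
    "reward-neutral": "diff_reward_minus_neutral",
    "reward": "dilation_reward",
    "neutral": "dilation_neutral",
    "control": "dilation_control",
    "fixation": "dilation_fixation_all",
    "fixation-diff": "diff_fixation_reward_minus_control",
    "consumption-reward": "dilation_consumption_reward",
    "consumption-neutral": "dilation_consumption_neutral",
}

SCORES = ("symptom_count", "anhedonia_score")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; echoed into the manifest."""

    out_dir: str = "pupilbayes_run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    pre: PreprocessParams = field(default_factory=PreprocessParams)
    priors: PriorSpec = field(default_factory=PriorSpec)
    mcmc: McmcSettings = field(default_factory=McmcSettings)
    reliability_pupil: float = 0.87  # split-half plug-in (0.70 = conservative alternative)
    reliability_symptoms: float = 0.78  # interview test-retest plug-in

    def path(self, name: str) -> Path:
        return Path(self.out_dir) / name

    def flatten(self) -> Dict[str, object]:
        flat: Dict[str, object] = {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "reliability_pupil": self.reliability_pupil,
            "reliability_symptoms": self.reliability_symptoms,
        }
        for section in ("sim", "pre", "priors", "mcmc"):
            obj = getattr(self, section)
            for f in dataclasses.fields(obj):
                flat[f"{section}.{f.name}"] = getattr(obj, f.name)
        return flat

    @classmethod
    def from_flat(cls, flat: Dict[str, str]) -> "RunConfig":
        run = cls()
        sections = {"sim": run.sim, "pre": run.pre, "priors": run.priors, "mcmc": run.mcmc}
        kwargs: Dict[str, Dict[str, object]] = {k: {} for k in sections}
        top: Dict[str, object] = {}
        for key, raw in flat.items():
            if "." in key:
                section, name = key.split(".", 1)
                if section not in sections:
                    raise ValueError(f"unknown config section {section!r}")
                target = sections[section]
                ftypes = {f.name: f.type for f in dataclasses.fields(target)}
                if name not in ftypes:
                    raise ValueError(f"unknown config key {key!r}")
                kwargs[section][name] = _coerce(raw, getattr(target, name))
            else:
                if key not in ("out_dir", "seed", "reliability_pupil", "reliability_symptoms"):
                    raise ValueError(f"unknown config key {key!r}")
                top[key] = _coerce(raw, getattr(run, key))
        return cls(
            out_dir=str(top.get("out_dir", run.out_dir)),
            seed=int(top.get("seed", run.seed)),
            sim=dataclasses.replace(run.sim, **kwargs["sim"]),
            pre=dataclasses.replace(run.pre, **kwargs["pre"]),
            priors=dataclasses.replace(run.priors, **kwargs["priors"]),
            mcmc=dataclasses.replace(run.mcmc, **kwargs["mcmc"]),
            reliability_pupil=float(top.get("reliability_pupil", run.reliability_pupil)),
            reliability_symptoms=float(top.get("reliability_symptoms", run.reliability_symptoms)),
        )

    def config_hash(self) -> str:
        payload = "\n".join(f"{k}={v}" for k, v in sorted(self.flatten().items()))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def write_manifest(self, stage: str) -> None:
        manifest = {"stage": stage, "version": __version__, "config_hash": self.config_hash()}
        manifest.update(self.flatten())
        write_config(manifest, self.path(f"manifest_{stage}.tsv"))


def _coerce(raw, template):
    if isinstance(raw, type(template)) and not isinstance(template, (tuple, list)):
        return raw
    text = str(raw)
    if isinstance(template, bool):
        return text.strip().lower() in ("true", "1", "yes")
    if isinstance(template, int) and not isinstance(template, bool):
        return int(text)
    if isinstance(template, float):
        return float(text)
    if isinstance(template, (tuple, list)):
        parts = [p.strip() for p in text.replace("(", "").replace(")", "").split(",") if p.strip()]

        def num(p: str):
            try:
                return int(p)
            except ValueError:
                return float(p)

        return tuple(num(p) for p in parts)
    return text


def _require(run: RunConfig, name: str, producer: str) -> Path:
    p = run.path(name)
    if not p.exists():
        raise FileNotFoundError(f"{p} not found: run the '{producer}' command first")
    return p


def stage_simulate(run: RunConfig) -> None:
    """Generate a simulated study and write the raw-data contracts."""
    Path(run.out_dir).mkdir(parents=True, exist_ok=True)
    sim = dataclasses.replace(run.sim, seed=run.seed)
    study = simulate_study(sim)
    write_table(series_to_samples(study.sessions), run.path("samples.tsv"))
    write_table(pd.concat(list(study.events.values()), ignore_index=True), run.path("events.tsv"))
    write_table(study.clinical, run.path("clinical.tsv"))
    write_table(study.truth.participants, run.path("ground_truth.tsv"))
    run.write_manifest("simulate")


def _events_by_pid(events: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    return {str(pid): sub.reset_index(drop=True) for pid, sub in events.groupby("participant_id", sort=False)}


def stage_preprocess(run: RunConfig) -> None:
    """Clean all sessions and write samples_clean.tsv plus qc_report.tsv."""
    Path(run.out_dir).mkdir(parents=True, exist_ok=True)
    samples = read_samples(_require(run, "samples.tsv", "simulate"))
    events = read_events(
        _require(run, "events.tsv", "simulate"),
        anticipation_s=run.sim.anticipation_s,
        sample_period_s=1.0 / run.sim.sampling_rate,
    )
    sessions = samples_to_series(samples, sampling_rate_hz=run.sim.sampling_rate)
    by_pid = _events_by_pid(events)
    cleaned, reports, _ = preprocess_study(
        {pid: (sessions[pid], by_pid[pid]) for pid in sessions}, run.pre
    )
    clean_df = series_to_samples(cleaned)
    interp = np.concatenate([cleaned[pid].interpolated for pid in cleaned])
    clean_df["interpolated"] = interp
    write_table(clean_df, run.path("samples_clean.tsv"))
    write_qc_report(reports, run.path("qc_report.tsv"))
    run.write_manifest("preprocess")


def _read_qc(run: RunConfig) -> Dict[str, QCReport]:
    df = read_table(_require(run, "qc_report.tsv", "preprocess"))
    reports: Dict[str, QCReport] = {}
    def as_bool(s: pd.Series) -> pd.Series:
        return s.map(lambda v: str(v).strip().lower() in ("true", "1"))

    for pid, sub in df.groupby("participant_id", sort=False):
        trials = sub[sub["row_type"] == "trial"].reset_index(drop=True)
        session = sub[sub["row_type"] == "session"].iloc[0]
        # the mixed trial/session layout leaves object dtypes behind
        trials = pd.DataFrame(
            {
                "trial_index": trials["trial_index"].astype(float).astype(int),
                "condition": trials["condition"].astype(str),
                "trial_missing_fraction": trials["trial_missing_fraction"].astype(float),
                "out_of_window_s": trials["out_of_window_s"].astype(float),
                "dropped": as_bool(trials["dropped"]),
                "drop_reason": trials["drop_reason"].astype(str),
            }
        )
        reports[str(pid)] = QCReport(
            participant_id=str(pid),
            session_missing_fraction=float(session["session_missing_fraction"]),
            session_dropped=str(session["session_dropped"]).strip().lower() in ("true", "1"),
            trials=trials,
        )
    return reports


def stage_features(run: RunConfig) -> None:
    """Per-participant dilation features and derived clinical scores."""
    clean = read_samples(_require(run, "samples_clean.tsv", "preprocess"))
    events = read_events(
        _require(run, "events.tsv", "simulate"),
        anticipation_s=run.sim.anticipation_s,
        sample_period_s=1.0 / run.sim.sampling_rate,
    )
    qc = _read_qc(run)
    sessions = samples_to_series(clean, sampling_rate_hz=run.sim.sampling_rate)
    feats, trials = aggregate_features(
        sessions, _events_by_pid(events), qc, feedback_s=run.sim.feedback_s
    )
    write_features(feats, run.path("features.tsv"))
    write_table(trials, run.path("trial_dilations.tsv"))
    clinical = read_clinical(_require(run, "clinical.tsv", "simulate"))
    write_table(derive_clinical(clinical), run.path("clinical_derived.tsv"))
    run.write_manifest("features")


def _merged(run: RunConfig) -> pd.DataFrame:
    feats = read_features(_require(run, "features.tsv", "features"))
    clin = read_table(_require(run, "clinical_derived.tsv", "features"))
    return feats.merge(clin, on="participant_id", how="inner")


def build_noisy_pairs(
    merged: pd.DataFrame,
    contrast: str,
    score: str,
    reliability_pupil: float,
    reliability_symptoms: float,
    subset: str = "all",
) -> NoisyPairData:
    """Assemble the observed pairs and their plug-in measurement SDs."""
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; choose from {sorted(CONTRASTS)}")
    if score not in SCORES:
        raise ValueError(f"unknown score {score!r}; choose from {SCORES}")
    if subset == "mdd":
        merged = merged[merged["group"] == "MDD"]
    elif subset != "all":
        raise ValueError("subset must be 'all' or 'mdd'")
    sub = merged[[CONTRASTS[contrast], score]].dropna()
    x = sub[CONTRASTS[contrast]].to_numpy(dtype=float)
    y = sub[score].to_numpy(dtype=float)
    se_x = measurement_se(float(np.std(x, ddof=1)), reliability_pupil)
    se_y = measurement_se(float(np.std(y, ddof=1)), reliability_symptoms)
    return NoisyPairData(x=x, y=y, se_x=se_x, se_y=se_y)


def stage_correlate(
    run: RunConfig,
    subset: str = "mdd",
    score: str = "symptom_count",
    contrast: str = "reward-control",
) -> LatentCorrPosterior:
    """Fit the measurement-error correlation model and write posterior.tsv."""
    merged = _merged(run)
    data = build_noisy_pairs(
        merged, contrast, score, run.reliability_pupil, run.reliability_symptoms, subset
    )
    post = fit_latent_correlation(data, run.priors, run.mcmc, seed=run.seed)
    summary = post.summary_dict()
    summary.update(
        {
            "subset": {"all": 0.0, "mdd": 1.0}[subset],
            "n_pairs": float(data.n),
            "se_x": float(data.se_x[0]),
            "se_y": float(data.se_y[0]),
        }
    )
    name = (
        "posterior.tsv"
        if (subset, score, contrast) == ("mdd", "symptom_count", "reward-control")
        else f"posterior_{contrast}_{score}_{subset}.tsv"
    )
    write_posterior_summary(summary, run.path(name))
    run.write_manifest("correlate")
    return post


def stage_items(run: RunConfig) -> pd.DataFrame:
    """BDI item screen against the differential dilation."""
    feats = read_features(_require(run, "features.tsv", "features"))
    clin = read_table(_require(run, "clinical_derived.tsv", "features"))
    screen = run_item_screen(feats, clin, x_col=CONTRASTS["reward-control"])
    write_table(screen, run.path("item_screen.tsv"))
    run.write_manifest("items")
    return screen


def stage_report(run: RunConfig) -> str:
    """Plain-text summary of the main result blocks."""
    merged = _merged(run)
    lines = ["pupilbayes report", "=" * 60]

    def corr_line(label: str, contrast: str, score: str, subset: str) -> str:
        try:
            data = build_noisy_pairs(
                merged, contrast, score, run.reliability_pupil, run.reliability_symptoms, subset
            )
        except Exception as exc:  # degenerate cells stay visible in the report
            return f"{label}: not computable ({exc})"
        res = bf10_pearson(data.x, data.y)
        return f"{label}: r = {res.statistic:.2f}, BF10 = {res.bf10:.1f} ({evidence_label(res.bf10)})"

    # replication-style latent-model fit on the differential score
    data = build_noisy_pairs(
        merged, "reward-control", "symptom_count",
        run.reliability_pupil, run.reliability_symptoms, "mdd",
    )
    post = fit_latent_correlation(data, run.priors, run.mcmc, seed=run.seed)
    lines += [
        "",
        "Latent correlation, differential dilation (reward - control) vs symptom count, "
        f"depressed only (n={data.n}):",
        f"  posterior mean r = {post.rho_mean:.2f}, 95% CI "
        f"[{post.rho_ci95[0]:.2f}, {post.rho_ci95[1]:.2f}], BF(-) = {post.bf_minus:.1f}"
        + (" (lower bound)" if post.bf_is_lower_bound else ""),
    ]
    data_all = build_noisy_pairs(
        merged, "reward-control", "symptom_count",
        run.reliability_pupil, run.reliability_symptoms, "all",
    )
    post_all = fit_latent_correlation(data_all, run.priors, run.mcmc, seed=run.seed)
    lines += [
        f"Full sample incl. controls (n={data_all.n}): posterior mean r = "
        f"{post_all.rho_mean:.2f}, BF(-) = {post_all.bf_minus:.1f}"
        + (" (lower bound)" if post_all.bf_is_lower_bound else ""),
    ]

    lines += ["", "Specificity (default BF10 correlations, full sample):"]
    for label, contrast in [
        ("  reward stimulus", "reward"),
        ("  neutral stimulus", "neutral"),
        ("  control stimulus", "control"),
        ("  fixation (all)", "fixation"),
        ("  fixation diff", "fixation-diff"),
        ("  consumption reward", "consumption-reward"),
        ("  consumption neutral", "consumption-neutral"),
    ]:
        lines.append(corr_line(label + " vs symptoms", contrast, "symptom_count", "all"))
    lines.append(corr_line("  reward-control vs anhedonia", "reward-control", "anhedonia_score", "all"))

    screen = stage_items(run)
    hits = screen[screen["moderate"] == True]  # noqa: E712
    lines += [
        "",
        f"BDI item screen: {len(hits)}/22 rows with BF10 > 3:",
    ]
    for row in hits.itertuples(index=False):
        lines.append(f"  {row.label}: r = {row.r:.2f}, BF10 = {row.bf10:.1f}")

    lines += ["", "Group comparisons (differential dilation):"]
    hc = merged.loc[merged["group"] == "HC", "diff_reward_minus_control"].dropna().to_numpy()
    mdd = merged.loc[merged["group"] == "MDD", "diff_reward_minus_control"].dropna().to_numpy()
    acute = merged.loc[merged["acute"] == True, "diff_reward_minus_control"].dropna().to_numpy()  # noqa: E712
    if hc.size >= 2 and mdd.size >= 2:
        res: BFResult = bf10_ttest(hc, mdd)
        lines.append(f"  HC vs all depressed: t = {res.statistic:.2f}, BF10 = {res.bf10:.2f}")
    if hc.size >= 2 and acute.size >= 2:
        res = bf10_ttest(hc, acute)
        lines.append(f"  HC vs acutely depressed (>=5 symptoms): t = {res.statistic:.2f}, "
                     f"BF10 = {res.bf10:.2f}")

    text = "\n".join(lines) + "\n"
    run.path("report.txt").write_text(text, encoding="utf-8")
    run.write_manifest("report")
    return text
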