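"""Orchestration: simulate -> invert -> evaluate for the three experiments.

A study emulates one of the retinotopic protocols — quadrants (4 angular
stimuli, 6 subjects), rings (3 eccentricities, 7 subjects) or quarter-rings
(6 stimuli, 5 subjects) — end to end: per-subject simulation at >= 95
trials per stimulus, source reconstruction with every requested method,
per-subject optimal-threshold selection, localization-accuracy tables and
nonparametric group statistics, all reproducible bit-for-bit from the
master seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import build_retinotopic_atlas
from .beamformer import TrialContrast, lcmv_weights, tf_beamformer, trial_source_stats
from .evaluation import (
    BONFERRONI_FAMILY,
    DEFAULT_Q_GRID,
    bonferroni,
    kruskal_wallis,
    localization_accuracy,
    optimize_threshold,
    signrank_vs_chance,
    threshold_active,
)
from .forward import compute_lead_field
from .geometry import build_sensor_array, build_source_space
from .minimum_norm import (
    dspm_map,
    estimate_noise_covariance,
    iid_map,
    make_inverse_operator,
)
from .simulate import (
    EvokedModel,
    NoiseModel,
    bandpass,
    quadrant_stimuli,
    quarter_ring_stimuli,
    reject_artifact_trials,
    ring_stimuli,
    simulate_subject,
)
from .sparse_priors import build_patch_library, msp_invert

log = logging.getLogger("retinomeg")

DEFAULT_SUBJECTS = {"quadrants": 6, "rings": 7, "quarter_rings": 5}
ALL_METHODS = ("mne", "iid", "beamformer", "tf_beamformer", "msp")


@dataclass(frozen=True)
class StudyConfig:
    """All knobs of one synthetic study; defaults are the study conditions.

    Timing parameters carry the standard protocol values: 4 Hz contrast
    reversal, 83 ms first response peak, 20 ms FRP window for dSPM and the
    evoked beamformer, 40 ms Gaussian window for MSP/IID, 7-9 Hz over
    200-1000 ms for the time-frequency beamformer, 1-40 Hz evoked band,
    -500..0 ms noise-covariance baseline and -250..0 ms ring baseline.
    """

    family: str = "quadrants"
    n_subjects: int | None = None
    n_trials: int = 95
    methods: tuple = ALL_METHODS
    seed: int = 0
    # geometry
    n_vertices_per_hemisphere: int = 120
    spacing: float = 0.004
    n_v3a: int = 12
    n_background: int = 48
    n_magnetometers: int = 60
    n_gradiometer_pairs: int = 60
    # signal and noise models (see simulate module for units)
    evoked: EvokedModel = field(default_factory=EvokedModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    v3a_coactivation: float = 0.3
    # solver parameters
    depth_exponent: float = 0.8
    lambda2: float = 1.0 / 9.0
    reg_fraction: float = 0.05
    shrinkage: float = 0.1
    evoked_band_hz: tuple = (1.0, 40.0)
    tf_band_hz: tuple = (7.0, 9.0)
    frp_window_ms: tuple = (73.0, 93.0)
    msp_window_ms: tuple = (63.0, 103.0)
    tf_window_ms: tuple = (200.0, 1000.0)
    baseline_window_ms: tuple = (-500.0, 0.0)
    ring_baseline_ms: tuple = (-250.0, 0.0)
    n_patches_unilateral: int = 48
    n_patches_bilateral: int = 24
    patch_smoothness: float = 0.008
    q_grid: tuple = DEFAULT_Q_GRID
    bonferroni_m: int | None = None  # default: family size for the protocol

    def resolved_subjects(self) -> int:
        return self.n_subjects if self.n_subjects is not None else DEFAULT_SUBJECTS[self.family]

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "evoked" in d and isinstance(d["evoked"], dict):
            d["evoked"] = EvokedModel(**d["evoked"])
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseModel(**d["noise"])
        for key, val in d.items():
            if isinstance(val, list):
                d[key] = tuple(val)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class StudyResult:
    config: StudyConfig
    records: pd.DataFrame      # one row per subject x method x stimulus x ROI
    thresholds: pd.DataFrame   # optimal q per subject x method x track
    group_stats: pd.DataFrame
    manifest: dict


def _stimuli_for(family: str):
    return {
        "quadrants": quadrant_stimuli,
        "rings": ring_stimuli,
        "quarter_rings": quarter_ring_stimuli,
    }[family]()


def _contrast_for(cfg: StudyConfig, stim) -> TrialContrast:
    if cfg.family == "quadrants":
        return TrialContrast("stimulus_vs_other_stimuli", stim.name)
    return TrialContrast("stimulus_vs_baseline", stim.name,
                         baseline_window_ms=cfg.ring_baseline_ms)


def _run_methods(cfg: StudyConfig, data, leadfield, stimuli):
    """All requested reconstructions for one subject.

    Returns {method: {stimulus: SourceEstimate}}.  Expensive shared pieces
    (filtered data, covariances, kernels, beamformer weights) are computed
    once per subject.
    """
    filtered = bandpass(data, *cfg.evoked_band_hz)
    noise_cov = estimate_noise_covariance(
        filtered, cfg.baseline_window_ms, cfg.shrinkage
    )
    out = {}
    if "mne" in cfg.methods:
        op = make_inverse_operator(leadfield, noise_cov, cfg.depth_exponent,
                                   cfg.lambda2)
        out["mne"] = {
            s: dspm_map(op, filtered, cfg.frp_window_ms,
                        trials=filtered.trials_for(s.name))
            for s in stimuli
        }
    if "iid" in cfg.methods:
        out["iid"] = {
            s: iid_map(filtered, leadfield, noise_cov, _contrast_for(cfg, s),
                       cfg.lambda2, cfg.msp_window_ms)
            for s in stimuli
        }
    if "beamformer" in cfg.methods:
        w = lcmv_weights(leadfield, filtered, cfg.evoked_band_hz,
                         (0.0, 1000.0), cfg.reg_fraction,
                         data_filtered=filtered.data)
        out["beamformer"] = {
            s: trial_source_stats(w, filtered, _contrast_for(cfg, s),
                                  cfg.frp_window_ms,
                                  data_filtered=filtered.data)
            for s in stimuli
        }
    if "tf_beamformer" in cfg.methods:
        out["tf_beamformer"] = {
            s: tf_beamformer(leadfield, data, _contrast_for(cfg, s),
                             cfg.tf_band_hz, cfg.tf_window_ms,
                             cfg.reg_fraction)
            for s in stimuli
        }
    if "msp" in cfg.methods:
        library = build_patch_library(
            leadfield.space, cfg.n_patches_unilateral, cfg.n_patches_bilateral,
            cfg.patch_smoothness,
        )
        out["msp"] = {
            s: msp_invert(filtered, leadfield, noise_cov, library,
                          _contrast_for(cfg, s), cfg.msp_window_ms)
            for s in stimuli
        }
    return out


def _tracks_for(family: str):
    """Evaluation tracks: (track name, threshold-objective selector,
    per-stimulus record selectors)."""
    if family == "quadrants":
        return [("angular", "angular", ["V1", "V2", "V3", "V3A"])]
    if family == "rings":
        return [("eccentricity", "eccentricity",
                 [("eccentricity", "L"), ("eccentricity", "R")])]
    return [
        ("angular", "angular", ["angular"]),
        ("eccentricity", "eccentricity", ["eccentricity"]),
    ]


def run_study(config: StudyConfig, out_dir=None) -> StudyResult:
    """Simulate, invert and evaluate a full study; optionally write reports."""
    cfg = config
    if cfg.family not in DEFAULT_SUBJECTS:
        raise ValueError(f"unknown experiment family {cfg.family!r}")
    log.info("[setup] building geometry and lead field")
    space = build_source_space(
        cfg.n_vertices_per_hemisphere, cfg.spacing,
        {"n_v3a": cfg.n_v3a, "n_background": cfg.n_background},
    )
    atlas = build_retinotopic_atlas(space)
    sensors = build_sensor_array(cfg.n_magnetometers, cfg.n_gradiometer_pairs)
    leadfield = compute_lead_field(space, sensors)
    stimuli = _stimuli_for(cfg.family)
    n_subjects = cfg.resolved_subjects()

    rec_rows, thr_rows = [], []
    for s_idx in range(n_subjects):
        subject = f"S{s_idx + 1}"
        seed = int(np.random.SeedSequence([cfg.seed, s_idx]).generate_state(1)[0]
                   % (2**31))
        log.info("[simulate] %s (seed %d)", subject, seed)
        data = simulate_subject(
            [(s, cfg.n_trials) for s in stimuli], atlas, leadfield,
            cfg.evoked, cfg.noise, subject_id=subject, seed=seed,
            v3a_coactivation=cfg.v3a_coactivation,
        )
        data, rej = reject_artifact_trials(data)
        if rej["n_rejected"]:
            log.info("[artifacts] %s: rejected %d/%d trials", subject,
                     rej["n_rejected"], rej["n_total"])
        log.info("[invert] %s: %s", subject, ", ".join(cfg.methods))
        estimates = _run_methods(cfg, data, leadfield, stimuli)
        for method, per_stim in estimates.items():
            for track, objective, selectors in _tracks_for(cfg.family):
                q_opt, _curve = optimize_threshold(per_stim, atlas, objective,
                                                   cfg.q_grid)
                thr_rows.append({"subject": subject, "method": method,
                                 "track": track, "q_optimal": q_opt})
                for stim, est in per_stim.items():
                    active = threshold_active(est, q_opt)
                    for sel in selectors:
                        rec = localization_accuracy(active, atlas, stim, sel,
                                                    method, subject)
                        rec_rows.append({
                            "subject": subject, "method": method,
                            "track": track, "stimulus": stim.name,
                            "roi": _selector_label(sel),
                            "accuracy_percent": rec.percent,
                            "chance_percent": rec.chance,
                            "n_active_in_roi": rec.n_active_in_roi,
                            "excluded": rec.excluded,
                            "q_percent": q_opt,
                        })

    records = pd.DataFrame(rec_rows)
    thresholds = pd.DataFrame(thr_rows)
    group = _group_statistics(cfg, records)
    manifest = {
        "package_version": __version__,
        "config": _config_dict(cfg),
        "n_subjects": n_subjects,
        "stimuli": [s.name for s in stimuli],
        "n_sensors": sensors.n_sensors,
        "n_vertices": space.n_vertices,
    }
    result = StudyResult(cfg, records, thresholds, group, manifest)
    if out_dir is not None:
        _write_report(result, out_dir)
    return result


def _selector_label(sel) -> str:
    if isinstance(sel, tuple):
        return f"{sel[0]}_{sel[1]}"
    return sel


def _config_dict(cfg: StudyConfig) -> dict:
    d = asdict(cfg)
    d["evoked"] = asdict(cfg.evoked)
    d["noise"] = asdict(cfg.noise)
    return d


def _subject_means(records: pd.DataFrame, by: str) -> pd.DataFrame:
    """Per-subject mean accuracy over stimuli (excluded records dropped)."""
    ok = records[~records["excluded"]]
    return (
        ok.groupby(["method", by, "subject"])["accuracy_percent"]
        .mean()
        .reset_index()
    )


def _group_statistics(cfg: StudyConfig, records: pd.DataFrame) -> pd.DataFrame:
    family_m = cfg.bonferroni_m or BONFERRONI_FAMILY[cfg.family]
    rows = []
    if cfg.family == "quadrants":
        cells = [("roi", roi) for roi in ("V1", "V2", "V3", "V3A")]
        group_col = "roi"
    elif cfg.family == "rings":
        cells = [("stimulus", s) for s in ("ECC1", "ECC2", "ECC3")]
        group_col = "stimulus"
    else:
        records = records.assign(
            field_half=np.where(records["stimulus"].str.startswith("U"),
                                "upper", "lower")
        )
        cells = [("field_half", h) for h in ("upper", "lower")]
        group_col = "field_half"

    for track in records["track"].unique():
        sub = records[records["track"] == track]
        means = _subject_means(sub, group_col)
        for col, value in cells:
            cell = means[means[group_col] == value]
            chance_vals = sub.loc[sub[group_col] == value, "chance_percent"]
            if cell.empty or chance_vals.empty:
                continue
            chance = float(chance_vals.iloc[0])
            for method in sub["method"].unique():
                vals = cell.loc[cell["method"] == method, "accuracy_percent"]
                row = {"track": track, "cell": value, "method": method,
                       "test": "wilcoxon_signrank_vs_chance",
                       "chance_percent": chance, "n": len(vals),
                       "mean_accuracy": float(vals.mean()) if len(vals) else np.nan,
                       "sd_accuracy": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan}
                try:
                    gs = signrank_vs_chance(vals, chance)
                    sig, alpha_c, p_c = bonferroni(gs.p, family_m)
                    row.update({"statistic": gs.statistic, "p_raw": gs.p,
                                "p_corrected": p_c, "alpha_corrected": alpha_c,
                                "significant": bool(sig),
                                "family_size": family_m,
                                "degenerate": gs.degenerate})
                except ValueError as err:
                    row.update({"statistic": np.nan, "p_raw": np.nan,
                                "p_corrected": np.nan,
                                "alpha_corrected": 0.05 / family_m,
                                "significant": False, "family_size": family_m,
                                "degenerate": True, "note": str(err)})
                rows.append(row)
            # between-method comparison within the cell
            groups = [
                cell.loc[cell["method"] == m, "accuracy_percent"].to_numpy()
                for m in sub["method"].unique()
            ]
            groups = [g for g in groups if len(g) >= 2]
            if len(groups) >= 2:
                kw = kruskal_wallis(groups)
                rows.append({"track": track, "cell": value, "method": "all",
                             "test": "kruskal_wallis_between_methods",
                             "chance_percent": chance, "n": kw.n,
                             "statistic": kw.statistic, "p_raw": kw.p,
                             "degenerate": kw.degenerate,
                             "family_size": 1})
    return pd.DataFrame(rows)


def summary_table(result: StudyResult) -> pd.DataFrame:
    """Mean (SD) accuracy per ROI/cell x method, mirroring a results table."""
    gs = result.group_stats
    sr = gs[gs["test"] == "wilcoxon_signrank_vs_chance"]
    out = sr.pivot_table(index=["track", "cell"], columns="method",
                         values="mean_accuracy", sort=False)
    return out.round(1)


def _write_report(result: StudyResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.records.to_csv(out / "accuracy_records.csv", index=False)
    result.thresholds.to_csv(out / "optimal_thresholds.csv", index=False)
    result.group_stats.to_csv(out / "group_stats.csv", index=False)
    summary_table(result).to_csv(out / "summary_table.csv")
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1,
                                                  default=str))
    log.info("[report] wrote %s", out)


def make_figures(result: StudyResult, out_dir) -> list[Path]:
    """Bar charts of accuracy per ROI and method with chance lines and
    significance asterisks; deterministic files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result.records.empty:
        raise ValueError("empty report; nothing to plot")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gs = result.group_stats
    sr = gs[gs["test"] == "wilcoxon_signrank_vs_chance"]
    paths = []
    for track in sr["track"].unique():
        sub = sr[sr["track"] == track]
        cells = list(dict.fromkeys(sub["cell"]))
        methods = list(dict.fromkeys(sub["method"]))
        width = 0.8 / max(len(methods), 1)
        fig, ax = plt.subplots(figsize=(1.8 + 1.4 * len(cells), 3.6))
        for mi, method in enumerate(methods):
            xs, ys = [], []
            for ci, cell in enumerate(cells):
                row = sub[(sub["cell"] == cell) & (sub["method"] == method)]
                if row.empty:
                    continue
                x = ci + (mi - (len(methods) - 1) / 2) * width
                y = float(row["mean_accuracy"].iloc[0])
                xs.append(x)
                ys.append(y)
                if bool(row["significant"].iloc[0]):
                    ax.text(x, y + 2, "*", ha="center", fontsize=12)
            ax.bar(xs, ys, width=width * 0.9, label=method)
        for ci, cell in enumerate(cells):
            chance = float(sub[sub["cell"] == cell]["chance_percent"].iloc[0])
            ax.hlines(chance, ci - 0.45, ci + 0.45, colors="k", linewidth=1.2)
        ax.set_xticks(range(len(cells)))
        ax.set_xticklabels(cells)
        ax.set_ylabel("localization accuracy (%)")
        ax.set_ylim(0, 110)
        ax.legend(fontsize=8)
        ax.set_title(f"{result.config.family}: {track}")
        fig.tight_layout()
        path = out / f"accuracy_{result.config.family}_{track}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths
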