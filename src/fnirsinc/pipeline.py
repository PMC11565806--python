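"""End-to-end study replica on synthetic data.

``run_study`` generates a cohort, simulates resting (fast/proper capping)
and task runs, computes channel quality, the combined hair-skin metric,
the correlation/robust-fit/fold-change tables, the robust multiple
regressions, the capping comparison, the NEP sensitivity curves, and the
task GLM summary — writing every stage's output as CSV plus a manifest.
``report`` renders a markdown summary with figures from a saved bundle.

Only the right hemisphere enters the analyses (the emulated study analyzed
a single, uniform detector type on that side); the simulator still
produces both.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import hrf_glm, io_formats, nep_inclusivity, quality_metrics, \
    stats_analysis, synthetic_data
from .participant_metrics import assign_group, combined_hair_skin_metric

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_study", "report"]

_REGRESSION_PRIORITY = [
    "skin_pigmentation", "hair_color", "avg_shaft_thickness", "avg_num_hairs",
    "sex_female", "head_circumference_cm", "age",
]


@dataclass
class PipelineConfig:
    n_participants: int = 50
    seed: int = 0
    output_dir: str = "fnirsinc_out"
    rois: tuple[str, ...] = ("forehead", "side", "back")
    hemisphere: str = "right"
    rest_duration_s: float = 180.0
    task_duration_s: float = 380.0
    n_trials: int = 15
    fs: float = 10.2
    unit_of_analysis: str = "channel"          # or "participant"
    log_before_average: bool = False
    use_short_separation: bool = True
    nep_grid: tuple[float, ...] = tuple(np.geomspace(1e-14, 1e-12, 9))
    run_glm: bool = True
    simulation: synthetic_data.SimulationConfig | None = None

    def __post_init__(self):
        if self.unit_of_analysis not in ("channel", "participant"):
            raise ValueError("unit_of_analysis must be channel|participant")
        if self.simulation is None:
            self.simulation = synthetic_data.SimulationConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a pipeline configuration from a YAML mapping; a nested
        ``simulation`` mapping configures the forward model."""
        import yaml
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("pipeline config must be a YAML mapping")
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = synthetic_data.SimulationConfig(
                seed=raw.get("seed", cfg.seed), **sim)
        return cfg


def _factor_row(profile: synthetic_data.ParticipantProfile, roi: str) -> dict:
    row = {
        "participant_id": profile.id,
        "skin_pigmentation": profile.skin_pigmentation,
        "skin_type": profile.skin_type,
        "hair_color": profile.hair_color,
        "hair_type": profile.hair_type,
        "hair_texture": profile.hair_texture,
        "sex_female": 1.0 if profile.sex == "female" else 0.0,
        "head_circumference_cm": profile.head_circumference_cm,
        "nasion_inion_cm": profile.nasion_inion_cm,
        "ear_to_ear_cm": profile.ear_to_ear_cm,
        "age": profile.age,
    }
    if roi in profile.trichoscopy:
        b = profile.trichoscopy[roi]
        row.update({
            "avg_num_hairs": b.avg_num_hairs,
            "avg_shaft_thickness": b.avg_shaft_thickness,
            "thin_hairs_pct": b.thin_pct,
            "middle_hairs_pct": b.middle_pct,
            "thick_hairs_pct": b.thick_pct,
            "single_fu_pct": b.single_fu_pct,
            "double_fu_pct": b.double_fu_pct,
            "triple_fu_pct": b.triple_fu_pct,
            "cumulative_thickness": b.cumulative_thickness,
            "n_follicular_units": b.n_follicular_units,
            "sinclair_scale": b.sinclair_scale,
        })
    return row


def _roi_factors(roi: str) -> list[str]:
    base = ["skin_pigmentation", "skin_type", "sex_female",
            "head_circumference_cm", "nasion_inion_cm", "ear_to_ear_cm", "age"]
    if roi == "forehead":
        return base
    hair = ["avg_num_hairs", "avg_shaft_thickness", "thin_hairs_pct",
            "middle_hairs_pct", "thick_hairs_pct", "single_fu_pct",
            "double_fu_pct", "triple_fu_pct", "cumulative_thickness",
            "n_follicular_units", "sinclair_scale",
            "hair_color", "hair_type", "hair_texture"]
    return hair + base


def _regression_candidates(roi: str) -> list[str]:
    if roi == "forehead":
        return ["skin_pigmentation", "skin_type", "sex_female",
                "head_circumference_cm", "age"]
    return ["avg_num_hairs", "avg_shaft_thickness", "skin_pigmentation",
            "skin_type", "hair_color", "hair_type", "hair_texture",
            "sex_female", "head_circumference_cm", "age"]


def correlation_table(merged: pd.DataFrame, roi: str,
                      response: str = "csm") -> pd.DataFrame:
    """Per-factor Spearman rho, BH-adjusted p, robust-fit slope/intercept
    and 1st-99th percentile fold change for one ROI."""
    rows = []
    factors = [f for f in _roi_factors(roi) if f in merged.columns]
    for factor in factors:
        sub = merged[[factor, response]].dropna()
        x, y = sub[factor].to_numpy(), sub[response].to_numpy()
        if np.ptp(x) == 0:
            continue
        sp = stats_analysis.spearman(x, y)
        fit = stats_analysis.robust_linfit(x, y)
        fc = stats_analysis.fold_change(fit, x)
        rows.append({"roi": roi, "factor": factor,
                     "fold_change": fc.fold_change, "rho": sp["rho"],
                     "p": sp["p"], "slope": fit["slope"],
                     "intercept": fit["intercept"], "n": len(sub)})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bh"] = stats_analysis.bh_adjust(out["p"].to_numpy())
        out["significant"] = out["p_bh"] <= stats_analysis.SIGNIFICANCE_ALPHA
    return out


def regression_table(merged: pd.DataFrame, roi: str,
                     response: str = "csm") -> pd.DataFrame:
    """Screened robust multiple regression for one ROI (estimate, SE, t, p,
    f², VIF per predictor)."""
    candidates = [c for c in _regression_candidates(roi) if c in merged.columns]
    sub = merged[candidates + [response]].dropna()
    X = sub[candidates]
    kept = stats_analysis.multicollinearity_screen(
        X, priority=[c for c in _REGRESSION_PRIORITY if c in candidates]
        + [c for c in candidates if c not in _REGRESSION_PRIORITY])
    rep = stats_analysis.robust_multiple_regression(X[kept],
                                                   sub[response].to_numpy())
    table = rep.table.reset_index(names="predictor")
    table.insert(0, "roi", roi)
    table["r_squared"] = rep.r_squared
    table["n"] = rep.n
    return table


def run_study(config: PipelineConfig) -> dict:
    """Run the full synthetic study; returns the bundle of output paths and
    in-memory tables."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    logger.info("generating cohort (n=%d)", config.n_participants)
    participants = synthetic_data.generate_participants(config.n_participants,
                                                        sim)
    probe = synthetic_data.generate_probe()
    io_formats.write_participants(participants, outdir / "participants.tsv")

    # --- per-participant simulation & QC -----------------------------------
    qc_rows_run1, qc_rows_run2, glm_rows = [], [], []
    rng = np.random.default_rng(sim.seed)
    for k, prof in enumerate(participants):
        base_seed = int(rng.integers(0, 2 ** 31 - 1))
        run1, run2 = synthetic_data.generate_capping_pair(
            prof, probe, sim, duration_s=config.rest_duration_s,
            fs=config.fs, seed=base_seed)
        qc1 = quality_metrics.channel_quality_table(
            run1, prof.id, config.log_before_average)
        qc2 = quality_metrics.channel_quality_table(
            run2, prof.id, config.log_before_average)
        qc_rows_run1.append(qc1)
        qc_rows_run2.append(qc2)
        if config.run_glm:
            stim = synthetic_data.generate_events(config.n_trials,
                                                  seed=base_seed + 2)
            dur = max(config.task_duration_s, stim.run_duration)
            task = synthetic_data.generate_recording(
                prof, probe, dur, config.fs, stim=stim, config=sim,
                seed=base_seed + 3, run_label="task")
            glm_rows.append(_participant_glm_summary(
                task, probe, stim, prof.id, config))
    qc1 = pd.concat(qc_rows_run1, ignore_index=True)
    qc2 = pd.concat(qc_rows_run2, ignore_index=True)
    qc1.to_csv(outdir / "qc_run1.csv", index=False)
    qc2.to_csv(outdir / "qc_run2.csv", index=False)

    # --- combined metric & groups ------------------------------------------
    metric_rows = []
    for prof in participants:
        thickness = np.mean([prof.trichoscopy[r].avg_shaft_thickness
                             for r in ("side", "back")])
        m = combined_hair_skin_metric(thickness, prof.hair_type,
                                      prof.hair_color, prof.skin_pigmentation)
        metric_rows.append({"participant_id": prof.id, "combined_metric": m,
                            "group": assign_group(m)})
    metrics = pd.DataFrame(metric_rows)
    metrics.to_csv(outdir / "metrics.csv", index=False)

    # --- statistics on the proper-capping run ------------------------------
    analysis = qc2[(qc2["hemisphere"] == config.hemisphere)
                   & (qc2["kind"] == "long")]
    corr_tables, reg_tables_csm, reg_tables_sci = [], [], []
    for roi in config.rois:
        factor_df = pd.DataFrame([_factor_row(p, roi) for p in participants])
        merged = analysis[analysis["roi"] == roi].merge(
            factor_df, left_on="participant", right_on="participant_id")
        if config.unit_of_analysis == "participant":
            num = merged.select_dtypes("number").columns
            merged = merged.groupby("participant", as_index=False)[num].mean()
        corr_tables.append(correlation_table(merged, roi, "csm"))
        reg_tables_csm.append(regression_table(merged, roi, "csm"))
        merged_sci = merged.rename(columns={"sci_z": "resp"})
        reg = regression_table(merged_sci, roi, "resp")
        reg_tables_sci.append(reg)
    corr = pd.concat(corr_tables, ignore_index=True)
    corr.to_csv(outdir / "correlation_table.csv", index=False)
    reg_csm = pd.concat(reg_tables_csm, ignore_index=True)
    reg_csm.to_csv(outdir / "regression_csm.csv", index=False)
    reg_sci = pd.concat(reg_tables_sci, ignore_index=True)
    reg_sci.to_csv(outdir / "regression_sci.csv", index=False)

    # --- capping comparison ------------------------------------------------
    capping_rows = []
    for roi in config.rois:
        sel1 = qc1[(qc1["roi"] == roi) & (qc1["hemisphere"] == config.hemisphere)]
        sel2 = qc2[(qc2["roi"] == roi) & (qc2["hemisphere"] == config.hemisphere)]
        for metric in ("sci", "usm"):
            cmp = quality_metrics.compare_runs(sel1[metric].to_numpy(),
                                               sel2[metric].to_numpy())
            cmp.update({"roi": roi, "metric": metric})
            capping_rows.append(cmp)
    capping = pd.DataFrame(capping_rows)
    capping.to_csv(outdir / "capping_comparison.csv", index=False)

    # --- NEP inclusivity ----------------------------------------------------
    nep_model = nep_inclusivity.NepModel(noise_floor_raw=sim.noise_floor_raw
                                         if sim.noise_floor_raw > 0 else 6.8e-6)
    nep_df = analysis.merge(metrics, left_on="participant",
                            right_on="participant_id")
    group_pct = nep_inclusivity.group_pass_percentages(
        nep_df["usm"].to_numpy(), nep_df["group"].to_numpy(), nep_model)
    curves = nep_inclusivity.sensitivity_sweep(
        nep_df["usm"].to_numpy(), nep_df["group"].to_numpy(),
        np.asarray(config.nep_grid), nep_model)
    group_pct.rename("percent").to_csv(outdir / "nep_group_pass.csv")
    curves.to_csv(outdir / "nep_curves.csv")

    # --- GLM regression table ----------------------------------------------
    glm_reg = None
    if config.run_glm and glm_rows:
        glm_df = pd.DataFrame(glm_rows)
        glm_df.to_csv(outdir / "glm_per_participant.csv", index=False)
        factor_df = pd.DataFrame([_factor_row(p, "side") for p in participants])
        merged = glm_df.merge(factor_df, on="participant_id")
        parts = []
        for resp in ("beta_hbo", "tstat_hbo"):
            t = regression_table(merged.rename(columns={resp: "resp"}),
                                 "side", "resp")
            t.insert(0, "response", resp)
            parts.append(t)
        glm_reg = pd.concat(parts, ignore_index=True)
        glm_reg.to_csv(outdir / "glm_regression.csv", index=False)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "n_participants": config.n_participants,
        "config_hash": hashlib.sha256(
            json.dumps(_jsonable(asdict(config)), sort_keys=True).encode()
        ).hexdigest(),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "outdir": outdir, "participants": participants, "probe": probe,
        "qc_run1": qc1, "qc_run2": qc2, "metrics": metrics,
        "correlation": corr, "regression_csm": reg_csm,
        "regression_sci": reg_sci, "capping": capping,
        "nep_group_pass": group_pct, "nep_curves": curves,
        "glm_regression": glm_reg, "manifest": manifest,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def channel_glm_table(task, probe, stim, roi: str = "side",
                      hemisphere: str | None = None,
                      use_short_separation: bool = True) -> pd.DataFrame:
    """Per-channel GLM outputs for one task recording.

    Fits HbO₂ and HbR (each with its own response kernel) for every
    SNR-retained long channel of the ROI, using the best-correlated
    retained short channel as nuisance regressor.  Columns: channel,
    condition, beta_hbo, beta_hbr, tstat_hbo, ss_channel.
    """
    snrs = [quality_metrics.snr(task, i) for i in range(len(task.channels))]
    keep = set(quality_metrics.prune_by_snr(snrs))
    hemis = [hemisphere] if hemisphere else list({ch.hemisphere
                                                  for ch in task.channels})
    long_idx, short_idx = [], []
    for h in hemis:
        long_idx += [i for i in probe.channel_indices(roi, "long", h)
                     if i in keep]
        short_idx += [i for i in probe.channel_indices(roi, "short", h)
                      if i in keep]
    use_idx = long_idx + short_idx
    if not long_idx:
        return pd.DataFrame(columns=["channel", "condition", "beta_hbo",
                                     "beta_hbr", "tstat_hbo", "ss_channel"])
    sub = synthetic_data.IntensityRecording(
        data=task.data[use_idx], fs=task.fs,
        channels=[task.channels[i] for i in use_idx],
        wavelengths=task.wavelengths,
        source_power_pct=task.source_power_pct[use_idx],
        run_label=task.run_label)
    od = hrf_glm.intensity_to_od(sub)
    od_f = hrf_glm.OdSeries(hrf_glm.lowpass(od.values, task.fs), task.fs,
                            od.channels, od.wavelengths)
    conc = hrf_glm.od_to_conc(od_f, [c.separation_mm for c in sub.channels])
    pos = {orig: new for new, orig in enumerate(use_idx)}
    rows = []
    for i in long_idx:
        hemi_shorts = [j for j in short_idx
                       if task.channels[j].hemisphere
                       == task.channels[i].hemisphere]
        ss_hbo = ss_hbr = ss_label = None
        if use_short_separation and hemi_shorts:
            shorts = {task.channels[j].label: conc.hbo[pos[j]]
                      for j in hemi_shorts}
            ss_label, ss_hbo = hrf_glm.select_ss_regressor(conc.hbo[pos[i]],
                                                           shorts)
            ss_hbr = conc.hbr[pos[[j for j in hemi_shorts
                                   if task.channels[j].label == ss_label][0]]]
        res_o = hrf_glm.glm_fit(conc.hbo[pos[i]], task.fs, stim,
                                hrf_glm.HRF_SPEC_HBO, ss_hbo, ss_label)
        res_r = hrf_glm.glm_fit(conc.hbr[pos[i]], task.fs, stim,
                                hrf_glm.HRF_SPEC_HBR, ss_hbr, ss_label)
        for cond in stim.conditions:
            rows.append({
                "channel": task.channels[i].label,
                "hemisphere": task.channels[i].hemisphere,
                "condition": cond,
                "beta_hbo": res_o.betas[f"cond:{cond}"],
                "beta_hbr": res_r.betas[f"cond:{cond}"],
                "tstat_hbo": res_o.tstats[f"cond:{cond}"],
                "ss_channel": ss_label,
            })
    return pd.DataFrame(rows)


def _participant_glm_summary(task, probe, stim, participant_id,
                             config: PipelineConfig) -> dict:
    """Mean HbO₂ beta and t-statistic over the analyzed motor (side, long)
    channels of one task run, using the SNR-pruned, SS-regressed GLM."""
    snrs = [quality_metrics.snr(task, i) for i in range(len(task.channels))]
    keep = set(quality_metrics.prune_by_snr(snrs))
    hemi = config.hemisphere
    long_idx = [i for i in probe.channel_indices("side", "long", hemi)
                if i in keep]
    short_idx = [i for i in probe.channel_indices("side", "short", hemi)
                 if i in keep]
    use_idx = long_idx + short_idx
    if not use_idx:
        return {"participant_id": participant_id, "beta_hbo": np.nan,
                "tstat_hbo": np.nan, "n_channels": 0}
    sub = synthetic_data.IntensityRecording(
        data=task.data[use_idx], fs=task.fs,
        channels=[task.channels[i] for i in use_idx],
        wavelengths=task.wavelengths,
        source_power_pct=task.source_power_pct[use_idx],
        run_label=task.run_label)
    od = hrf_glm.intensity_to_od(sub)
    filt = hrf_glm.lowpass(od.values, task.fs)
    od_f = hrf_glm.OdSeries(filt, task.fs, od.channels, od.wavelengths)
    seps = [ch.separation_mm for ch in sub.channels]
    conc = hrf_glm.od_to_conc(od_f, seps)
    pos = {orig: new for new, orig in enumerate(use_idx)}
    betas, tstats = [], []
    for i in long_idx:
        ss_reg = ss_label = None
        if config.use_short_separation and short_idx:
            shorts = {task.channels[j].label: conc.hbo[pos[j]]
                      for j in short_idx}
            ss_label, ss_reg = hrf_glm.select_ss_regressor(conc.hbo[pos[i]],
                                                           shorts)
        res = hrf_glm.glm_fit(conc.hbo[pos[i]], task.fs, stim,
                              hrf_glm.HRF_SPEC_HBO, ss_reg, ss_label)
        # contralateral condition for the analyzed hemisphere
        cond = "left" if hemi == "right" else "right"
        betas.append(res.betas[f"cond:{cond}"])
        tstats.append(res.tstats[f"cond:{cond}"])
    return {"participant_id": participant_id,
            "beta_hbo": float(np.mean(betas)) if betas else np.nan,
            "tstat_hbo": float(np.mean(tstats)) if tstats else np.nan,
            "n_channels": len(betas)}


def report(bundle: dict, filename: str = "report.md") -> Path:
    """Render a markdown summary plus figures from a run_study bundle."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(bundle["outdir"])
    if bundle["metrics"].empty:
        raise ValueError("empty cohort; nothing to report")
    lines = ["# Synthetic inclusivity study report", ""]
    lines.append(f"Cohort: {len(bundle['participants'])} participants; "
                 f"seed {bundle['manifest']['seed']}.")
    lines.append("")
    lines.append("## Correlation analysis (Corrected Signal Mean)")
    lines.append(bundle["correlation"].to_string(index=False))
    lines.append("")
    lines.append("## Robust regression (Corrected Signal Mean)")
    lines.append(bundle["regression_csm"].to_string(index=False))
    lines.append("")
    lines.append("Effect-size bands: f² ≥ 0.02 small, ≥ 0.15 medium, "
                 "≥ 0.35 large.")
    lines.append("")
    lines.append("## Capping comparison")
    lines.append(bundle["capping"].to_string(index=False))
    lines.append("")
    lines.append("## NEP group pass percentages")
    lines.append(bundle["nep_group_pass"].to_frame("percent").to_string())

    # violin: CSM by combined-metric bin (shares the analysis binning)
    qc = bundle["qc_run2"]
    merged = qc[qc["kind"] == "long"].merge(
        bundle["metrics"], left_on="participant", right_on="participant_id")
    fig, ax = plt.subplots(figsize=(6, 4))
    try:
        bins = stats_analysis.equal_width_bins(
            merged["combined_metric"].to_numpy())
        data = [merged["csm"][bins == b].dropna() for b in range(1, 5)]
        ax.violinplot([d for d in data if len(d)], showmedians=True)
        ax.set_xlabel("combined hair-skin metric bin")
        ax.set_ylabel("Corrected Signal Mean (log10)")
    except ValueError:
        ax.text(0.5, 0.5, "binning undefined", ha="center")
    fig.savefig(outdir / "fig_violin_csm.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    reg = bundle["regression_csm"]
    for roi, sub in reg.groupby("roi"):
        ax.bar(sub["predictor"] + f"\n({roi})", sub["f2"], alpha=0.6,
               label=roi)
    for level in (0.02, 0.15, 0.35):
        ax.axhline(level, ls="--", lw=0.8)
    ax.set_ylabel("Cohen's f²")
    ax.tick_params(axis="x", labelsize=6, rotation=90)
    fig.tight_layout()
    fig.savefig(outdir / "fig_f2.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    curves = bundle["nep_curves"]
    for g in range(1, 6):
        col = g if g in curves.columns else str(g)   # CSV round trip
        if col in curves.columns and curves[col].notna().any():
            ax.plot(np.asarray(curves.index, dtype=float) * 1e15,
                    curves[col], marker="o", label=f"group {g}")
    ax.set_xscale("log")
    ax.set_xlabel("NEP (fW/$\\sqrt{Hz}$)")
    ax.set_ylabel("% channels passing 20 dB threshold")
    ax.legend(fontsize=7)
    fig.savefig(outdir / "fig_nep_curves.png", dpi=120)
    plt.close(fig)

    path = outdir / filename
    path.write_text("\n".join(lines))
    return path
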