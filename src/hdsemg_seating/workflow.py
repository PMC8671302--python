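"""End-to-end orchestration: simulate -> preprocess -> map -> analyze.

The cohort is processed in a streaming fashion (one 20 s epoch in memory at
a time); the per-trial outcome of the signal stages is a single row of the
region-of-activity (ROA) table, which then feeds the statistics and the
consolidated report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import mapping, preprocess, questionnaires, stats, synthetic_data
from .core import ElectrodeGridSpec, MonopolarEpoch
from .synthetic_data import ActivityGroundTruth, CohortConfig

log = logging.getLogger("hdsemg_seating")

__all__ = ["StudyConfig", "analyze_epoch", "build_roa_table", "analyze_roa_table", "run_pipeline"]


@dataclass
class StudyConfig:
    """All tunable settings of the pipeline, serializable to YAML."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    band_low_hz: float = 20.0
    band_high_hz: float = 400.0
    filter_order: int = 4
    powerline_hz: float = 50.0
    n_harmonics: int = 10
    noise_level_uv: float = 5.0
    interp_factor: int = 15
    alpha: float = 0.05
    questionnaire_seed: int = 1
    questionnaire_effect: str = "paper-like"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["grid"] = dataclasses.asdict(self.cohort.grid)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", {})
        grid_raw = cohort_raw.pop("grid", {})
        chair_eff = cohort_raw.pop("chair_effect_pct", None)
        cohort = CohortConfig(
            grid=ElectrodeGridSpec(**grid_raw),
            **({"chair_effect_pct": tuple(chair_eff)} if chair_eff else {}),
            **cohort_raw,
        )
        return cls(cohort=cohort, **raw)

    @property
    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"config_hash": self.config_hash, "seed": self.cohort.seed, "config": self.to_dict()}


def analyze_epoch(
    epoch: MonopolarEpoch,
    cfg: StudyConfig,
    truth: ActivityGroundTruth | None = None,
) -> dict[str, Any]:
    """Signal stages for one epoch: clean, map, segment; returns one ROA row.

    When the ground truth is supplied, the row additionally carries the true
    in-region amplitude and the intersection-over-union between the
    segmented mask and the true mask (compared on the native pixel grid).
    """
    diff = preprocess.preprocess_epoch(
        epoch,
        low=cfg.band_low_hz,
        high=cfg.band_high_hz,
        order=cfg.filter_order,
        powerline_base=cfg.powerline_hz,
        n_harmonics=cfg.n_harmonics,
    )
    native = mapping.compute_rms_map(diff)
    interp = mapping.interpolate_map(native, factor=cfg.interp_factor)
    roa = mapping.segment_roa(interp, noise_level=cfg.noise_level_uv)
    dx, dy = interp.pixel_mm
    key = epoch.key
    row: dict[str, Any] = {
        "subject": key.subject_id,
        "chair": key.chair,
        "side": key.side,
        "trial_index": key.trial_index,
        "time_min": key.time_min,
        "spatial_mean": interp.spatial_mean,
        "rms_roa": roa.rms_roa,
        "used_full_map": roa.used_full_map,
        "x_cm_mm": roa.centroid_mm[0],
        "y_cm_mm": roa.centroid_mm[1],
        "mask_area_mm2": roa.area_pixels * dx * dy,
    }
    if truth is not None:
        row["true_roa_mean"] = truth.true_roa_mean
        row["true_x_mm"], row["true_y_mm"] = truth.center_true_mm
        # compare masks on the native grid: downsample the fine mask by
        # block-majority at the native pixel centres
        fine = roa.mask
        f = cfg.interp_factor
        centres = fine[::f, ::f]
        tm = truth.roa_mask_true
        inter = np.logical_and(centres, tm).sum()
        union = np.logical_or(centres, tm).sum()
        row["iou_true"] = float(inter / union) if union else float("nan")
    return row


def build_roa_table(cfg: StudyConfig, progress: bool = False) -> pd.DataFrame:
    """Simulate the full cohort and run the signal stages on every epoch."""
    rows = []
    t0 = time.time()
    for i, (key, epoch, truth) in enumerate(synthetic_data.simulate_cohort(cfg.cohort)):
        rows.append(analyze_epoch(epoch, cfg, truth))
        if progress and (i + 1) % 50 == 0:
            log.info("processed %d epochs in %.1f s", i + 1, time.time() - t0)
    return pd.DataFrame(rows)


def analyze_roa_table(roa: pd.DataFrame, cfg: StudyConfig) -> dict[str, Any]:
    """Statistics stage: chair comparison, mixed model, centroid analysis."""
    results: dict[str, Any] = {}
    results["table2"] = stats.percent_change_table(roa, alpha=cfg.alpha)
    if roa["subject"].nunique() >= 2:
        results["mixed_model"] = stats.fit_rms_mixed_model(roa)
    else:
        log.warning("single-subject table: mixed model skipped")
    if roa["subject"].nunique() >= 2 and roa.groupby(["chair", "side"]).ngroups == 4:
        results["centroid_anova"] = stats.centroid_anova(roa)
        results["centroid_displacement"] = mapping.centroid_displacement(roa)
    # per-subject time changes (start -> end of session), per chair and side
    tc = []
    for (subject, chair, side), g in roa.groupby(["subject", "chair", "side"]):
        g = g.sort_values("trial_index")
        first, last = g["trial_index"].iloc[0], g["trial_index"].iloc[-1]
        expect_first, expect_last = roa["trial_index"].min(), roa["trial_index"].max()
        if first != expect_first or last != expect_last:
            log.warning(
                "subject %s %s/%s misses endpoint trials; excluded from time-change analysis",
                subject,
                chair,
                side,
            )
            continue
        tc.append(
            {
                "subject": subject,
                "chair": chair,
                "side": side,
                "time_change_pct": stats.time_change(g["rms_roa"].to_numpy()),
            }
        )
    results["time_change"] = pd.DataFrame(tc)
    return results


def analyze_questionnaires(q: pd.DataFrame, alpha: float = 0.05) -> dict[str, Any]:
    """Questionnaire stage on a long response table
    (subject, chair, instrument, item, score)."""
    out: dict[str, Any] = {}
    gcr = q[q["instrument"] == "GCR"]
    out["gcr"] = questionnaires.score_gcr(
        {chair: g["score"].to_numpy() for chair, g in gcr.groupby("chair")}
    )
    for inst in ("HZc", "HZd"):
        sub = q[q["instrument"] == inst]
        items = {}
        for item, g in sub.groupby("item"):
            piv = g.pivot(index="subject", columns="chair", values="score").dropna()
            items[item] = questionnaires.hz_item_test(
                piv["A"].to_numpy(), piv["SS"].to_numpy()
            )
        out[inst.lower() + "_items"] = items
        pct = (
            sub.groupby(["subject", "chair"])["score"]
            .apply(lambda v: questionnaires.hz_percent(v.to_numpy()))
            .unstack("chair")
            .dropna()
        )
        from scipy import stats as _sps

        res = _sps.ttest_rel(pct["A"], pct["SS"])
        out[inst.lower() + "_percent"] = {
            "mean_pct": {c: float(pct[c].mean()) for c in pct.columns},
            "t": float(res.statistic),
            "p": float(res.pvalue),
        }
    out["bpd"] = questionnaires.bpd_compare(q[q["instrument"] == "BPD"])
    out["bpd"]["per_part_means"] = out["bpd"]["per_part_means"].to_dict()
    return out


def _quant_qual_correlations(roa_results: dict, q: pd.DataFrame) -> dict[str, Any]:
    """Spearman link between the chair-related RMS time-change difference and
    each questionnaire outcome, per side."""
    tc = roa_results.get("time_change")
    if tc is None or tc.empty:
        return {}
    out: dict[str, Any] = {}
    gcr = q[q["instrument"] == "GCR"].pivot(index="subject", columns="chair", values="score")
    gcr_diff = (gcr["SS"] - gcr["A"]).rename("gcr_diff")
    for side, g in tc.groupby("side"):
        piv = g.pivot(index="subject", columns="chair", values="time_change_pct").dropna()
        if not {"SS", "A"} <= set(piv.columns):
            continue
        emg = (piv["A"] - piv["SS"]).rename("emg_diff")
        joined = pd.concat([emg, gcr_diff], axis=1).dropna()
        if len(joined) >= 4 and joined.nunique().min() > 1:
            out[side] = {"gcr": stats.spearman_corr(joined["emg_diff"], joined["gcr_diff"])}
    return out


def run_pipeline(cfg: StudyConfig, out_dir: str | Path | None = None, progress: bool = False) -> dict:
    """Execute the full chain and (optionally) write the report bundle.

    Returns a dict with the ROA table, the chair-comparison summary, the
    mixed-model and centroid results, the questionnaire analysis and the
    quantitative-qualitative correlations; deterministic for a fixed config.
    """
    stages: dict[str, float] = {}
    t0 = time.time()
    roa = build_roa_table(cfg, progress=progress)
    stages["signal"] = time.time() - t0

    t0 = time.time()
    results = analyze_roa_table(roa, cfg)
    q = synthetic_data.simulate_questionnaires(
        n_subjects=cfg.cohort.n_subjects,
        seed=cfg.questionnaire_seed,
        effect=cfg.questionnaire_effect,
    )
    results["questionnaires"] = analyze_questionnaires(q, alpha=cfg.alpha)
    results["correlations"] = _quant_qual_correlations(results, q)
    stages["stats"] = time.time() - t0

    bundle = {
        "roa": roa,
        "responses": q,
        "provenance": cfg.provenance() | {"stage_seconds": stages},
        **results,
    }
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    prov = bundle["provenance"]
    (out_dir / "provenance.json").write_text(json.dumps(_jsonable(prov), indent=1))
    bundle["roa"].to_csv(out_dir / "roa.csv", index=False)
    bundle["table2"].to_csv(out_dir / "chair_comparison.csv", index=False)
    bundle["responses"].to_csv(out_dir / "questionnaire_responses.csv", index=False)
    model_keys = (
        "mixed_model",
        "centroid_anova",
        "questionnaires",
        "correlations",
    )
    models = {k: _jsonable(bundle[k]) for k in model_keys if k in bundle}
    models["provenance"] = {"config_hash": prov["config_hash"], "seed": prov["seed"]}
    (out_dir / "models.json").write_text(json.dumps(models, indent=1))
    _write_report_md(bundle, out_dir / "report.md")


def _write_report_md(bundle: dict, path: Path) -> None:
    t2 = bundle["table2"]
    pooled = t2[t2["subject"] == "Total"].set_index("side")
    per_subj = t2[t2["subject"] != "Total"]
    n_subj = per_subj["subject"].nunique()
    lines = [
        "# Chair-comparison report",
        "",
        f"Config `{bundle['provenance']['config_hash']}`, seed {bundle['provenance']['seed']}.",
        "",
        "## RMS_ROA percent change (stool vs. lumbar-support chair)",
        "",
    ]
    for side in pooled.index:
        n_sig = int(per_subj[per_subj["side"] == side]["significant"].sum())
        lines.append(
            f"- side {side}: pooled change {pooled.loc[side, 'mean_pct_change']:.2f} "
            f"+/- {pooled.loc[side, 'sd_pct_change']:.2f} %, "
            f"{n_sig}/{n_subj} subjects individually significant"
        )
    if "mixed_model" in bundle:
        mm = bundle["mixed_model"]
        lines += [
            "",
            "## Mixed model (fixed: chair, side; random: subject, time)",
            "",
            f"- chair: F = {mm['fixed']['chair']['F']:.2f}, p = {mm['fixed']['chair']['p']:.3g}",
            f"- side: F = {mm['fixed']['side']['F']:.2f}, p = {mm['fixed']['side']['p']:.3g}",
            f"- conditional R^2 = {mm['r2_conditional']:.3f}, residual SD = {mm['residual_sd']:.2f} uV",
            "",
        ]
    qn = bundle.get("questionnaires", {})
    if qn:
        gcr = qn["gcr"]
        lines += [
            "## Questionnaires",
            "",
            f"- GCR modes: "
            + ", ".join(f"{c}: {m} ({gcr['mode_label'][c]})" for c, m in gcr["mode"].items())
            + f"; ANOVA p = {gcr['anova_p']:.3g}",
            f"- BPD chair mean difference (SS - A): {qn['bpd']['mean_difference']:.2f} points",
        ]
    path.write_text("\n".join(lines) + "\n")
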