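"""End-to-end orchestration: per-recording analysis and cohort statistics.

A recording flows keypoint reading -> preprocessing -> segmentation ->
kinematics; a failure at any stage yields a structured error record naming
the stage, never a crash of a batch run.  The cohort layer joins the
extracted parameters with survey measures and runs the full statistical
battery: the 21-comparison correlation screen, the six-comparison screen in
the 50-years-and-older subgroup, trunk-angle group comparisons across the
largest race/ethnicity groups (Kruskal-Wallis + Dunn), the covariate-
adjusted regressions, and the included-vs-excluded SMD balance table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as kio
from . import kinematics, stats
from .preprocess import CleanSeries, PreprocessConfig, preprocess
from .segment import Segmentation, SegmentationParams, segment


@dataclass
class RunConfig:
    """Knobs for a full pipeline run."""

    fps: float = 30.0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    subgroup_min_age: float = 50.0
    primary_family_size: int = 21
    subgroup_family_size: int = 6
    n_race_groups: int = 4


#: STS parameters and survey measures forming the primary correlation family
#: (3 parameters x 7 measures = 21 comparisons).
PRIMARY_PARAMS = ("total_time_s", "max_trunk_angle_deg", "max_trunk_ang_acc_deg_s2")
PRIMARY_MEASURES = ("age", "sex_code", "bmi", "ethnicity_code", "gph", "gmh",
                    "oa_diagnosis")
SUBGROUP_MEASURES = ("gph", "gmh")

#: Covariate-adjusted models: (model, outcome, predictors, subgroup_only).
DEFAULT_REGRESSIONS = (
    ("logistic", "oa_diagnosis",
     ("max_trunk_angle_deg", "age", "sex_code", "bmi", "total_time_s"), False),
    ("logistic", "oa_diagnosis", ("total_time_s", "age", "sex_code", "bmi"), False),
    ("linear", "gph", ("total_time_s", "age", "sex_code", "bmi"), False),
    ("logistic", "ethnicity_code",
     ("max_trunk_angle_deg", "age", "sex_code", "bmi", "gph"), False),
    ("linear", "gmh",
     ("max_trunk_ang_acc_deg_s2", "age", "sex_code", "bmi", "total_time_s"), True),
)


def analyze_series(
    series: kio.KeypointSeries,
    config: RunConfig | None = None,
) -> tuple[kinematics.STSParameters, Segmentation, CleanSeries]:
    """Run the per-recording chain on an in-memory keypoint series."""
    config = config or RunConfig()
    clean = preprocess(series, config.preprocess)
    nose = clean.trace(kio.LandmarkID.NOSE)[:, 1]
    seg = segment(nose, clean.fps, config.segmentation)
    clean.qc.pause_flag = seg.pause_flag
    if seg.pause_flag:
        clean.qc.flag("long pause between repetitions")
    params = kinematics.extract_parameters(clean, seg)
    return params, seg, clean


def analyze_recording(
    path: str | Path,
    fps: float,
    config: RunConfig | None = None,
) -> dict:
    """Analyse one OpenPose directory; never raises on bad data.

    Returns ``{"ok": True, "parameters": ..., "segmentation": ..., "qc": ...}``
    or ``{"ok": False, "stage": ..., "error": ...}``.
    """
    config = config or RunConfig()
    stage = "read"
    try:
        series = kio.read_openpose_dir(
            path, fps, config.preprocess.missing_conf_threshold)
        stage = "analyze"
        params, seg, clean = analyze_series(series, config)
    except Exception as exc:  # noqa: BLE001 - batch contract: contain failures
        return {"ok": False, "source": str(path), "stage": stage,
                "error": f"{type(exc).__name__}: {exc}"}
    return {
        "ok": True,
        "source": str(path),
        "parameters": params.to_dict(),
        "segmentation": seg.to_dict(),
        "qc": clean.qc.to_dict(),
    }


def analyze_batch(
    paths: list[str | Path],
    fps: float,
    config: RunConfig | None = None,
) -> tuple[dict[str, dict], list[dict]]:
    """Analyse many recordings; returns (results by id, error records)."""
    results: dict[str, dict] = {}
    errors: list[dict] = []
    for p in paths:
        rec = analyze_recording(p, fps, config)
        if rec["ok"]:
            results[Path(p).name] = rec
        else:
            errors.append(rec)
    return results, errors


def _code_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Add numeric codings: sex (female=1), ethnicity (two largest groups)."""
    out = df.copy()
    out["sex_code"] = (out["sex"].astype(str).str.lower() == "female").astype(float)
    counts = out["race_ethnicity"].value_counts()
    if len(counts) >= 2:
        top_two = list(counts.index[:2])
        out["ethnicity_code"] = out["race_ethnicity"].map(
            {top_two[0]: 0.0, top_two[1]: 1.0})
    else:
        out["ethnicity_code"] = np.nan
    return out


def analyze_cohort(
    params_table: pd.DataFrame,
    cohort_table: pd.DataFrame,
    config: RunConfig | None = None,
) -> dict:
    """Run the full statistical battery on joined cohort + parameter tables.

    Participants carrying manual exclusion flags enter only the SMD balance
    table; all association analyses use the included subset.  Per-analysis
    failures are collected under ``"errors"`` instead of aborting the run.
    """
    config = config or RunConfig()
    cohort = _code_columns(cohort_table)
    joined = cohort.merge(params_table, on="participant_id", how="inner")
    excluded_mask = cohort["exclusion_flags"].astype(str).str.len() > 0
    included = joined[joined["exclusion_flags"].astype(str).str.len() == 0]
    if len(included) < 3:
        raise stats.StatsError(
            f"only {len(included)} included participants after join; need >= 3"
        )

    bundle: dict = {"errors": []}

    def run(name, fn):
        try:
            bundle[name] = fn()
        except Exception as exc:  # noqa: BLE001 - per-test containment
            bundle["errors"].append({"analysis": name,
                                     "error": f"{type(exc).__name__}: {exc}"})

    pairs = [(p, m) for p in PRIMARY_PARAMS for m in PRIMARY_MEASURES]
    run("correlations", lambda: stats.correlation_screen(
        included, pairs, m=config.primary_family_size))

    older = included[included["age"] >= config.subgroup_min_age]
    sub_pairs = [(p, m) for p in PRIMARY_PARAMS for m in SUBGROUP_MEASURES]
    run("subgroup_correlations", lambda: stats.correlation_screen(
        older, sub_pairs, m=config.subgroup_family_size))

    def race_comparison():
        counts = included["race_ethnicity"].value_counts()
        keep = list(counts.index[:config.n_race_groups])
        sub = included[included["race_ethnicity"].isin(keep)]
        return stats.group_comparison(sub["max_trunk_angle_deg"],
                                      sub["race_ethnicity"])
    run("trunk_angle_by_race", race_comparison)

    regressions = []
    for model, outcome, predictors, subgroup_only in DEFAULT_REGRESSIONS:
        data = older if subgroup_only else included
        X = data.loc[:, list(predictors)]
        fn = stats.logistic_fit if model == "logistic" else stats.linear_fit
        try:
            regressions.append(fn(data[outcome], X, outcome=outcome))
        except Exception as exc:  # noqa: BLE001
            bundle["errors"].append({
                "analysis": f"{model}:{outcome}~{'+'.join(predictors)}",
                "error": f"{type(exc).__name__}: {exc}"})
    bundle["regressions"] = regressions

    def balance():
        inc, exc = cohort[~excluded_mask], cohort[excluded_mask]
        rows = []
        for var, kind in (("age", "continuous"), ("bmi", "continuous"),
                          ("sex_code", "binary")):
            rows.append(stats.smd(inc[var], exc[var], kind=kind, variable=var))
        return rows
    run("smd_balance", balance)

    bundle["n_included"] = int(len(included))
    bundle["n_excluded"] = int(excluded_mask.sum())
    return bundle


def bundle_to_frames(bundle: dict) -> dict[str, pd.DataFrame]:
    """Flatten an analyze_cohort bundle into tidy DataFrames."""
    frames: dict[str, pd.DataFrame] = {}
    for key in ("correlations", "subgroup_correlations"):
        if key in bundle:
            frames[key] = pd.DataFrame([vars(r) for r in bundle[key]])
    if "trunk_angle_by_race" in bundle:
        gc = bundle["trunk_angle_by_race"]
        frames["race_global"] = pd.DataFrame(
            [{"H": gc.H, "p_global": gc.p_global,
              "groups": "; ".join(f"{g}(n={n})" for g, n in gc.groups)}])
        frames["race_pairwise"] = gc.pairwise_frame()
    if "regressions" in bundle:
        rows = []
        for reg in bundle["regressions"]:
            for name, beta, lo, hi, p in reg.terms:
                rows.append({"model": reg.model, "outcome": reg.outcome,
                             "term": name, "beta": beta, "ci_low": lo,
                             "ci_high": hi, "p": p, "n": reg.n})
        frames["regressions"] = pd.DataFrame(rows)
    if "smd_balance" in bundle:
        frames["smd_balance"] = pd.DataFrame(
            [{"variable": r.variable, "smd": r.smd, "ci_low": r.ci_low,
              "ci_high": r.ci_high, "negligible": r.negligible}
             for r in bundle["smd_balance"]])
    return frames


def write_bundle(bundle: dict, out_dir: str | Path) -> None:
    """Write one CSV per analysis family plus a JSON summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = bundle_to_frames(bundle)
    for name, df in frames.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    summary = {
        "n_included": bundle.get("n_included"),
        "n_excluded": bundle.get("n_excluded"),
        "analyses": sorted(frames),
        "errors": bundle.get("errors", []),
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
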