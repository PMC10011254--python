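"""Study orchestration: cohort simulation through statistical report.

``run_study`` reproduces the full evaluation design: a cohort of simulated
lesions is segmented by the four individual methods under two initial-mask
conditions (rectangle bounding box vs irregular cropping), consensus
contours are formed by majority vote, accuracy (MATV, RE, DSC) is measured
against the known ground truth, robustness between mask conditions is
quantified by the test–retest statistic, and methods are compared with
Friedman + post hoc Wilcoxon/Bonferroni tests.  Everything derives
deterministically from the study seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import ConsensusConfig, aveseg, majority_vote
from .metrics import metrics_record, trt_table
from .phantom import PhantomSpec, cohort_specs, gen_masks, simulate_case
from .segmentation import METHODS, SegConfig, seg_st
from .stats import box_stats, friedman_test, wilcoxon_bonferroni

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyReport", "run_study", "summarize", "evaluate_cohort"]

MASK_CONDITIONS = ("rectangle", "irregular")
METHOD_ORDER = ("MASAC", "AP", "ST", "41MAX", "AveSeg", "ConSeg")


@dataclass
class StudyConfig:
    """Configuration of one simulation study."""

    n_cases: int = 13
    seed: int = 2023
    motion: bool = True
    consensus_k: int = 3
    seg: SegConfig = field(default_factory=SegConfig)
    phantom_overrides: dict = field(default_factory=dict)
    methods: tuple[str, ...] = ("MASAC", "AP", "ST", "41MAX")
    output_dir: str | None = None
    write_nifti: bool = False

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        unknown = set(m.upper() for m in self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


@dataclass
class StudyReport:
    """Everything the study computes, in analysis-ready tables."""

    metrics: pd.DataFrame        # long form: case x method x mask condition
    trt: pd.DataFrame            # TRT per case x method x metric
    summary: pd.DataFrame        # median (Q1, Q3) per method x mask condition
    trt_summary: pd.DataFrame    # median TRT and median |TRT| per method x metric
    stats: dict                  # Friedman + Wilcoxon outcomes per metric/condition
    manifest: pd.DataFrame       # case id, seed, GT volumes (cm^3)


def evaluate_cohort(cfg: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate and segment every case; return (metrics rows, manifest)."""
    specs = cohort_specs(cfg.n_cases, base_seed=cfg.seed, **cfg.phantom_overrides)
    noise_seeds = np.random.SeedSequence([cfg.seed, 1]).generate_state(cfg.n_cases)
    mask_seeds = np.random.SeedSequence([cfg.seed, 2]).generate_state(cfg.n_cases)
    rows: list[dict] = []
    manifest: list[dict] = []
    out = Path(cfg.output_dir) if cfg.output_dir else None

    for i, spec in enumerate(specs):
        case_id = f"case{i:02d}"
        case = simulate_case(spec, motion=cfg.motion, case_id=case_id,
                             noise_seed=int(noise_seeds[i] % (2**31)))
        gt = case.gt_motion if cfg.motion else case.gt_static
        rect, irr = gen_masks(gt, seed=int(mask_seeds[i] % (2**31)))
        spacing = case.pet_image.spacing
        manifest.append({
            "case": case_id,
            "seed": spec.seed,
            "target_volume_cm3": spec.lesion_volume_cm3,
            "gt_static_cm3": np.count_nonzero(case.gt_static) * case.activity.voxel_volume_cm3,
            "gt_motion_cm3": np.count_nonzero(case.gt_motion) * case.activity.voxel_volume_cm3,
        })
        if out is not None and cfg.write_nifti:
            from .volume import write_nifti
            (out / case_id).mkdir(parents=True, exist_ok=True)
            write_nifti(case.pet_image, out / case_id / "pet.nii.gz")
            write_nifti(case.activity.like(gt.astype(np.uint8)), out / case_id / "gt.nii.gz")

        for cond, init in zip(MASK_CONDITIONS, (rect, irr)):
            masks = {}
            for name in cfg.methods:
                try:
                    res = METHODS[name.upper()](case.pet_image, init, cfg=cfg.seg)
                except Exception:
                    logger.exception("%s failed on %s/%s", name, case_id, cond)
                    continue
                if res.warning:
                    logger.warning("%s on %s/%s: %s", name, case_id, cond, res.warning)
                if not res.failed:
                    masks[name.upper()] = res.mask
                rows.append(metrics_record(case_id, name.upper(), cond, res.mask, gt, spacing))
            if len(masks) >= 2:
                conseg = majority_vote(list(masks.values()), ConsensusConfig(cfg.consensus_k))
                rows.append(metrics_record(case_id, "ConSeg", cond, conseg, gt, spacing))
            # AveSeg: per-case arithmetic mean of the individual methods' metrics
            sub = [r for r in rows
                   if r["case"] == case_id and r["mask_condition"] == cond
                   and r["method"] in (m.upper() for m in cfg.methods)]
            rows.append({
                "case": case_id, "method": "AveSeg", "mask_condition": cond,
                "MATV_cm3": aveseg([r["MATV_cm3"] for r in sub]),
                "RE_pct": aveseg([r["RE_pct"] for r in sub]),
                "DSC": aveseg([r["DSC"] for r in sub]),
            })
    return pd.DataFrame(rows), pd.DataFrame(manifest)


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Median (Q1, Q3) of each metric per method x mask condition."""
    if records.empty:
        raise ValueError("no records to summarize")
    rows = []
    for (cond, method), grp in records.groupby(["mask_condition", "method"]):
        row = {"mask_condition": cond, "method": method, "n": len(grp)}
        for col in ("MATV_cm3", "RE_pct", "DSC"):
            vals = grp[col].dropna()
            if vals.empty:
                row[f"{col}_median"] = row[f"{col}_q1"] = row[f"{col}_q3"] = np.nan
                continue
            bs = box_stats(vals)
            row[f"{col}_median"] = bs.median
            row[f"{col}_q1"] = bs.q1
            row[f"{col}_q3"] = bs.q3
        rows.append(row)
    df = pd.DataFrame(rows)
    order = {m: i for i, m in enumerate(METHOD_ORDER)}
    return (df.assign(_o=df["method"].map(order))
              .sort_values(["mask_condition", "_o"]).drop(columns="_o")
              .reset_index(drop=True))


def _summarize_trt(trt: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (method, metric), grp in trt.groupby(["method", "metric"]):
        vals = grp["TRT"].dropna()
        rows.append({
            "method": method,
            "metric": metric,
            "median_TRT": float(vals.median()) if not vals.empty else np.nan,
            "median_abs_TRT": float(vals.abs().median()) if not vals.empty else np.nan,
            "n": int(vals.size),
        })
    return pd.DataFrame(rows)


def _stats_block(records: pd.DataFrame, trt: pd.DataFrame) -> dict:
    """Friedman + post hoc Wilcoxon per metric and mask condition, and on TRT."""
    out: dict = {}
    for metric in ("MATV_cm3", "RE_pct", "DSC"):
        out[metric] = {}
        for cond in MASK_CONDITIONS:
            sub = records[records["mask_condition"] == cond]
            wide = sub.pivot_table(index="case", columns="method", values=metric,
                                   aggfunc="first").dropna(axis=1, how="any").dropna()
            if wide.shape[0] < 2 or wide.shape[1] < 2:
                continue
            stat, p = friedman_test(wide.to_numpy())
            posthoc = wilcoxon_bonferroni(wide.to_numpy(), treatments=list(wide.columns))
            out[metric][cond] = {
                "friedman_stat": stat,
                "friedman_p": p,
                "wilcoxon": posthoc.to_dict(orient="records"),
            }
    trt_wide = trt[trt["metric"] == "MATV_cm3"].pivot_table(
        index="case", columns="method", values="TRT", aggfunc="first"
    ).dropna(axis=1, how="any").dropna()
    if trt_wide.shape[0] >= 2 and trt_wide.shape[1] >= 2:
        stat, p = friedman_test(trt_wide.to_numpy())
        out["TRT_MATV"] = {"friedman_stat": stat, "friedman_p": p}
    return out


def run_study(cfg: StudyConfig) -> StudyReport:
    """Run the full study and (optionally) write its artifacts.

    When ``cfg.output_dir`` is set, writes metrics.csv, trt.csv,
    summary.csv, trt_summary.csv, manifest.csv and stats.json.
    """
    records, manifest = evaluate_cohort(cfg)
    trt = trt_table(records)
    summary = summarize(records)
    trt_summary = _summarize_trt(trt)
    stats = _stats_block(records, trt)
    report = StudyReport(records, trt, summary, trt_summary, stats, manifest)

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.6g"
        records.to_csv(out / "metrics.csv", index=False, float_format=fmt)
        trt.to_csv(out / "trt.csv", index=False, float_format=fmt)
        summary.to_csv(out / "summary.csv", index=False, float_format=fmt)
        trt_summary.to_csv(out / "trt_summary.csv", index=False, float_format=fmt)
        manifest.to_csv(out / "manifest.csv", index=False, float_format=fmt)
        with open(out / "stats.json", "w") as fh:
            json.dump(stats, fh, indent=2, sort_keys=True, default=float)
    return report
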