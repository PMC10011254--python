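"""Quantitative evaluation: MATV, relative volume error, Dice, test–retest.

MATV is the metabolically active tumor volume of a contour.  Accuracy
against a known ground truth GT is measured by

    RE  = (MATV(SM) - MATV(GT)) / MATV(GT) * 100%
    DSC = 2 |SM ∩ GT| / (|SM| + |GT|)

and robustness between the two initial-mask conditions by the test–retest
statistic

    TRT = (m_rect - m_irr) / ((m_rect + m_irr) / 2),

which is 0 for perfectly reproducible metrics and bounded by ±2 when both
metrics are non-negative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["matv", "rel_vol_error", "dsc", "trt", "metrics_record", "trt_table"]

_DENOM_EPS = 1e-9


def matv(mask: np.ndarray, spacing) -> float:
    """Metabolically active tumor volume in cm^3: voxel count x voxel volume."""
    mask = np.asarray(mask, dtype=bool)
    return float(np.count_nonzero(mask) * np.prod(np.asarray(spacing, dtype=float)))


def rel_vol_error(sm: np.ndarray, gt: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Relative volume error of SM versus GT, in percent."""
    v_gt = matv(gt, spacing)
    if v_gt == 0:
        raise ValueError("ground-truth mask is empty; RE undefined")
    return (matv(sm, spacing) - v_gt) / v_gt * 100.0


def dsc(sm: np.ndarray, gt: np.ndarray) -> float:
    """Dice similarity coefficient, in [0, 1]; undefined when both are empty."""
    sm = np.asarray(sm, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if sm.shape != gt.shape:
        raise ValueError("masks must share one grid")
    total = np.count_nonzero(sm) + np.count_nonzero(gt)
    if total == 0:
        raise ValueError("both masks are empty; DSC undefined")
    return 2.0 * np.count_nonzero(sm & gt) / total


def trt(m_rect: float, m_irr: float) -> float:
    """Test–retest statistic between the two mask conditions.

    Returns NaN when the symmetric denominator is (numerically) zero —
    possible for signed metrics such as RE.
    """
    denom = (m_rect + m_irr) / 2.0
    if not np.isfinite(m_rect) or not np.isfinite(m_irr) or abs(denom) < _DENOM_EPS:
        return float("nan")
    return (m_rect - m_irr) / denom


def metrics_record(case_id: str, method: str, mask_condition: str,
                   sm: np.ndarray, gt: np.ndarray | None, spacing) -> dict:
    """One long-form row: MATV always; RE/DSC when a ground truth is known."""
    row = {
        "case": case_id,
        "method": method,
        "mask_condition": mask_condition,
        "MATV_cm3": matv(sm, spacing),
        "RE_pct": np.nan,
        "DSC": np.nan,
    }
    if gt is not None:
        row["RE_pct"] = rel_vol_error(sm, gt, spacing)
        row["DSC"] = dsc(sm, gt)
    return row


def trt_table(records: pd.DataFrame,
              metrics: tuple[str, ...] = ("MATV_cm3", "RE_pct", "DSC")) -> pd.DataFrame:
    """TRT per case x method x metric from a long-form metrics table.

    ``records`` needs columns case, method, mask_condition plus the metric
    columns; both 'rectangle' and 'irregular' rows must be present for a
    (case, method) pair to contribute.
    """
    wide = records.pivot_table(index=["case", "method"], columns="mask_condition",
                               values=list(metrics), aggfunc="first")
    rows = []
    for (case, method), row in wide.iterrows():
        for metric in metrics:
            if (metric, "rectangle") not in wide.columns or (metric, "irregular") not in wide.columns:
                continue
            rows.append({
                "case": case,
                "method": method,
                "metric": metric,
                "rectangle": row[(metric, "rectangle")],
                "irregular": row[(metric, "irregular")],
                "TRT": trt(row[(metric, "rectangle")], row[(metric, "irregular")]),
            })
    return pd.DataFrame(rows)
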