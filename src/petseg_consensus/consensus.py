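"""Fusion of multiple segmentations: majority-vote contours and metric averages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConsensusConfig", "majority_vote", "average_contour", "aveseg"]


@dataclass
class ConsensusConfig:
    """Vote threshold for consensus contours.

    ``k`` is the minimum number of agreeing methods; the default 3 is a
    strict majority of four methods.
    """

    k: int = 3

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("vote threshold k must be >= 1")


def majority_vote(masks: list[np.ndarray], cfg: ConsensusConfig | int | None = None
                  ) -> np.ndarray:
    """Voxelwise vote: keep voxels present in at least ``k`` input masks.

    With ``k = 1`` this is the union, with ``k = len(masks)`` the
    intersection; any intermediate threshold is sandwiched between the two.
    """
    if len(masks) < 2:
        raise ValueError("need at least two masks to vote")
    if cfg is None:
        cfg = ConsensusConfig()
    elif isinstance(cfg, int):
        cfg = ConsensusConfig(k=cfg)
    if cfg.k > len(masks):
        raise ValueError(f"k={cfg.k} exceeds the number of masks ({len(masks)})")
    arrs = [np.asarray(m, dtype=bool) for m in masks]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("all masks must share one grid")
    votes = np.zeros(shape, dtype=np.int16)
    for a in arrs:
        votes += a
    return votes >= cfg.k


def average_contour(masks: list[np.ndarray]) -> np.ndarray:
    """Mean-probability contour: voxels covered by at least half the masks.

    Provided as the contour-space alternative to metric-level averaging;
    for an even number of masks it coincides with ``majority_vote`` at
    ``k = n/2``.
    """
    if len(masks) < 2:
        raise ValueError("need at least two masks to average")
    prob = np.mean([np.asarray(m, dtype=float) for m in masks], axis=0)
    return prob >= 0.5


def aveseg(values) -> float:
    """Metric-level average over the individual methods for one case.

    Arithmetic mean of the per-method metric values (MATV, RE, or DSC);
    missing (NaN) entries are ignored, and NaN is returned when every
    entry is missing.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0 or np.all(np.isnan(vals)):
        return float("nan")
    return float(np.nanmean(vals))
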