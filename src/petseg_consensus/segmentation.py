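"""Four PET tumor delineation methods, each confined to an initial mask.

* ``seg_41max`` — fixed threshold at 41% of the in-mask maximum.
* ``seg_st`` — contrast-oriented adaptive threshold: a calibrated linear
  combination of the mean of the 70%-isocontour region and the local
  background, iterated to a fixed point.
* ``seg_ap`` — affinity-propagation clustering of voxel intensities; the
  reported contour is one exemplar cluster ("hottest" exemplar by default).
* ``seg_masac`` — region-based active contour (two-phase level set with a
  Chan–Vese energy), data-fidelity weight lambda, initialized from the 41%
  threshold mask.

Every result mask is a subset of the initial mask, and the largest
26-connected component is retained (single-lesion assumption).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.segmentation import morphological_chan_vese
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from .volume import VoxelVolume

__all__ = ["SegConfig", "SegmentationResult", "segment",
           "seg_41max", "seg_st", "seg_ap", "seg_masac", "METHODS"]


@dataclass
class SegConfig:
    """Tunable parameters of the individual segmentation methods."""

    lam: float = 3.0              # active-contour data-fidelity weight
    st_a: float = 0.5             # contrast-threshold coefficient on mSUV70
    st_b: float = 0.5             # contrast-threshold coefficient on background
    ap_damping: float = 0.5
    ap_preference: float | None = None   # None -> median similarity
    ap_rule: str = "hottest"      # 'hottest' | 'largest' cluster selection
    ap_levels: int = 32           # intensity quantization levels fed to AP
    max_iter: int = 200
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        if not 0 < self.ap_damping < 1:
            raise ValueError("ap_damping must lie in (0, 1)")
        if self.ap_rule not in ("hottest", "largest"):
            raise ValueError("ap_rule must be 'hottest' or 'largest'")


@dataclass
class SegmentationResult:
    """A binary contour mask tagged with its provenance."""

    mask: np.ndarray
    method: str
    mask_condition: str = ""
    case_id: str = ""
    failed: bool = False
    warning: str | None = None


def _as_array(image: VoxelVolume | np.ndarray) -> np.ndarray:
    return image.data if isinstance(image, VoxelVolume) else np.asarray(image)


def _check_init(init: np.ndarray) -> np.ndarray:
    init = np.asarray(init, dtype=bool)
    if not init.any():
        raise ValueError("initial mask is empty")
    return init

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _largest_cc(mask: np.ndarray) -> np.ndarray:
    """Largest 26-connected component (arrays of dim < 3 use full connectivity)."""
    if not mask.any():
        return mask
    struct = np.ones((3,) * mask.ndim, dtype=bool)
    lab, n = ndimage.label(mask, structure=struct)
    if n <= 1:
        return mask
    counts = np.bincount(lab.ravel())[1:]
    return lab == (np.argmax(counts) + 1)


def _crop(init: np.ndarray, pad: int = 2):
    sl = ndimage.find_objects(init.astype(np.uint8))[0]
    return tuple(slice(max(0, s.start - pad), min(n, s.stop + pad))
                 for s, n in zip(sl, init.shape))


def seg_41max(image: VoxelVolume | np.ndarray, init: np.ndarray,
              cfg: SegConfig | None = None) -> SegmentationResult:
    """Threshold at 41% of the maximum intensity inside the initial mask."""
    img = _as_array(image)
    init = _check_init(init)
    vmax = img[init].max()
    if vmax <= 0:
        return SegmentationResult(np.zeros_like(init), "41MAX", failed=True,
                                  warning="all-zero image inside the initial mask")
    mask = _largest_cc(init & (img >= 0.41 * vmax))
    return SegmentationResult(mask, "41MAX")


def seg_st(image: VoxelVolume | np.ndarray, init: np.ndarray,
           bg: np.ndarray | None = None,
           cfg: SegConfig | None = None) -> SegmentationResult:
    """Contrast-oriented adaptive threshold (iterated to a stable mask).

    ``T = a * mSUV70 + b * BG`` where ``mSUV70`` is the mean intensity of
    the region above 70% of the current maximum and ``BG`` the mean of the
    background region (default: a 3-voxel shell around the initial mask).
    """
    cfg = cfg or SegConfig()
    img = _as_array(image)
    init = _check_init(init)
    if bg is None:
        shell = ndimage.binary_dilation(init, _STRUCT26, iterations=3) & ~init
        bg = shell
    else:
        bg = np.asarray(bg, dtype=bool)
        if not bg.any():
            raise ValueError("background mask is empty")
        if (bg & init).any():
            raise ValueError("background mask overlaps the initial mask")
    bg_mean = float(img[bg].mean())

    current = init
    for _ in range(cfg.max_iter):
        vals = img[current]
        vmax = vals.max()
        if vmax <= 0:
            return SegmentationResult(np.zeros_like(init), "ST", failed=True,
                                      warning="all-zero image inside the initial mask")
        msuv70 = float(vals[vals >= 0.7 * vmax].mean())
        thr = cfg.st_a * msuv70 + cfg.st_b * bg_mean
        new = init & (img >= thr)
        if not new.any():
            new = init & (img >= 0.7 * vmax)  # degenerate threshold above the lesion
        if np.array_equal(new, current):
            break
        current = new
    return SegmentationResult(_largest_cc(current), "ST")


def _ap_cluster(values: np.ndarray, cfg: SegConfig) -> tuple[np.ndarray, np.ndarray, bool]:
    """Affinity propagation on scalar intensities.

    Returns (labels, exemplar values, converged).  Similarity is the
    negative squared intensity difference; preference defaults to the
    median similarity.
    """
    ap = AffinityPropagation(
        damping=cfg.ap_damping,
        max_iter=cfg.max_iter,
        preference=cfg.ap_preference,
        random_state=0,
    )
    x = values.reshape(-1, 1)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        labels = ap.fit_predict(x)
    converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    if labels.max() < 0 or ap.cluster_centers_.size == 0:
        # no exemplar emerged: treat everything as one cluster
        return np.zeros(values.size, dtype=int), np.array([values.max()]), False
    return labels, ap.cluster_centers_.ravel(), converged


def seg_ap(image: VoxelVolume | np.ndarray, init: np.ndarray,
           cfg: SegConfig | None = None) -> SegmentationResult:
    """Affinity-propagation segmentation inside the initial mask.

    Voxel intensities are quantized to at most ``ap_levels`` discrete
    levels (each represented by the mean intensity of its voxels) and the
    levels are clustered by affinity propagation; every voxel inherits its
    level's cluster.  The reported grouping is selected by ``ap_rule``:
    the cluster whose exemplar is hottest (default) or the cluster
    covering the most voxels.  Instances with few distinct intensities
    (at most ``ap_levels``) are clustered exactly, without quantization.
    """
    cfg = cfg or SegConfig()
    img = _as_array(image)
    init = _check_init(init)
    idx = np.flatnonzero(init.ravel())
    vals = img.ravel()[idx].astype(np.float64)
    vmin, vmax = vals.min(), vals.max()

    if vmax - vmin < 1e-12 * max(abs(vmax), 1.0):
        # constant image: zero dissimilarity, a single cluster
        return SegmentationResult(init.copy(), "AP")

    quanta = np.round((vals - vmin) / (vmax - vmin) * (cfg.ap_levels - 1)).astype(int)
    levels, inverse = np.unique(quanta, return_inverse=True)
    points = np.bincount(inverse, weights=vals) / np.bincount(inverse)
    level_labels, exemplars, converged = _ap_cluster(points, cfg)
    labels = level_labels[inverse]

    if cfg.ap_rule == "hottest":
        chosen = int(np.argmax(exemplars))
    else:
        chosen = int(np.argmax(np.bincount(labels, minlength=exemplars.size)))
    mask = np.zeros(init.shape, dtype=bool).ravel()
    mask[idx[labels == chosen]] = True
    mask = _largest_cc(mask.reshape(init.shape))
    return SegmentationResult(mask, "AP", failed=not mask.any(),
                              warning=None if converged else "message passing did not converge")


def seg_masac(image: VoxelVolume | np.ndarray, init: np.ndarray,
              cfg: SegConfig | None = None) -> SegmentationResult:
    """Region-based active-contour segmentation (Chan–Vese level set).

    The contour evolves inside the initial mask (outside voxels are pinned
    to the local background mean so the front has no incentive to cross),
    starting from the 41% threshold mask, with ``lam`` weighting both
    data-fidelity terms against the curvature regularization.
    """
    cfg = cfg or SegConfig()
    img = _as_array(image).astype(np.float64)
    init = _check_init(init)
    sl = _crop(init)
    sub_img = img[sl].copy()
    sub_init = init[sl]
    outside = ~sub_init
    if outside.any():
        sub_img[outside] = sub_img[outside].mean()

    seed = seg_41max(img, init).mask[sl] & sub_init
    if not seed.any():
        return SegmentationResult(np.zeros_like(init), "MASAC", failed=True,
                                  warning="empty threshold initialization")

    # lam sets the data-fidelity : curvature balance; the morphological
    # curvature pass runs once every ceil(lam) data iterations, so larger
    # lam weakens the length penalty as in the continuous energy.
    # Convergence is assessed on (and the result taken from) the state
    # after a data phase, where the two-region fit is at equilibrium.
    period = max(1, int(np.ceil(cfg.lam)))
    u = seed.astype(np.int8)
    prev_data: np.ndarray | None = None
    result = seed.copy()
    for _ in range(max(1, cfg.max_iter // period)):
        u = morphological_chan_vese(
            sub_img, num_iter=max(1, period - 1), init_level_set=u,
            smoothing=0, lambda1=cfg.lam, lambda2=cfg.lam,
        ).astype(np.int8)
        result = u.astype(bool)
        if prev_data is not None and np.array_equal(result, prev_data):
            break
        prev_data = result
        u = morphological_chan_vese(
            sub_img, num_iter=1, init_level_set=u, smoothing=1,
            lambda1=cfg.lam, lambda2=cfg.lam,
        ).astype(np.int8)
    mask = np.zeros_like(init)
    mask[sl] = result & sub_init
    mask = _largest_cc(mask)
    if not mask.any():
        return SegmentationResult(mask, "MASAC", failed=True,
                                  warning="contour evolution vanished")
    return SegmentationResult(mask, "MASAC")


METHODS = {
    "MASAC": seg_masac,
    "AP": seg_ap,
    "ST": seg_st,
    "41MAX": seg_41max,
}


def segment(method: str, image: VoxelVolume | np.ndarray, init: np.ndarray,
            cfg: SegConfig | None = None, **kwargs) -> SegmentationResult:
    """Dispatch a segmentation method by name (case-insensitive)."""
    key = method.upper()
    if key not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(METHODS)}")
    return METHODS[key](image, init, cfg=cfg, **kwargs)
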