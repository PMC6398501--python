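"""Nuclei segmentation and per-cell ROI construction for the screen pipeline.

The stages mirror the screen's custom image-analysis scripts: illumination
correction and contrast stretching of the nuclei (DAPI) channel, global
thresholding with a size-based outlier cutoff, 8-connected labelling, and
cell ROIs built by dilating each nucleus centroid into a disk of the cellular
radius (~10 px at 20x).  Overlapping disks are resolved by nearest-centroid
assignment so per-cell intensities stay additive; nuclei failing the clump
(solidity) or out-of-focus (intensity-variance) filters contribute no ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops

__all__ = [
    "SegmentationParams",
    "RoiMap",
    "preprocess_nuclei_image",
    "segment_nuclei",
    "make_cell_rois",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the nuclei-segmentation stage.

    size_cutoff removes outlier components (debris, clumps) by area;
    roi_radius_px is the cellular radius used to dilate centroids into ROIs;
    clump_solidity_min rejects merged/concave nuclei; focus_variance_min
    rejects out-of-focus cells whose ROI intensity variance is below the
    floor (0 disables the filter).
    """

    size_cutoff: tuple[int, int] = (20, 2000)
    roi_radius_px: int = 10
    clump_solidity_min: float = 0.8
    focus_variance_min: float = 0.0
    threshold_method: str = "otsu"

    def __post_init__(self) -> None:
        if self.size_cutoff[0] >= self.size_cutoff[1]:
            raise ValueError("size_cutoff must be (min_px, max_px) with min < max")
        if self.roi_radius_px < 1:
            raise ValueError("roi_radius_px must be >= 1")
        if not 0 < self.clump_solidity_min <= 1:
            raise ValueError("clump_solidity_min must lie in (0, 1]")


def _quadratic_surface(img: np.ndarray, stride: int = 2) -> np.ndarray:
    """Intensity-weighted least-squares quadratic surface fitted to the image.

    A global polynomial fit has no boundary bias (unlike windowed smoothing,
    which underestimates illumination wherever the cell density drops near
    the field edge).  Weighting by intensity makes the fit track the
    multiplicative gradient on the bright structures that carry it, instead
    of sagging toward the empty background.
    """
    h, w = img.shape
    y = (np.arange(h) / max(h - 1, 1)) * 2.0 - 1.0
    x = (np.arange(w) / max(w - 1, 1)) * 2.0 - 1.0
    yy, xx = np.meshgrid(y[::stride], x[::stride], indexing="ij")
    basis = np.stack([np.ones_like(yy), yy, xx, yy * xx, yy**2, xx**2], axis=-1)
    design = basis.reshape(-1, 6)
    vals = img[::stride, ::stride].ravel()
    sw = np.sqrt(vals)
    coef, *_ = np.linalg.lstsq(design * sw[:, None], vals * sw, rcond=None)
    yy_f, xx_f = np.meshgrid(y, x, indexing="ij")
    full = np.stack([np.ones_like(yy_f), yy_f, xx_f, yy_f * xx_f,
                     yy_f**2, xx_f**2], axis=-1)
    return full @ coef


def preprocess_nuclei_image(nuclei: np.ndarray, *, stride: int = 2) -> np.ndarray:
    """Illumination-correct and contrast-stretch a nuclei channel.

    The illumination field is estimated as a least-squares quadratic surface
    over the image and divided out; the result is linearly rescaled to
    [0, 1].  A constant image maps to the rescale midpoint 0.5; an all-zero
    image is returned unchanged.
    """
    img = np.asarray(nuclei, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2D raster")
    if np.any(img < 0):
        raise ValueError("nuclei channel must be non-negative")
    if not np.any(img):
        return img.copy()
    illum = _quadratic_surface(img, stride=stride)
    # floor the illumination estimate away from zero to keep the division sane
    floor = 0.05 * illum.max()
    corrected = img / np.maximum(illum, floor)
    lo, hi = corrected.min(), corrected.max()
    if hi - lo < 1e-12:
        return np.full_like(corrected, 0.5)
    return (corrected - lo) / (hi - lo)


def segment_nuclei(preprocessed: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Global-threshold + size-filter + 8-connected labelling.

    Returns an integer label map (0 = background, labels 1..K).  An empty
    foreground simply yields K = 0.
    """
    img = np.asarray(preprocessed, dtype=np.float64)
    if img.max() - img.min() < 1e-12:
        return np.zeros(img.shape, dtype=np.int32)
    if params.threshold_method != "otsu":
        raise ValueError(f"unknown threshold_method {params.threshold_method!r}")
    thr = threshold_otsu(img)
    fg = img > thr
    labels = sk_label(fg, connectivity=2)  # 8-connectivity
    lo, hi = params.size_cutoff
    counts = np.bincount(labels.ravel())
    bad = np.flatnonzero((counts < lo) | (counts > hi))
    mask = np.isin(labels, bad[bad > 0])
    labels[mask] = 0
    # relabel sequentially, preserving raster order of first appearance
    out, _, _ = _relabel_sequential(labels)
    return out


def _relabel_sequential(labels: np.ndarray):
    vals = np.unique(labels)
    vals = vals[vals > 0]
    mapping = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    for new, old in enumerate(vals, start=1):
        mapping[old] = new
    return mapping[labels], vals, mapping


@dataclass
class RoiMap:
    """Disjoint per-cell disk ROIs with their centroids.

    ``labels`` assigns each pixel to at most one cell; ``centroids`` maps
    cell id -> (row, col); ``rejected`` maps dropped nucleus ids to the
    filter that removed them (clump | focus).
    """

    labels: np.ndarray
    centroids: dict[int, tuple[float, float]]
    radius_px: int
    rejected: dict[int, str] = dc_field(default_factory=dict)

    @property
    def cell_ids(self) -> list[int]:
        return sorted(self.centroids)

    def to_frame(self) -> pd.DataFrame:
        areas = np.bincount(self.labels.ravel())
        rows = [
            (cid, rc[0], rc[1], int(areas[cid]) if cid < len(areas) else 0, True, "")
            for cid, rc in sorted(self.centroids.items())
        ]
        rows += [(cid, np.nan, np.nan, 0, False, reason)
                 for cid, reason in sorted(self.rejected.items())]
        return pd.DataFrame(
            rows, columns=["cell_id", "row", "col", "area", "kept", "reject_reason"])


def make_cell_rois(labels: np.ndarray, gfp_channel: np.ndarray,
                   params: SegmentationParams) -> RoiMap:
    """Dilate nucleus centroids into disk ROIs of the cellular radius.

    Pixels claimed by several disks go to the nearest centroid (ties to the
    lower label).  Nuclei with solidity below ``clump_solidity_min`` or with
    ROI intensity variance (on ``gfp_channel``) below ``focus_variance_min``
    are excluded.
    """
    labels = np.asarray(labels)
    gfp = np.asarray(gfp_channel, dtype=np.float64)
    if labels.shape != gfp.shape:
        raise ValueError("labels and gfp_channel must have the same shape")
    r = params.roi_radius_px
    h, w = labels.shape
    roi = np.zeros((h, w), dtype=np.int32)
    best = np.full((h, w), np.inf)
    centroids: dict[int, tuple[float, float]] = {}
    rejected: dict[int, str] = {}

    for prop in regionprops(labels):
        cid = int(prop.label)
        if prop.solidity < params.clump_solidity_min:
            rejected[cid] = "clump"
            continue
        # the centroid pixel is dilated, so ROIs are lattice disks around an
        # integer centre (area exactly 317 px at radius 10)
        cy, cx = (float(round(prop.centroid[0])), float(round(prop.centroid[1])))
        r0, r1 = max(int(np.floor(cy - r)), 0), min(int(np.ceil(cy + r)) + 1, h)
        c0, c1 = max(int(np.floor(cx - r)), 0), min(int(np.ceil(cx + r)) + 1, w)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        inside = d2 <= r * r
        if params.focus_variance_min > 0:
            vals = gfp[r0:r1, c0:c1][inside]
            if vals.size == 0 or float(np.var(vals)) < params.focus_variance_min:
                rejected[cid] = "focus"
                continue
        win_best = best[r0:r1, c0:c1]
        upd = inside & (d2 < win_best)  # strict <: ties keep the lower label
        roi_win = roi[r0:r1, c0:c1]
        roi_win[upd] = cid
        win_best[upd] = d2[upd]
        centroids[cid] = (float(cy), float(cx))

    return RoiMap(labels=roi, centroids=centroids, radius_px=r, rejected=rejected)
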