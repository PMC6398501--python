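"""Per-cell GFP intensity features and macro-equivalent cell counting.

Two quantification routes live here:

* the screen route: local background correction of the GFP channel by a
  morphological top-hat (opening with a 3 px disk subtracted from the image),
  then average and total intensity per cell ROI;
* the macro route, equivalent to the recorded ImageJ workflow used for the
  dose/time experiments: 8-bit conversion, mean subtraction, binarisation and
  distance-transform watershed for the nuclei count (particles of size
  10-500 px), and background subtraction + binarisation + proximity merging
  for the count of aggregate-positive cells.

The aggregate-positive fraction of a field is the ratio of the two counts,
and a simple OLS line links dose (or protein level) to that fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed

from .segmentation import RoiMap

__all__ = [
    "MacroParams",
    "DoseResponseFit",
    "subtract_local_background",
    "cell_intensity_features",
    "count_cells_binary",
    "count_aggregate_positive_cells",
    "aggregate_fraction",
    "fit_dose_response",
]


@dataclass(frozen=True)
class MacroParams:
    """Parameters of the macro-equivalent counters.

    ``rolling_radius`` follows the recorded macro value 0.3: values below 1
    are interpreted as a fraction of the cell diameter (2 x cell_radius_px),
    values >= 1 as pixels, since a sub-pixel morphological background
    estimate is degenerate.  ``merge_radius_px`` is the closing radius that
    integrates puncta of one cell into a single object (objects closer than
    the cell radius merge).  Circularity [0, 1] imposes no exclusion, the
    reading of the macro's "circularity 1".
    """

    particle_size_range: tuple[int, int] = (10, 500)
    circularity_range: tuple[float, float] = (0.0, 1.0)
    rolling_radius: float = 0.3
    dapi_particle_size_range: tuple[int, int] = (10, 500)
    cell_radius_px: float = 10.0
    watershed_min_distance: int = 7

    def __post_init__(self) -> None:
        for rng_ in (self.particle_size_range, self.dapi_particle_size_range):
            if rng_[0] > rng_[1]:
                raise ValueError("size ranges must be non-empty")
        if self.circularity_range[0] > self.circularity_range[1]:
            raise ValueError("circularity_range must be non-empty")

    @property
    def rolling_radius_px(self) -> float:
        if self.rolling_radius >= 1.0:
            return self.rolling_radius
        return self.rolling_radius * 2.0 * self.cell_radius_px

    @property
    def merge_radius_px(self) -> int:
        # closing with radius rho merges objects with gaps < 2*rho, so half
        # the cell radius merges everything within one cell footprint
        return max(int(round(self.cell_radius_px / 2.0)), 1)


# ---------------------------------------------------------------------------
# Screen route: background correction + per-ROI features
# ---------------------------------------------------------------------------


def subtract_local_background(gfp: np.ndarray, disk_radius_px: float = 3.0) -> np.ndarray:
    """Local background correction: image minus its opening by a disk.

    The opening with a small disk (3 px in the screen) keeps the smooth
    diffuse/illumination background and erases compact bright puncta, so the
    difference retains puncta while removing any constant pedestal or smooth
    gradient.  Output is floored at 0.
    """
    img = np.asarray(gfp, dtype=np.float64)
    if np.any(img < 0):
        raise ValueError("gfp raster must be non-negative")
    footprint = disk(max(int(round(disk_radius_px)), 1))
    background = ndi.grey_opening(img, footprint=footprint)
    return np.clip(img - background, 0.0, None)


def cell_intensity_features(rois: RoiMap, corrected_gfp: np.ndarray, *,
                            positive_min_intensity: float | None = None) -> pd.DataFrame:
    """Average and total background-corrected GFP intensity per cell ROI.

    Returns one row per ROI with columns ``cell_id, row, col, area,
    avg_intensity, total_intensity, positive``.  The positive flag marks
    cells whose ROI contains at least one pixel at or above
    ``positive_min_intensity`` (left False when the threshold is None).
    """
    gfp = np.asarray(corrected_gfp, dtype=np.float64)
    if gfp.shape != rois.labels.shape:
        raise ValueError("corrected_gfp and ROI map must have the same shape")
    ids = rois.cell_ids
    if not ids:
        return pd.DataFrame(columns=["cell_id", "row", "col", "area",
                                     "avg_intensity", "total_intensity", "positive"])
    index = np.asarray(ids)
    areas = ndi.sum_labels(np.ones_like(gfp), labels=rois.labels, index=index)
    totals = ndi.sum_labels(gfp, labels=rois.labels, index=index)
    maxima = ndi.labeled_comprehension(gfp, rois.labels, index, np.max, float, 0.0)
    avg = np.divide(totals, areas, out=np.zeros_like(totals), where=areas > 0)
    positive = (
        maxima >= positive_min_intensity if positive_min_intensity is not None
        else np.zeros(len(index), dtype=bool)
    )
    return pd.DataFrame(
        {
            "cell_id": index,
            "row": [rois.centroids[i][0] for i in ids],
            "col": [rois.centroids[i][1] for i in ids],
            "area": areas.astype(int),
            "avg_intensity": avg,
            "total_intensity": totals,
            "positive": positive,
        }
    )


# ---------------------------------------------------------------------------
# Macro route: whole-field counts
# ---------------------------------------------------------------------------


def _to_8bit(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < 1e-12:
        return np.zeros(img.shape, dtype=np.float64)
    return np.round((img - lo) / (hi - lo) * 255.0)


def _count_filtered(binary: np.ndarray, size_range: tuple[int, int],
                    circularity_range: tuple[float, float] | None) -> int:
    labels = sk_label(binary, connectivity=2)
    n = 0
    for prop in regionprops(labels):
        if not size_range[0] <= prop.area <= size_range[1]:
            continue
        if circularity_range is not None:
            perim = prop.perimeter
            circ = 4.0 * np.pi * prop.area / perim**2 if perim > 0 else 1.0
            circ = min(circ, 1.0)  # discrete perimeters can push 4piA/P^2 above 1
            if not circularity_range[0] <= circ <= circularity_range[1]:
                continue
        n += 1
    return n


def count_cells_binary(dapi: np.ndarray, params: MacroParams = MacroParams()) -> int:
    """Total cell count from the nuclei channel, macro-equivalent.

    8-bit conversion (min-max), mean subtraction floored at 0, Otsu
    binarisation, distance-transform watershed to split touching nuclei,
    then particle filtering by size 10-500 px and circularity.
    """
    img = _to_8bit(np.asarray(dapi, dtype=np.float64))
    img = np.clip(img - img.mean(), 0.0, None)
    if img.max() <= 0:
        return 0
    binary = img > threshold_otsu(img)
    if not binary.any():
        return 0
    distance = ndi.distance_transform_edt(binary)
    # plateau-aware markers: connected local-maximum regions of the distance
    # map, so one convex object (even elongated) yields one marker while
    # touching nuclei with separate cores are split
    d = params.watershed_min_distance
    local_max = binary & (distance >= ndi.maximum_filter(distance, size=2 * d + 1))
    markers, _n = ndi.label(local_max, structure=np.ones((3, 3), dtype=int))
    comp = sk_label(binary, connectivity=2)
    # every binary component must own at least one marker
    has_marker = np.unique(comp[markers > 0])
    missing = np.setdiff1d(np.unique(comp), np.append(has_marker, 0))
    next_marker = int(markers.max()) + 1
    for m in missing:
        mask = comp == m
        peak = np.unravel_index(np.argmax(np.where(mask, distance, -1)), comp.shape)
        markers[peak] = next_marker
        next_marker += 1
    segmented = watershed(-distance, markers, mask=binary)
    n = 0
    for prop in regionprops(segmented):
        if not params.dapi_particle_size_range[0] <= prop.area <= params.dapi_particle_size_range[1]:
            continue
        perim = prop.perimeter
        circ = min(4.0 * np.pi * prop.area / perim**2 if perim > 0 else 1.0, 1.0)
        if not params.circularity_range[0] <= circ <= params.circularity_range[1]:
            continue
        n += 1
    return n


def count_aggregate_positive_cells(gfp: np.ndarray,
                                   params: MacroParams = MacroParams()) -> int:
    """Count of aggregate-positive cells from the GFP channel, macro-equivalent.

    Background subtraction by top-hat (disk of ``rolling_radius_px``) removes
    the diffuse reticular signal and illumination gradient while keeping
    compact puncta; the image is binarised, puncta belonging to one cell are
    integrated into a single object by a morphological closing, and objects
    of size 10-500 px are counted.
    """
    img = np.asarray(gfp, dtype=np.float64)
    footprint = disk(max(int(round(params.rolling_radius_px)), 1))
    tophat = np.clip(img - ndi.grey_opening(img, footprint=footprint), 0.0, None)
    if tophat.max() <= 0:
        return 0
    # robust floor keeps pure-noise fields from binarising; Otsu takes over
    # as soon as genuine bright puncta are present
    med = float(np.median(tophat))
    mad = float(np.median(np.abs(tophat - med)))
    floor = med + 6.0 * 1.4826 * mad
    thr = max(float(threshold_otsu(tophat)), floor)
    binary = tophat > thr
    if not binary.any():
        return 0
    closed = ndi.binary_closing(binary, structure=disk(params.merge_radius_px))
    return _count_filtered(closed, params.particle_size_range, None)


def aggregate_fraction(dapi_count: int, positive_count: int) -> float:
    """Fraction of cells showing aggregates, clipped to [0, 1]."""
    if dapi_count <= 0:
        raise ValueError("dapi_count must be positive to define a fraction")
    if positive_count < 0:
        raise ValueError("positive_count must be >= 0")
    return float(np.clip(positive_count / dapi_count, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Dose-response fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseResponseFit:
    """OLS line through (dose-or-level, fraction) points."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


def fit_dose_response(x, y) -> DoseResponseFit:
    """Ordinary least-squares line for fraction vs dose or protein level."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 2:
        raise ValueError("need >= 2 (x, y) points of equal length")
    if np.ptp(x) == 0:
        raise ValueError("all x values identical; slope undefined")
    if np.ptp(y) == 0:
        return DoseResponseFit(slope=0.0, intercept=float(y[0]),
                               r_squared=0.0, n_points=int(x.size))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.linregress(x, y)
    return DoseResponseFit(slope=float(res.slope), intercept=float(res.intercept),
                           r_squared=float(res.rvalue**2), n_points=int(x.size))
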