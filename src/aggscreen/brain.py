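"""3D aggregation density in larval-brain stacks and group comparisons.

Aggregates are bright 26-connected components above an intensity threshold
(auto: a high percentile of the stack, default 99.5, standing in for the
per-image manual threshold), filtered to the detectable 10-1000 voxel range
(inclusive).  Aggregation density is the mean per-ROI object count over the
ROI volume in um^3, taken over three fixed-size boxes along the ventral
nerve cord; densities are normalised to the control-group mean and compared
by Student's t-test or one-way ANOVA with Fisher's LSD (unadjusted pairwise
t-tests on the pooled within-group variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

from .synthetic import BrainStack, RoiBox

__all__ = [
    "BrainParams",
    "DensityRecord",
    "detect_aggregates_3d",
    "aggregation_density",
    "normalize_and_compare",
]

SIZE_RANGE_VOX = (10, 1000)  # inclusive object filter, in voxels


@dataclass(frozen=True)
class BrainParams:
    """Detection settings for the brain assay."""

    threshold: float | None = None       # absolute AFU; None = auto percentile
    auto_percentile: float = 99.5
    min_vox: int = 10
    max_vox: int = 1000

    def __post_init__(self) -> None:
        if self.min_vox >= self.max_vox:
            raise ValueError("min_vox must be < max_vox")


@dataclass(frozen=True)
class DensityRecord:
    """Per-animal aggregation density (aggregates per um^3)."""

    animal_id: str
    group: str
    n_aggregates: int          # total objects counted over the ROIs
    roi_volume_um3: float      # volume of one ROI box
    density: float             # mean per-ROI count / ROI volume
    normalized_density: float | None = None


def detect_aggregates_3d(stack: BrainStack, params: BrainParams = BrainParams()
                         ) -> tuple[np.ndarray, pd.DataFrame]:
    """Label bright 26-connected components within the size filter.

    Returns the filtered label array and a table with one row per object
    (``label, n_vox, z, y, x`` centroid).  A threshold above the stack
    maximum simply yields zero objects.
    """
    data = stack.data
    thr = params.threshold
    if thr is None:
        thr = float(np.percentile(data, params.auto_percentile))
    mask = data > thr
    if not mask.any():
        return np.zeros(data.shape, dtype=np.int32), _empty_objects()
    labels, n = ndi.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        return labels.astype(np.int32), _empty_objects()
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero((counts >= params.min_vox) & (counts <= params.max_vox))
    keep = keep[keep > 0]
    if keep.size == 0:
        return np.zeros(data.shape, dtype=np.int32), _empty_objects()
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    out = remap[labels]
    centroids = ndi.center_of_mass(np.ones_like(out), labels=out,
                                   index=np.arange(1, keep.size + 1))
    table = pd.DataFrame(
        {
            "label": np.arange(1, keep.size + 1),
            "n_vox": counts[keep],
            "z": [c[0] for c in centroids],
            "y": [c[1] for c in centroids],
            "x": [c[2] for c in centroids],
        }
    )
    return out, table


def _empty_objects() -> pd.DataFrame:
    return pd.DataFrame(columns=["label", "n_vox", "z", "y", "x"])


def aggregation_density(objects: pd.DataFrame, roi_boxes: Sequence[RoiBox],
                        voxel_size_um: Sequence[float], *,
                        stack_shape: tuple[int, int, int] | None = None,
                        animal_id: str = "animal01",
                        group: str = "control") -> DensityRecord:
    """Aggregates per um^3: mean per-ROI centroid count over the ROI volume.

    Objects belong to an ROI iff their centroid falls in the half-open box
    [lo, hi).  ROI boxes must be congruent; with ``stack_shape`` given they
    are also checked against the stack bounds.
    """
    boxes = list(roi_boxes)
    if not boxes:
        raise ValueError("at least one ROI box is required")
    shapes = {b.shape for b in boxes}
    if len(shapes) != 1:
        raise ValueError(f"ROI boxes must be congruent, got shapes {shapes}")
    if stack_shape is not None:
        for b in boxes:
            if any(x < 0 for x in b.lo) or any(h > s for h, s in zip(b.hi, stack_shape)):
                raise ValueError(f"ROI box {b} outside stack of shape {stack_shape}")
    vol = boxes[0].volume_um3(voxel_size_um)
    if objects.empty:
        counts = [0] * len(boxes)
    else:
        pts = objects[["z", "y", "x"]].to_numpy()
        counts = [int(sum(b.contains(p) for p in pts)) for b in boxes]
    density = float(np.mean(counts) / vol)
    return DensityRecord(animal_id=animal_id, group=group,
                         n_aggregates=int(np.sum(counts)), roi_volume_um3=vol,
                         density=density)


def _records_frame(records: Sequence[DensityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal": [r.animal_id for r in records],
            "group": [r.group for r in records],
            "n_aggregates": [r.n_aggregates for r in records],
            "volume_um3": [r.roi_volume_um3 for r in records],
            "density": [r.density for r in records],
        }
    )


def normalize_and_compare(records: Sequence[DensityRecord], control_group: str,
                          test: str = "anova_lsd"
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalise densities to the control-group mean and run group tests.

    Returns ``(density_table, stats_table)``.  The density table carries a
    ``normalized`` column (control-group mean = 1 by construction).  With
    ``test='t_test'`` each non-control group is compared with the control by
    a two-sided Student's t-test; with ``test='anova_lsd'`` a one-way ANOVA
    row is followed by unadjusted pairwise LSD t-tests using the pooled
    within-group variance.  LSD p-values are deliberately unadjusted for
    multiplicity (that is Fisher's LSD).
    """
    df = _records_frame(records)
    if control_group not in set(df["group"]):
        raise ValueError(f"control group {control_group!r} not among records")
    ctrl_mean = df.loc[df["group"] == control_group, "density"].mean()
    if ctrl_mean == 0:
        raise ValueError("control-group mean density is zero; cannot normalise")
    df["normalized"] = df["density"] / ctrl_mean

    groups = {}
    for g, sub in df.groupby("group"):
        vals = sub["density"].to_numpy(dtype=float)
        if vals.size < 2:
            warnings.warn(f"group {g!r} has n < 2; excluded from tests",
                          stacklevel=2)
            continue
        groups[g] = vals

    stats_rows = []
    if test == "t_test":
        ctrl = groups.get(control_group)
        if ctrl is None:
            raise ValueError("control group has n < 2; no test possible")
        for g, vals in sorted(groups.items()):
            if g == control_group:
                continue
            t, p = stats.ttest_ind(vals, ctrl, equal_var=True)
            stats_rows.append(("t_test", g, control_group, float(t), float(p), np.nan))
    elif test == "anova_lsd":
        if len(groups) >= 2:
            names = sorted(groups)
            arrays = [groups[g] for g in names]
            f, p = stats.f_oneway(*arrays)
            stats_rows.append(("anova", "all", "", float(f), float(p), np.nan))
            # Fisher's LSD: pooled within-group variance, df = N - k
            n_total = sum(a.size for a in arrays)
            k = len(arrays)
            ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
            msw = ssw / (n_total - k)
            for g1, g2 in combinations(names, 2):
                a, b = groups[g1], groups[g2]
                se = np.sqrt(msw * (1.0 / a.size + 1.0 / b.size))
                if se == 0:
                    t_lsd, p_lsd = 0.0, 1.0
                else:
                    t_lsd = (a.mean() - b.mean()) / se
                    p_lsd = 2.0 * stats.t.sf(abs(t_lsd), df=n_total - k)
                stats_rows.append(("lsd", g1, g2, float(t_lsd), float(p_lsd),
                                   float(a.mean() - b.mean())))
    else:
        raise ValueError(f"unknown test {test!r}; use 't_test' or 'anova_lsd'")

    stats_df = pd.DataFrame(
        stats_rows, columns=["test", "group1", "group2", "statistic", "p_value",
                             "mean_difference"])
    return df, stats_df
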