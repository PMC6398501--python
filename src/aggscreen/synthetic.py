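"""Synthetic two-channel screening fields, 384-well plates and 3D brain stacks.

Everything here emulates the data the screening and brain-density pipelines
consume, with exact ground truth carried alongside:

* a 384-well plate layout with gene wells in triplicate and a pool of
  negative-control wells, placed at random;
* two-channel fields (nuclei + GFP) with ~400 cells per field, a configurable
  fraction of aggregate-positive cells carrying 1-3 bright puncta, diffuse
  reticular GFP in the remaining cells, a smooth multiplicative illumination
  gradient and Gaussian noise;
* a dose/time model linking CuSO4 concentration and hours post-induction to
  the true aggregate-positive fraction (linear, clipped to [0, 1]);
* 3D confocal-like stacks with a known number of bright connected components
  and three fixed-size ROI boxes.

All randomness flows from integer seeds through named ``numpy`` substreams,
so identical (spec, seed) pairs give bit-identical images and truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FieldSpec",
    "FieldImage",
    "CellTruth",
    "FieldTruth",
    "DoseTimeModel",
    "EffectTable",
    "PlateLayout",
    "LayoutError",
    "PlacementError",
    "UnknownGeneError",
    "ScreenSimulation",
    "RoiBox",
    "BrainStack",
    "BrainTruth",
    "build_plate_layout",
    "generate_field",
    "generate_screen",
    "generate_brain_stack",
]

PLATE_ROWS = "ABCDEFGHIJKLMNOP"
PLATE_COLS = 24
PLATE_WELLS = [f"{r}{c:02d}" for r in PLATE_ROWS for c in range(1, PLATE_COLS + 1)]


class LayoutError(ValueError):
    """Plate capacity exceeded or layout otherwise impossible."""


class PlacementError(RuntimeError):
    """Objects could not be placed without overlap; enlarge the image/stack."""


class UnknownGeneError(KeyError):
    """An effect table refers to a gene absent from the plate layout."""


# ---------------------------------------------------------------------------
# Field specification and generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one simulated two-channel field.

    Defaults reproduce the screen's imaging conditions: ~400 cells per field,
    a 10 px cell radius at 20x magnification, and a mutant-like
    aggregate-positive fraction of 0.85 at 500 uM CuSO4 / 24 h.
    Intensities are arbitrary fluorescence units (AFU).
    """

    n_cells: int = 400
    positive_fraction: float = 0.85
    nucleus_radius_px: float = 10.0
    puncta_rate: float = 1.2          # truncated-Poisson mean, support {1,2,3}
    punctum_intensity: float = 150.0
    diffuse_intensity: float = 4.0
    nucleus_intensity: float = 120.0
    illumination_gradient_amplitude: float = 0.15
    noise_sd: float = 2.0
    image_shape: tuple[int, int] = (640, 640)
    axis_ratio_max: float = 1.5       # nuclei are Gaussian ellipses

    def __post_init__(self) -> None:
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must lie in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.nucleus_radius_px <= 0:
            raise ValueError("nucleus_radius_px must be positive")
        if self.noise_sd < 0 or self.diffuse_intensity < 0:
            raise ValueError("noise_sd and diffuse_intensity must be >= 0")
        if self.n_cells > self.grid_capacity():
            raise LayoutError(
                f"image_shape {self.image_shape} fits at most "
                f"{self.grid_capacity()} non-overlapping nuclei of radius "
                f"{self.nucleus_radius_px}; {self.n_cells} requested "
                f"(deficit {self.n_cells - self.grid_capacity()})"
            )

    # cells are placed on a jittered grid; spacing 3r keeps thresholded
    # nuclei disjoint while allowing ~400 cells in a 640 px field
    def grid_spacing(self) -> float:
        return 3.0 * self.nucleus_radius_px

    def grid_capacity(self) -> int:
        s = self.grid_spacing()
        return int(self.image_shape[0] // s) * int(self.image_shape[1] // s)

    @classmethod
    def mutant_like(cls, **kw) -> "FieldSpec":
        """VAP(P58S):GFP-like field: >80% of cells carry bright puncta."""
        kw.setdefault("positive_fraction", 0.85)
        kw.setdefault("diffuse_intensity", 4.0)
        return cls(**kw)

    @classmethod
    def wild_type_like(cls, **kw) -> "FieldSpec":
        """VAP:GFP-like field: diffuse reticular signal, <10% puncta-positive."""
        kw.setdefault("positive_fraction", 0.05)
        kw.setdefault("diffuse_intensity", 10.0)
        return cls(**kw)


@dataclass
class FieldImage:
    """One imaged field: nuclei + GFP rasters plus identity metadata."""

    nuclei: np.ndarray
    gfp: np.ndarray
    pixel_size_um: float = 0.5
    plate: str = "plate01"
    well: str = "A01"
    field: int = 0


@dataclass
class CellTruth:
    cell_id: int
    row: float
    col: float
    positive: bool
    puncta: list[tuple[float, float]] = dc_field(default_factory=list)


@dataclass
class FieldTruth:
    """Exact per-cell ground truth for one generated field."""

    cells: list[CellTruth]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_positive(self) -> int:
        return sum(c.positive for c in self.cells)

    @property
    def positive_fraction(self) -> float:
        return self.n_positive / self.n_cells if self.cells else 0.0

    @property
    def n_puncta(self) -> int:
        return sum(len(c.puncta) for c in self.cells)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": [c.cell_id for c in self.cells],
                "row": [c.row for c in self.cells],
                "col": [c.col for c in self.cells],
                "positive": [c.positive for c in self.cells],
                "n_puncta": [len(c.puncta) for c in self.cells],
            }
        )


def _stamp(canvas: np.ndarray, cy: float, cx: float, patch_radius: int, values: np.ndarray) -> None:
    """Add a local patch (centred window) onto the canvas, clipped at edges."""
    h, w = canvas.shape
    r0 = int(np.floor(cy)) - patch_radius
    c0 = int(np.floor(cx)) - patch_radius
    r1, c1 = r0 + values.shape[0], c0 + values.shape[1]
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r1, h), min(c1, w)
    if rr0 >= rr1 or cc0 >= cc1:
        return
    canvas[rr0:rr1, cc0:cc1] += values[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0]


def _gaussian_ellipse(patch_radius: int, cy: float, cx: float, sig_u: float,
                      sig_v: float, theta: float, amplitude: float) -> np.ndarray:
    """Gaussian-profile ellipse, truncated at 2.8 sigma (zero outside)."""
    n = 2 * patch_radius + 1
    yy, xx = np.mgrid[0:n, 0:n]
    dy = yy - patch_radius - (cy - np.floor(cy))
    dx = xx - patch_radius - (cx - np.floor(cx))
    u = np.cos(theta) * dx + np.sin(theta) * dy
    v = -np.sin(theta) * dx + np.cos(theta) * dy
    d2 = (u / sig_u) ** 2 + (v / sig_v) ** 2
    out = amplitude * np.exp(-0.5 * d2)
    out[d2 > 2.8**2] = 0.0
    return out


def _disk_punctum(radius: float, amplitude: float) -> np.ndarray:
    """Bright punctum: near-plateau disk (soft Gaussian shoulder, hard edge).

    The flat profile keeps the thresholded area close to the full disk
    footprint, so even a single punctum stays above the macro's 10 px
    particle floor.
    """
    pr = int(np.ceil(radius))
    n = 2 * pr + 1
    yy, xx = np.mgrid[0:n, 0:n]
    d2 = (yy - pr) ** 2 + (xx - pr) ** 2
    out = amplitude * np.exp(-0.5 * d2 / max(radius, 0.5) ** 2)
    out[d2 > radius**2] = 0.0
    return out


def _illumination_surface(shape: tuple[int, int], amplitude: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Smooth low-order polynomial surface, 1 +/- amplitude."""
    if amplitude == 0:
        return np.ones(shape)
    y = np.linspace(-1.0, 1.0, shape[0])[:, None]
    x = np.linspace(-1.0, 1.0, shape[1])[None, :]
    c = rng.normal(size=5)
    p = c[0] * x + c[1] * y + c[2] * x * y + c[3] * x**2 + c[4] * y**2
    p /= max(np.abs(p).max(), 1e-12)
    return 1.0 + amplitude * p


def generate_field(spec: FieldSpec, seed: int, *, plate: str = "plate01",
                   well: str = "A01", field: int = 0) -> tuple[FieldImage, FieldTruth]:
    """Render one two-channel field and its exact ground truth.

    Nuclei are Gaussian-profile ellipses on a jittered grid (non-overlapping);
    every aggregate-positive cell carries 1-3 bright puncta near the nucleus
    centroid, negative cells only the diffuse reticular signal.  Both channels
    are multiplied by a smooth illumination surface before noise is added.
    Deterministic for a given (spec, seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF1E1D]))
    h, w = spec.image_shape
    nuclei = np.zeros((h, w), dtype=np.float64)
    gfp = np.zeros((h, w), dtype=np.float64)

    s = spec.grid_spacing()
    nrow, ncol = int(h // s), int(w // s)
    slots = [(i, j) for i in range(nrow) for j in range(ncol)]
    if spec.n_cells > len(slots):  # defended in __post_init__, kept for safety
        raise PlacementError("not enough grid slots; increase image_shape")
    order = rng.permutation(len(slots))[: spec.n_cells]
    jitter_amp = 0.12 * s

    r = spec.nucleus_radius_px
    patch_radius = int(np.ceil(1.4 * r)) + 1

    # positivity via a uniform draw per cell: monotone-coupled across
    # positive_fraction values at a common seed
    u = rng.random(spec.n_cells)
    positives = u < spec.positive_fraction

    cells: list[CellTruth] = []
    for k, slot_idx in enumerate(order):
        i, j = slots[slot_idx]
        cy = (i + 0.5) * s + rng.uniform(-jitter_amp, jitter_amp)
        cx = (j + 0.5) * s + rng.uniform(-jitter_amp, jitter_amp)
        cy = float(np.clip(cy, r, h - 1 - r))
        cx = float(np.clip(cx, r, w - 1 - r))

        q = rng.uniform(1.0, spec.axis_ratio_max)
        sig_u = (r * np.sqrt(q)) / 2.0
        sig_v = (r / np.sqrt(q)) / 2.0
        theta = rng.uniform(0, np.pi)
        _stamp(nuclei, cy, cx, patch_radius,
               _gaussian_ellipse(patch_radius, cy, cx, sig_u, sig_v, theta,
                                 spec.nucleus_intensity * rng.uniform(0.8, 1.2)))

        if spec.diffuse_intensity > 0:
            _stamp(gfp, cy, cx, patch_radius,
                   _gaussian_ellipse(patch_radius, cy, cx, r * 0.6, r * 0.6, 0.0,
                                     spec.diffuse_intensity))

        puncta: list[tuple[float, float]] = []
        if positives[k]:
            n_puncta = int(np.clip(rng.poisson(spec.puncta_rate), 1, 3))
            for _ in range(n_puncta):
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0, 0.4 * r)
                py, px = cy + rad * np.sin(ang), cx + rad * np.cos(ang)
                diameter = rng.uniform(4.0, 7.0)  # digital footprint 13-38 px
                _stamp(gfp, py, px, int(np.ceil(diameter / 2)),
                       _disk_punctum(diameter / 2.0,
                                     spec.punctum_intensity * rng.uniform(0.8, 1.2)))
                puncta.append((float(py), float(px)))
        cells.append(CellTruth(cell_id=k + 1, row=cy, col=cx,
                               positive=bool(positives[k]), puncta=puncta))

    gradient = _illumination_surface((h, w), spec.illumination_gradient_amplitude, rng)
    nuclei *= gradient
    gfp *= gradient
    if spec.noise_sd > 0:
        nuclei = np.clip(nuclei + rng.normal(0, spec.noise_sd, (h, w)), 0, None)
        gfp = np.clip(gfp + rng.normal(0, spec.noise_sd, (h, w)), 0, None)

    img = FieldImage(nuclei=nuclei, gfp=gfp, plate=plate, well=well, field=field)
    return img, FieldTruth(cells=cells)


# ---------------------------------------------------------------------------
# Dose/time model and effect table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseTimeModel:
    """Linear map (CuSO4 uM, hours post-induction) -> true positive fraction.

    Defaults are chosen so that the screen condition (500 uM, 24 h) gives a
    positive fraction of 0.85 and the response stays linear over the assayed
    250-1000 uM range at 24 h (clipping to [0, 1] applies outside it).
    """

    slope_conc: float = 3.0e-4   # fraction per uM
    slope_time: float = 0.025    # fraction per hour
    baseline: float = 0.10

    def __call__(self, conc_um: float, hours: float) -> float:
        f = self.baseline + self.slope_conc * conc_um + self.slope_time * hours
        return float(np.clip(f, 0.0, 1.0))


@dataclass
class EffectTable:
    """Per-gene multiplicative shifts: suppressors < 1, enhancers > 1.

    ``fraction`` scales the true aggregate-positive fraction (clipped to
    [0, 1]); ``intensity`` scales per-cell GFP intensities.  Genes absent
    from both maps have effect 1 (null).
    """

    fraction: dict[str, float] = dc_field(default_factory=dict)
    intensity: dict[str, float] = dc_field(default_factory=dict)

    def genes(self) -> set[str]:
        return set(self.fraction) | set(self.intensity)

    def fraction_effect(self, gene: str) -> float:
        return self.fraction.get(gene, 1.0)

    def intensity_effect(self, gene: str) -> float:
        return self.intensity.get(gene, 1.0)


# ---------------------------------------------------------------------------
# Plate layout
# ---------------------------------------------------------------------------

CONTROL_GENE = "control"


@dataclass
class PlateLayout:
    """Assignment of 384 wells to genes (in replicate) and negative controls."""

    table: pd.DataFrame  # columns: plate, well, role, gene_id, replicate
    plate: str = "plate01"

    @property
    def genes(self) -> list[str]:
        g = self.table.loc[self.table["role"] == "gene", "gene_id"]
        return sorted(g.unique())

    @property
    def control_wells(self) -> list[str]:
        return list(self.table.loc[self.table["role"] == "control", "well"])

    def wells_for_gene(self, gene: str) -> list[str]:
        t = self.table
        return list(t.loc[(t["role"] == "gene") & (t["gene_id"] == gene), "well"])


def build_plate_layout(n_genes_per_plate: int, n_control_wells: int,
                       n_replicates: int, seed: int, *,
                       plate: str = "plate01",
                       gene_names: Sequence[str] | None = None) -> PlateLayout:
    """Randomly place gene triplicates and control wells on a 384-well plate.

    Mirrors the screen design: 114 genes x 3 replicates + 42 negative-control
    wells fill the plate exactly.  Raises :class:`LayoutError` naming the
    deficit if the requested wells exceed 384.
    """
    needed = n_genes_per_plate * n_replicates + n_control_wells
    if needed > len(PLATE_WELLS):
        raise LayoutError(
            f"{n_genes_per_plate} genes x {n_replicates} replicates + "
            f"{n_control_wells} control wells = {needed} wells exceeds 384 "
            f"(deficit {needed - len(PLATE_WELLS)})"
        )
    if gene_names is None:
        gene_names = [f"gene_{i + 1:03d}" for i in range(n_genes_per_plate)]
    elif len(gene_names) != n_genes_per_plate:
        raise LayoutError("gene_names length must equal n_genes_per_plate")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1A9]))
    wells = list(rng.permutation(PLATE_WELLS))[:needed]
    rows = []
    idx = 0
    for i in range(n_control_wells):
        rows.append((plate, wells[idx], "control", CONTROL_GENE, i + 1))
        idx += 1
    for gene in gene_names:
        for rep in range(1, n_replicates + 1):
            rows.append((plate, wells[idx], "gene", gene, rep))
            idx += 1
    table = (
        pd.DataFrame(rows, columns=["plate", "well", "role", "gene_id", "replicate"])
        .sort_values("well", kind="stable")
        .reset_index(drop=True)
    )
    return PlateLayout(table=table, plate=plate)


# ---------------------------------------------------------------------------
# Whole-screen simulation
# ---------------------------------------------------------------------------


@dataclass
class ScreenSimulation:
    """Lazy, reproducible screen dataset: per-well field specs plus truth.

    Images are rendered on demand by :meth:`iter_fields` so a full plate never
    has to sit in memory; identical (layout, effects, seed) always yields the
    same images.
    """

    layout: PlateLayout
    well_params: pd.DataFrame  # well, gene_id, role, replicate, true_fraction, intensity_scale, seed
    base_spec: FieldSpec
    n_fields_per_well: int
    conc_um: float
    hours: float
    seed: int

    def spec_for_well(self, well: str) -> FieldSpec:
        row = self.well_params.set_index("well").loc[well]
        return dataclasses.replace(
            self.base_spec,
            positive_fraction=float(row["true_fraction"]),
            punctum_intensity=self.base_spec.punctum_intensity * float(row["intensity_scale"]),
            diffuse_intensity=self.base_spec.diffuse_intensity * float(row["intensity_scale"]),
        )

    def iter_fields(self, wells: Sequence[str] | None = None
                    ) -> Iterator[tuple[FieldImage, FieldTruth]]:
        wp = self.well_params if wells is None else self.well_params[
            self.well_params["well"].isin(wells)]
        for row in wp.itertuples():
            spec = self.spec_for_well(row.well)
            for f in range(self.n_fields_per_well):
                img, truth = generate_field(
                    spec, int(row.seed) + f, plate=self.layout.plate,
                    well=row.well, field=f)
                yield img, truth

    def true_modifiers(self, tol: float = 1e-9) -> set[str]:
        """Genes whose simulated condition differs from the control condition."""
        wp = self.well_params
        ctrl = wp.loc[wp["role"] == "control", "true_fraction"].iloc[0]
        out = set()
        for row in wp[wp["role"] == "gene"].itertuples():
            if abs(row.true_fraction - ctrl) > tol or abs(row.intensity_scale - 1.0) > tol:
                out.add(row.gene_id)
        return out


def generate_screen(layout: PlateLayout, dose_time: DoseTimeModel,
                    effects: EffectTable, n_fields_per_well: int, seed: int, *,
                    base_spec: FieldSpec | None = None,
                    conc_um: float = 500.0, hours: float = 24.0) -> ScreenSimulation:
    """Build a reproducible whole-plate simulation.

    Each well's true positive fraction is ``clip(dose_time(conc, hours) *
    fraction_effect(gene))``; control wells always use effect 1.  Raises
    :class:`UnknownGeneError` if the effect table names a gene not on the plate.
    """
    if base_spec is None:
        base_spec = FieldSpec()
    unknown = effects.genes() - set(layout.genes)
    if unknown:
        raise UnknownGeneError(f"effect table refers to unknown genes: {sorted(unknown)}")

    base_fraction = dose_time(conc_um, hours)
    ss = np.random.SeedSequence([int(seed), 0x5C12EE])
    well_seeds = ss.generate_state(len(layout.table)) % (2**31)

    rows = []
    for i, rec in enumerate(layout.table.itertuples()):
        if rec.role == "control":
            frac, inten = base_fraction, 1.0
        else:
            frac = float(np.clip(base_fraction * effects.fraction_effect(rec.gene_id), 0, 1))
            inten = effects.intensity_effect(rec.gene_id)
        rows.append((rec.well, rec.gene_id, rec.role, rec.replicate, frac, inten,
                     int(well_seeds[i]) * 1000))
    well_params = pd.DataFrame(
        rows, columns=["well", "gene_id", "role", "replicate",
                       "true_fraction", "intensity_scale", "seed"])
    return ScreenSimulation(layout=layout, well_params=well_params,
                            base_spec=base_spec, n_fields_per_well=n_fields_per_well,
                            conc_um=conc_um, hours=hours, seed=int(seed))


# ---------------------------------------------------------------------------
# 3D brain stacks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RoiBox:
    """Half-open 3D box [lo, lo+shape) in voxel coordinates (z, y, x)."""

    lo: tuple[int, int, int]
    shape: tuple[int, int, int]

    @property
    def hi(self) -> tuple[int, int, int]:
        return tuple(l + s for l, s in zip(self.lo, self.shape))

    def contains(self, point: Sequence[float]) -> bool:
        return all(l <= p < h for l, p, h in zip(self.lo, point, self.hi))

    def volume_um3(self, voxel_size_um: Sequence[float]) -> float:
        return float(np.prod([s * v for s, v in zip(self.shape, voxel_size_um)]))


@dataclass
class BrainStack:
    """3D raster (z, y, x) with physical voxel size in micrometres."""

    data: np.ndarray
    voxel_size_um: tuple[float, float, float]
    animal_id: str = "animal01"
    group: str = "control"

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("stack must be a non-empty 3D array")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")


@dataclass
class BrainTruth:
    """Ground truth for one synthetic stack."""

    centers: list[tuple[float, float, float]]
    roi_boxes: list[RoiBox]
    voxel_size_um: tuple[float, float, float]

    @property
    def n_puncta(self) -> int:
        return len(self.centers)

    @property
    def counts_per_roi(self) -> list[int]:
        return [sum(b.contains(c) for c in self.centers) for b in self.roi_boxes]

    @property
    def density(self) -> float:
        """Mean per-ROI count over one ROI volume (aggregates per um^3)."""
        vols = [b.volume_um3(self.voxel_size_um) for b in self.roi_boxes]
        return float(np.mean(self.counts_per_roi) / np.mean(vols))


PUNCTUM_VOXEL_RANGE = (10, 1000)  # detectable object-size filter range


def _render_ball(data: np.ndarray, center: np.ndarray, target_voxels: int,
                 intensity: float) -> int:
    """Stamp a solid digital ball of ~target_voxels voxels; returns the count.

    The radius is found by bisection on the digital voxel count so the
    rendered object always stays inside the detectable [10, 1000] range.
    """
    shape = data.shape
    r_lo, r_hi = 0.8, 9.0
    best_mask = None
    best_sl = None
    best_count = -1
    for _ in range(40):
        r = 0.5 * (r_lo + r_hi)
        sl = tuple(slice(max(int(np.floor(ci - r)) - 1, 0),
                         min(int(np.ceil(ci + r)) + 2, s))
                   for ci, s in zip(center, shape))
        grids = np.meshgrid(*[np.arange(s.start, s.stop) for s in sl], indexing="ij")
        d2 = sum((g - ci) ** 2 for g, ci in zip(grids, center))
        mask = d2 <= r * r
        count = int(mask.sum())
        if best_count < 0 or abs(count - target_voxels) < abs(best_count - target_voxels):
            if PUNCTUM_VOXEL_RANGE[0] <= count <= PUNCTUM_VOXEL_RANGE[1]:
                best_mask, best_sl, best_count = mask, sl, count
        if count < target_voxels:
            r_lo = r
        else:
            r_hi = r
        if abs(count - target_voxels) <= max(1, target_voxels // 20):
            break
    if best_mask is None:  # fall back to the smallest admissible ball
        r = 1.6
        sl = tuple(slice(max(int(np.floor(ci - r)) - 1, 0),
                         min(int(np.ceil(ci + r)) + 2, s))
                   for ci, s in zip(center, shape))
        grids = np.meshgrid(*[np.arange(s.start, s.stop) for s in sl], indexing="ij")
        d2 = sum((g - ci) ** 2 for g, ci in zip(grids, center))
        best_mask, best_sl = d2 <= r * r, sl
        best_count = int(best_mask.sum())
    data[best_sl][best_mask] = intensity
    return best_count


def generate_brain_stack(n_puncta: int, roi_boxes: Sequence[RoiBox],
                         voxel_size_um: tuple[float, float, float],
                         punctum_voxels: int, seed: int, *,
                         shape: tuple[int, int, int] = (40, 160, 160),
                         inside_fraction: float | None = None,
                         punctum_intensity: float = 200.0,
                         noise_sd: float = 1.0,
                         max_tries: int = 20000) -> tuple[BrainStack, BrainTruth]:
    """Render a 3D stack with exactly ``n_puncta`` bright blobs over background.

    ``punctum_voxels`` is the approximate voxel count of each blob and must
    lie in the detectable range [10, 1000].  With ``inside_fraction`` set,
    that share of puncta (rounded) is placed with its centre inside the ROI
    boxes, the rest outside; otherwise placement is uniform.  Deterministic
    per seed; raises :class:`PlacementError` if non-overlapping placement
    fails.
    """
    lo, hi = PUNCTUM_VOXEL_RANGE
    if not lo <= punctum_voxels <= hi:
        raise ValueError(
            f"punctum_voxels={punctum_voxels} outside detectable range [{lo}, {hi}]")
    boxes = list(roi_boxes)
    for b in boxes:
        if any(x < 0 for x in b.lo) or any(h > s for h, s in zip(b.hi, shape)):
            raise ValueError(f"ROI box {b} outside stack of shape {shape}")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB1A1]))
    radius = max((3.0 * punctum_voxels / (4.0 * np.pi)) ** (1.0 / 3.0), 1.3)
    margin = radius + 1.0
    min_sep = 2.0 * radius + 2.0

    n_inside = None
    if inside_fraction is not None:
        n_inside = int(round(inside_fraction * n_puncta))

    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_puncta:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"placed only {len(centers)}/{n_puncta} puncta after {max_tries} "
                "tries; enlarge the stack or reduce n_puncta")
        want_inside = n_inside is not None and len(centers) < n_inside
        if want_inside:
            b = boxes[rng.integers(len(boxes))]
            c = np.array([rng.uniform(l + 0.01, h - 0.01) for l, h in zip(b.lo, b.hi)])
        else:
            c = np.array([rng.uniform(margin, s - margin) for s in shape])
            if n_inside is not None and any(b.contains(c) for b in boxes):
                continue
        if any(np.linalg.norm(c - p) < min_sep for p in centers):
            continue
        centers.append(c)

    data = np.zeros(shape, dtype=np.float64)
    for c in centers:
        _render_ball(data, c, punctum_voxels, punctum_intensity)
    if noise_sd > 0:
        data = np.clip(data + rng.normal(0, noise_sd, shape), 0, None)

    stack = BrainStack(data=data, voxel_size_um=tuple(voxel_size_um))
    truth = BrainTruth(centers=[tuple(map(float, c)) for c in centers],
                       roi_boxes=boxes, voxel_size_um=tuple(voxel_size_um))
    return stack, truth
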