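"""File formats and run configuration.

Formats are deliberately plain: multi-page TIFF for fields (page 0 = nuclei,
page 1 = GFP) named ``<plate>_<well>_f<field>.tif``, 3D TIFF for brain
stacks with a YAML sidecar carrying the voxel size, CSV for the plate map
(columns ``plate,well,role,gene_id,replicate``), TSV for per-cell/per-well
features, hits and densities, JSON for thresholds, YAML for the run
configuration.  The run configuration round-trips losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .brain import BrainParams
from .features import MacroParams
from .screen import ScreenStatsParams
from .segmentation import SegmentationParams
from .synthetic import BrainStack, FieldImage, FieldTruth, PlateLayout, RoiBox

__all__ = [
    "RunConfig",
    "field_filename",
    "write_field_tiff",
    "read_field_tiff",
    "write_truth_tsv",
    "write_plate_map",
    "read_plate_map",
    "write_brain_stack",
    "read_brain_stack",
]

FLOAT_FORMAT = "%.6g"  # fixed text formatting keeps reruns byte-identical


# ---------------------------------------------------------------------------
# Field images and plate maps
# ---------------------------------------------------------------------------


def field_filename(plate: str, well: str, field: int) -> str:
    return f"{plate}_{well}_f{field:02d}.tif"


def write_field_tiff(path: Path | str, img: FieldImage) -> Path:
    """Two-page TIFF: page 0 = nuclei channel, page 1 = GFP channel."""
    path = Path(path)
    stack = np.stack([img.nuclei, img.gfp]).astype(np.float32)
    tifffile.imwrite(path, stack, metadata={
        "plate": img.plate, "well": img.well, "field": img.field,
        "pixel_size_um": img.pixel_size_um})
    return path


def read_field_tiff(path: Path | str) -> FieldImage:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValueError(f"{path} is not a two-page (nuclei, GFP) field TIFF")
    stem = path.stem
    parts = stem.split("_")
    plate = str(meta.get("plate", parts[0] if parts else "plate01"))
    well = str(meta.get("well", parts[1] if len(parts) > 1 else "A01"))
    field = int(meta.get("field", int(parts[2][1:]) if len(parts) > 2 else 0))
    return FieldImage(nuclei=stack[0].astype(np.float64),
                      gfp=stack[1].astype(np.float64),
                      pixel_size_um=float(meta.get("pixel_size_um", 0.5)),
                      plate=plate, well=well, field=field)


def write_truth_tsv(path: Path | str, truth: FieldTruth) -> Path:
    path = Path(path)
    truth.to_frame().to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    return path


def write_plate_map(path: Path | str, layout: PlateLayout) -> Path:
    path = Path(path)
    layout.table.to_csv(path, index=False)
    return path


def read_plate_map(path: Path | str) -> PlateLayout:
    table = pd.read_csv(path, dtype={"plate": str, "well": str, "role": str,
                                     "gene_id": str, "replicate": int})
    expected = ["plate", "well", "role", "gene_id", "replicate"]
    if list(table.columns) != expected:
        raise ValueError(f"plate map must have columns {expected}, got "
                         f"{list(table.columns)}")
    plate = table["plate"].iloc[0] if len(table) else "plate01"
    return PlateLayout(table=table, plate=plate)


# ---------------------------------------------------------------------------
# Brain stacks
# ---------------------------------------------------------------------------


def write_brain_stack(path: Path | str, stack: BrainStack) -> Path:
    """3D TIFF plus a YAML sidecar with voxel size and labels."""
    path = Path(path)
    tifffile.imwrite(path, stack.data.astype(np.float32))
    sidecar = {
        "voxel_size_um": [float(v) for v in stack.voxel_size_um],
        "animal_id": stack.animal_id,
        "group": stack.group,
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=True))
    return path


def read_brain_stack(path: Path | str) -> BrainStack:
    path = Path(path)
    data = tifffile.imread(path).astype(np.float64)
    sidecar_path = path.with_suffix(".yaml")
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"voxel-size sidecar {sidecar_path} missing; physical units are "
            "required and never assumed")
    meta = yaml.safe_load(sidecar_path.read_text())
    return BrainStack(data=data, voxel_size_um=tuple(meta["voxel_size_um"]),
                      animal_id=str(meta.get("animal_id", path.stem)),
                      group=str(meta.get("group", "control")))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of a screen or brain run.

    Round-trips losslessly through YAML; every pipeline run logs the resolved
    configuration and global seed next to its outputs.
    """

    seed: int = 1
    input_dir: str = ""
    output_dir: str = "results"
    segmentation: SegmentationParams = dc_field(default_factory=SegmentationParams)
    macro: MacroParams = dc_field(default_factory=MacroParams)
    screen_stats: ScreenStatsParams = dc_field(default_factory=ScreenStatsParams)
    brain: BrainParams = dc_field(default_factory=BrainParams)
    roi_boxes: tuple[RoiBox, ...] = ()
    timepoint: str = "24h"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["roi_boxes"] = [
            {"lo": list(b["lo"]), "shape": list(b["shape"])} for b in d["roi_boxes"]
        ]
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(_plainify(self.to_dict()), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def tupled(sub: dict, keys: tuple[str, ...]) -> dict:
            return {k: tuple(v) if k in keys and isinstance(v, list) else v
                    for k, v in sub.items()}

        seg = SegmentationParams(**tupled(d.get("segmentation", {}), ("size_cutoff",)))
        mac = MacroParams(**tupled(d.get("macro", {}),
                                   ("particle_size_range", "circularity_range",
                                    "dapi_particle_size_range")))
        scr = ScreenStatsParams(**tupled(d.get("screen_stats", {}), ("parameters",)))
        brn = BrainParams(**d.get("brain", {}))
        boxes = tuple(RoiBox(lo=tuple(b["lo"]), shape=tuple(b["shape"]))
                      for b in d.get("roi_boxes", []))
        return cls(seed=int(d.get("seed", 1)),
                   input_dir=str(d.get("input_dir", "")),
                   output_dir=str(d.get("output_dir", "results")),
                   segmentation=seg, macro=mac, screen_stats=scr, brain=brn,
                   roi_boxes=boxes, timepoint=str(d.get("timepoint", "24h")))


def _plainify(obj):
    """Recursively convert numpy scalars/tuples so yaml.safe_dump accepts them."""
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
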