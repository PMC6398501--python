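"""End-to-end screen and brain pipelines.

``run_screen_pipeline`` chains segmentation, per-cell feature extraction and
hit calling over a whole plate (simulated in memory or read from field
TIFFs), writing the per-cell and per-well TSVs, the Monte-Carlo thresholds,
``hits.tsv`` and a QC report.  ``run_brain_pipeline`` chains 3D aggregate
detection, density computation, control normalisation and group statistics.
Both are deterministic given (inputs, config, seed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import io as wio
from .brain import BrainParams, DensityRecord, aggregation_density, detect_aggregates_3d, normalize_and_compare
from .features import cell_intensity_features, subtract_local_background
from .screen import (ScreenStatsParams, ThresholdResult, call_hits, hits_frame,
                     monte_carlo_threshold, zscore_plate)
from .segmentation import SegmentationParams, make_cell_rois, preprocess_nuclei_image, segment_nuclei
from .synthetic import BrainStack, FieldImage, PlateLayout, RoiBox, ScreenSimulation

__all__ = [
    "DEFAULT_FIELDS_PER_WELL",
    "ScreenRunResult",
    "BrainRunResult",
    "process_field",
    "analyze_plate",
    "run_screen_pipeline",
    "run_brain_pipeline",
]

# the screen imaged ten fields per well; plate-scale simulations may scale down
DEFAULT_FIELDS_PER_WELL = 10

BG_DISK_RADIUS_PX = 3.0           # local background disk of the screen
POSITIVE_MIN_INTENSITY = 50.0     # corrected-AFU floor marking a cell positive


def process_field(img: FieldImage, seg_params: SegmentationParams, *,
                  bg_disk_radius_px: float = BG_DISK_RADIUS_PX,
                  positive_min_intensity: float = POSITIVE_MIN_INTENSITY
                  ) -> pd.DataFrame:
    """Segment one field and extract per-cell intensity features."""
    pre = preprocess_nuclei_image(img.nuclei)
    labels = segment_nuclei(pre, seg_params)
    rois = make_cell_rois(labels, img.gfp, seg_params)
    corrected = subtract_local_background(img.gfp, bg_disk_radius_px)
    feats = cell_intensity_features(rois, corrected,
                                    positive_min_intensity=positive_min_intensity)
    feats.insert(0, "plate", img.plate)
    feats.insert(1, "well", img.well)
    feats.insert(2, "field", img.field)
    return feats


@dataclass
class ScreenRunResult:
    per_cell: pd.DataFrame
    per_well: pd.DataFrame
    well_stats: pd.DataFrame
    thresholds: dict[str, ThresholdResult]
    hits: pd.DataFrame
    warnings: list[str] = dc_field(default_factory=list)
    output_dir: Path | None = None


def _per_well_summary(per_cell: pd.DataFrame) -> pd.DataFrame:
    g = per_cell.groupby("well", sort=True)
    out = g.agg(n_cells=("cell_id", "size"), n_positive=("positive", "sum"))
    out["fraction"] = out["n_positive"] / out["n_cells"]
    return out.reset_index()


def analyze_plate(per_cell: pd.DataFrame, layout: PlateLayout,
                  stats_params: ScreenStatsParams, seed: int, *,
                  timepoint: str = "24h"
                  ) -> tuple[pd.DataFrame, dict[str, ThresholdResult], pd.DataFrame]:
    """Hit calling for one plate from the per-cell feature table.

    For each intensity parameter: plate Z-scores against the pooled controls,
    a Monte-Carlo threshold on control triplicates, and the 2-of-3 rule.
    Returns (well statistics, thresholds by parameter, hit table).
    """
    control_wells = layout.control_wells
    all_stats = []
    thresholds: dict[str, ThresholdResult] = {}
    all_calls = []
    mc_seeds = np.random.SeedSequence([int(seed), 0xCA11]).generate_state(
        len(stats_params.parameters)) % (2**31)
    for pi, parameter in enumerate(stats_params.parameters):
        values_by_well = {
            w: sub[parameter].to_numpy(dtype=float)
            for w, sub in per_cell.groupby("well") if len(sub) > 0
        }
        stats_df = zscore_plate(values_by_well, control_wells,
                                layout=layout.table, parameter=parameter,
                                timepoint=timepoint)
        all_stats.append(stats_df)
        ctrl_values = {w: values_by_well[w] for w in control_wells
                       if w in values_by_well}
        thr = monte_carlo_threshold(ctrl_values, stats_params.n_sim,
                                    stats_params.alpha, int(mc_seeds[pi]))
        thresholds[parameter] = thr
        gene_stats = stats_df[stats_df["role"] == "gene"]
        z_by_gene = {g: sub.sort_values("replicate")["z"].to_list()
                     for g, sub in gene_stats.groupby("gene")}
        calls = call_hits(z_by_gene, thr.z_threshold,
                          min_hits=stats_params.min_hits, parameter=parameter,
                          timepoint=timepoint)
        all_calls.extend(calls)
    well_stats = pd.concat(all_stats, ignore_index=True)
    hits = hits_frame(all_calls)
    return well_stats, thresholds, hits


def _iter_input_fields(input_dir: Path, layout: PlateLayout,
                       problems: list[str]) -> Iterable[FieldImage]:
    seen_wells = set()
    for path in sorted(input_dir.glob("*.tif")):
        try:
            img = wio.read_field_tiff(path)
        except Exception as exc:  # corrupt image: record, keep going
            problems.append(f"could not read {path.name}: {exc}")
            continue
        seen_wells.add(img.well)
        yield img
    missing = sorted(set(layout.table["well"]) - seen_wells)
    for w in missing:
        problems.append(f"well {w} has no images; excluded")


def run_screen_pipeline(config: wio.RunConfig, *,
                        simulation: ScreenSimulation | None = None,
                        input_dir: Path | str | None = None,
                        layout: PlateLayout | None = None,
                        output_dir: Path | str | None = None) -> ScreenRunResult:
    """Run the whole screen pipeline and write its output tables.

    Either a :class:`ScreenSimulation` (in-memory, reproducible) or an
    ``input_dir`` with field TIFFs plus a ``plate_map.csv`` must be given.
    Outputs: ``per_cell.tsv``, ``per_well.tsv``, ``thresholds.json``,
    ``hits.tsv``, ``qc_report.md`` and the resolved ``config.yaml``.
    """
    problems: list[str] = []
    if simulation is not None:
        layout = simulation.layout
        fields = (img for img, _truth in simulation.iter_fields())
    elif input_dir is not None:
        input_dir = Path(input_dir)
        if layout is None:
            map_path = input_dir / "plate_map.csv"
            if not map_path.exists():
                raise FileNotFoundError(f"no plate map at {map_path}")
            layout = wio.read_plate_map(map_path)
        fields = _iter_input_fields(input_dir, layout, problems)
    else:
        raise ValueError("provide either a simulation or an input_dir")

    frames = []
    field_counts = []
    for img in fields:
        feats = process_field(img, config.segmentation)
        frames.append(feats)
        field_counts.append((img.well, img.field, len(feats)))
    if not frames:
        raise ValueError("no fields to analyse")
    per_cell = pd.concat(frames, ignore_index=True)
    per_well = _per_well_summary(per_cell)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        well_stats, thresholds, hits = analyze_plate(
            per_cell, layout, config.screen_stats, config.seed,
            timepoint=config.timepoint)
    problems.extend(str(w.message) for w in caught)

    result = ScreenRunResult(per_cell=per_cell, per_well=per_well,
                             well_stats=well_stats, thresholds=thresholds,
                             hits=hits, warnings=problems)
    if output_dir is not None:
        result.output_dir = _write_screen_outputs(
            Path(output_dir), config, result, field_counts)
    return result


def _write_screen_outputs(out: Path, config: wio.RunConfig,
                          result: ScreenRunResult,
                          field_counts: list[tuple[str, int, int]]) -> Path:
    out.mkdir(parents=True, exist_ok=True)
    ff = wio.FLOAT_FORMAT
    cols = ["plate", "well", "field", "cell_id", "avg_intensity", "total_intensity"]
    result.per_cell[cols].to_csv(out / "per_cell.tsv", sep="\t", index=False,
                                 float_format=ff)
    result.per_well.to_csv(out / "per_well.tsv", sep="\t", index=False,
                           float_format=ff)
    hit_rows = result.hits[result.hits["is_hit"]]
    result.hits.to_csv(out / "hits.tsv", sep="\t", index=False, float_format=ff)
    (out / "thresholds.json").write_text(json.dumps(
        {p: {"z_threshold": t.z_threshold, "alpha": t.alpha,
             "n_simulations": t.n_simulations, "seed": t.seed}
         for p, t in result.thresholds.items()}, indent=2))
    (out / "config.yaml").write_text(config.to_yaml())

    counts = pd.DataFrame(field_counts, columns=["well", "field", "n_cells"])
    ctrl = result.well_stats[result.well_stats["role"] == "control"]
    lines = [
        "# Screen QC report",
        "",
        f"- fields analysed: {len(counts)}",
        f"- cells per field: median {counts['n_cells'].median():.0f}, "
        f"range {counts['n_cells'].min()}-{counts['n_cells'].max()}",
        f"- wells analysed: {result.per_well.shape[0]}",
        f"- warnings: {len(result.warnings)}",
        "",
        "## Control Z-score distribution",
        "",
    ]
    for p, sub in ctrl.groupby("parameter"):
        lines.append(f"- {p}: median z {sub['z'].median():+.3f}, "
                     f"MAD-scaled spread {1.4826 * (sub['z'] - sub['z'].median()).abs().median():.3f} "
                     f"over {len(sub)} control wells")
    lines += ["", "## Thresholds", ""]
    for p, t in result.thresholds.items():
        lines.append(f"- {p}: |z| > {t.z_threshold:.3f} "
                     f"(alpha={t.alpha}, {t.n_simulations} simulations)")
    lines += ["", f"## Hits ({int(hit_rows.shape[0])} rows)", ""]
    for rec in hit_rows.itertuples():
        lines.append(f"- {rec.gene} [{rec.parameter}] direction={rec.direction}")
    if result.warnings:
        lines += ["", "## Warnings", ""] + [f"- {w}" for w in result.warnings]
    (out / "qc_report.md").write_text("\n".join(lines) + "\n")
    return out


# ---------------------------------------------------------------------------
# Brain pipeline
# ---------------------------------------------------------------------------


@dataclass
class BrainRunResult:
    densities: pd.DataFrame
    stats: pd.DataFrame
    records: list[DensityRecord]
    output_dir: Path | None = None


def run_brain_pipeline(stacks: Sequence[BrainStack], roi_boxes: Sequence[RoiBox],
                       params: BrainParams = BrainParams(), *,
                       control_group: str = "control", test: str = "anova_lsd",
                       output_dir: Path | str | None = None,
                       make_plot: bool = False) -> BrainRunResult:
    """Detect aggregates in every stack, compute densities and compare groups.

    With a single group the density table is still normalised (control mean
    = 1) but no tests are run.
    """
    if not stacks:
        raise ValueError("no brain stacks to analyse")
    records = []
    for stack in stacks:
        _labels, objects = detect_aggregates_3d(stack, params)
        rec = aggregation_density(objects, roi_boxes, stack.voxel_size_um,
                                  stack_shape=stack.data.shape,
                                  animal_id=stack.animal_id, group=stack.group)
        records.append(rec)
    groups = {r.group for r in records}
    if len(groups) == 1:
        densities, stats = _normalize_only(records, next(iter(groups)))
    else:
        densities, stats = normalize_and_compare(records, control_group, test=test)

    result = BrainRunResult(densities=densities, stats=stats, records=records)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        densities.to_csv(out / "density.tsv", sep="\t", index=False,
                         float_format=wio.FLOAT_FORMAT)
        stats.to_csv(out / "stats.tsv", sep="\t", index=False,
                     float_format=wio.FLOAT_FORMAT)
        if make_plot:
            _plot_densities(densities, out / "normalized_density.png")
        result.output_dir = out
    return result


def _normalize_only(records: Sequence[DensityRecord], group: str):
    import pandas as pd  # local alias keeps signature simple

    df = pd.DataFrame(
        {"animal": [r.animal_id for r in records],
         "group": [r.group for r in records],
         "n_aggregates": [r.n_aggregates for r in records],
         "volume_um3": [r.roi_volume_um3 for r in records],
         "density": [r.density for r in records]})
    mean = df["density"].mean()
    if mean == 0:
        raise ValueError("control-group mean density is zero; cannot normalise")
    df["normalized"] = df["density"] / mean
    stats = pd.DataFrame(columns=["test", "group1", "group2", "statistic",
                                  "p_value", "mean_difference"])
    return df, stats


def _plot_densities(densities: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    order = sorted(densities["group"].unique())
    for i, g in enumerate(order):
        vals = densities.loc[densities["group"] == g, "normalized"]
        x = np.full(len(vals), i) + np.linspace(-0.1, 0.1, len(vals))
        ax.plot(x, vals, "o", ms=4)
        ax.hlines(vals.mean(), i - 0.2, i + 0.2, color="k")
    ax.set_xticks(range(len(order)), order, rotation=30, ha="right")
    ax.set_ylabel("normalized aggregation density")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
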