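"""Hit calling for the high-content screen.

Per-cell intensity distributions (average or total GFP per cell) are turned
into per-gene calls through four stages:

1. a signed two-sample Kolmogorov-Smirnov statistic between each well's
   per-cell values and the pooled negative-control cells of the same plate
   (positive sign = the well's intensities are stochastically smaller, the
   suppressor direction);
2. robust per-plate Z-scores: the null location/scale are the median and
   1.4826 x MAD of leave-one-out control-vs-pooled-controls KS statistics;
3. a Monte-Carlo threshold calibrated on the exact 2-of-3 decision rule:
   pseudo-genes are triplicates resampled from the control wells and the
   (1 - alpha) quantile of their second-largest |z| is the cutoff;
4. the 2-of-3 rule: a gene is a hit iff at least ``min_hits`` replicates
   have |z| above the threshold, with a direction annotation.

Error-rate estimation against simulation ground truth and per-category hit
percentages close the loop.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScreenStatsParams",
    "ThresholdResult",
    "HitCall",
    "ErrorRates",
    "DegenerateNullError",
    "ks_statistic",
    "zscore_plate",
    "monte_carlo_threshold",
    "call_hits",
    "estimate_error_rates",
    "category_summary",
]

MIN_CONTROL_WELLS_Z = 8
MIN_CONTROL_WELLS_MC = 4


class DegenerateNullError(ValueError):
    """All null KS statistics identical: the robust scale is zero."""


@dataclass(frozen=True)
class ScreenStatsParams:
    """Hit-calling settings: significance level, simulation depth, 2-of-3 rule."""

    alpha: float = 0.001
    n_sim: int = 10000
    min_hits: int = 2
    parameters: tuple[str, ...] = ("avg_intensity", "total_intensity")

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")


def ks_statistic(sample: Sequence[float], reference: Sequence[float]) -> float:
    """Signed two-sample KS statistic D in [-1, 1].

    D = F_sample(t*) - F_reference(t*) at the point t* maximising the
    absolute ECDF difference over the pooled support.  D > 0 means the
    sample is stochastically smaller than the reference (the suppressor
    direction for intensity data).
    """
    s = np.sort(np.asarray(sample, dtype=np.float64))
    r = np.sort(np.asarray(reference, dtype=np.float64))
    if s.size == 0 or r.size == 0:
        raise ValueError("ks_statistic requires non-empty sample and reference")
    return _ks_signed_sorted(s, r)


def _ks_signed_sorted(s: np.ndarray, r: np.ndarray) -> float:
    """Signed D for pre-sorted arrays in O((n+m) log(nm)).

    sup_t (F_s - F_r) is attained at a sample point, sup_t (F_r - F_s) at a
    reference point; both suprema are evaluated by rank lookups.
    """
    fs_at_s = np.arange(1, s.size + 1) / s.size
    fr_at_s = np.searchsorted(r, s, side="right") / r.size
    d_plus = float(np.max(fs_at_s - fr_at_s, initial=0.0))
    fr_at_r = np.arange(1, r.size + 1) / r.size
    fs_at_r = np.searchsorted(s, r, side="right") / s.size
    d_minus = float(np.max(fr_at_r - fs_at_r, initial=0.0))
    return d_plus if d_plus >= d_minus else -d_minus


def _null_scores(control_values: Mapping[str, np.ndarray]) -> pd.Series:
    """Leave-one-out KS statistic of each control well vs the pooled rest."""
    wells = sorted(control_values)
    out = {}
    for w in wells:
        pooled = np.concatenate([np.asarray(control_values[v]) for v in wells if v != w])
        out[w] = ks_statistic(control_values[w], pooled)
    return pd.Series(out, name="ks_signed")


def _robust_location_scale(null_d: np.ndarray) -> tuple[float, float]:
    med = float(np.median(null_d))
    mad = float(np.median(np.abs(null_d - med)))
    scale = 1.4826 * mad
    if scale <= 0:
        raise DegenerateNullError(
            "all null KS statistics are identical; cannot normalise (zero scale)")
    return med, scale


def zscore_plate(values_by_well: Mapping[str, np.ndarray],
                 control_wells: Sequence[str], *,
                 layout: pd.DataFrame | None = None,
                 parameter: str = "avg_intensity",
                 timepoint: str = "24h") -> pd.DataFrame:
    """Per-plate KS statistics and robust Z-scores for every well.

    ``values_by_well`` maps well -> per-cell values for one plate, parameter
    and timepoint.  Control wells get leave-one-out statistics; gene wells
    are compared against the full control pool.  Requires at least
    8 control wells.
    """
    controls = [w for w in control_wells if w in values_by_well]
    if len(controls) < MIN_CONTROL_WELLS_Z:
        raise ValueError(
            f"need at least {MIN_CONTROL_WELLS_Z} control wells for plate "
            f"normalisation, got {len(controls)}")
    ctrl_values = {w: np.asarray(values_by_well[w], dtype=np.float64) for w in controls}
    null_d = _null_scores(ctrl_values)
    med, scale = _robust_location_scale(null_d.to_numpy())
    pooled = np.concatenate(list(ctrl_values.values()))

    meta = None
    if layout is not None:
        meta = layout.set_index("well")

    rows = []
    for well in sorted(values_by_well):
        vals = np.asarray(values_by_well[well], dtype=np.float64)
        if well in null_d.index:
            d = float(null_d[well])
            role = "control"
        else:
            d = ks_statistic(vals, pooled)
            role = "gene"
        gene, rep = "", 0
        if meta is not None and well in meta.index:
            gene = str(meta.loc[well, "gene_id"])
            rep = int(meta.loc[well, "replicate"])
            role = str(meta.loc[well, "role"])
        rows.append((well, gene, role, rep, parameter, timepoint, d,
                     (d - med) / scale, len(vals)))
    return pd.DataFrame(
        rows, columns=["well", "gene", "role", "replicate", "parameter",
                       "timepoint", "ks_signed", "z", "n_cells"])


@dataclass(frozen=True)
class ThresholdResult:
    """Monte-Carlo calibrated |z| cutoff for the 2-of-3 rule."""

    z_threshold: float
    alpha: float
    n_simulations: int
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {"z_threshold": self.z_threshold, "alpha": self.alpha,
             "n_simulations": self.n_simulations, "seed": self.seed},
            indent=2)


def monte_carlo_threshold(control_values: Mapping[str, np.ndarray],
                          n_sim: int, alpha: float, seed: int) -> ThresholdResult:
    """Calibrate the Z-score threshold on resampled control triplicates.

    Each pseudo-gene is a triplicate of control-well cell sets: three
    distinct control wells are drawn (without replacement within the
    triplicate) and each well's cell set is resampled with replacement, so
    the simulated null carries both the between-well and the cell-sampling
    variation and is not capped at the observed control extremes.  Every
    pseudo-well's KS statistic against the pooled controls is converted to a
    Z-score with the plate's null location/scale, and the pseudo-gene scored
    by its second-largest |z| -- the order statistic the 2-of-3 rule
    thresholds.  The cutoff is the (1 - alpha) quantile of the simulated
    null, taken with the conservative "higher" interpolation.
    """
    if len(control_values) < MIN_CONTROL_WELLS_MC:
        raise ValueError(
            f"need at least {MIN_CONTROL_WELLS_MC} control wells for the "
            f"Monte-Carlo null, got {len(control_values)}")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    ctrl = {w: np.asarray(v, dtype=np.float64) for w, v in control_values.items()}
    null_d = _null_scores(ctrl)
    med, scale = _robust_location_scale(null_d.to_numpy())
    wells = sorted(ctrl)
    cell_sets = [ctrl[w] for w in wells]
    pooled = np.sort(np.concatenate(cell_sets))

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x3C0]))
    n_wells = len(wells)
    sims = np.empty(n_sim)
    for i in range(n_sim):
        trip = rng.choice(n_wells, size=3, replace=False)
        z = np.empty(3)
        for j, wi in enumerate(trip):
            cells = cell_sets[wi]
            boot = np.sort(rng.choice(cells, size=cells.size, replace=True))
            z[j] = abs((_ks_signed_sorted(boot, pooled) - med) / scale)
        sims[i] = np.sort(z)[-2]
    if alpha >= 1.0:
        thr = float(sims.min())
    else:
        thr = float(np.quantile(sims, 1.0 - alpha, method="higher"))
    return ThresholdResult(z_threshold=thr, alpha=float(alpha),
                           n_simulations=int(n_sim), seed=int(seed))


@dataclass(frozen=True)
class HitCall:
    gene: str
    parameter: str
    timepoint: str
    n_replicates_above: int
    is_hit: bool
    direction: str  # suppressor | enhancer | mixed | none
    z_values: tuple[float, ...] = dc_field(default=())


def call_hits(z_by_gene: Mapping[str, Sequence[float]], z_threshold: float, *,
              min_hits: int = 2, parameter: str = "avg_intensity",
              timepoint: str = "24h") -> list[HitCall]:
    """Apply the 2-of-3 rule: hit iff >= min_hits replicates have |z| > threshold.

    Direction comes from the signs of the qualifying replicates: all positive
    (stochastically smaller intensities) = suppressor, all negative =
    enhancer, disagreement = mixed.  Genes with fewer than ``min_hits``
    replicate values are skipped with a warning.
    """
    calls = []
    for gene in sorted(z_by_gene):
        z = np.asarray(z_by_gene[gene], dtype=np.float64)
        if z.size < min_hits:
            warnings.warn(
                f"gene {gene!r} has {z.size} replicate z-values "
                f"(< {min_hits}); skipped", stacklevel=2)
            continue
        above = z[np.abs(z) > z_threshold]
        n_above = int(above.size)
        is_hit = n_above >= min_hits
        if not is_hit or n_above == 0:
            direction = "none"
        elif np.all(above > 0):
            direction = "suppressor"
        elif np.all(above < 0):
            direction = "enhancer"
        else:
            direction = "mixed"
        calls.append(HitCall(gene=gene, parameter=parameter, timepoint=timepoint,
                             n_replicates_above=n_above, is_hit=is_hit,
                             direction=direction, z_values=tuple(map(float, z))))
    return calls


def hits_frame(calls: Sequence[HitCall]) -> pd.DataFrame:
    """Tabulate hit calls (one row per gene x parameter x timepoint)."""
    rows = []
    for c in calls:
        z = list(c.z_values) + [np.nan] * max(0, 3 - len(c.z_values))
        rows.append((c.gene, c.parameter, c.timepoint, z[0], z[1], z[2],
                     c.n_replicates_above, c.is_hit, c.direction))
    return pd.DataFrame(rows, columns=["gene", "parameter", "timepoint",
                                       "z1", "z2", "z3", "n_above", "is_hit",
                                       "direction"])


@dataclass(frozen=True)
class ErrorRates:
    """False-positive / false-negative rates of a simulated screen."""

    fp_rate: float
    fn_rate: float | None
    parameter: str = "avg_intensity"
    timepoint: str = "24h"


def estimate_error_rates(calls: Sequence[HitCall], true_modifiers: set[str],
                         all_genes: Sequence[str]) -> ErrorRates:
    """Compare hit calls with the simulation's planted-modifier truth."""
    genes = set(all_genes)
    unknown = true_modifiers - genes
    if unknown:
        raise ValueError(f"true modifiers not among screened genes: {sorted(unknown)}")
    hit_genes = {c.gene for c in calls if c.is_hit}
    nulls = genes - true_modifiers
    fp = len(hit_genes & nulls) / len(nulls) if nulls else 0.0
    fn = (len(true_modifiers - hit_genes) / len(true_modifiers)
          if true_modifiers else None)
    param = calls[0].parameter if calls else "avg_intensity"
    tp = calls[0].timepoint if calls else "24h"
    return ErrorRates(fp_rate=float(fp), fn_rate=None if fn is None else float(fn),
                      parameter=param, timepoint=tp)


def category_summary(hit_genes: Sequence[str], categories: Mapping[str, str],
                     screened_genes: Sequence[str]) -> pd.DataFrame:
    """Percent of screened genes called as targets, per gene category."""
    hits = set(hit_genes)
    uncategorised = sorted(g for g in hits if g not in categories)
    if uncategorised:
        raise KeyError(f"hit genes without a category: {uncategorised}")
    rows = {}
    for g in screened_genes:
        cat = categories.get(g)
        if cat is None:
            continue
        n_scr, n_hit = rows.get(cat, (0, 0))
        rows[cat] = (n_scr + 1, n_hit + (1 if g in hits else 0))
    out = pd.DataFrame(
        [(cat, n_scr, n_hit, 100.0 * n_hit / n_scr)
         for cat, (n_scr, n_hit) in sorted(rows.items())],
        columns=["category", "n_screened", "n_hits", "percent_targets"])
    return out
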