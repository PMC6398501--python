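"""3D aggregate detection, density arithmetic and group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import aggscreen as ag
from aggscreen.brain import (BrainParams, aggregation_density,
                             detect_aggregates_3d, normalize_and_compare)
from aggscreen.synthetic import BrainStack, RoiBox

VOX = (0.5, 0.25, 0.25)
BOXES = (RoiBox(lo=(4, 8, 8), shape=(16, 24, 24)),
         RoiBox(lo=(4, 40, 8), shape=(16, 24, 24)),
         RoiBox(lo=(4, 72, 8), shape=(16, 24, 24)))


def stack_of(data):
    return BrainStack(data=np.asarray(data, dtype=float), voxel_size_um=VOX)


class TestDetectAggregates:
    def test_background_only(self):
        rng = np.random.default_rng(0)
        stack = stack_of(rng.normal(1, 0.2, (16, 32, 32)).clip(0))
        _labels, objects = detect_aggregates_3d(stack, BrainParams(threshold=50))
        assert objects.empty

    def test_threshold_above_max(self):
        stack = stack_of(np.full((8, 8, 8), 10.0))
        _l, objects = detect_aggregates_3d(stack, BrainParams(threshold=1e6))
        assert objects.empty

    def test_exact_count_on_clean_stack(self):
        stack, truth = ag.generate_brain_stack(
            60, BOXES, VOX, 60, seed=3, shape=(24, 104, 48), noise_sd=0.0)
        _l, objects = detect_aggregates_3d(stack, BrainParams(threshold=50.0))
        assert len(objects) == truth.n_puncta == 60

    def test_size_filter_sharp_at_bounds(self):
        """Objects of exactly 10 and 1000 voxels are kept; 9 and 1001 removed."""
        data = np.zeros((30, 60, 60))
        data[2, 2, 2:11] = 100.0            # 9 voxels
        data[6, 6, 6:16] = 100.0            # 10 voxels
        data[10:20, 20:30, 20:30] = 100.0   # 1000 voxels
        data[10:20, 40:50, 40:50] = 100.0   # 1000 voxels ...
        data[9, 40, 40] = 100.0             # ... plus 1: 1001-voxel object
        stack = stack_of(data)
        _l, objects = detect_aggregates_3d(stack, BrainParams(threshold=50.0))
        assert sorted(objects["n_vox"]) == [10, 1000]

    def test_26_connectivity(self):
        data = np.zeros((10, 10, 10))
        data[2:4, 2:4, 2:4] = 100.0   # 8-voxel cube
        data[4, 4, 4] = 100.0         # touches the corner only diagonally
        stack = stack_of(data)
        _l, objects = detect_aggregates_3d(
            stack, BrainParams(threshold=50.0, min_vox=1, max_vox=1000))
        assert len(objects) == 1


class TestAggregationDensity:
    def test_zero_objects(self):
        rec = aggregation_density(pd.DataFrame(columns=["z", "y", "x"]),
                                  BOXES, VOX)
        assert rec.density == 0.0

    def test_truth_arithmetic(self):
        stack, truth = ag.generate_brain_stack(
            60, BOXES, VOX, 60, seed=2, shape=(24, 104, 48),
            inside_fraction=0.75, noise_sd=0.0)
        _l, objects = detect_aggregates_3d(stack, BrainParams(threshold=50.0))
        rec = aggregation_density(objects, BOXES, VOX,
                                  stack_shape=stack.data.shape)
        assert rec.n_aggregates == sum(truth.counts_per_roi) == 45
        assert rec.density == pytest.approx(truth.density)
        total_vol = sum(b.volume_um3(VOX) for b in BOXES)
        assert rec.density == pytest.approx(45 / total_vol)

    def test_half_open_box_convention(self):
        box = RoiBox(lo=(2, 2, 2), shape=(4, 4, 4))
        on_lo = pd.DataFrame({"z": [2.0], "y": [2.0], "x": [2.0]})
        on_hi = pd.DataFrame({"z": [6.0], "y": [3.0], "x": [3.0]})
        assert aggregation_density(on_lo, [box], VOX).n_aggregates == 1
        assert aggregation_density(on_hi, [box], VOX).n_aggregates == 0

    def test_roi_outside_stack_error(self):
        box = RoiBox(lo=(0, 0, 0), shape=(64, 8, 8))
        with pytest.raises(ValueError, match="outside stack"):
            aggregation_density(pd.DataFrame(columns=["z", "y", "x"]),
                                [box], VOX, stack_shape=(16, 16, 16))

    def test_scale_covariance(self):
        pts = pd.DataFrame({"z": [5.0, 6.0], "y": [10.0, 42.0], "x": [10.0, 12.0]})
        d1 = aggregation_density(pts, BOXES, VOX).density
        d2 = aggregation_density(pts, BOXES, tuple(2 * v for v in VOX)).density
        assert d1 == pytest.approx(8 * d2)

    def test_density_exact_on_noise_free_stacks(self):
        for seed in (5, 6):
            stack, truth = ag.generate_brain_stack(
                40, BOXES, VOX, 80, seed=seed, shape=(24, 104, 48),
                noise_sd=0.0, inside_fraction=0.6)
            _l, objects = detect_aggregates_3d(stack, BrainParams(threshold=50.0))
            rec = aggregation_density(objects, BOXES, VOX)
            assert rec.density == pytest.approx(truth.density, abs=0.0)


def density_records(values_by_group):
    recs = []
    for g, vals in values_by_group.items():
        for i, v in enumerate(vals):
            recs.append(ag.DensityRecord(animal_id=f"{g}{i}", group=g,
                                         n_aggregates=0, roi_volume_um3=1.0,
                                         density=float(v)))
    return recs


class TestNormalizeAndCompare:
    def test_control_mean_exactly_one(self):
        recs = density_records({"control": [0.2, 0.4, 0.9], "kd": [0.1, 0.2]})
        df, _ = normalize_and_compare(recs, "control")
        assert df.loc[df["group"] == "control", "normalized"].mean() == pytest.approx(1.0)

    def test_identical_groups_t_test_p1(self):
        recs = density_records({"control": [2.0, 4.0, 6.0], "other": [2.0, 4.0, 6.0]})
        df, st = normalize_and_compare(recs, "control", test="t_test")
        row = st.iloc[0]
        assert row["p_value"] == pytest.approx(1.0)
        assert row["statistic"] == pytest.approx(0.0)

    def test_anova_textbook_example(self):
        """One-way ANOVA of {2,4,6} vs {8,10,12}: SSB=54, SSW=16, df=(1,4),
        so F = 54/4 = 13.5; cross-checked against scipy."""
        recs = density_records({"a": [2.0, 4.0, 6.0], "b": [8.0, 10.0, 12.0]})
        _df, st = normalize_and_compare(recs, "a", test="anova_lsd")
        f_row = st[st["test"] == "anova"].iloc[0]
        assert f_row["statistic"] == pytest.approx(13.5)
        assert f_row["statistic"] == pytest.approx(
            sps.f_oneway([2, 4, 6], [8, 10, 12]).statistic)
        lsd = st[st["test"] == "lsd"].iloc[0]
        # hand LSD: t = -6 / sqrt(4*(2/3)), df = 4
        assert lsd["statistic"] == pytest.approx(-6 / np.sqrt(8 / 3))
        assert lsd["p_value"] == pytest.approx(
            2 * sps.t.sf(6 / np.sqrt(8 / 3), df=4))

    def test_small_group_excluded_with_warning(self):
        recs = density_records({"control": [1.0, 2.0, 3.0], "tiny": [5.0]})
        with pytest.warns(UserWarning, match="n < 2"):
            _df, st = normalize_and_compare(recs, "control", test="anova_lsd")
        assert st.empty  # only one testable group remains

    def test_suppressor_power_simulation(self):
        """A suppressor group at a third of the control density (n=8/group)
        is detected by LSD at p<0.05 in >=90% of replicates, with normalized
        mean in [0.2, 0.5].  Counts are Poisson over the ROI volume, the
        generative law of the synthetic stacks."""
        rng = np.random.default_rng(314)
        vol, lam_ctrl = 600.0, 45.0
        n_sig = 0
        norm_means = []
        for _ in range(100):
            ctrl = rng.poisson(lam_ctrl, 8) / vol
            supp = rng.poisson(lam_ctrl / 3, 8) / vol
            recs = density_records({"control": ctrl, "supp": supp})
            df, st = normalize_and_compare(recs, "control", test="anova_lsd")
            lsd = st[(st["test"] == "lsd")].iloc[0]
            if lsd["p_value"] < 0.05:
                n_sig += 1
            norm_means.append(df.loc[df["group"] == "supp", "normalized"].mean())
        assert n_sig >= 90
        assert 0.2 <= np.mean(norm_means) <= 0.5

    def test_unknown_control_group(self):
        recs = density_records({"a": [1.0, 2.0]})
        with pytest.raises(ValueError, match="control group"):
            normalize_and_compare(recs, "missing")
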