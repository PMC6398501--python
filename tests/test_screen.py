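"""KS statistic, plate Z-scores, Monte-Carlo threshold, hit calling."""

import numpy as np
import pytest
from scipy import stats as sps

from aggscreen.screen import (DegenerateNullError, call_hits, category_summary,
                              estimate_error_rates, hits_frame, ks_statistic,
                              monte_carlo_threshold, zscore_plate)
from conftest import draw_null_well_values


def brute_force_ks(sample, reference):
    """Independent oracle: max |ECDF difference| over every pooled point."""
    best = 0.0
    for t in list(sample) + list(reference):
        fs = sum(1 for v in sample if v <= t) / len(sample)
        fr = sum(1 for v in reference if v <= t) / len(reference)
        best = max(best, abs(fs - fr))
    return best


class TestKsStatistic:
    def test_identical_samples(self):
        assert ks_statistic([1, 2, 2, 5], [1, 2, 2, 5]) == 0.0

    def test_disjoint_supports(self):
        assert ks_statistic([1, 2, 3], [10, 11]) == 1.0     # sample below
        assert ks_statistic([10, 11], [1, 2, 3]) == -1.0    # sample above

    def test_small_example(self):
        d = ks_statistic([1, 2, 3], [2, 3, 4])
        assert d == pytest.approx(1 / 3)  # attained on t in [1, 2)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            ks_statistic([], [1.0])

    def test_matches_brute_force_and_scipy_on_200_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n, m = rng.integers(1, 51, size=2)
            s = rng.normal(rng.uniform(-1, 1), 1, n)
            r = rng.normal(0, rng.uniform(0.5, 2), m)
            if rng.random() < 0.3:  # exercise ties
                s = np.round(s)
                r = np.round(r)
            d = ks_statistic(s, r)
            assert abs(d) == pytest.approx(brute_force_ks(s, r), abs=1e-12)
            assert abs(d) == pytest.approx(sps.ks_2samp(s, r).statistic, abs=1e-12)

    def test_invariant_under_increasing_transform(self):
        rng = np.random.default_rng(7)
        s = rng.normal(0, 1, 40)
        r = rng.normal(0.5, 1.2, 60)
        d = ks_statistic(s, r)
        for f in (np.exp, lambda x: 3 * x + 7, lambda x: x**3):
            assert ks_statistic(f(s), f(r)) == pytest.approx(d, abs=1e-12)


def simulated_plate_values(rng, n_controls=42, n_gene_wells=30):
    values = {}
    controls = [f"C{i:02d}" for i in range(n_controls)]
    for w in controls:
        values[w] = draw_null_well_values(rng)
    for i in range(n_gene_wells):
        values[f"G{i:02d}"] = draw_null_well_values(rng)
    return values, controls


class TestZscorePlate:
    def test_null_calibration_over_20_plates(self):
        """Control z-scores under the null: median ~0, MAD-scaled spread ~1
        (tolerance 0.15 over 42 control wells x 20 simulated plates)."""
        rng = np.random.default_rng(99)
        meds, spreads = [], []
        for _ in range(20):
            values, controls = simulated_plate_values(rng, n_gene_wells=0)
            out = zscore_plate(values, controls)
            z = out["z"].to_numpy()
            meds.append(np.median(z))
            spreads.append(1.4826 * np.median(np.abs(z - np.median(z))))
        assert abs(np.mean(meds)) < 0.15
        assert abs(np.mean(spreads) - 1.0) < 0.15

    def test_z_formula_consistent(self):
        rng = np.random.default_rng(3)
        values, controls = simulated_plate_values(rng, n_gene_wells=5)
        out = zscore_plate(values, controls).set_index("well")
        null_d = out.loc[controls, "ks_signed"].to_numpy()
        med = np.median(null_d)
        scale = 1.4826 * np.median(np.abs(null_d - med))
        for w in out.index:
            assert out.loc[w, "z"] == pytest.approx(
                (out.loc[w, "ks_signed"] - med) / scale)

    def test_too_few_controls(self):
        rng = np.random.default_rng(1)
        values, controls = simulated_plate_values(rng, n_controls=7)
        with pytest.raises(ValueError, match="at least 8"):
            zscore_plate(values, controls)

    def test_degenerate_null(self):
        vals = {f"C{i}": np.arange(10.0) for i in range(10)}
        with pytest.raises(DegenerateNullError):
            zscore_plate(vals, list(vals))


@pytest.fixture(scope="module")
def control_values():
    rng = np.random.default_rng(17)
    values, _controls = simulated_plate_values(rng, n_gene_wells=0)
    return values


class TestMonteCarloThreshold:

    def test_alpha_one_gives_minimum(self, control_values):
        res = monte_carlo_threshold(control_values, 500, 1.0, seed=1)
        res2 = monte_carlo_threshold(control_values, 500, 0.5, seed=1)
        assert res.z_threshold <= res2.z_threshold

    def test_monotone_in_alpha(self, control_values):
        thr = [monte_carlo_threshold(control_values, 2000, a, seed=5).z_threshold
               for a in (0.001, 0.01, 0.1, 0.5)]
        assert all(a >= b for a, b in zip(thr, thr[1:]))

    def test_determinism(self, control_values):
        a = monte_carlo_threshold(control_values, 1000, 0.01, seed=9)
        b = monte_carlo_threshold(control_values, 1000, 0.01, seed=9)
        assert a == b

    def test_too_few_wells(self):
        with pytest.raises(ValueError, match="at least 4"):
            monte_carlo_threshold({"a": np.arange(5.0)}, 100, 0.1, seed=1)

    def test_held_out_null_exceedance(self):
        """Fresh null pseudo-genes exceed the alpha=0.001 threshold at a rate
        of at most 0.002."""
        rng = np.random.default_rng(2024)
        values, controls = simulated_plate_values(rng, n_gene_wells=0)
        thr = monte_carlo_threshold(values, 5000, 0.001, seed=11).z_threshold
        out = zscore_plate(values, controls).set_index("well")
        null_d = out["ks_signed"].to_numpy()
        med = np.median(null_d)
        scale = 1.4826 * np.median(np.abs(null_d - med))
        pooled = np.concatenate(list(values.values()))
        exceed = 0
        n_fresh = 2000
        for _ in range(n_fresh):
            z = [abs((ks_statistic(draw_null_well_values(rng), pooled) - med) / scale)
                 for _ in range(3)]
            if sorted(z)[-2] > thr:
                exceed += 1
        assert exceed / n_fresh <= 0.002


class TestCallHits:
    def test_two_of_three_rule(self):
        t = 2.0
        calls = call_hits({"a": [t + 1, t + 1, t - 1]}, t)
        assert calls[0].is_hit and calls[0].n_replicates_above == 2
        calls = call_hits({"b": [t + 1, t - 1, t - 1]}, t)
        assert not calls[0].is_hit

    def test_direction_from_sign(self):
        t = 2.0
        assert call_hits({"g": [-t - 1, -t - 1, 0]}, t)[0].direction == "enhancer"
        assert call_hits({"g": [t + 1, t + 1, 0]}, t)[0].direction == "suppressor"
        assert call_hits({"g": [t + 1, -t - 1, t + 1]}, t)[0].direction == "mixed"

    def test_missing_replicates_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            calls = call_hits({"g": [5.0]}, 2.0)
        assert calls == []

    def test_invariant_to_replicate_order(self):
        z = [3.1, -0.2, 2.8]
        a = call_hits({"g": z}, 2.0)[0]
        b = call_hits({"g": z[::-1]}, 2.0)[0]
        assert (a.is_hit, a.n_replicates_above, a.direction) == \
               (b.is_hit, b.n_replicates_above, b.direction)


class TestErrorRatesAndCategories:
    def _calls(self, hit_genes, all_genes):
        return call_hits(
            {g: ([5.0, 5.0, 0.0] if g in hit_genes else [0.1, 0.2, 0.0])
             for g in all_genes}, 2.0)

    def test_null_screen_fp_zero(self):
        genes = [f"g{i}" for i in range(20)]
        er = estimate_error_rates(self._calls(set(), genes), set(), genes)
        assert er.fp_rate == 0.0 and er.fn_rate is None

    def test_fn_against_truth(self):
        genes = [f"g{i}" for i in range(20)]
        truth = {"g0", "g1", "g2", "g3"}
        er = estimate_error_rates(self._calls({"g0", "g1"}, genes), truth, genes)
        assert er.fn_rate == pytest.approx(0.5)
        assert er.fp_rate == 0.0

    def test_infinite_threshold_limit(self):
        genes = ["a", "b", "c"]
        calls = call_hits({g: [9.0, 9.0, 9.0] for g in genes}, np.inf)
        er = estimate_error_rates(calls, {"a"}, genes)
        assert er.fp_rate == 0.0 and er.fn_rate == 1.0

    def test_category_summary(self):
        cats = {f"g{i}": ("ALS" if i < 20 else "UPS") for i in range(40)}
        hits = [f"g{i}" for i in range(5)]
        out = category_summary(hits, cats, list(cats)).set_index("category")
        assert out.loc["ALS", "percent_targets"] == pytest.approx(25.0)
        assert out.loc["UPS", "percent_targets"] == 0.0

    def test_empty_hits_all_zero(self):
        cats = {"a": "x", "b": "y"}
        out = category_summary([], cats, ["a", "b"])
        assert out["percent_targets"].eq(0).all()

    def test_uncategorised_hit_error(self):
        with pytest.raises(KeyError, match="mystery"):
            category_summary(["mystery"], {"a": "x"}, ["a", "mystery"])

    def test_two_parameter_overlap_from_hit_table(self):
        genes = ["a", "b", "c", "d"]
        calls = []
        for param, hit_set in (("avg_intensity", {"a", "b", "c"}),
                               ("total_intensity", {"b", "c", "d"})):
            calls += call_hits(
                {g: ([5.0, 5.0, 0.0] if g in hit_set else [0.1, 0.2, 0.0])
                 for g in genes}, 2.0, parameter=param)
        hf = hits_frame(calls)
        by_param = {p: set(sub.loc[sub["is_hit"], "gene"])
                    for p, sub in hf.groupby("parameter")}
        assert by_param["avg_intensity"] & by_param["total_intensity"] == {"b", "c"}
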