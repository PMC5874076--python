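"""Study-pipeline arithmetic, group tests, rank correlations."""

import math

import numpy as np
import pytest

from fxarev import (
    AnimalRecord,
    SimulationConfig,
    adjusted_blood_loss,
    analyze_study,
    compare_groups,
    correlate,
    fold_change,
    generate_rabbit_study,
    percent_change,
    read_animal_csv,
    summarize_groups,
    write_animal_csv,
)


class TestDerivedArithmetic:
    @pytest.mark.parametrize(
        "before,after,expected",
        [(548.0, 100.0, 82.0), (507.0, 447.0, 12.0), (99.0, 21.0, 79.0), (7.0, 7.0, 0.0)],
    )
    def test_percent_change(self, before, after, expected):
        assert percent_change(before, after).value == expected

    def test_percent_change_requires_positive_baseline(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)

    @pytest.mark.parametrize(
        "a,b,expected", [(22.2, 9.3, 2.4), (5.0, 5.0, 1.0), (18.6, 9.3, 2.0)]
    )
    def test_fold_change(self, a, b, expected):
        assert fold_change(a, b).value == expected

    def test_adjusted_blood_loss(self):
        assert adjusted_blood_loss(11.9, 9.3).value == 2.6
        assert adjusted_blood_loss(22.2, 9.3).value == 12.9
        assert adjusted_blood_loss(9.3, 9.3).value == 0.0
        assert adjusted_blood_loss(10.0, 9.3).value == 0.7
        # adjusted reduction: 2.6 vs 12.9 g -> 80%
        assert percent_change(12.9, 2.6).value == 80.0


class TestCompareGroups:
    def test_identical_samples(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == pytest.approx(0.0)
        assert res.p_t == pytest.approx(1.0)
        assert not res.degenerate

    def test_pooled_variance_t_matches_hand_formula(self):
        # means 2 and 12; pooled variance 1; SE = sqrt(2/3)
        res = compare_groups([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert res.t_statistic == pytest.approx(-10.0 / math.sqrt(2.0 / 3.0), rel=1e-12)
        assert res.p_t < 0.001
        assert res.rank_p < 0.15  # rank-sum has limited resolution at n=3+3

    def test_zero_variance_degenerate(self):
        res = compare_groups([2.0, 2.0], [2.0, 2.0])
        assert res.degenerate

    def test_rejection_pattern_on_configured_group_effects(self):
        # Arms drawn at the configured blood-loss means/SDs at n=10 should
        # separate vehicle from control in most replicates, reversal from
        # vehicle often, and reversal from control rarely.
        rng = np.random.default_rng(42)
        hits = {"veh_ctl": 0, "rev_veh": 0, "rev_ctl": 0}
        reps = 40
        for _ in range(reps):
            ctl = rng.normal(9.3, 3.0, 10)
            veh = rng.normal(22.2, 8.9, 10)
            rev = rng.normal(11.9, 3.7, 10)
            hits["veh_ctl"] += compare_groups(veh, ctl).p_t <= 0.05
            hits["rev_veh"] += compare_groups(rev, veh).p_t <= 0.05
            hits["rev_ctl"] += compare_groups(rev, ctl).p_t <= 0.05
        assert hits["veh_ctl"] / reps > 0.9
        assert hits["rev_veh"] / reps > 0.5
        assert hits["rev_ctl"] / reps < 0.6


class TestCorrelate:
    def test_perfect_monotone(self):
        up = correlate([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert up.spearman_r == pytest.approx(1.0)
        down = correlate([1, 2, 3, 4, 5], [50, 40, 30, 20, 10])
        assert down.spearman_r == pytest.approx(-1.0)

    def test_tied_ranks_match_hand_computed_formula(self):
        # y ranks with average ties: [1, 2.5, 2.5, 4, 5];
        # Pearson([1..5], ranks) = 9.5 / sqrt(10 * 9.5)
        res = correlate([1, 2, 3, 4, 5], [10, 20, 20, 40, 50])
        assert res.spearman_r == pytest.approx(9.5 / math.sqrt(95.0), rel=1e-12)
        assert 0.0 < res.p <= 1.0  # exact permutation p at n=5

    def test_constant_input_flagged(self):
        res = correlate([1, 2, 3, 4], [7, 7, 7, 7])
        assert res.undefined

    def test_needs_four_pairs(self):
        with pytest.raises(ValueError):
            correlate([1, 2, 3], [1, 2, 3])


def _tiny_study(seed=0, n=4):
    return generate_rabbit_study(SimulationConfig(seed=seed, n_per_group=n))


class TestPipeline:
    def test_summaries_permutation_invariant(self):
        records = _tiny_study()
        shuffled = list(reversed(records))
        a = summarize_groups(records)
        b = summarize_groups(shuffled)
        for g in a:
            assert a[g].n == b[g].n
            for key in a[g].means:
                assert a[g].means[key] == pytest.approx(b[g].means[key], rel=1e-12)

    def test_analyze_reproduces_configured_arithmetic_at_zero_noise(self):
        records = generate_rabbit_study(SimulationConfig(seed=1, noise_scale=0.0, n_per_group=3))
        report = analyze_study(records)
        d = report["derived"]
        assert d["anti_fxa_reduction_reversal_pct"] == 82.0
        assert d["anti_fxa_reduction_vehicle_pct"] == 12.0
        assert d["anti_fxa_vehicle_decrease_ng_ml"] == 60.0
        assert d["blood_loss_fold_vehicle_vs_control"] == 2.4
        assert d["adjusted_blood_loss_reversal_g"] == 2.6
        assert d["adjusted_blood_loss_vehicle_g"] == 12.9
        assert d["blood_loss_reduction_pct"] == 80.0
        assert d["molar_ratio_decoy_to_inhibitor"] == 1.6

    def test_analyze_requires_core_groups(self):
        records = [r for r in _tiny_study() if r.group == "control"]
        with pytest.raises(ValueError):
            analyze_study(records)

    def test_animal_csv_round_trip(self, tmp_path):
        records = _tiny_study(seed=3)
        path = tmp_path / "animals.csv"
        write_animal_csv(records, path)
        back = read_animal_csv(path)
        assert len(back) == len(records)
        assert back[0].group == records[0].group
        assert back[5].value("anti_fxa", 25) == pytest.approx(
            records[5].value("anti_fxa", 25), rel=1e-9
        )

    def test_record_validation(self):
        with pytest.raises(ValueError):
            AnimalRecord("x", "not_a_group", 1.0)
        with pytest.raises(ValueError):
            AnimalRecord("x", "control", -1.0)
        with pytest.raises(ValueError):
            AnimalRecord("x", "control", 1.0, timepoints={13: {}})
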