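import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bap1timing import (
    CohortConfig,
    DoublingTimeScenario,
    GrowthParams,
    InvalidInputError,
    generate_cohort,
    km_fit,
    mutation_timing,
    recovery_experiment,
    simulate_growth,
)


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        cfg = CohortConfig(n_tumors=25, seed=123, cells_per_tumor=20)
        t1, c1 = generate_cohort(cfg)
        t2, c2 = generate_cohort(cfg)
        assert t1.to_csv() == t2.to_csv()
        assert c1.to_csv() == c2.to_csv()

    def test_seed_changes_output(self):
        t1, _ = generate_cohort(CohortConfig(n_tumors=25, seed=1, cells_per_tumor=1))
        t2, _ = generate_cohort(CohortConfig(n_tumors=25, seed=2, cells_per_tumor=1))
        assert not np.allclose(t1["volume_mm3"], t2["volume_mm3"])

    def test_empty_cohort(self):
        tumors, cells = generate_cohort(CohortConfig(n_tumors=0, seed=0))
        assert len(tumors) == 0 and len(cells) == 0

    def test_dimension_calibration(self):
        cfg = CohortConfig(n_tumors=10_000, seed=5, cells_per_tumor=1)
        tumors, _ = generate_cohort(cfg)
        assert tumors["thickness_mm"].mean() == pytest.approx(7.2, abs=0.2)
        assert (tumors["thickness_mm"] >= 1).all()
        assert (tumors["lbd_mm"] >= 3).all()
        assert (tumors["thickness_mm"] <= tumors["lbd_mm"]).all()

    def test_cell_volume_calibration(self):
        cfg = CohortConfig(n_tumors=100, seed=8, cells_per_tumor=100)
        _, cells = generate_cohort(cfg)
        from bap1timing import summarize_cell_population

        s = summarize_cell_population(cells)
        assert s.loc["lost", "mean_volume_um3"] == pytest.approx(2657, rel=0.05)
        assert s.loc["retained", "mean_volume_um3"] == pytest.approx(1593, rel=0.05)
        assert (cells["long_caliper_um"] >= cells["short_caliper_um"]).all()

    def test_survival_median_calibration(self):
        cfg = CohortConfig(n_tumors=10_000, seed=13, cells_per_tumor=1)
        tumors, _ = generate_cohort(cfg)
        mut = tumors[tumors["bap1_mutant"]]
        c = km_fit(mut["follow_up_months"] / 12, mut["metastasis_event"])
        assert c.median == pytest.approx(2.4, rel=0.15)

    def test_percent_loss_bounds_and_wildtype_floor(self):
        tumors, _ = generate_cohort(CohortConfig(n_tumors=500, seed=2, cells_per_tumor=1))
        assert tumors["percent_bap1_loss"].between(0, 100).all()
        wt = tumors.loc[~tumors["bap1_mutant"], "percent_bap1_loss"]
        mut = tumors.loc[tumors["bap1_mutant"], "percent_bap1_loss"]
        assert wt.mean() < 10 < mut.mean()

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidInputError):
            CohortConfig(n_tumors=-1)
        with pytest.raises(InvalidInputError):
            CohortConfig(mutation_prevalence=1.5)


class TestSimulateGrowth:
    def test_equal_rates_total_is_single_exponential(self):
        p = GrowthParams(128, 128, 2.1, 348.0)
        res = simulate_growth(p)
        assert res.total_cells == pytest.approx(
            2 ** (res.duration_days / 128), rel=1e-9)
        assert res.mutant_fraction == pytest.approx(2 ** -2.1, rel=1e-9)

    def test_round_trip_recovery_named_example(self):
        """Mutation at generation 2.1 recovered exactly from final counts."""
        p = GrowthParams(128, 128, 2.1, 348.0)
        res = simulate_growth(p)
        est = mutation_timing(res.total_cells, res.mutant_cells,
                              DoublingTimeScenario(128))
        assert est.tumor_age_at_mutation == pytest.approx(2.1 * 128, abs=1e-6)
        assert est.clone_size_at_mutation == pytest.approx(2**2.1, rel=1e-9)

    @given(
        gen=st.floats(min_value=0.1, max_value=15.0),
        t_double=st.floats(min_value=30.0, max_value=600.0),
        end_volume=st.floats(min_value=10.0, max_value=2000.0),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_round_trip_recovery_property(self, gen, t_double, end_volume):
        """Under equal doubling times the estimator inverts the simulator."""
        p = GrowthParams(t_double, t_double, gen, end_volume)
        res = simulate_growth(p)
        est = mutation_timing(res.total_cells, res.mutant_cells,
                              DoublingTimeScenario(t_double))
        assert est.tumor_age_at_mutation == pytest.approx(
            gen * t_double, rel=1e-6, abs=1e-6)

    def test_mutation_at_initiation_is_whole_tumor(self):
        p = GrowthParams(128, 128, 0.0, 50.0)
        res = simulate_growth(p)
        assert res.mutant_fraction == pytest.approx(1.0)

    def test_faster_mutant_biases_mutation_older(self):
        """A growth-advantaged clone makes the mutation look older (bias > 0)."""
        p = GrowthParams(128, 100, 3.0, 348.0)
        res = simulate_growth(p)
        est = mutation_timing(res.total_cells, res.mutant_cells,
                              DoublingTimeScenario(128))
        true_since = res.duration_days - res.mutation_day
        assert est.mutation_days_before_dx > true_since

    def test_trajectory_monotone(self):
        res = simulate_growth(GrowthParams(128, 200, 4.0, 100.0))
        traj = res.trajectory
        total = traj["wt_cells"] + traj["mutant_cells"]
        assert (np.diff(total) > -1e-9).all()

    def test_end_before_mutation_rejected(self):
        with pytest.raises(InvalidInputError):
            # 2^40 cells needed before mutation, end volume only ~475k cells
            simulate_growth(GrowthParams(128, 128, 40.0, 1.0))


class TestRecoveryExperiment:
    def test_equal_rate_grid_is_exact(self):
        grid = [
            GrowthParams(t, t, g, 348.0)
            for t in (128.0, 292.0, 511.0)
            for g in (0.5, 2.1, 8.0)
        ]
        table = recovery_experiment(
            grid, [DoublingTimeScenario(t) for t in (128.0, 292.0, 511.0)]
        )
        exact = table[table["doubling_time_wt"] == [
            float(s.rstrip("d")) for s in table["scenario"]
        ]]
        assert exact["bias_days"].abs().max() < 1.0

    def test_faster_mutant_bias_sign_constant(self):
        grid = [GrowthParams(128, 128 / 1.1, g, 348.0) for g in (1.0, 3.0, 6.0)]
        table = recovery_experiment(grid, [DoublingTimeScenario(128)])
        assert (table["bias_days"] > 0).all()

    def test_empty_scenarios_empty_table(self):
        table = recovery_experiment([GrowthParams(128, 128, 2.0, 10.0)], [])
        assert len(table) == 0

    def test_empty_grid_rejected(self):
        with pytest.raises(InvalidInputError):
            recovery_experiment([], [DoublingTimeScenario(128)])
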