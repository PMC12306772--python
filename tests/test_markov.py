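"""Markov cohort engine: rate conversions, accrual, and the microsim oracle."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungscreen_cea.decision_tree import Branch, BranchSet, HealthState, Strategy, evaluate_tree
from lungscreen_cea.markov import (
    LifeTable,
    ModelSettings,
    annual_rate_from_survival,
    microsim_oracle,
    probability_from_rate,
    run_cohort,
)
from lungscreen_cea.synthetic import perturbed_fixture


def single_state_branches(state: HealthState) -> BranchSet:
    return BranchSet(
        strategy=Strategy.NO_SCREENING,
        branches=(Branch("single", state, 1.0, 0.0),),
    )


def zero_mortality_table(max_age: int = 150) -> LifeTable:
    # deliberately bypasses validate(): no terminal row, used with a fixed horizon
    return LifeTable(ages=np.arange(max_age + 1), qx=np.zeros(max_age + 1))


class TestRateConversions:
    @pytest.mark.parametrize(
        "survival, horizon, expected",
        [(0.535, 5.0, 0.1251), (0.039, 5.0, 0.6488), (1.0, 5.0, 0.0)],
    )
    def test_exponential_method_from_five_year_survival(self, survival, horizon, expected):
        assert annual_rate_from_survival(survival, horizon) == pytest.approx(
            expected, abs=5e-5
        )

    def test_survival_domain_errors(self):
        with pytest.raises(ValueError):
            annual_rate_from_survival(0.0, 5.0)
        with pytest.raises(ValueError):
            annual_rate_from_survival(0.5, 0.0)

    def test_probability_from_rate_values(self):
        assert probability_from_rate(0.0) == 0.0
        assert probability_from_rate(0.6488) == pytest.approx(0.477327, abs=1e-6)
        assert probability_from_rate(50.0) == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(ValueError):
            probability_from_rate(-0.1)

    @given(rate=st.floats(0.0, 10.0))
    def test_probability_in_unit_interval_and_monotone_link(self, rate):
        p = probability_from_rate(rate)
        assert 0.0 <= p < 1.0
        assert p <= rate  # p = 1 - exp(-r) <= r


class TestLifeTable:
    def test_lookup_uses_floor_of_age(self, table):
        assert table.death_probability(62.4) == table.death_probability(62.0)

    def test_beyond_terminal_age_is_certain_death(self, table):
        assert table.death_probability(150.0) == 1.0

    def test_synthetic_hazard_increases_with_age(self, table):
        assert table.death_probability(70.0) > table.death_probability(60.0)

    def test_validation_rejects_bad_tables(self):
        with pytest.raises(ValueError, match="empty"):
            LifeTable(ages=np.array([]), qx=np.array([])).validate()
        with pytest.raises(ValueError, match="contiguous"):
            LifeTable(ages=np.array([0, 2, 3]), qx=np.array([0.1, 0.1, 1.0])).validate()
        with pytest.raises(ValueError, match="terminal"):
            LifeTable(ages=np.array([0, 1, 2]), qx=np.array([0.1, 0.1, 0.5])).validate()

    def test_csv_round_trip(self, table, tmp_path):
        path = tmp_path / "lt.csv"
        table.to_csv(path)
        loaded = LifeTable.from_csv(path)
        np.testing.assert_array_equal(loaded.ages, table.ages)
        np.testing.assert_allclose(loaded.qx, table.qx)


class TestCohortAccrual:
    def test_constant_cohort_accrues_utility_per_cycle(self, base_draw):
        """Full survival at zero discount: QALYs = cycles x utility; the
        half-cycle correction is a no-op when membership never changes."""
        draw = base_draw.replace(discount_rate=0.0, initial_age=60.0)
        trace = run_cohort(
            single_state_branches(HealthState.NO_CANCER),
            draw,
            zero_mortality_table(),
            ModelSettings(horizon_cycles=10),
        )
        assert trace.total_qaly_per_person == pytest.approx(10 * 0.8580, abs=1e-12)
        assert trace.total_cost_per_person == 0.0

    def test_advanced_cohort_matches_closed_form_annuity(self, base_draw, table):
        """Discounted totals for a single-state cohort equal the geometric
        half-cycle annuity sum_t 0.5(s^t + s^{t+1}) u (1+d)^-(t+1/2)."""
        settings_ = ModelSettings(stop_mass=0.0)
        trace = run_cohort(
            single_state_branches(HealthState.ADVANCED_STAGE), base_draw, table, settings_
        )
        s = np.exp(-base_draw["mortality_rate_advanced"])
        d = base_draw["discount_rate"]
        n_cycles = int(np.ceil(100.0 - base_draw["initial_age"]))
        t = np.arange(n_cycles)
        annuity = np.sum(0.5 * (s**t + s ** (t + 1)) * (1 + d) ** -(t + 0.5))
        assert trace.total_qaly_per_person == pytest.approx(
            0.5730 * annuity, rel=1e-12
        )
        assert trace.total_cost_per_person == pytest.approx(
            2135.81 * annuity, rel=1e-12
        )

    def test_end_of_cycle_discounting_flag(self, base_draw, table):
        settings_ = ModelSettings(discount_timing="end", stop_mass=0.0)
        trace = run_cohort(
            single_state_branches(HealthState.ADVANCED_STAGE), base_draw, table, settings_
        )
        s = np.exp(-base_draw["mortality_rate_advanced"])
        t = np.arange(int(np.ceil(100.0 - base_draw["initial_age"])))
        annuity = np.sum(0.5 * (s**t + s ** (t + 1)) * 1.05 ** -(t + 1.0))
        assert trace.total_qaly_per_person == pytest.approx(0.5730 * annuity, rel=1e-12)

    @given(seed=st.integers(0, 5_000))
    @settings(max_examples=25)
    def test_occupancy_conserved_and_dead_monotone(self, table, seed):
        specs = perturbed_fixture(np.random.default_rng(seed), 0.15)
        draw = specs.base_draw()
        for strategy in Strategy:
            trace = run_cohort(evaluate_tree(strategy, draw), draw, table)
            sums = trace.occupancy.sum(axis=1)
            assert np.all(np.abs(sums - 1.0) < 1e-12)
            dead = trace.occupancy[:, 3]
            assert np.all(np.diff(dead) >= -1e-15)
            assert np.all(trace.occupancy >= -1e-15)

    def test_discounted_totals_decrease_with_discount_rate(self, base_draw, table):
        rates = [0.0, 0.03, 0.05, 0.10]
        totals = []
        for d in rates:
            draw = base_draw.replace(discount_rate=d)
            trace = run_cohort(
                evaluate_tree(Strategy.SCREENING, draw), draw, table
            )
            totals.append((trace.total_cost_per_person, trace.total_qaly_per_person))
        costs, qalys = zip(*totals)
        assert all(a > b for a, b in zip(costs, costs[1:]))
        assert all(a > b for a, b in zip(qalys, qalys[1:]))

    def test_stage_shift_toward_early_increases_qalys(self, base_draw, table):
        """Early diagnosis carries lower mortality and higher utility, so
        moving initial mass from advanced to early must raise total QALYs."""

        def qalys(early_mass):
            branches = BranchSet(
                strategy=Strategy.NO_SCREENING,
                branches=(
                    Branch("e", HealthState.EARLY_STAGE, early_mass, 0.0),
                    Branch("a", HealthState.ADVANCED_STAGE, 1.0 - early_mass, 0.0),
                ),
            )
            return run_cohort(branches, base_draw, table).total_qaly_per_person

        values = [qalys(m) for m in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestMicrosimOracle:
    def test_cohort_model_matches_microsimulation_mean(self, base_draw, table):
        """Expected-value cohort equals individual simulation within 3 sigma."""
        branches = evaluate_tree(Strategy.SCREENING, base_draw)
        cohort = run_cohort(branches, base_draw, table)
        sim = microsim_oracle(
            branches, base_draw, table, 200_000, np.random.default_rng(7)
        )
        assert abs(sim.cost_mean - cohort.total_cost_per_person) < 3 * sim.cost_se
        assert abs(sim.qaly_mean - cohort.total_qaly_per_person) < 3 * sim.qaly_se

    def test_degenerate_dynamics_agree_exactly(self, base_draw):
        """With a single branch and death certain in the first cycle, both
        routes are fully deterministic and must agree to rounding."""
        certain_death = LifeTable(ages=np.arange(101), qx=np.ones(101)).validate()
        draw = base_draw.replace(mortality_rate_advanced=50.0)
        branches = single_state_branches(HealthState.ADVANCED_STAGE)
        cohort = run_cohort(branches, draw, certain_death)
        sim = microsim_oracle(branches, draw, certain_death, 500, np.random.default_rng(1))
        assert sim.qaly_mean == pytest.approx(cohort.total_qaly_per_person, abs=1e-9)
        assert sim.cost_mean == pytest.approx(cohort.total_cost_per_person, abs=1e-6)
        # everyone dies mid-way through cycle 0
        assert cohort.total_qaly_per_person == pytest.approx(
            0.5 * 0.5730 * 1.05**-0.5, rel=1e-6
        )

    def test_seed_repeatability(self, base_draw, table):
        branches = evaluate_tree(Strategy.NO_SCREENING, base_draw)
        a = microsim_oracle(branches, base_draw, table, 1_000, np.random.default_rng(5))
        b = microsim_oracle(branches, base_draw, table, 1_000, np.random.default_rng(5))
        assert a == b
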