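"""The monthly price-propagation loop."""

import dataclasses
import math

import numpy as np
import pytest

from eprsim import (
    AdjustmentPolicy,
    BenchmarkRule,
    CountryEPRConfig,
    PriceTrajectory,
    RuleVariant,
    SimulationConfig,
    initialize_state,
    run_simulation,
    step_month,
)
from eprsim.synthetic import SystemRecipe, fixture_cascade, generate_system

from naive_oracle import naive_run


def small_system(**kwargs):
    defaults = dict(
        countries=(
            CountryEPRConfig("DE", ("IT",), 1, BenchmarkRule(RuleVariant.AVERAGE)),
            CountryEPRConfig("IT", ("DE",), 1, BenchmarkRule(RuleVariant.MINIMUM)),
            CountryEPRConfig(
                "XX", ("DE", "IT"), 2, BenchmarkRule(RuleVariant.AVERAGE)
            ),
        ),
        kickoff_prices={"DE": 100.0, "IT": 70.0},
        horizon_months=5,
    )
    defaults.update(kwargs)
    return SimulationConfig(**defaults)


def test_initialize_state_base_case(base_config):
    state = initialize_state(base_config)
    assert state.month == 0
    assert state.prices == {
        "DE": 100.0, "IT": 70.0, "DK": 100.0, "SE": 100.0, "UK": 100.0
    }
    assert all(m == 0 for m in state.set_month.values())


def test_initial_setting_requires_minimum_availability():
    config = small_system(
        countries=(
            CountryEPRConfig("DE", ("IT",), 1, BenchmarkRule(RuleVariant.AVERAGE)),
            CountryEPRConfig("IT", ("DE",), 1, BenchmarkRule(RuleVariant.MINIMUM)),
            CountryEPRConfig("FR", ("DE", "IT"), 2, BenchmarkRule(RuleVariant.AVERAGE)),
            CountryEPRConfig(
                "XX", ("DE", "IT", "FR"), 3, BenchmarkRule(RuleVariant.AVERAGE)
            ),
        ),
    )
    s1 = step_month(initialize_state(config), config)
    # FR prices at month 1 from the two kick-off countries
    assert s1.prices["FR"] == pytest.approx(85.0)
    # XX still waits: FR was unset in the month-0 state it read
    assert "XX" not in s1.prices
    s2 = step_month(s1, config)
    assert s2.prices["XX"] == pytest.approx((100 + 70 + 85) / 3)
    assert s2.set_month["XX"] == 2


def test_step_is_synchronous_no_within_month_cascade():
    config = small_system()
    s1 = step_month(initialize_state(config), config)
    assert s1.prices["XX"] == pytest.approx(85.0)


def test_no_revision_country_stays_constant():
    config = small_system(horizon_months=24)
    traj = run_simulation(config)
    assert np.allclose(traj.row("XX")[1:], 85.0)


def test_revision_clock_anchored_at_first_setting():
    # cascade AA -> ZZ -> BB -> YY; YY first prices at month 3 and its
    # 3-monthly revisions (months 6, 9, ...) find an unchanged reference
    config = SimulationConfig(
        countries=(
            CountryEPRConfig("AA", ("YY",), 1, BenchmarkRule(RuleVariant.AVERAGE)),
            CountryEPRConfig(
                "ZZ", ("AA",), 1, BenchmarkRule(RuleVariant.AVERAGE),
                revision_interval_months=None,
            ),
            CountryEPRConfig(
                "BB", ("AA", "ZZ"), 2, BenchmarkRule(RuleVariant.AVERAGE)
            ),
            CountryEPRConfig(
                "YY", ("BB",), 1, BenchmarkRule(RuleVariant.AVERAGE),
                revision_interval_months=3,
            ),
        ),
        kickoff_prices={"AA": 100.0},
        horizon_months=8,
    )
    traj = run_simulation(config)
    # cascade: ZZ month 1 (100), BB month 2 (100), YY month 3 (100)
    assert traj.set_month == {"AA": 0, "ZZ": 1, "BB": 2, "YY": 3}
    assert np.allclose(traj.row("YY")[3:], 100.0)  # revisions see no change


def test_skipped_revision_keeps_old_price():
    # XX revises every 2 months but its only reference never prices,
    # leaving fewer than min_required available at every revision.
    config = SimulationConfig(
        countries=(
            CountryEPRConfig("DE", ("XX",), 1, BenchmarkRule(RuleVariant.AVERAGE)),
            CountryEPRConfig(
                "XX", ("DE", "QQ"), 2, BenchmarkRule(RuleVariant.AVERAGE),
                revision_interval_months=2, active_count=2,
            ),
            CountryEPRConfig("QQ", ("RR",), 1, BenchmarkRule(RuleVariant.AVERAGE)),
            CountryEPRConfig("RR", ("QQ",), 1, BenchmarkRule(RuleVariant.AVERAGE)),
        ),
        kickoff_prices={"DE": 100.0, "XX": 80.0},
        horizon_months=6,
    )
    traj = run_simulation(config)
    assert np.allclose(traj.row("XX"), 80.0)  # revisions due but skipped
    assert np.all(np.isnan(traj.row("QQ")))  # QQ/RR form an unpriceable island


def test_horizon_zero_is_initial_state_only(base_config):
    config = dataclasses.replace(base_config, horizon_months=0)
    traj = run_simulation(config)
    assert traj.values.shape[1] == 1
    assert sorted(
        c for c in traj.countries if not math.isnan(traj.price(c, 0))
    ) == ["DE", "DK", "IT", "SE", "UK"]


def test_cascade_fixture_matches_hand_trace():
    config, expected = fixture_cascade()
    traj = run_simulation(config)
    assert traj.countries == expected.countries
    np.testing.assert_array_equal(traj.values, expected.values)
    assert traj.set_month == expected.set_month


def test_exogenous_rows_constant_and_once_set_always_set(base_trajectory):
    for code in ("DK", "SE", "UK"):
        assert np.allclose(base_trajectory.row(code), 100.0)
    for code in base_trajectory.countries:
        row = base_trajectory.row(code)
        set_idx = np.flatnonzero(~np.isnan(row))
        assert set_idx.size > 0
        # contiguous from first setting to the horizon
        assert np.array_equal(set_idx, np.arange(set_idx[0], row.size))


def test_country_order_invariance(base_config):
    reordered = dataclasses.replace(
        base_config, countries=tuple(reversed(base_config.countries))
    )
    a = run_simulation(base_config)
    b = run_simulation(reordered)
    np.testing.assert_array_equal(a.values, b.values)


def test_bitwise_determinism(base_config):
    a = run_simulation(base_config)
    b = run_simulation(base_config)
    np.testing.assert_array_equal(a.values, b.values)


@pytest.mark.parametrize("seed", range(12))
def test_naive_oracle_equivalence(seed):
    config = generate_system(SystemRecipe(seed=seed, n_countries=8, horizon_months=40))
    traj = run_simulation(config)
    oracle = naive_run(config)
    for month, expected in enumerate(oracle):
        for code in traj.countries:
            got = traj.price(code, month)
            if code in expected:
                assert got == pytest.approx(expected[code], rel=1e-12), (
                    seed, code, month
                )
            else:
                assert math.isnan(got), (seed, code, month)


@pytest.mark.parametrize("lam", [0.5, 3.0])
def test_scaling_equivariance(lam):
    config = generate_system(SystemRecipe(seed=7, n_countries=10, horizon_months=40))
    scaled = dataclasses.replace(
        config,
        kickoff_prices={k: lam * v for k, v in config.kickoff_prices.items()},
        exogenous_prices={k: lam * v for k, v in config.exogenous_prices.items()},
    )
    a = run_simulation(config).values
    b = run_simulation(scaled).values
    np.testing.assert_allclose(b, lam * a, rtol=1e-9)


def test_discount_dominance_monthwise():
    config = generate_system(
        SystemRecipe(
            seed=11,
            n_countries=10,
            horizon_months=60,
            adjustments=AdjustmentPolicy(
                statutory_discounts={"AA": 0.07, "AB": 0.10},
                commercial_discount_rate=0.20,
                commercial_discount_countries=("AC", "AD"),
            ),
        )
    )
    plain = run_simulation(config).values
    discounted = dataclasses.replace(
        config,
        adjustments=dataclasses.replace(
            config.adjustments, statutory_active=True, commercial_active=True
        ),
    )
    disc = run_simulation(discounted).values
    # discounts never change availability, only lower prices
    np.testing.assert_array_equal(np.isnan(plain), np.isnan(disc))
    mask = ~np.isnan(plain)
    assert np.all(disc[mask] <= plain[mask] + 1e-12)


def test_all_minimum_trajectories_non_increasing():
    recipe = SystemRecipe(
        seed=3,
        n_countries=9,
        horizon_months=48,
        rule_mix={"minimum": 1.0},
        revision_mix={6: 0.5, 12: 0.5},
        partial_pool_fraction=0.0,
    )
    config = generate_system(recipe)
    # keep kick-off launch prices constant: no revisions for kick-off countries
    config = dataclasses.replace(
        config,
        countries=tuple(
            dataclasses.replace(c, revision_interval_months=None)
            if c.code in config.kickoff_prices
            else c
            for c in config.countries
        ),
    )
    values = run_simulation(config).values
    for row in values:
        set_part = row[~np.isnan(row)]
        assert np.all(np.diff(set_part) <= 1e-12)


def test_long_format_export_round_trip():
    config, _ = fixture_cascade()
    traj = run_simulation(config)
    df = traj.to_frame("base_case")
    assert set(df.columns) == {"scenario", "country", "month", "price", "is_set"}
    assert len(df) == 3 * (config.horizon_months + 1)
    back = PriceTrajectory.from_frame(df)
    np.testing.assert_array_equal(back.values, traj.values)
    assert back.set_month == traj.set_month
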