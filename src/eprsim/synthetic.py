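"""Seeded generation of random EPR country networks for property testing.

Generated systems mirror the structural features of the real 2015 European
landscape — priority-ordered baskets, minimum-availability gates, the five
benchmark formulas, revision clocks between 6 and 60 months or none — but
make no attempt at realistic price levels or country economics.  The
generator is the only source of randomness in the whole package; the
simulation itself is deterministic.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .config import (
    AdjustmentPolicy,
    BenchmarkRule,
    CountryEPRConfig,
    RuleVariant,
    SimulationConfig,
    validate_config,
)
from .engine import PriceTrajectory

__all__ = ["SystemRecipe", "generate_system", "synthetic_codes", "fixture_cascade"]

DEFAULT_RULE_MIX: dict[str, float] = {
    "average": 0.35,
    "minimum": 0.30,
    "average_of_m_lowest": 0.15,
    "kth_lowest": 0.15,
    "kth_lowest_capped": 0.05,
}

DEFAULT_REVISION_MIX: dict[int | None, float] = {
    None: 0.2, 6: 0.2, 12: 0.2, 24: 0.2, 36: 0.1, 60: 0.1,
}


def synthetic_codes(n: int) -> tuple[str, ...]:
    """Two-letter synthetic country codes: AA, AB, AC, ..."""
    pairs = itertools.product(string.ascii_uppercase, repeat=2)
    return tuple("".join(p) for _, p in zip(range(n), pairs))


@dataclass(frozen=True)
class SystemRecipe:
    """Parameters of one random system draw.

    ``min_required_policy`` maps a basket size to the availability gate;
    the default requires a single reference price, matching the most common
    2015 legislation.  ``partial_pool_fraction`` is the share of countries
    that evaluate only the first k available pool members (the
    Croatia/Cyprus alternates construction).  Identical recipes produce
    identical systems.
    """

    seed: int
    n_countries: int = 10
    basket_size_range: tuple[int, int] = (2, 6)
    rule_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RULE_MIX)
    )
    revision_mix: Mapping[int | None, float] = field(
        default_factory=lambda: dict(DEFAULT_REVISION_MIX)
    )
    min_required_policy: Callable[[int], int] = lambda size: 1
    kickoff_fraction: float = 0.2
    partial_pool_fraction: float = 0.1
    horizon_months: int = 60
    adjustments: AdjustmentPolicy | None = None


def generate_system(recipe: SystemRecipe) -> SimulationConfig:
    """Draw one random EPR system; a deterministic function of the recipe."""
    lo, hi = recipe.basket_size_range
    if not (1 <= lo <= hi <= recipe.n_countries - 1):
        raise ValueError(
            f"infeasible basket_size_range {recipe.basket_size_range} for "
            f"{recipe.n_countries} countries"
        )
    if recipe.n_countries < 2:
        raise ValueError("need at least 2 countries")

    rng = np.random.default_rng(recipe.seed)
    codes = synthetic_codes(recipe.n_countries)

    n_kickoff = max(1, round(recipe.kickoff_fraction * recipe.n_countries))
    kickoff = tuple(str(c) for c in rng.choice(codes, size=n_kickoff, replace=False))
    kickoff_prices = {
        code: float(rng.uniform(50.0, 150.0)) for code in sorted(kickoff)
    }

    rule_names = sorted(recipe.rule_mix)
    rule_w = np.array([recipe.rule_mix[r] for r in rule_names], dtype=float)
    rule_w /= rule_w.sum()
    rev_choices = sorted(recipe.revision_mix, key=lambda x: (x is None, x))
    rev_w = np.array([recipe.revision_mix[r] for r in rev_choices], dtype=float)
    rev_w /= rev_w.sum()

    countries = []
    for code in codes:
        others = [c for c in codes if c != code]
        size = int(rng.integers(lo, hi + 1))
        pool = tuple(str(c) for c in rng.choice(others, size=size, replace=False))
        active = size
        if size > 1 and rng.random() < recipe.partial_pool_fraction:
            active = int(rng.integers(1, size))
        rule = _draw_rule(
            rng, str(rng.choice(rule_names, p=rule_w)), pool, active
        )
        min_req = min(max(1, recipe.min_required_policy(size)), active)
        revision = rev_choices[int(rng.choice(len(rev_choices), p=rev_w))]
        countries.append(
            CountryEPRConfig(
                code=code,
                reference_pool=pool,
                active_count=active,
                min_required=min_req,
                rule=rule,
                revision_interval_months=revision,
            )
        )

    config = SimulationConfig(
        countries=tuple(countries),
        kickoff_prices=kickoff_prices,
        exogenous_prices={},
        adjustments=recipe.adjustments or AdjustmentPolicy(),
        horizon_months=recipe.horizon_months,
        universe=codes,
    )
    violations = validate_config(config)
    if violations:  # pragma: no cover - generator contract
        raise AssertionError(
            "generator produced an invalid system:\n  " + "\n  ".join(violations)
        )
    return config


def _draw_rule(
    rng: np.random.Generator,
    name: str,
    pool: tuple[str, ...],
    active: int,
) -> BenchmarkRule:
    if name == "average":
        return BenchmarkRule(RuleVariant.AVERAGE)
    if name == "minimum":
        return BenchmarkRule(RuleVariant.MINIMUM)
    if name == "average_of_m_lowest":
        return BenchmarkRule(
            RuleVariant.AVERAGE_OF_M_LOWEST, m=int(rng.integers(1, max(2, active) + 1))
        )
    k = int(rng.integers(1, max(2, active) + 1))
    if name == "kth_lowest":
        return BenchmarkRule(RuleVariant.KTH_LOWEST, k=k)
    n_caps = int(rng.integers(1, min(2, len(pool)) + 1))
    caps = tuple(str(c) for c in rng.choice(pool, size=n_caps, replace=False))
    return BenchmarkRule(RuleVariant.KTH_LOWEST_CAPPED, k=k, caps=caps)


def fixture_cascade(horizon_months: int = 6) -> tuple[SimulationConfig, PriceTrajectory]:
    """The hand-traceable 3-country chain and its expected trajectory.

    AA launches at 100.  BB references {AA} (minimum, one price required) and
    therefore prices at month 1 at 100.  CC references {AA, BB} (average,
    both required) and prices at month 2 at 100.  Nobody revises, so all
    rows are constant once set.
    """
    config = SimulationConfig(
        countries=(
            CountryEPRConfig(
                code="BB",
                reference_pool=("AA",),
                min_required=1,
                rule=BenchmarkRule(RuleVariant.MINIMUM),
            ),
            CountryEPRConfig(
                code="CC",
                reference_pool=("AA", "BB"),
                min_required=2,
                rule=BenchmarkRule(RuleVariant.AVERAGE),
            ),
            CountryEPRConfig(
                code="AA",
                reference_pool=("BB", "CC"),
                min_required=1,
                rule=BenchmarkRule(RuleVariant.AVERAGE),
            ),
        ),
        kickoff_prices={"AA": 100.0},
        horizon_months=horizon_months,
    )
    values = np.full((3, horizon_months + 1), np.nan)
    values[0, :] = 100.0  # AA
    if horizon_months >= 1:
        values[1, 1:] = 100.0  # BB from month 1
    if horizon_months >= 2:
        values[2, 2:] = 100.0  # CC from month 2
    expected = PriceTrajectory(
        countries=("AA", "BB", "CC"),
        values=values,
        set_month={"AA": 0, **({"BB": 1} if horizon_months >= 1 else {}),
                   **({"CC": 2} if horizon_months >= 2 else {})},
    )
    return config, expected
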