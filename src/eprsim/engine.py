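"""The discrete-event core: a synchronous monthly price-propagation loop.

Month 0 is the kick-off state (launch prices plus constant exogenous
prices); every later month is computed *synchronously* from the previous
one — all benchmark evaluations read month-t prices, so no within-month
cascades occur and the result is independent of country enumeration order.

An unpriced country sets its first price as soon as the legislated minimum
number of reference prices is available; a priced country is revised on its
own clock, anchored at its first price setting (set_month + R, + 2R, ...).
A due revision with fewer than ``min_required`` available references is
skipped and retried at the next scheduled revision.  The model has no
stochastic elements: trajectories are bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .config import CountryEPRConfig, SimulationConfig
from .rules import ReferenceQuote, adjust_reference_price, compute_benchmark

__all__ = [
    "UNSET",
    "PriceState",
    "PriceTrajectory",
    "initialize_state",
    "step_month",
    "run_simulation",
]

#: Sentinel for "no price set yet" in exported matrices (NaN).
UNSET = float("nan")


@dataclass(frozen=True)
class PriceState:
    """Prices at one month; countries absent from ``prices`` are unset."""

    month: int
    prices: Mapping[str, float]
    set_month: Mapping[str, int]


@dataclass
class PriceTrajectory:
    """Country × month price matrix; NaN marks months before first setting."""

    countries: tuple[str, ...]
    values: np.ndarray  # shape (len(countries), horizon + 1)
    set_month: dict[str, int] = field(default_factory=dict)

    @property
    def horizon_months(self) -> int:
        return self.values.shape[1] - 1

    def row(self, code: str) -> np.ndarray:
        return self.values[self.countries.index(code)]

    def price(self, code: str, month: int) -> float:
        return float(self.values[self.countries.index(code), month])

    def to_frame(self, scenario: str = "") -> pd.DataFrame:
        """Long-format export: (scenario, country, month, price, is_set)."""
        n, m = self.values.shape
        df = pd.DataFrame(
            {
                "scenario": scenario,
                "country": np.repeat(self.countries, m),
                "month": np.tile(np.arange(m), n),
                "price": self.values.ravel(),
            }
        )
        df["is_set"] = ~df["price"].isna()
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PriceTrajectory":
        wide = df.pivot(index="country", columns="month", values="price")
        wide = wide.sort_index()
        traj = cls(countries=tuple(wide.index), values=wide.to_numpy(dtype=float))
        for code in traj.countries:
            row = traj.row(code)
            set_at = np.flatnonzero(~np.isnan(row))
            if set_at.size:
                traj.set_month[code] = int(set_at[0])
        return traj


def initialize_state(config: SimulationConfig) -> PriceState:
    """Month-0 state: kick-off and exogenous prices set, all others unset."""
    prices = dict(config.exogenous_prices)
    prices.update(config.kickoff_prices)
    return PriceState(
        month=0,
        prices=prices,
        set_month={code: 0 for code in prices},
    )


def _gather_quotes(
    prices: Mapping[str, float],
    country: CountryEPRConfig,
    config: SimulationConfig,
) -> list[ReferenceQuote]:
    """First ``active_count`` pool members with available prices, in pool order."""
    quotes: list[ReferenceQuote] = []
    for ref in country.reference_pool:
        raw = prices.get(ref)
        if raw is None:
            continue
        quotes.append(
            ReferenceQuote(
                source=ref,
                raw_price=raw,
                adjusted_price=adjust_reference_price(
                    raw, ref, country.code, config.adjustments
                ),
            )
        )
        if len(quotes) == country.active_count:
            break
    return quotes


def _evaluate(
    prices: Mapping[str, float],
    country: CountryEPRConfig,
    config: SimulationConfig,
) -> float | None:
    """Benchmark price for one country, or None if below min_required."""
    quotes = _gather_quotes(prices, country, config)
    if len(quotes) < country.min_required:
        return None
    cap_prices = {
        cap: adjust_reference_price(prices[cap], cap, country.code, config.adjustments)
        for cap in country.rule.caps
        if cap in prices
    }
    return compute_benchmark(country.rule, quotes, cap_prices)


def step_month(state: PriceState, config: SimulationConfig) -> PriceState:
    """Advance one month; every evaluation reads the *input* state."""
    month = state.month + 1
    new_prices = dict(state.prices)
    new_set_month = dict(state.set_month)

    for country in config.countries:
        code = country.code
        if code in config.exogenous_prices:
            continue
        if code not in state.prices:
            value = _evaluate(state.prices, country, config)
            if value is not None:
                new_prices[code] = value
                new_set_month[code] = month
        else:
            r = country.revision_interval_months
            if r is None:
                continue
            elapsed = month - state.set_month[code]
            if elapsed > 0 and elapsed % r == 0:
                value = _evaluate(state.prices, country, config)
                if value is not None:
                    new_prices[code] = value
                # insufficient references: keep the old price, retry at the
                # next scheduled revision

    return PriceState(month=month, prices=new_prices, set_month=new_set_month)


def run_simulation(config: SimulationConfig) -> PriceTrajectory:
    """Iterate the monthly loop from kick-off to the horizon.

    Returns a trajectory with ``horizon_months + 1`` columns (month 0 is the
    kick-off state).  Rows cover every universe country with a rulebook or a
    fixed price; exogenous rows are constant.
    """
    codes = tuple(
        sorted(
            {c.code for c in config.countries}
            | set(config.kickoff_prices)
            | set(config.exogenous_prices)
        )
    )
    values = np.full((len(codes), config.horizon_months + 1), UNSET)
    index = {code: i for i, code in enumerate(codes)}

    state = initialize_state(config)
    for code, price in state.prices.items():
        values[index[code], 0] = price
    for _ in range(config.horizon_months):
        state = step_month(state, config)
        for code, price in state.prices.items():
            values[index[code], state.month] = price

    return PriceTrajectory(
        countries=codes, values=values, set_month=dict(state.set_month)
    )
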