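"""Pure price arithmetic: reference-price adjustment and benchmark formulas.

Everything here is stateless and side-effect free.  Adjustments are
multiplicative and therefore order-independent; benchmark formulas operate
on the adjusted prices of the quotes they are handed.  No rounding is
applied anywhere — reporting rounds at display time only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .config import AdjustmentPolicy, BenchmarkRule, ConfigError, RuleVariant

__all__ = ["ReferenceQuote", "adjust_reference_price", "compute_benchmark"]


@dataclass(frozen=True)
class ReferenceQuote:
    """One reference country's price as seen by the referencing country."""

    source: str
    raw_price: float
    adjusted_price: float


def adjust_reference_price(
    raw_price: float,
    ref: str,
    own: str,
    policy: AdjustmentPolicy,
) -> float:
    """Apply the active adjustments to one reference price.

    The adjusted price is

        raw × (1 − statutory_rate[ref])            if statutory active and defined
            × (1 − commercial_rate)                if commercial active and ref in set
            × (ppp_index[own] / ppp_index[ref])    if PPP active

    Statutory discounts only exist for countries that publish one; a missing
    statutory rate simply means no statutory discount for that country.  A
    missing PPP index under an active PPP flag is a configuration error.
    """
    price = float(raw_price)
    if policy.statutory_active:
        rate = policy.statutory_discounts.get(ref)
        if rate is not None:
            price *= 1.0 - rate
    if policy.commercial_active and ref in policy.commercial_discount_countries:
        price *= 1.0 - policy.commercial_discount_rate
    if policy.ppp_active:
        try:
            price *= policy.ppp_index[own] / policy.ppp_index[ref]
        except KeyError as exc:
            raise ConfigError(
                f"PPP adjustment active but index missing for {exc.args[0]!r} "
                f"(quote {ref} -> {own})"
            ) from exc
    return price


def compute_benchmark(
    rule: BenchmarkRule,
    quotes: Sequence[ReferenceQuote],
    cap_prices: Mapping[str, float] | None = None,
) -> float:
    """Evaluate a benchmark formula over a non-empty set of quotes.

    Fewer available quotes than the rule's ``m`` or ``k`` degrade gracefully:
    the average-of-m-lowest uses all available quotes and the k-th lowest
    falls back to the largest available rank.  For the capped variant the
    result is additionally bounded above by each available cap price
    (unavailable caps are ignored).
    """
    if not quotes:
        raise ValueError("compute_benchmark requires at least one quote")
    prices = sorted(q.adjusted_price for q in quotes)

    if rule.variant is RuleVariant.AVERAGE:
        return sum(prices) / len(prices)
    if rule.variant is RuleVariant.MINIMUM:
        return prices[0]
    if rule.variant is RuleVariant.AVERAGE_OF_M_LOWEST:
        lowest = prices[: rule.m]
        return sum(lowest) / len(lowest)
    if rule.variant is RuleVariant.KTH_LOWEST:
        return prices[min(rule.k, len(prices)) - 1]
    if rule.variant is RuleVariant.KTH_LOWEST_CAPPED:
        value = prices[min(rule.k, len(prices)) - 1]
        if cap_prices:
            for cap in rule.caps:
                if cap in cap_prices:
                    value = min(value, cap_prices[cap])
        return value
    raise ValueError(f"unhandled rule variant {rule.variant!r}")  # pragma: no cover
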