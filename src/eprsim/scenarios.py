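"""The eight policy scenarios as declarative transforms of a base case.

Each scenario changes exactly one parameter family of the EPR methodology
for *all* simulated countries and leaves everything else country-specific:

====================================  =========================================
base_case                             no change
strategic_basket                      every basket becomes {DE, IT, FI, PT}
                                      minus the country itself
large_basket                          every basket becomes the 30 other
                                      countries of the universe
lowest_price                          every benchmark formula becomes MINIMUM
statutory_discounts                   statutory rebates (DE, GR, IE) active
statutory_and_commercial_discounts    additionally a 20% confidential rebate
                                      on six large economies
ppp                                   reference prices rescaled by relative
                                      national price levels
biannual_revisions                    every country revises every 6 months,
                                      including former no-revision countries
====================================  =========================================
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

from .config import (
    BenchmarkRule,
    ConfigError,
    CountryEPRConfig,
    RuleVariant,
    SimulationConfig,
    validate_config,
)
from .engine import PriceTrajectory, run_simulation

__all__ = [
    "ScenarioSpec",
    "STANDARD_SCENARIOS",
    "standard_scenarios",
    "apply_scenario",
    "run_all_scenarios",
]

STRATEGIC_BASKET = ("DE", "IT", "FI", "PT")


@dataclass(frozen=True)
class ScenarioSpec:
    """A named transform of the base-case configuration.

    The built-in names cover the eight standard scenarios; a user-defined
    spec supplies explicit overrides instead (basket replacement, rule
    replacement, revision interval, and/or adjustment activation).
    """

    name: str
    basket: tuple[str, ...] | None = None
    rule: BenchmarkRule | None = None
    revision_interval_months: int | None = None
    activate_statutory: bool = False
    activate_commercial: bool = False
    activate_ppp: bool = False


STANDARD_SCENARIOS: tuple[str, ...] = (
    "base_case",
    "strategic_basket",
    "large_basket",
    "lowest_price",
    "statutory_discounts",
    "statutory_and_commercial_discounts",
    "ppp",
    "biannual_revisions",
)


def standard_scenarios() -> list[ScenarioSpec]:
    """The eight standard scenario specs, base case first."""
    return [
        ScenarioSpec("base_case"),
        ScenarioSpec("strategic_basket", basket=STRATEGIC_BASKET),
        ScenarioSpec("large_basket", basket=("*",)),
        ScenarioSpec("lowest_price", rule=BenchmarkRule(RuleVariant.MINIMUM)),
        ScenarioSpec("statutory_discounts", activate_statutory=True),
        ScenarioSpec(
            "statutory_and_commercial_discounts",
            activate_statutory=True,
            activate_commercial=True,
        ),
        ScenarioSpec("ppp", activate_ppp=True),
        ScenarioSpec("biannual_revisions", revision_interval_months=6),
    ]


_BUILTIN: dict[str, Callable[[], ScenarioSpec]] = {
    s.name: (lambda s=s: s) for s in standard_scenarios()
}


def _rebasket(
    country: CountryEPRConfig, pool: tuple[str, ...]
) -> CountryEPRConfig:
    pool = tuple(c for c in pool if c != country.code)
    rule = country.rule
    if rule.variant is RuleVariant.KTH_LOWEST_CAPPED:
        # cap countries tied to the old basket drop out with it
        caps = tuple(c for c in rule.caps if c in pool)
        rule = (
            replace(rule, caps=caps)
            if caps
            else BenchmarkRule(RuleVariant.KTH_LOWEST, k=rule.k)
        )
    return replace(
        country,
        reference_pool=pool,
        active_count=len(pool),
        min_required=min(country.min_required, len(pool)),
        rule=rule,
    )


def apply_scenario(base: SimulationConfig, spec: ScenarioSpec | str) -> SimulationConfig:
    """Return a new configuration with the scenario's transform applied.

    ``base_case`` is the identity.  The input configuration is never
    mutated; the output always passes :func:`validate_config`.
    """
    if isinstance(spec, str):
        try:
            spec = _BUILTIN[spec]()
        except KeyError:
            raise ConfigError(
                f"unknown scenario {spec!r}; known: {', '.join(STANDARD_SCENARIOS)}"
            ) from None
    elif spec.name in _BUILTIN and _is_blank(spec):
        spec = _BUILTIN[spec.name]()

    countries = list(base.countries)
    adjustments = base.adjustments

    if spec.basket is not None:
        pool = (
            tuple(base.universe) if spec.basket == ("*",) else tuple(spec.basket)
        )
        countries = [_rebasket(c, pool) for c in countries]
    if spec.rule is not None:
        countries = [replace(c, rule=spec.rule) for c in countries]
    if spec.revision_interval_months is not None:
        countries = [
            replace(c, revision_interval_months=spec.revision_interval_months)
            for c in countries
        ]
    if spec.activate_statutory:
        adjustments = replace(adjustments, statutory_active=True)
    if spec.activate_commercial:
        adjustments = replace(adjustments, commercial_active=True)
    if spec.activate_ppp:
        adjustments = replace(adjustments, ppp_active=True)

    out = replace(base, countries=tuple(countries), adjustments=adjustments)
    violations = validate_config(out)
    if violations:
        raise ConfigError(
            f"scenario {spec.name!r} produced an invalid configuration:\n  "
            + "\n  ".join(violations)
        )
    return out


def _is_blank(spec: ScenarioSpec) -> bool:
    return (
        spec.basket is None
        and spec.rule is None
        and spec.revision_interval_months is None
        and not (spec.activate_statutory or spec.activate_commercial or spec.activate_ppp)
    )


def run_all_scenarios(
    base: SimulationConfig,
    specs: list[ScenarioSpec | str] | None = None,
) -> dict[str, PriceTrajectory]:
    """Run a batch of scenarios; defaults to the eight standard ones.

    Results are keyed by scenario name; duplicate names are an error.
    """
    if specs is None:
        specs = list(standard_scenarios())
    if not specs:
        raise ValueError("no scenarios supplied")
    results: dict[str, PriceTrajectory] = {}
    for spec in specs:
        name = spec if isinstance(spec, str) else spec.name
        if name in results:
            raise ConfigError(f"duplicate scenario name {name!r}")
        results[name] = run_simulation(apply_scenario(base, spec))
    return results
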