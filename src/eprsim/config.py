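"""Country EPR rulebooks and simulation configurations.

External price referencing (EPR) sets a medicine's price in one country by
benchmarking against its prices in a basket of reference countries.  This
module holds the declarative model of one country's EPR methodology
(:class:`CountryEPRConfig`), the cross-country adjustment policy
(:class:`AdjustmentPolicy`) and a complete simulation setup
(:class:`SimulationConfig`), together with YAML (de)serialisation,
validation, and the bundled 2015 European base case.

All prices are unitless fictitious euro values at ex-factory level; no
currency conversion or inflation is modelled anywhere.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ConfigError",
    "RuleVariant",
    "BenchmarkRule",
    "CountryEPRConfig",
    "AdjustmentPolicy",
    "SimulationConfig",
    "SIMULATED_COUNTRIES",
    "EXOGENOUS_COUNTRIES",
    "DEFAULT_UNIVERSE",
    "load_simulation_config",
    "write_simulation_config",
    "validate_config",
    "builtin_base_case",
]


class ConfigError(ValueError):
    """Raised on unparseable or invalid configuration input."""


#: The 28 countries that applied EPR to outpatient medicines in 2015:
#: 25 EU Member States plus the EFTA members Iceland, Norway, Switzerland.
SIMULATED_COUNTRIES: tuple[str, ...] = (
    "AT", "BE", "BG", "CH", "CY", "CZ", "DE", "EE", "ES", "FI",
    "FR", "GR", "HR", "HU", "IE", "IS", "IT", "LT", "LU", "LV",
    "MT", "NL", "NO", "PL", "PT", "RO", "SI", "SK",
)

#: Denmark, Sweden and the UK did not apply EPR (outpatient) in 2015 but are
#: referenced by others; they enter every simulation at a constant price.
EXOGENOUS_COUNTRIES: tuple[str, ...] = ("DK", "SE", "UK")

DEFAULT_UNIVERSE: tuple[str, ...] = tuple(
    sorted(SIMULATED_COUNTRIES + EXOGENOUS_COUNTRIES)
)


class RuleVariant(str, enum.Enum):
    """Benchmark-price formulas observed across 2015 EPR legislations."""

    AVERAGE = "average"
    MINIMUM = "minimum"
    AVERAGE_OF_M_LOWEST = "average_of_m_lowest"
    KTH_LOWEST = "kth_lowest"
    KTH_LOWEST_CAPPED = "kth_lowest_capped"


@dataclass(frozen=True)
class BenchmarkRule:
    """A benchmark formula plus its parameters.

    ``m`` is used by AVERAGE_OF_M_LOWEST, ``k`` by the k-th-lowest variants,
    and ``caps`` lists countries whose own price acts as an upper bound on
    the benchmark (the Latvian construction: third lowest of the basket, but
    never above the Lithuanian or Estonian price).
    """

    variant: RuleVariant
    m: int | None = None
    k: int | None = None
    caps: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d: dict = {"variant": self.variant.value}
        if self.m is not None:
            d["m"] = self.m
        if self.k is not None:
            d["k"] = self.k
        if self.caps:
            d["caps"] = list(self.caps)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "BenchmarkRule":
        try:
            variant = RuleVariant(d["variant"])
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"unknown benchmark rule: {d!r}") from exc
        return cls(
            variant=variant,
            m=d.get("m"),
            k=d.get("k"),
            caps=tuple(d.get("caps", ())),
        )


@dataclass(frozen=True)
class CountryEPRConfig:
    """One country's complete EPR rulebook.

    ``reference_pool`` is priority-ordered: countries that keep alternates
    for unavailable price data (Croatia 3-of-5, Cyprus 4-of-10) evaluate the
    first ``active_count`` pool members with available prices.  For every
    other country ``active_count`` equals the pool length.  ``min_required``
    is the legislated minimum number of reference prices needed before the
    first price can be set.
    """

    code: str
    reference_pool: tuple[str, ...]
    min_required: int
    rule: BenchmarkRule
    revision_interval_months: int | None = None
    active_count: int | None = None

    def __post_init__(self) -> None:
        if self.active_count is None:
            object.__setattr__(self, "active_count", len(self.reference_pool))

    def to_dict(self) -> dict:
        return {
            "code": self.code,
            "pool": list(self.reference_pool),
            "active_count": self.active_count,
            "min_required": self.min_required,
            "rule": self.rule.to_dict(),
            "revision_interval_months": self.revision_interval_months,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CountryEPRConfig":
        return cls(
            code=d["code"],
            reference_pool=tuple(d["pool"]),
            active_count=d.get("active_count"),
            min_required=int(d["min_required"]),
            rule=BenchmarkRule.from_dict(d["rule"]),
            revision_interval_months=d.get("revision_interval_months"),
        )


@dataclass(frozen=True)
class AdjustmentPolicy:
    """Which price adjustments apply when quoting a reference country.

    statutory_discounts
        Published manufacturer rebates, keyed by the *referenced* country
        (Germany, Greece, Ireland in 2015).  Magnitudes are configuration
        inputs; the bundled defaults are documented placeholders.
    commercial_discount_rate / commercial_discount_countries
        A uniform assumed confidential discount applied when quoting any
        country in the set.
    ppp_index
        National price-level indices; when active, reference prices are
        rescaled by index(own) / index(reference).
    """

    statutory_discounts: Mapping[str, float] = field(default_factory=dict)
    commercial_discount_rate: float = 0.0
    commercial_discount_countries: tuple[str, ...] = ()
    ppp_index: Mapping[str, float] = field(default_factory=dict)
    statutory_active: bool = False
    commercial_active: bool = False
    ppp_active: bool = False

    def to_dict(self) -> dict:
        return {
            "statutory_discounts": dict(self.statutory_discounts),
            "commercial_discount_rate": self.commercial_discount_rate,
            "commercial_discount_countries": list(self.commercial_discount_countries),
            "ppp_index": dict(self.ppp_index),
            "active": {
                "statutory": self.statutory_active,
                "commercial": self.commercial_active,
                "ppp": self.ppp_active,
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AdjustmentPolicy":
        active = d.get("active", {})
        return cls(
            statutory_discounts=dict(d.get("statutory_discounts", {})),
            commercial_discount_rate=float(d.get("commercial_discount_rate", 0.0)),
            commercial_discount_countries=tuple(
                d.get("commercial_discount_countries", ())
            ),
            ppp_index=dict(d.get("ppp_index", {})),
            statutory_active=bool(active.get("statutory", False)),
            commercial_active=bool(active.get("commercial", False)),
            ppp_active=bool(active.get("ppp", False)),
        )

    def __eq__(self, other: object) -> bool:  # dict fields need value equality
        if not isinstance(other, AdjustmentPolicy):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def __hash__(self) -> int:
        return hash(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass(frozen=True)
class SimulationConfig:
    """A complete, runnable EPR system.

    ``kickoff_prices`` are launch prices of the countries that seed the
    cascade (base case: Germany 100, Italy 70); kick-off countries are
    otherwise ordinary simulated countries with their own rulebooks.
    ``exogenous_prices`` are held constant for the whole horizon and the
    countries carrying them are never simulated (base case: DK/SE/UK at 100).
    """

    countries: tuple[CountryEPRConfig, ...]
    kickoff_prices: Mapping[str, float] = field(default_factory=dict)
    exogenous_prices: Mapping[str, float] = field(default_factory=dict)
    adjustments: AdjustmentPolicy = field(default_factory=AdjustmentPolicy)
    horizon_months: int = 120
    universe: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.universe:
            codes = sorted(
                {c.code for c in self.countries}
                | set(self.kickoff_prices)
                | set(self.exogenous_prices)
            )
            object.__setattr__(self, "universe", tuple(codes))

    @property
    def simulated_codes(self) -> tuple[str, ...]:
        return tuple(c.code for c in self.countries)

    def country(self, code: str) -> CountryEPRConfig:
        for c in self.countries:
            if c.code == code:
                return c
        raise KeyError(code)

    def to_dict(self) -> dict:
        return {
            "universe": list(self.universe),
            "horizon_months": self.horizon_months,
            "kickoff": dict(self.kickoff_prices),
            "exogenous": dict(self.exogenous_prices),
            "countries": [c.to_dict() for c in self.countries],
            "adjustments": self.adjustments.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        try:
            countries = tuple(
                CountryEPRConfig.from_dict(c) for c in d.get("countries", ())
            )
            return cls(
                countries=countries,
                kickoff_prices={k: float(v) for k, v in d.get("kickoff", {}).items()},
                exogenous_prices={
                    k: float(v) for k, v in d.get("exogenous", {}).items()
                },
                adjustments=AdjustmentPolicy.from_dict(d.get("adjustments", {})),
                horizon_months=int(d.get("horizon_months", 120)),
                universe=tuple(d.get("universe", ())),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"malformed configuration: {exc}") from exc

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimulationConfig):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def __hash__(self) -> int:
        return hash(yaml.safe_dump(self.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# validation

def validate_config(config: SimulationConfig) -> list[str]:
    """Check every structural invariant; return a list of violations.

    Validation never raises: an empty list means the configuration is valid,
    otherwise each entry names the country, the field and the rule breached.
    """
    v: list[str] = []
    universe = set(config.universe)
    seen: set[str] = set()

    if config.horizon_months < 0:
        v.append(f"horizon_months: must be >= 0, got {config.horizon_months}")

    overlap = set(config.kickoff_prices) & set(config.exogenous_prices)
    if overlap:
        v.append(f"kickoff/exogenous overlap: {sorted(overlap)}")
    for label, prices in (
        ("kickoff", config.kickoff_prices),
        ("exogenous", config.exogenous_prices),
    ):
        for code, price in prices.items():
            if code not in universe:
                v.append(f"{label} {code}: not in declared universe")
            if not price > 0:
                v.append(f"{label} {code}: price must be positive, got {price}")

    exogenous = set(config.exogenous_prices)
    for code in config.kickoff_prices:
        if code not in {c.code for c in config.countries}:
            v.append(f"kickoff {code}: has no country rulebook")

    for c in config.countries:
        if c.code in seen:
            v.append(f"{c.code}: duplicate country entry")
        seen.add(c.code)
        if c.code not in universe:
            v.append(f"{c.code}: code not in declared universe")
        if c.code in exogenous:
            v.append(f"{c.code}: exogenous country must not carry a rulebook")
        if c.code in c.reference_pool:
            v.append(f"{c.code}: self-reference in pool")
        if len(set(c.reference_pool)) != len(c.reference_pool):
            v.append(f"{c.code}: duplicate pool members")
        for ref in c.reference_pool:
            if ref not in universe:
                v.append(f"{c.code}: pool member {ref} not in universe")
        if not c.reference_pool:
            v.append(f"{c.code}: empty reference pool")
        if not (1 <= c.min_required <= (c.active_count or 0)):
            v.append(
                f"{c.code}: min_required={c.min_required} must satisfy "
                f"1 <= min_required <= active_count={c.active_count}"
            )
        if not (1 <= (c.active_count or 0) <= len(c.reference_pool)):
            v.append(
                f"{c.code}: active_count={c.active_count} must satisfy "
                f"1 <= active_count <= pool size {len(c.reference_pool)}"
            )
        if c.revision_interval_months is not None and c.revision_interval_months < 1:
            v.append(f"{c.code}: revision interval must be >= 1 month or null")
        v.extend(_validate_rule(c))

    v.extend(_validate_adjustments(config))
    return v


def _validate_rule(c: CountryEPRConfig) -> list[str]:
    v: list[str] = []
    r = c.rule
    if r.variant is RuleVariant.AVERAGE_OF_M_LOWEST and (r.m is None or r.m < 1):
        v.append(f"{c.code}: rule average_of_m_lowest needs m >= 1, got {r.m}")
    if r.variant in (RuleVariant.KTH_LOWEST, RuleVariant.KTH_LOWEST_CAPPED) and (
        r.k is None or r.k < 1
    ):
        v.append(f"{c.code}: rule {r.variant.value} needs k >= 1, got {r.k}")
    if r.variant is RuleVariant.KTH_LOWEST_CAPPED:
        if not r.caps:
            v.append(f"{c.code}: capped rule needs a non-empty cap country set")
        if c.code in r.caps:
            v.append(f"{c.code}: cap countries must not include the country itself")
    return v


def _validate_adjustments(config: SimulationConfig) -> list[str]:
    v: list[str] = []
    adj = config.adjustments
    for code, rate in adj.statutory_discounts.items():
        if not (0 <= rate < 1):
            v.append(f"adjustments: statutory rate for {code} must be in [0,1)")
    if not (0 <= adj.commercial_discount_rate < 1):
        v.append("adjustments: commercial discount rate must be in [0,1)")
    for code, idx in adj.ppp_index.items():
        if not idx > 0:
            v.append(f"adjustments: PPP index for {code} must be positive")
    if adj.ppp_active:
        involved: set[str] = set()
        for c in config.countries:
            involved.add(c.code)
            involved.update(c.reference_pool)
            involved.update(c.rule.caps)
        missing = sorted(involved - set(adj.ppp_index))
        if missing:
            v.append(f"adjustments: PPP active but index missing for {missing}")
    return v


# ---------------------------------------------------------------------------
# I/O

def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML simulation configuration.

    Raises :class:`ConfigError` on parse failure or if any invariant is
    violated; the message lists every violation found.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: YAML parse error: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    config = SimulationConfig.from_dict(raw)
    violations = validate_config(config)
    if violations:
        raise ConfigError(
            f"{path}: invalid configuration:\n  " + "\n  ".join(violations)
        )
    return config


def write_simulation_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a configuration as YAML; round-trips through :func:`load_simulation_config`."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# bundled 2015 base case

def _read_bundled(name: str) -> dict:
    ref = resources.files("eprsim.data").joinpath(name)
    try:
        text = ref.read_text()
    except (FileNotFoundError, OSError) as exc:
        raise ConfigError(
            f"bundled data file {name!r} is missing or unreadable; supply a "
            "replacement file (see builtin_base_case(membership_path=...))"
        ) from exc
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"bundled data file {name!r} is corrupt")
    return data


def builtin_base_case(
    membership_path: str | Path | None = None,
    horizon_months: int = 120,
) -> SimulationConfig:
    """The 28-country 2015 European base case.

    Scalar parameters (basket size, minimum reference-price count, benchmark
    formula, revision interval) follow each country's surveyed 2015
    legislation.  Basket *membership* is not part of the published scalar
    table: the bundled membership file is a documented reconstruction and can
    be overridden via ``membership_path`` (same YAML layout: code -> ordered
    country list).  No adjustments are active in the base case.
    """
    scalars = _read_bundled("base_case_2015.yaml")["countries"]
    if membership_path is None:
        membership = _read_bundled("basket_membership_2015.yaml")["membership"]
    else:
        membership = yaml.safe_load(Path(membership_path).read_text())["membership"]
    adj_raw = _read_bundled("default_adjustments.yaml")

    countries = []
    for code in sorted(scalars):
        row = scalars[code]
        pool = tuple(membership.get(code, ()))
        if not pool:
            raise ConfigError(
                f"no basket membership for {code}; supply a membership file"
            )
        countries.append(
            CountryEPRConfig(
                code=code,
                reference_pool=pool,
                active_count=row.get("active_count", len(pool)),
                min_required=row["min_required"],
                rule=BenchmarkRule.from_dict(row["rule"]),
                revision_interval_months=row.get("revision_interval_months"),
            )
        )

    config = SimulationConfig(
        countries=tuple(countries),
        kickoff_prices={"DE": 100.0, "IT": 70.0},
        exogenous_prices={"DK": 100.0, "SE": 100.0, "UK": 100.0},
        adjustments=AdjustmentPolicy.from_dict(adj_raw),
        horizon_months=horizon_months,
        universe=DEFAULT_UNIVERSE,
    )
    violations = validate_config(config)
    if violations:  # pragma: no cover - guards against a corrupted data file
        raise ConfigError(
            "bundled base case failed validation:\n  " + "\n  ".join(violations)
        )
    return config
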