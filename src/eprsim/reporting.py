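"""End-of-horizon comparison statistics versus the base case.

The headline output of a scenario run is the relative change of each
country's final price against the base-case run, summarised by an
unweighted mean and the five-number summary that a boxplot displays.
Sign convention: negative = cheaper than the base case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .engine import PriceTrajectory

__all__ = [
    "ScenarioComparison",
    "final_prices",
    "compare_to_base",
    "summary_table",
    "comparison_boxplot",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioComparison:
    """Relative price changes at the horizon, scenario versus base case.

    ``per_country`` holds signed fractions ((scenario − base) / base) for
    every country priced at the horizon in *both* runs; countries priced in
    only one run are listed in ``excluded``.  ``mean_change`` and
    ``quartiles`` (min, Q1, median, Q3, max; linear interpolation between
    closest ranks) are computed over exactly the ``per_country`` set,
    restricted to simulated (non-exogenous) countries.
    """

    per_country: Mapping[str, float]
    mean_change: float
    quartiles: tuple[float, float, float, float, float]
    excluded: tuple[str, ...] = ()


def final_prices(traj: PriceTrajectory) -> dict[str, float]:
    """Month-``horizon`` prices of the countries that are set by then."""
    month = traj.horizon_months
    out: dict[str, float] = {}
    for code in traj.countries:
        price = traj.price(code, month)
        if np.isnan(price):
            log.warning("country %s never priced; omitted from final prices", code)
        else:
            out[code] = price
    return out


def compare_to_base(
    scenario_traj: PriceTrajectory,
    base_traj: PriceTrajectory,
    exogenous: tuple[str, ...] = (),
) -> ScenarioComparison:
    """Relative change of final prices, scenario versus base.

    Both trajectories must cover the same country universe and horizon.
    ``exogenous`` codes are excluded from the averages (their prices are
    constant by construction).
    """
    if scenario_traj.countries != base_traj.countries:
        raise ValueError(
            "mismatched country universes: "
            f"{scenario_traj.countries} vs {base_traj.countries}"
        )
    if scenario_traj.horizon_months != base_traj.horizon_months:
        raise ValueError("mismatched horizons")

    base_final = final_prices(base_traj)
    scen_final = final_prices(scenario_traj)

    per_country: dict[str, float] = {}
    excluded: list[str] = []
    for code in scenario_traj.countries:
        if code in exogenous:
            continue
        if code in base_final and code in scen_final:
            per_country[code] = (scen_final[code] - base_final[code]) / base_final[code]
        else:
            excluded.append(code)
            log.warning("country %s unpriced in one run; excluded from comparison", code)

    changes = np.array(list(per_country.values()), dtype=float)
    if changes.size == 0:
        raise ValueError("no country priced in both runs; nothing to compare")
    quartiles = tuple(
        float(q) for q in np.percentile(changes, [0, 25, 50, 75, 100], method="linear")
    )
    return ScenarioComparison(
        per_country=per_country,
        mean_change=float(changes.mean()),
        quartiles=quartiles,  # type: ignore[arg-type]
        excluded=tuple(excluded),
    )


def summary_table(comparisons: Mapping[str, ScenarioComparison]) -> pd.DataFrame:
    """One row per (scenario, country) plus one summary row per scenario.

    Country rows carry the signed fractional change in ``change``; summary
    rows (country = ``__mean__``) add the quartiles.  Row order is
    deterministic: scenario name, then country code, summary last.  The
    frame is CSV-writable at full precision; round for display only.
    """
    if not comparisons:
        raise ValueError("no comparisons supplied")
    rows: list[dict] = []
    for name in sorted(comparisons):
        comp = comparisons[name]
        for code in sorted(comp.per_country):
            rows.append(
                {"scenario": name, "country": code, "change": comp.per_country[code]}
            )
        q = comp.quartiles
        rows.append(
            {
                "scenario": name,
                "country": "__mean__",
                "change": comp.mean_change,
                "min": q[0],
                "q1": q[1],
                "median": q[2],
                "q3": q[3],
                "max": q[4],
            }
        )
    return pd.DataFrame(rows)


def comparison_boxplot(
    comparisons: Mapping[str, ScenarioComparison],
    path: str | Path,
) -> None:
    """Boxplot of per-country changes per scenario, base case excluded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [n for n in comparisons if n != "base_case"]
    data = [
        [100 * v for v in comparisons[n].per_country.values()] for n in names
    ]
    fig, ax = plt.subplots(figsize=(9, 5))
    ax.boxplot(data, tick_labels=[n.replace("_", "\n") for n in names])
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_ylabel("price change vs base case after 10 years (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
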