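# Methods

## Model

`eprsim` simulates external price referencing (EPR) as a deterministic,
synchronous, monthly-stepped dynamical system on a network of countries.
The state at month *t* is a partial map from country to price: a country is
either *unset* (the medicine has no price there yet) or carries a positive
price. Month 0 holds only the kick-off launch prices (Germany 100, Italy
70 in the base case) and the constant exogenous prices (Denmark, Sweden,
UK at 100). Month *t + 1* is computed entirely from month *t*:

1. **Initial setting.** An unset country gathers the first `active_count`
   members of its priority-ordered reference pool that have a price. If at
   least `min_required` quotes are available, the country's first price is
   the benchmark formula applied to the adjusted quotes, and the month of
   first setting is recorded. Otherwise it stays unset and tries again next
   month.
2. **Revision.** A priced country with revision interval *R* recomputes the
   benchmark the same way whenever `(t + 1 − set_month)` is a positive
   multiple of *R*. If fewer than `min_required` references are available
   at a due revision, the revision is skipped and the old price kept until
   the *next scheduled* revision (not retried monthly). Countries with no
   legislated revision never change after first setting. Exogenous
   countries never change at all.

Because every evaluation reads only the month-*t* state, there are no
within-month cascades and the trajectory is invariant under permutation of
the country list — a property the test suite checks bit-exactly. There is
no inflation, no exchange-rate movement, no stochastic term anywhere;
repeated runs are bit-identical.

Design choices where the contract was genuinely open:

- **Revision anchoring.** Clocks are anchored at each country's own first
  price setting (`set_month + R, + 2R, …`) rather than at a global
  calendar. This keeps "prices held constant until a revision is due"
  well-defined for countries that price late in the cascade.
- **Kick-off countries** are ordinary simulated countries: they enter as
  reference sources immediately, are never re-derived at launch, and are
  revised later only if their own rulebook provides revisions (Italy every
  24 months; Germany none).
- **Skipped revisions** retry at the next scheduled revision rather than
  monthly. This is the simplest deterministic contract; with the bundled
  base case the distinction never triggers (all references exist by the
  first revision of any country).

## Benchmark formulas and adjustments

Five formulas cover the 2015 European legislations: average, minimum,
average of the *m* lowest, *k*-th lowest, and *k*-th lowest capped by named
countries' prices (Latvia: third lowest, capped by Lithuania and Estonia).
Degenerate inputs degrade gracefully and deterministically: fewer quotes
than *m* average all of them; fewer than *k* take the largest available
rank; an unavailable cap country is ignored. Ties in sorted prices are
resolved by value — only values are selected, so tie order is irrelevant.
No rounding happens anywhere in the pipeline; reporting rounds to 0.1
percentage points at display time only.

Adjustments are multiplicative and commute: statutory rebate of the quoted
country (if it publishes one), confidential discount if the quoted country
is in the commercial set, and PPP conversion `index(own) / index(ref)`,
which expresses the reference price at the referencing country's price
level (so a high-price-level country like Switzerland scales its references
*up*). Cap prices pass through the same adjustment pipeline as ordinary
quotes, which preserves positive homogeneity (scaling all launch prices by
λ scales whole trajectories by λ) and discount dominance exactly.

## Parameters

| Parameter | Default | Why |
|---|---|---|
| Horizon | 120 months | standard 10-year policy window |
| Kick-off prices | DE 100, IT 70 | first-launch market plus a widely referenced second market |
| Exogenous prices | DK/SE/UK 100 | non-EPR countries referenced at a constant list price |
| Statutory rebates | DE 7%, GR 9%, IE 5.25% | published 2015 magnitudes; placeholders, freely overridable |
| Commercial discount | 20% on DE, FR, IT, NL, ES, UK | assumed confidential rebate on large economies (the scenario's defining assumption names five economies but lists six countries; all six are included) |
| PPP indices | ≈2015 comparative price levels, EU28 = 100 | approximate public figures; replaceable in the adjustments config |

The scalar 2015 rulebook parameters (basket size, minimum count, formula,
revision interval) are bundled in `base_case_2015.yaml`. Basket
*membership* is not published; `basket_membership_2015.yaml` is a
reconstruction — hand-picked where 2015 practice is commonly reported
(France → DE/IT/ES/UK, Luxembourg → BE, Spain → Eurozone, Iceland → Nordics)
and otherwise filled from a fixed priority ordering of commonly referenced
economies. Two published basket sizes (Hungary and Poland, 31) exceed the
30 other countries of the modelled universe and are clipped to 30. Both
files are plain YAML and overridable.

## Scenarios

Each non-base scenario overrides exactly one parameter family for all
simulated countries. Two conventions needed fixing: a country never
references itself, so under the strategic basket the four basket countries
get three-member pools; and `min_required` is clipped to the new pool size
when a basket shrinks (otherwise small baskets could never price). Where a
basket replacement removes a cap country, the cap drops; if all caps drop,
the rule degrades to the plain *k*-th lowest. Bi-annual revisions apply to
every simulated country, including kick-off Germany and former no-revision
countries.

## Synthetic systems

`eprsim.synthetic.generate_system` draws random country networks — basket
sizes, rule mix, revision mix, minimum-count policy, kick-off fraction,
optional partial-pool (alternates) countries — from a single seeded
`numpy` generator; identical recipes yield identical systems, and the
generator is the only source of randomness in the package. Synthetic
systems emulate the *mechanics* of real EPR networks (availability gating,
priority pools, revision clocks) but not realistic price levels, country
economics, or launch strategy; green property tests therefore certify the
propagation arithmetic, not policy conclusions about real markets.

The standing property suite runs, over hundreds of seeded systems: formula
dominance (minimum ≤ average-of-m-lowest ≤ average), country-order
invariance, equality with an independently coded naive month-by-month
oracle, scaling equivariance, month-wise discount dominance, and — on
systems where every rule is the minimum, every country evaluates its full
pool and kick-off prices are constant — non-increasing price series. The
last restriction is necessary, not cosmetic: with partial pools
(alternates) the evaluated subset of a pool can change between revisions,
and with revised kick-off countries a launch price can be revised upward,
so monotonicity genuinely fails outside that regime.

## Comparison statistics

Scenario outcomes are summarised at month 120 as per-country relative
changes versus the base-case run, `(scenario − base) / base` (negative =
cheaper). Means and five-number summaries (linear interpolation between
closest ranks) are unweighted and taken over the 28 simulated countries
only; a country unpriced at the horizon in either run is excluded from the
averages and reported. With the bundled configuration every country prices
within the first few months, so no exclusions occur in practice.

## Known limitations

- Results at the country level are only as good as the reconstructed
  basket membership; the bundled file is an approximation and the package
  deliberately makes replacing it a one-argument operation.
- Without discounts, no price can fall below the running minimum of the
  system (the Italian launch price of 70 in the bundled setup). Mean
  reductions in the lowest-price scenario are therefore structurally
  bounded near −30% under these launch prices, whatever the membership.
  Conversely, statutory rebates compound through revision loops (a 9%
  rebate applied at every quoting of a falling reference), producing
  reductions far larger than the rebate itself — both effects are model
  consequences worth keeping in mind when comparing against external
  figures computed from other inputs.
- Volume weighting, expenditure and budget impact, launch-delay spill-over
  between countries, managed-entry agreements and real price-database
  ingestion are out of scope; prices are the sole outcome indicator.
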