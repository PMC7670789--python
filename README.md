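# eprsim

A discrete-event simulator of **external price referencing (EPR)** — the
pharmaceutical pricing policy under which a country sets or negotiates a
medicine's price by benchmarking against the price of the same medicine in a
basket of other countries. `eprsim` is written for health-policy analysts who
want to ask *what-if* questions about the design of EPR: how do the choice of
reference basket, benchmark formula, discount treatment, purchasing-power
adjustment and revision frequency shape prices once every country's rule
feeds back into every other country's rule?

## The model

Countries form a price-propagation network evolving in monthly steps over a
10-year (120-month) horizon. Each simulated country *i* carries a rulebook:

- a priority-ordered **reference pool** `B_i` (of which the first `a_i`
  members with available prices are evaluated — countries with alternates,
  such as Croatia's 3-of-5 or Cyprus' 4-of-10, have `a_i < |B_i|`),
- a **minimum availability count** `n_i`: the first price is set as soon as
  at least `n_i` reference prices exist,
- a **benchmark formula** `f_i`: the average, the minimum, the average of
  the *m* lowest, or the *k*-th lowest of the evaluated reference prices
  (optionally capped by named countries' prices, as in Latvia's
  "third-lowest, but not above Lithuania or Estonia"),
- a **revision interval** `R_i` in months, or none: a priced country
  recomputes its benchmark at `t_i + R_i, t_i + 2R_i, …` where `t_i` is the
  month of its first price setting.

When country *i* quotes country *j*'s price `p_j`, the quote may be
adjusted multiplicatively:

```
q_ij = p_j · (1 − s_j) · (1 − c·1[j ∈ C]) · (PPP_i / PPP_j)
```

with statutory rebates `s_j` (published for Germany, Greece, Ireland in
2015), an assumed confidential discount `c` on a set `C` of large economies,
and national price-level indices `PPP`. All updates within a month are
synchronous (they read only the previous month's state), so the simulation
is fully deterministic and independent of country ordering.

The cascade is seeded by two kick-off launch prices (Germany 100, Italy 70);
Denmark, Sweden and the UK do not apply EPR and are referenced at a constant
exogenous price of 100.

The bundled base case encodes the surveyed 2015 EPR legislation of 28
European countries (25 EU Member States plus Iceland, Norway and
Switzerland). Published sources give each country's basket *size*, minimum
count, formula and revision interval; basket *membership* is not published,
so `eprsim` ships a clearly marked reconstructed membership file
(`src/eprsim/data/basket_membership_2015.yaml`) that you can replace via
`builtin_base_case(membership_path=...)`. Eight standard scenarios change
one parameter family at a time for all countries: a strategic 4-country
basket (DE/IT/FI/PT), a 30-country basket, lowest-price benchmarking,
statutory discounts, statutory + 20% commercial discounts, PPP adjustment,
and bi-annual revisions.

## Worked example

```python
import eprsim

base = eprsim.builtin_base_case()            # 2015 rulebooks, 120 months
results = eprsim.run_all_scenarios(base)     # 8 deterministic trajectories
comps = {
    name: eprsim.compare_to_base(traj, results["base_case"],
                                 exogenous=("DK", "SE", "UK"))
    for name, traj in results.items() if name != "base_case"
}
for name, c in sorted(comps.items(), key=lambda kv: kv[1].mean_change):
    print(f"{name:38s} {100 * c.mean_change:+6.1f}%")
```

prints the mean price change across the 28 simulated countries after 10
years, relative to continuing each country's existing methodology:

```
statutory_and_commercial_discounts      -54.4%
statutory_discounts                     -29.8%
ppp                                     -15.5%
lowest_price                            -12.3%
large_basket                             -6.2%
biannual_revisions                       -5.8%
strategic_basket                        +13.2%
```

Negative means cheaper than the base case. Considering discounted rather
than list prices dominates every other design lever, because each discount
is re-applied every time a discounted country is quoted inside a revision
loop and therefore compounds over the horizon. Lowest-price benchmarking
is bounded here by the Italian launch price of 70, the lowest price in the
system: without discounts no benchmark can fall below it. Note that the
base case itself depends on the reconstructed basket membership — swap in
your own membership file to study its influence. Per-country detail:

```python
traj = results["base_case"]
eprsim.final_prices(traj)["AT"]   # 89.1 — Austria's month-120 price
traj.set_month["AT"]              # 2 — Austria prices once 14 references exist
```

A CLI wraps the same functions: `eprsim batch --out-dir out --plot` writes
`trajectories.csv` (long format), `summary.csv` and a boxplot; see
`eprsim --help` for `run`, `compare`, `synth` and `validate`.

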