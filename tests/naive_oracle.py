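"""A deliberately naive re-implementation of the monthly loop.

Used as an independent oracle in the engine tests: it recomputes every
country's due events from scratch each month with plain dicts and the
statistics module, sharing no code with the engine beyond the configuration
dataclasses.  Returns a list of {country: price} dicts, one per month.
"""

from statistics import mean


def naive_adjust(price, ref, own, adj):
    if adj.statutory_active and ref in adj.statutory_discounts:
        price = price * (1 - adj.statutory_discounts[ref])
    if adj.commercial_active and ref in adj.commercial_discount_countries:
        price = price * (1 - adj.commercial_discount_rate)
    if adj.ppp_active:
        price = price * adj.ppp_index[own] / adj.ppp_index[ref]
    return price


def naive_benchmark(rule, adjusted, caps):
    s = sorted(adjusted)
    v = rule.variant.value
    if v == "average":
        return mean(s)
    if v == "minimum":
        return s[0]
    if v == "average_of_m_lowest":
        return mean(s[: rule.m])
    if v == "kth_lowest":
        return s[rule.k - 1] if rule.k <= len(s) else s[-1]
    if v == "kth_lowest_capped":
        value = s[rule.k - 1] if rule.k <= len(s) else s[-1]
        for c in caps.values():
            if c < value:
                value = c
        return value
    raise AssertionError(v)


def naive_run(config):
    prices = dict(config.exogenous_prices)
    prices.update(config.kickoff_prices)
    set_at = {c: 0 for c in prices}
    history = [dict(prices)]
    for month in range(1, config.horizon_months + 1):
        prev = history[-1]
        cur = dict(prev)
        for c in config.countries:
            if c.code in config.exogenous_prices:
                continue
            if c.code not in prev:
                due = "initial"
            elif (
                c.revision_interval_months is not None
                and month > set_at[c.code]
                and (month - set_at[c.code]) % c.revision_interval_months == 0
            ):
                due = "revision"
            else:
                continue
            avail = [(r, prev[r]) for r in c.reference_pool if r in prev]
            avail = avail[: c.active_count]
            if len(avail) < c.min_required:
                continue
            adjusted = [
                naive_adjust(p, r, c.code, config.adjustments) for r, p in avail
            ]
            caps = {
                cap: naive_adjust(prev[cap], cap, c.code, config.adjustments)
                for cap in c.rule.caps
                if cap in prev
            }
            cur[c.code] = naive_benchmark(c.rule, adjusted, caps)
            if due == "initial":
                set_at[c.code] = month
        history.append(cur)
    return history
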