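# Default adjustment parameters; all flags inactive in the base case.
# Statutory discount magnitudes are documented placeholders (2015 published
# rebates: German AMNOG manufacturer rebate 7%, Greek payer rebate 9%,
# Irish framework-agreement rebate 5.25%); treat them as free parameters.
# The commercial discount is the assumed 20% confidential rebate applied to
# the six listed large economies.  ppp_index holds approximate 2015
# comparative price-level indices (EU28 = 100).
active:
  commercial: false
  ppp: false
  statutory: false
commercial_discount_countries:
- DE
- FR
- IT
- NL
- ES
- UK
commercial_discount_rate: 0.2
ppp_index:
  AT: 107.0
  BE: 109.0
  BG: 48.0
  CH: 162.0
  CY: 89.0
  CZ: 64.0
  DE: 104.0
  DK: 134.0
  EE: 75.0
  ES: 92.0
  FI: 123.0
  FR: 108.0
  GR: 84.0
  HR: 66.0
  HU: 59.0
  IE: 122.0
  IS: 119.0
  IT: 100.0
  LT: 63.0
  LU: 122.0
  LV: 71.0
  MT: 81.0
  NL: 112.0
  'NO': 141.0
  PL: 55.0
  PT: 81.0
  RO: 52.0
  SE: 125.0
  SI: 83.0
  SK: 68.0
  UK: 121.0
statutory_discounts:
  DE: 0.07
  GR: 0.09
  IE: 0.0525
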