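# Scalar EPR parameters of the 28 EPR-applying European countries, 2015:
# basket size, legislated minimum number of reference prices, benchmark
# formula, and revision interval in months (null = no revision provided for).
# Croatia evaluates 3 of a pool of 5 and Cyprus 4 of a pool of 10
# (active_count), falling back to alternates when data are unavailable.
# Latvia takes the third-lowest basket price capped by the Lithuanian and
# Estonian prices.  pool_size is the published basket size; Hungary's and
# Poland's published 31 exceeds the 30 other countries of the modelled
# universe and is clipped to 30 in the membership file.
countries:
  AT:
    min_required: 14
    pool_size: 26
    revision_interval_months: null
    rule:
      variant: average
  BE:
    min_required: 1
    pool_size: 27
    revision_interval_months: null
    rule:
      variant: average
  BG:
    min_required: 1
    pool_size: 17
    revision_interval_months: 6
    rule:
      variant: minimum
  CH:
    min_required: 1
    pool_size: 6
    revision_interval_months: 36
    rule:
      variant: average
  CY:
    active_count: 4
    min_required: 1
    pool_size: 10
    revision_interval_months: 12
    rule:
      variant: average
  CZ:
    min_required: 3
    pool_size: 19
    revision_interval_months: 36
    rule:
      m: 3
      variant: average_of_m_lowest
  DE:
    min_required: 1
    pool_size: 15
    revision_interval_months: null
    rule:
      variant: average
  EE:
    min_required: 1
    pool_size: 3
    revision_interval_months: 12
    rule:
      variant: minimum
  ES:
    min_required: 1
    pool_size: 18
    revision_interval_months: 12
    rule:
      variant: minimum
  FI:
    min_required: 1
    pool_size: 29
    revision_interval_months: 60
    rule:
      variant: average
  FR:
    min_required: 1
    pool_size: 4
    revision_interval_months: 60
    rule:
      variant: average
  GR:
    min_required: 3
    pool_size: 26
    revision_interval_months: 3
    rule:
      m: 3
      variant: average_of_m_lowest
  HR:
    active_count: 3
    min_required: 2
    pool_size: 5
    revision_interval_months: 12
    rule:
      variant: average
  HU:
    min_required: 3
    pool_size: 31
    revision_interval_months: null
    rule:
      variant: minimum
  IE:
    min_required: 1
    pool_size: 9
    revision_interval_months: 36
    rule:
      variant: average
  IS:
    min_required: 3
    pool_size: 4
    revision_interval_months: 24
    rule:
      variant: average
  IT:
    min_required: 1
    pool_size: 25
    revision_interval_months: 24
    rule:
      variant: minimum
  LT:
    min_required: 1
    pool_size: 8
    revision_interval_months: 12
    rule:
      variant: average
  LU:
    min_required: 1
    pool_size: 1
    revision_interval_months: 12
    rule:
      variant: minimum
  LV:
    min_required: 1
    pool_size: 7
    revision_interval_months: 24
    rule:
      caps:
      - LT
      - EE
      k: 3
      variant: kth_lowest_capped
  MT:
    min_required: 3
    pool_size: 12
    revision_interval_months: 18
    rule:
      variant: average
  NL:
    min_required: 2
    pool_size: 4
    revision_interval_months: 6
    rule:
      variant: average
  'NO':
    min_required: 1
    pool_size: 9
    revision_interval_months: 12
    rule:
      m: 3
      variant: average_of_m_lowest
  PL:
    min_required: 1
    pool_size: 31
    revision_interval_months: 24
    rule:
      variant: average
  PT:
    min_required: 1
    pool_size: 3
    revision_interval_months: 12
    rule:
      variant: average
  RO:
    min_required: 1
    pool_size: 12
    revision_interval_months: 60
    rule:
      variant: minimum
  SI:
    min_required: 1
    pool_size: 3
    revision_interval_months: 6
    rule:
      variant: minimum
  SK:
    min_required: 1
    pool_size: 27
    revision_interval_months: 6
    rule:
      m: 3
      variant: average_of_m_lowest
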