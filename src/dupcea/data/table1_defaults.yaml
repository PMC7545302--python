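# Base-case model inputs for the recurrent Dupuytren contracture treatment
# microsimulation. Every entry with {base, low, high, distribution} is a
# sampled parameter in probabilistic sensitivity analysis; low/high are the
# deterministic sensitivity-analysis bounds. Complication rates are stored
# as probabilities (not percent). Costs are 2018-19 USD.

demographics:
  age: {base: 60, low: 45, high: 75, distribution: uniform}

mortality:
  # Age-dependent annual all-cause mortality (US), Gompertz anchored at two
  # ages: 0.87%/yr at 60 and 0.18%/yr at 45. Death certain at max_age.
  kind: gompertz
  anchor_age: 60
  rate_at_anchor: 0.0087
  low_anchor_age: 45
  rate_at_low_anchor: 0.0018
  max_age: 100

transitions:
  success:
    CCH:
      MCP:
        low:  {base: 0.61, low: 0.52, high: 0.71, distribution: beta}
        high: {base: 0.39, low: 0.33, high: 0.45, distribution: beta}
      PIP:
        low:  {base: 0.33, low: 0.28, high: 0.38, distribution: beta}
        high: {base: 0.13, low: 0.11, high: 0.15, distribution: beta}
    PNA:
      MCP:
        low:  {base: 0.58, low: 0.49, high: 0.67, distribution: beta}
        high: {base: 0.33, low: 0.28, high: 0.38, distribution: beta}
      PIP:
        low:  {base: 0.37, low: 0.31, high: 0.43, distribution: beta}
        high: {base: 0.21, low: 0.18, high: 0.24, distribution: beta}
    LF:
      MCP:
        low:  {base: 0.71, low: 0.60, high: 0.82, distribution: beta}
        high: {base: 0.61, low: 0.52, high: 0.70, distribution: beta}
      PIP:
        low:  {base: 0.59, low: 0.50, high: 0.68, distribution: beta}
        high: {base: 0.25, low: 0.21, high: 0.29, distribution: beta}
  recurrence:
    CCH:
      MCP:
        low:  {base: 0.25, low: 0.21, high: 0.29, distribution: beta}
        high: {base: 0.25, low: 0.21, high: 0.29, distribution: beta}
      PIP:
        low:  {base: 0.48, low: 0.41, high: 0.55, distribution: beta}
        high: {base: 0.48, low: 0.41, high: 0.55, distribution: beta}
    PNA:
      MCP:
        low:  {base: 0.26, low: 0.22, high: 0.30, distribution: beta}
        high: {base: 0.26, low: 0.22, high: 0.30, distribution: beta}
      PIP:
        low:  {base: 0.40, low: 0.34, high: 0.46, distribution: beta}
        high: {base: 0.40, low: 0.34, high: 0.46, distribution: beta}
    LF:
      MCP:
        low:  {base: 0.18, low: 0.15, high: 0.21, distribution: beta}
        high: {base: 0.18, low: 0.15, high: 0.21, distribution: beta}
      PIP:
        low:  {base: 0.24, low: 0.20, high: 0.28, distribution: beta}
        high: {base: 0.24, low: 0.20, high: 0.28, distribution: beta}

direct_costs:
  CCH:
    clinic_visit:       {base: 172.26,  low: 146.42,  high: 198.10,  distribution: normal}
    medication:         {base: 5400.00, low: 4590.00, high: 6210.00, distribution: normal}
    manipulation_visit: {base: 209.02,  low: 177.67,  high: 240.37,  distribution: normal}
    hand_therapy:       {base: 314.62,  low: 221.64,  high: 407.60,  distribution: normal}
  PNA:
    procedure:          {base: 322.91,  low: 274.47,  high: 371.35,  distribution: normal}
    hand_therapy:       {base: 673.57,  low: 487.61,  high: 859.53,  distribution: normal}
  LF:
    procedure:          {base: 1149.29, low: 976.90,  high: 1321.68, distribution: normal}
    anesthesia:         {base: 245.00,  low: 208.25,  high: 281.75,  distribution: normal}
    facility_fee:       {base: 2623.34, low: 2229.84, high: 3016.84, distribution: normal}
    hand_therapy:       {base: 1394.35, low: 1115.41, high: 1859.25, distribution: normal}

complication_costs:
  tendon_injury:      {base: 3479.56, low: 2957.63, high: 4001.49, distribution: normal}
  admission:          {base: 7987.00, low: 6788.95, high: 9185.05, distribution: normal}
  medication_allergy: {base: 176.23,  low: 149.80,  high: 202.66,  distribution: normal}
  skin_tear:          {base: 75.32,   low: 64.02,   high: 86.62,   distribution: normal}
  infection:          {base: 2746.26, low: 2334.32, high: 3158.20, distribution: normal}
  crps:               {base: 2000.33, low: 1700.28, high: 2300.38, distribution: normal}
  nerve_injury:       {base: 5435.18, low: 4619.90, high: 6250.46, distribution: normal}
  artery_injury:      {base: 3581.64, low: 3044.39, high: 4118.89, distribution: normal}
  hematoma:           {base: 1658.78, low: 1409.96, high: 1907.60, distribution: normal}

complication_rates:
  CCH:
    tendon_injury:      {base: 0.0038, low: 0.0034, high: 0.0046, distribution: beta}
    admission:          {base: 0.0156, low: 0.0133, high: 0.0179, distribution: beta}
    medication_allergy: {base: 0.0026, low: 0.0022, high: 0.0030, distribution: beta}
    skin_tear:          {base: 0.0397, low: 0.0337, high: 0.0457, distribution: beta}
  PNA:
    tendon_injury:      {base: 0.0038, low: 0.0032, high: 0.0044, distribution: beta}
    infection:          {base: 0.0155, low: 0.0132, high: 0.0178, distribution: beta}
    crps:               {base: 0.0052, low: 0.0044, high: 0.0060, distribution: beta}
    nerve_injury:       {base: 0.0038, low: 0.0032, high: 0.0044, distribution: beta}
    artery_injury:      {base: 0.0091, low: 0.0077, high: 0.0105, distribution: beta}
  LF:
    tendon_injury:      {base: 0.0017, low: 0.0014, high: 0.0020, distribution: beta}
    admission:          {base: 0.0113, low: 0.0096, high: 0.0130, distribution: beta}
    infection:          {base: 0.0128, low: 0.0109, high: 0.0147, distribution: beta}
    nerve_injury:       {base: 0.0216, low: 0.0184, high: 0.0248, distribution: beta}
    artery_injury:      {base: 0.0095, low: 0.0081, high: 0.0109, distribution: beta}
    hematoma:           {base: 0.0128, low: 0.0109, high: 0.0147, distribution: beta}

indirect_costs:
  annual_income: 63179.0   # 2018 US median income
  # Lost wages are valued at annual_income / wage_divisor_days per day off
  # work and accrue only below retirement_age (societal perspective).
  wage_divisor_days: 365
  retirement_age: 65
  days_off_work:
    CCH: {base: 1,  low: 0,  high: 3,  distribution: normal}
    PNA: {base: 1,  low: 0,  high: 14, distribution: normal}
    LF:  {base: 37, low: 14, high: 60, distribution: normal}

utilities:
  symptom_free: 1.0
  symptomatic:
    MCP:
      low:  {base: 0.969, low: 0.824, high: 1.000, distribution: beta}
      high: {base: 0.938, low: 0.891, high: 0.985, distribution: beta}
    PIP:
      low:  {base: 0.970, low: 0.922, high: 1.000, distribution: beta}
      high: {base: 0.942, low: 0.895, high: 0.989, distribution: beta}

economics:
  discount_rate: 0.03
  willingness_to_pay: 100000.0
  perspective: societal   # societal | health_sector

simulation:
  n_patients: 10000
  # Utility credited for the year of a successful treatment: the full
  # symptom-free utility ("symptom_free") or the symptomatic utility
  # ("symptomatic"). Failure and recurrence years always accrue the
  # symptomatic utility for the entire year.
  success_year_utility: symptom_free
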