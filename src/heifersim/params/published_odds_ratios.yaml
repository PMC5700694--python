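# Published mixed-model odds ratios for conception to AI service in
# seasonal-calving dairy heifers.  Breed reference: FR (Friesian); month
# reference: April.  Age enters in units of 10 days on the raw scale
# (age_center_days 0): the large month odds ratios are offset by the
# age-by-month interaction at realistic ages (~450-540 d).
# No intercept was published; it is calibrated at run time so that the
# simulated marginal conception rate matches the study's 77.7%.
odds_ratios:
  breed:
    FRX: 1.21
    HO: 1.19
    JE: 0.85
    JEX: 1.15
    MO: 0.64
    NO: 1.79
    NR: 0.47
    Other: 0.64
  age_per_10d: 1.00
  civ_per_day: 0.93
  month:
    May: 7.70
    JuneJuly: 146.98
  age_x_month:
    May: 0.97
    JuneJuly: 0.92
random_effect_sd: 0.78
age_center_days: 0.0
intercept: null
target_conception_rate: 0.777
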