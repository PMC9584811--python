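# Bundled five-country demo anchor table.
#
# anchor_value is roughly 10% of the average monthly household income in
# local currency; gini is a fraction in [0, 1]; log_gdp_pc is the natural
# log of per-capita GDP in USD; inflation_rate is percent per year.  The
# values are plausible round numbers for demonstration, not statistics.
countries:
  - country_id: US
    currency_label: USD
    anchor_value: 500
    large_multiplier: 10
    gini: 0.41
    log_gdp_pc: 11.1
    inflation_rate: 8.0
  - country_id: JP
    currency_label: JPY
    anchor_value: 50000
    large_multiplier: 10
    gini: 0.33
    log_gdp_pc: 10.6
    inflation_rate: 2.5
  - country_id: DE
    currency_label: EUR
    anchor_value: 400
    large_multiplier: 10
    gini: 0.32
    log_gdp_pc: 10.8
    inflation_rate: 7.9
  - country_id: AR
    currency_label: ARS
    anchor_value: 25000
    large_multiplier: 10
    gini: 0.42
    log_gdp_pc: 9.2
    inflation_rate: 72.0
  - country_id: NG
    currency_label: NGN
    anchor_value: 45000
    large_multiplier: 10
    gini: 0.35
    log_gdp_pc: 7.7
    inflation_rate: 18.0
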