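{
  "description": "Published projection tables for the Japanese 2019 closed cohort aged 40-79: base-case 10-year outcomes, outcomes averted under the two substitution scenarios, and discounted healthcare-expenditure savings. Used as reference fixtures; they are model outputs, not model inputs.",
  "checksums": {
    "table2_base_case.csv": "a0a90aaff4b8977db3a6d82fa2ffb2e50fd1f0f068e3989cc1aa80595ae3cdaf",
    "table3_averted.csv": "5c921fdf709c4e74011a957ec2ad55a24795a3d8850514c52c5bc2c8b7eb3a24",
    "table4_savings.csv": "c122c47fd4a5768f88785b7bab1d9697ac44e912c367f6d03f19ea751d02f376"
  },
  "text_totals": {
    "comment": "Cohort-level summary figures as printed in the source's running text; percentages as printed.",
    "cum_cases_base": 3785678,
    "cum_deaths_base": 5070213,
    "cum_deaths_base_pct": 7.6,
    "averted_cases_s1": 49413,
    "averted_cases_s1_pct": 1.3,
    "averted_cases_s2": 129367,
    "averted_cases_s2_pct": 3.4,
    "averted_deaths_s1": 506,
    "averted_deaths_s1_pct": 0.01,
    "averted_deaths_s2": 1080,
    "averted_deaths_s2_pct": 0.02,
    "savings_s1_usd": 31300000,
    "savings_s1_pct": 0.2,
    "savings_s2_usd": 80500000,
    "savings_s2_pct": 0.5,
    "expenditure_base_usd": 15800000000
  },
  "rounding_discordances": [
    "Sum of age-band death counts (5,070,212) differs by 1 from the printed cohort total 5,070,213; the sex-subtotal rows (3,354,874 + 1,715,339) reproduce the printed total exactly.",
    "Scenario 1 averted cases: age rows sum to 49,412 vs printed cohort total 49,413 (sex subtotals 31,742 + 17,671 match the printed total).",
    "Scenario 2 averted cases: age rows sum to 129,368 vs printed cohort total 129,367 (sex subtotals match).",
    "Averted deaths Scenario 1: sex subtotals 384 + 121 = 505 vs printed cohort total 506.",
    "Averted deaths Scenario 2: sex subtotals 820 + 261 = 1,081 vs printed cohort total 1,080; female age rows sum to 260 vs female subtotal 261.",
    "Male Scenario 1 savings: age rows sum to 23,535,924 vs printed male subtotal 23,535,925."
  ],
  "aggregation_rule": "Cohort totals are recomputed from the 40-79 sex-subtotal rows, which reproduce every running-text figure except the two averted-death totals noted above."
}
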