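"""Aggregate the packaged published projection tables to cohort summaries.

The package ships stratum-level transcriptions of the published 10-year
projections (base-case outcomes, averted outcomes, savings).  Summing the
sex-subtotal rows reproduces the published cohort-level headline numbers;
this script prints them next to the arithmetic that produced them.
"""

from ricesim import load_fixtures

t = load_fixtures()
base = t.base_case[t.base_case["row_kind"] == "sex_total"].set_index("sex")
averted = t.averted[t.averted["row_kind"] == "sex_total"].set_index("sex")
sav = t.savings[t.savings["row_kind"] == "sex_total"].set_index("sex")

pop = base["population"].sum()
cases = base["t2d_incidence_n"].sum()
deaths = base["deaths_n"].sum()
print(f"population 40-79:        {pop:,}")
print(f"base-case T2D cases:     {cases:,}")
print(f"base-case deaths:        {deaths:,} ({100 * deaths / pop:.1f}%)")
print(f"base-case T2D costs:     USD {base['expenditure_usd'].sum() / 1e9:.1f} billion")
for s in ("s1", "s2"):
    a = averted[f"averted_cases_{s}_n"].sum()
    m = sav[f"savings_{s}_usd"].sum()
    print(
        f"{s}: averted cases {a:,} ({100 * a / cases:.1f}%), "
        f"savings USD {m / 1e6:.1f} million"
    )

print(
    "\nKnown +-1 rounding discordances between printed rows are listed in "
    "the fixture manifest:",
)
for note in t.manifest["rounding_discordances"]:
    print(" -", note)
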