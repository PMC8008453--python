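"""Compare the three concentration-truncation scenarios with matched seeds.

An uncapped log-normal occasionally produces concentrations far above anything
observed; capping at the observed maximum (or twice it) mostly affects the
upper intake percentiles. Matched seeds make the draws common random numbers,
so the ratio columns are stable.
"""
import mehgsim as m

datasets = m.generate_concentration_datasets(seed=42)
survey = m.generate_survey(m.default_survey_spec(seed=2021))

table = m.compare_scenarios(datasets, survey, n_iterations=100_000, seed=11)
print("intake statistics (µg/kg bw/day) by truncation scenario:")
print(table.round(4).to_string())
print("\nRatios below 1 show the cap biting; the effect grows from the median "
      "to the 99th percentile because truncation only removes the upper tail.")
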