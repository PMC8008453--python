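"""Run the headline Monte Carlo intake estimate on calibrated synthetic data.

Uses the published concentration models (capped at twice the observed group
maxima) and a synthetic survey calibrated to the published consumer
proportions, contribution shares, and mean intake; prints the intake
distribution summary and the exceedance of the tolerable daily intake.
"""
import mehgsim as m
from mehgsim.synthetic import OBSERVED_GROUP_MAXIMA

survey = m.generate_survey(m.default_survey_spec(seed=2021))
config = m.configure_from_params(
    m.published_concentration_params(),
    OBSERVED_GROUP_MAXIMA,
    survey,
    scenario=m.TruncationScenario.TWICE_MAX,
    n_iterations=100_000,
    body_weight=50.0,
    seed=11,
)
result = m.run_simulation(config)

summary = m.summarize(result)
print("daily methylmercury intake, µg/kg bw/day (twice-max cap, 100,000 iterations)")
for name, value in summary.items():
    print(f"  {name:>7s}: {value:.4f}")

tdi = m.tdi_from_twi(2.0)
print(f"\nzero-intake fraction: {m.zero_intake_fraction(result):.3f} "
      "(no fish eaten that day)")
print(f"P(intake > TDI {tdi:.3f}): {m.exceedance_probability(result, tdi):.3f}")
print("\ncontribution to mean intake by group:")
for group, share in m.group_contributions(result).items():
    print(f"  {group:28s} {share:6.1%}")
print("\nThe mean sits well below the TDI, but the upper percentiles exceed it: "
      "risk concentrates in high-consumption days of high-mercury groups.")
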