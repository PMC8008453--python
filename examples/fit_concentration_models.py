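"""Fit per-group log-normal concentration models and rank candidate families.

Generates a synthetic 210-sample concentration study (log-normal per group,
capped at the observed group maxima), fits each group by moments, and shows
why the log-normal family wins the goodness-of-fit comparison.
"""
import numpy as np
from scipy import stats

import mehgsim as m
from mehgsim.concentration import ad_statistic_cdf, ks_statistic_cdf

datasets = m.generate_concentration_datasets(seed=42)

print(f"{'group':28s} {'n':>4s} {'mean':>6s} {'sd':>6s} {'max':>5s} "
      f"{'KS(logn)':>9s} {'KS(norm)':>9s}")
for group, dataset in datasets.items():
    params = m.fit_lognormal(dataset, method="moments")
    normal_cdf = stats.norm(params.arithmetic_mean, params.arithmetic_sd).cdf
    print(
        f"{group.value:28s} {dataset.n:4d} {params.arithmetic_mean:6.3f} "
        f"{params.arithmetic_sd:6.3f} {dataset.max_observed:5.2f} "
        f"{m.ks_statistic(dataset, params):9.4f} "
        f"{ks_statistic_cdf(dataset.values, normal_cdf):9.4f}"
    )

tuna = m.fit_lognormal(datasets[m.FishGroup.TUNA_SWORDFISH])
salmon = m.fit_lognormal(datasets[m.FishGroup.SALMON_TROUT])
print(f"\nhighest/lowest group mean ratio: {tuna.arithmetic_mean / salmon.arithmetic_mean:.1f}")
print("Lower KS = better fit; the right-skewed mg/kg data generally favour the "
      "log-normal over a moment-matched normal, though a group with only a few "
      "dozen capped samples can occasionally rank otherwise by chance.")
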