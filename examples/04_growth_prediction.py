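"""Baseline predictors of GA growth: bootstrap R² and quartile stratification.

Simulates a cross-section of eyes whose 12-month growth is driven by
baseline isolated-PRD area, fits the univariable (PRD/RPE-loss ratio) and
multivariable (ratio + isolated PRD + intact macula) regressions, and
stratifies growth by isolated-PRD quartile.
"""

import numpy as np
import pandas as pd

from qoctga import multivariable_growth_model, quartile_stratify, univariable_ratio_model

rng = np.random.default_rng(1)
n = 197
table = pd.DataFrame(
    {
        "eye_id": [f"e{i}" for i in range(n)],
        "arm": "SHAM",
        "ratio_prd_rpe": 1.0 + rng.gamma(2.0, 0.4, n),
        "prd_isolated_mm2": rng.gamma(3.0, 1.8, n),
        "intact_macula_mm2": np.clip(rng.normal(14.0, 5.0, n), 0.2, None),
    }
)
table["growth_12m"] = 0.2 + 0.02 * table.prd_isolated_mm2 + rng.normal(0, 0.1, n)

uni = univariable_ratio_model(table, seed=1)
print(f"Univariable (ratio only):    bootstrap R² = {uni.r2_boot_mean:.4f} "
      f"[{uni.r2_boot_ci[0]:.4f}, {uni.r2_boot_ci[1]:.4f}], n={uni.n}")

multi = multivariable_growth_model(table, seed=1)
print(f"Multivariable:               bootstrap R² = {multi.r2_boot_mean:.4f}")
print(multi.coefficients.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

qs = quartile_stratify(table, "prd_isolated_mm2")
print()
print("Growth by baseline isolated-PRD quartile:")
print(qs.table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"Spearman(quartile, mean growth) = {qs.spearman_rho:.2f}")
print()
print(
    "The planted isolated-PRD coefficient (0.02 mm growth per mm²) is"
    " recovered with its bootstrap interval; the highest quartile shows"
    " the greatest mean growth."
)
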