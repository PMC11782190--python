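"""Estimate frailty-indicator odds ratios for each cluster versus NOR.

Two routes to the same estimand are shown. First, the closed-form 2x2 odds
ratio from published-style count summaries (49/213 slow-gait cases in the
persistent-rise cluster vs 33/254 in the reference group). Second, logistic
regression on a simulated cohort whose per-group indicator prevalences encode
the same associations, demonstrating recovery of the generating odds ratio.
"""

from orthomorph import SimConfig, association_table, odds_ratio_2x2, simulate_cohort

res = odds_ratio_2x2(49, 213, 33, 254, indicator="slow_gait", cluster="OHYPER")
print("From counts: slow gait, persistent-rise cluster vs reference")
print(f"  OR {res.or_hat:.2f}  (95% CI {res.ci_low:.2f}-{res.ci_high:.2f})  "
      f"Wald p = {res.wald_p:.3f}")

_, participants = simulate_cohort(SimConfig(n=4000, seed=11),
                                  with_recordings=False)
table = association_table(
    participants["true_group"],
    participants[["slow_gait", "recent_fall"]],
    covariates=participants[["age", "female"]],
    models=("unadjusted", "age_sex"),
)
print("\nFrom a simulated cohort (n = 4000), vs the NOR reference group:")
for _, row in table.iterrows():
    print(f"  {row['indicator']:12s} {row['cluster']:7s} {row['model']:10s} "
          f"OR {row['or_hat']:.2f} ({row['ci_low']:.2f}-{row['ci_high']:.2f}) "
          f"p={row['wald_p']:.3f}")
print("\nOdds ratios near the generating values (slow gait ~2.0 for the rise")
print("cluster, recent fall <1 for the deficit clusters) indicate recovery.")
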