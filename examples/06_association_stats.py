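"""Penetrance GLM with max-|t| permutation FWER correction.

Simulates a 19-feature family in which only one feature carries a
penetrance effect, corrects across the family with Freedman-Lane
max-|t| permutations, contrasts the continuous model with the binary
carrier model, and prints the leave-one-CNV-out sensitivity of the hit.
"""

from cnvtract import (SimulationDesign, binary_model, build_cohort,
                      loo_cnv_sensitivity, permutation_correct,
                      score_correlation, simulate_feature_table)

cohort = build_cohort(SimulationDesign(seed=0))
Y = simulate_feature_table(cohort, 19, effect_slope=0.0, seed=1)
Y["feat1"] = simulate_feature_table(cohort, 1, effect_slope=0.06,
                                    seed=2)["feat1"]

res = permutation_correct(Y, cohort, "P_DD", B=2000, seed=0,
                          diffusion_derived=True, family_id="demo")
hits = [r for r in res if r.p_corr <= 0.05]
print("feature   beta      t        p        p_corr")
for r in sorted(res, key=lambda r: r.p)[:4]:
    print(f"{r.feature:8s} {r.beta:+.4f} {r.t:+7.2f} {r.p:9.2e} {r.p_corr:.4f}")
print(f"\nfamily-wise significant: {[r.feature for r in hits]}")

t_bin = {r.feature: r.t for r in binary_model(Y, cohort,
                                              diffusion_derived=True)}
print(f"feat1 |t|: penetrance {abs(res[0].t):.2f} vs binary "
      f"{abs(t_bin['feat1']):.2f}")

loo = loo_cnv_sensitivity(Y["feat1"], cohort, "P_DD",
                          diffusion_derived=True)
print("\nlargest leave-one-CNV-out shifts (delta t):")
print(loo["delta_t"].abs().sort_values(ascending=False).head(3).to_string())

corr = score_correlation(cohort)
print(f"\nSpearman rho(P_Sz, P_DD) = {corr.rho:.2f} (p = {corr.p:.1e}, "
      f"n = {corr.n})")
print()
print("Only the feature with a real dose effect survives the family-wise")
print("correction; the binary carrier contrast is weaker than the")
print("continuous penetrance model, and the LOO table shows which CNV")
print("class contributes most to the pooled association.")
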