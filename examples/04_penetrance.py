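"""CNV penetrance: Bayes-rate computation and the bundled lookup table.

Penetrance is the probability that a carrier of a CNV manifests a
phenotype: P(disease | CNV) = P(CNV | disease) x prevalence / P(CNV).
"""

from cnvtract import compute_penetrance, load_penetrance_table

# a CNV seen in 0.2 % of schizophrenia cases and 0.01 % of the general
# population, with ~1 % lifetime prevalence of the disorder:
p = compute_penetrance(freq_in_cases=0.002, freq_in_population=0.0001,
                       prevalence=0.01)
print(f"worked example: 100 * 0.002 * 0.01 / 0.0001 = {p:.1f} % penetrance")

table = load_penetrance_table()
print("\nper-CNV scores (percent):")
for label in ("22q11.2 deletion", "3q29 deletion", "17q12 duplication",
              "15q11.2 BP1-2 deletion"):
    sz, dd = table.lookup(label)
    print(f"  {label:28s} Sz {sz:5.1f}  DD {dd:5.1f}")

sz, dd = table.carrier_summary()
print(f"\ncarrier-weighted cohort means: Sz {sz:.1f} %, DD {dd:.1f} %")
print()
print("The weighted means over the 21 carriers are the summary row of the")
print("study cohort; the per-carrier scores are the continuous dose")
print("regressor every imaging variable is tested against.")
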