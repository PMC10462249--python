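"""Sham-vs-rTBI group comparisons on a simulated cohort.

Generates one 20-mouse, 44-variable feature table at the study's
group effects and missingness pattern, then prints the comparison rows
for the enzyme-activity variables (mean +- SD per group, fold change
with direction, unpaired t-test p-value).
"""

from rtbimr import CohortSpec, generate_feature_table, summarize_study

table = generate_feature_table(CohortSpec(seed=0))
summary = summarize_study(table)

cols = ["n_sham", "n_rtbi", "mean_sham", "sd_sham", "mean_rtbi", "sd_rtbi",
        "fold_change", "direction", "p"]
enzymes = [v for v in summary.index if v.startswith(("PDH", "LDH"))]
print(summary.loc[enzymes, cols].round(4).to_string())
print()
print("With the configured effects, PDH in prefrontal cortex and cortex")
print("trends lower in rTBI (generating folds 1.57 and 1.67); most other")
print("regions carry no real group difference, so their p-values are flat.")
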