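"""Check that established risk markers keep their effects in synthetic data.

For each marker of the favorable / intermediate / adverse risk panel (plus
age), a univariable logistic OR for CR and Cox HRs for EFS and OS are fit
per cohort; every effect pair is classified by direction and significance.
An 'inverse' cell — a marker flipping from favorable to adverse — would
disqualify the synthetic cohort for explorative analysis.
"""

from synthaml import (concordance_matrix, default_config, fit_generator,
                      sample_synthetic, simulate_cohort, split_train_test,
                      univariable_panel)

cohort, _ = simulate_cohort(default_config(seed=1, n=1606))
train, _ = split_train_test(cohort, 0.8, seed=2)
syn = sample_synthetic(fit_generator(train, seed=3), 1606, seed=4)

panel_real = univariable_panel(cohort)
panel_syn = univariable_panel(syn)
summary = concordance_matrix(panel_real, panel_syn)

print("concordance classes over", len(summary.cells), "marker-endpoint pairs:")
for cls, cnt in sorted(summary.counts.items()):
    print(f"  {cls}: {cnt}")
print(f"inverse effects: {summary.inverse_count}")

tp53 = panel_real[(panel_real.marker == "TP53") & (panel_real.endpoint == "OS")].iloc[0]
tp53_s = panel_syn[(panel_syn.marker == "TP53") & (panel_syn.endpoint == "OS")].iloc[0]
cell = summary.cells[(summary.cells.marker == "TP53")
                     & (summary.cells.endpoint == "OS")].iloc[0]
print(f"example, TP53 on OS: HR {tp53['estimate']:.2f} (original) vs "
      f"{tp53_s['estimate']:.2f} (synthetic) -> class {cell['class']}")
print("Zero inverse cells means no marker's clinical meaning flipped in "
      "the synthetic cohort.")
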