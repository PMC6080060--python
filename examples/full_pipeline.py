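"""End-to-end comparison on a synthetic COPD cohort: predict FEV1 under all
three equation sets, stage each patient, cross-tabulate the stagings and
report agreement and concordance.

Run:  python examples/full_pipeline.py
"""

from spiroref import CopdSpec, RunConfig, generate_copd, run_comparison

cohort = generate_copd(CopdSpec(n=500, seed=11))
bundle = run_comparison(
    RunConfig(cohort=cohort, sources=("local", "ecsc", "gli"), output_dir="scratch/run")
)

print(f"Cohort: {bundle.header['n_subjects']} synthetic COPD patients "
      f"(GLI lookup: {bundle.header['gli_lookup_version']})\n")

for (a, b), rep in bundle.agreement.items():
    print(f"{a} vs {b}: {rep.percent_agreement:.1f}% exact agreement, "
          f"linear kappa {rep.kappa_linear:.3f}")

print()
for (a, b, outcome), rep in bundle.concordance.items():
    if b != "measured" or outcome != "fev1":
        continue
    print(f"{a} predicted vs measured FEV1: Lin's ccc {rep.lins_ccc:.3f}, "
          f"Pearson r {rep.pearson_r:.3f}, "
          f"mean difference {rep.average_difference:+.2f} L")

print("\nCross-tabs, predictions and a JSON summary were written to "
      "scratch/run/.  High kappas across source pairs mirror the finding "
      "that the choice of reference equations barely changes GOLD staging; "
      "the positive predicted-minus-measured FEV1 differences reflect the "
      "airflow obstruction of a COPD cohort.")
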