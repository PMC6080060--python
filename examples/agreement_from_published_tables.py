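"""Recompute the agreement battery from the three packaged published
GOLD-staging cross-tabulations of the 124-patient COPD cohort.

Run:  python examples/agreement_from_published_tables.py
"""

from spiroref import STAGE_CROSSTAB_NAMES, load_stage_crosstab
from spiroref.agreement import agreement_report

for name in STAGE_CROSSTAB_NAMES:
    tab = load_stage_crosstab(name)
    rep = agreement_report(tab)
    print(f"{name}: n={rep.n}")
    print(f"  exact agreement : {rep.diagonal}/{rep.n} = {rep.percent_agreement:.1f}%")
    print(f"  kappa unweighted: {rep.kappa_unweighted:.3f}")
    print(f"  kappa linear    : {rep.kappa_linear:.3f}   <- published convention")
    print(f"  kappa quadratic : {rep.kappa_quadratic:.3f}")

print("\nLinear-weighted kappa credits near-miss disagreements (adjacent "
      "stages) and reproduces the published coefficients 0.936 / 0.895 / "
      "0.862; values above ~0.8 indicate almost-perfect agreement between "
      "staging under the different reference equations.")
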