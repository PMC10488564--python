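"""Run the full diagnostic statistics stage on a synthetic cohort.

Generates a larger phantom cohort (60 cases per class for stable cutoffs),
then for the carcinoma-vs-thymoma contrast: Youden-optimal cutoff per
feature, binarization, 2x2 Wald odds ratio, and stepwise logistic selection
over the univariately significant features.  With the default calibration
the ECV carries the class signal and should be selected.
"""

import dataclasses

from iodect import Contrast, PhantomConfig, TumorGroup, analyze_cohort, generate_cohort

config = dataclasses.replace(
    PhantomConfig(seed=11), cases_per_class={g: 60 for g in TumorGroup}
)
_, table = generate_cohort(config)
report = analyze_cohort(table, Contrast.CARCINOMA_VS_THYMOMA)

print(f"{report['n_cases']} cases, {report['n_positive']} carcinomas\n")
print(f"{'feature':>13} {'rule':>16} {'OR':>8} {'p':>7}  sig")
for name, info in report["features"].items():
    if info.get("skipped"):
        continue
    rule = f"{'>' if info['direction'] == 'greater_than' else '<='}{info['cutoff']:.2f}"
    orv = "n/a (sep)" if info["separation_flag"] else f"{info['odds_ratio']:.2f}"
    print(f"{name:>13} {rule:>16} {orv:>8} {info['p_value'] if info['p_value'] else float('nan'):7.3f}"
          f"  {'*' if info['univariate_significant'] else ''}")

print(f"\nstepwise model kept: {report['stepwise']['included']}")
for name, est in report["stepwise"]["estimates"].items():
    print(f"  {name}: OR {est['odds_ratio']:.2f} "
          f"CI ({est['ci_low']:.2f}, {est['ci_high']:.2f}) p {est['p_value']:.4f}")
if "fibrosis" in report:
    fib = report["fibrosis"]
    print(f"\nfibrosis grade: carcinoma mean {fib['mean_positive']:.2f} vs "
          f"thymoma {fib['mean_negative']:.2f} (Mann-Whitney p {fib['mann_whitney_p']:.4f})")
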