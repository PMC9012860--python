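"""Replicate the simulation study's exposure-status validation.

Runs the full pipeline for one seed: simulate, fit the SEE, draw one
random date per patient, tally the confusion matrix, compute the ten
classification metrics, the duration-error summary, and the
class-balanced re-analysis.
"""

import json

from sessa import RunConfig, run_replication

report = run_replication(RunConfig(seed=1))

m = report["confusion_matrix"]
print(f"confusion matrix at the random dates (n={report['n_patients']}):")
print(f"  TP={m['tp']}  FP={m['fp']}  FN={m['fn']}  TN={m['tn']}")
print("\nmetrics (%):")
for name, v in report["metrics"].items():
    print(f"  {name:<18} {100 * v:5.1f}")
mis = report["misclassification_days"]["pooled"]
print(f"\n|true - assigned| duration, pooled over TP/TN/FN fills: "
      f"median {mis['median']:.0f} d (IQR {mis['q1']:.0f}-{mis['q3']:.0f})")
bal = report["balanced"]["metrics"]
print(f"\nafter down-sampling the dominant exposed class: "
      f"NPV {100 * report['metrics']['npv']:.1f} -> {100 * bal['npv']:.1f} %")
print("\nMost random dates fall on truly exposed days (high prevalence), so")
print("PPV/specificity are near-perfect while NPV is diluted by false negatives")
print("from refill delays the cluster medians do not cover; balancing the")
print("classes recovers NPV.")
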