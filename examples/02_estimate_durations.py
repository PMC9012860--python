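"""Fit the Sessa Empirical Estimator on a simulated cohort.

Shows the five algorithm steps' outputs: gap pool, 80% ECDF cutoff,
silhouette table, selected K, per-cluster median durations, and a few
assigned fills with their end of supply.
"""

from sessa import (
    SeeConfig,
    SimulationConfig,
    assign_durations,
    compute_refill_gaps,
    fit_see,
    simulate_cohort,
    trim_ecdf,
)

cohort, _ = simulate_cohort(SimulationConfig(seed=1))
gaps = compute_refill_gaps(cohort)
retained, cutoff = trim_ecdf(gaps, 0.8)
print(f"{len(gaps)} refill gaps; 80% ECDF cutoff = {cutoff:.0f} days "
      f"({len(gaps) - len(retained)} long gaps discarded)")

model = fit_see(cohort, SeeConfig(seed=2))
print("\naverage silhouette width by K:")
for k, s in model.silhouette_by_k.items():
    marker = "  <- selected" if k == model.k_selected else ""
    print(f"  K={k}: {s:.3f}{marker}")
print(f"\ncluster median durations (days): {list(model.median_duration_days)}")

assigned = assign_durations(cohort, model)
print("\nfirst patient's assigned fills:")
first = assigned[assigned["patient_id"] == assigned["patient_id"].iloc[0]]
print(first[["day", "gap_days", "cluster_id", "duration_days", "end_day"]].to_string(index=False))
print("\nEach fill's duration is its gap-cluster's median; the final fill")
print("inherits the patient's previous cluster. End of supply = fill day + duration.")
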