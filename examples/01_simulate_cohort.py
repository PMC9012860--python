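"""Simulate a prescription-fill cohort with six adherence trajectories.

Builds the default synthetic cohort (1000 patients, 730-day window,
initial 30-day fill, refills of 30/60/90 days) and summarises the
realized trajectory mix and supply-based medication availability (CMA).
"""

import numpy as np

from sessa import SimulationConfig, compute_cma, simulate_cohort

cohort, groups = simulate_cohort(SimulationConfig(seed=1))

print(f"{cohort.n_patients} patients, {len(cohort.fills)} fills, "
      f"window of {cohort.window_days} days")
print()
print("trajectory group      n   median CMA")
for label, sub in groups.groupby("label", sort=False):
    pids = set(sub["patient_id"])
    cmas = [
        compute_cma(f, (0, cohort.window_days))
        for pid, f in cohort.fills.groupby("patient_id")
        if pid in pids
    ]
    print(f"{label:<18} {len(pids):>4}   {np.median(cmas):.2f}")

print()
print("CMA is the fraction of the window covered by dispensed supply at the")
print("nominal one-duration-per-fill rate; high-adherence patients sit near")
print("1.0, non-persistent patients near 0.15 (they stop after 1-2 refills).")
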