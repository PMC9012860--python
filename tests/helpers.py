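"""Shared fixture builders."""

from sessa import cohort_from_days


def make_gap_cohort(per_patient_gaps, window_days=None):
    """Cohort whose consecutive-fill gaps are exactly the given lists."""
    rows = []
    maxday = 0
    for i, gaps in enumerate(per_patient_gaps):
        day = 0
        rows.append((f"G{i:03d}", 0))
        for g in gaps:
            day += int(g)
            rows.append((f"G{i:03d}", day))
        maxday = max(maxday, day)
    return cohort_from_days(rows, window_days=window_days or maxday + 1)
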