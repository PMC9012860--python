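"""SEE core: gaps, ECDF trimming, pair sampling, clustering, assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sessa import (
    SeeConfig,
    assign_durations,
    build_exposure_timeline,
    cohort_from_days,
    compute_refill_gaps,
    fit_see,
    sample_random_pairs,
    select_k_silhouette,
    standardize,
    trim_ecdf,
)
from sessa.estimator import SeeModel

from helpers import make_gap_cohort
from oracles import select_k_oracle, trim_oracle


class TestRefillGaps:
    def test_simple_differences(self):
        c = cohort_from_days([("p", 0), ("p", 30), ("p", 90)], window_days=100)
        g = compute_refill_gaps(c)
        assert list(g["gap_days"]) == [30, 60]
        assert list(g["fill_index"]) == [0, 1]

    def test_single_fill_patient_contributes_nothing(self):
        c = cohort_from_days([("p", 5)], window_days=10)
        assert compute_refill_gaps(c).empty

    def test_patient_tags(self):
        c = cohort_from_days([("a", 0), ("a", 30), ("b", 0), ("b", 60)], window_days=100)
        g = compute_refill_gaps(c)
        assert dict(zip(g["patient_id"], g["gap_days"])) == {"a": 30, "b": 60}


class TestTrimEcdf:
    def _gaps(self, values):
        return pd.DataFrame(
            {"patient_id": [f"p{i}" for i in range(len(values))],
             "fill_index": 0, "gap_days": values}
        )

    def test_one_to_ten(self):
        retained, cutoff = trim_ecdf(self._gaps(list(range(1, 11))), 0.8)
        assert cutoff == 8
        assert sorted(retained["gap_days"]) == list(range(1, 9))

    def test_degenerate_all_equal(self):
        retained, cutoff = trim_ecdf(self._gaps([30] * 7), 0.8)
        assert cutoff == 30
        assert len(retained) == 7

    def test_stoppers_removed(self):
        retained, cutoff = trim_ecdf(self._gaps([30] * 8 + [300, 400]), 0.8)
        assert cutoff == 30
        assert sorted(retained["gap_days"]) == [30] * 8

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            trim_ecdf(self._gaps([]), 0.8)

    @given(
        st.lists(st.integers(1, 400), min_size=1, max_size=60),
        st.floats(0.05, 1.0),
    )
    def test_matches_oracle_and_is_downward_closed(self, values, retention):
        retained, cutoff = trim_ecdf(self._gaps(values), retention)
        assert cutoff == trim_oracle(values, retention)
        assert len(retained) / len(values) >= retention
        # downward-closed: everything <= cutoff retained, nothing above
        assert set(retained["gap_days"]) == {v for v in values if v <= cutoff}
        assert retained["gap_days"].tolist() == [v for v in values if v <= cutoff]


class TestSampleRandomPairs:
    def _gaps(self):
        return pd.DataFrame(
            {
                "patient_id": ["a"] * 3 + ["b"],
                "fill_index": [0, 1, 2, 0],
                "gap_days": [30, 60, 90, 45],
            }
        )

    def test_one_per_patient_uniform(self):
        counts = {30: 0, 60: 0, 90: 0}
        for seed in range(3000):
            s = sample_random_pairs(self._gaps(), seed)
            counts[int(s.set_index("patient_id").loc["a", "gap_days"])] += 1
        # binomial(3000, 1/3): 99% interval is roughly +/- 67 around 1000
        for v in counts.values():
            assert 900 < v < 1100

    def test_single_gap_patient_keeps_it(self):
        s = sample_random_pairs(self._gaps(), 0)
        assert int(s.set_index("patient_id").loc["b", "gap_days"]) == 45

    def test_patient_without_retained_gaps_absent(self):
        g = self._gaps()
        retained, cutoff = trim_ecdf(g, 0.6)
        s = sample_random_pairs(retained, 0)
        present = set(s["patient_id"])
        # "a"'s 90-day gap exceeded the cutoff but the others remain
        assert cutoff == 60
        assert present == {"a", "b"}

    def test_deterministic(self):
        a = sample_random_pairs(self._gaps(), 123)
        b = sample_random_pairs(self._gaps(), 123)
        pd.testing.assert_frame_equal(a, b)


class TestStandardize:
    def test_hand_example(self):
        z, mean, sd = standardize([10, 20, 30])
        assert mean == 20 and sd == 10
        np.testing.assert_allclose(z, [-1, 0, 1])

    def test_constant_signals_degenerate(self):
        z, _, sd = standardize([5, 5, 5])
        assert sd == 0.0

    @given(st.lists(st.integers(1, 500), min_size=2, max_size=50).filter(lambda v: len(set(v)) > 1))
    def test_mean_zero_sd_one_and_invertible(self, values):
        z, mean, sd = standardize(values)
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1) < 1e-9
        np.testing.assert_allclose(z * sd + mean, values, atol=1e-9)


class TestSelectK:
    def test_two_separated_groups(self):
        raw = np.array([28, 30, 32, 88, 90, 92], dtype=float)
        z, _, _ = standardize(raw)
        k, sil, labels, centers = select_k_silhouette(z, 2, 10, 25, 0)
        assert k == 2
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1

    def test_three_tight_groups(self):
        rng = np.random.default_rng(4)
        raw = np.concatenate([c + rng.uniform(-1, 1, 5) for c in (30, 60, 90)])
        z, _, _ = standardize(raw)
        k, *_ = select_k_silhouette(z, 2, 10, 25, 0)
        assert k == 3

    def test_matches_exhaustive_oracle_small_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(40):
            n = int(rng.integers(5, 11))
            centers = rng.uniform(0, 100, int(rng.integers(1, 4)))
            x = rng.choice(centers, n) + rng.normal(0, 4, n)
            if len(np.unique(x)) < 4:
                continue
            z, _, _ = standardize(x)
            k_impl, sil_impl, *_ = select_k_silhouette(z, 2, 10, 25, 1)
            k_orc, sil_orc = select_k_oracle(z, 2, 10)
            assert k_impl == k_orc
            for k in sil_orc:
                assert abs(sil_impl[k] - sil_orc[k]) < 1e-8


class TestFitSee:
    def test_degenerate_constant_gaps(self):
        c = make_gap_cohort([[30, 30]] * 5)
        m = fit_see(c, SeeConfig(seed=0))
        assert m.k_selected == 1
        assert m.median_duration_days == (30.0,)

    def test_two_cluster_parameter_recovery(self):
        rng = np.random.default_rng(8)
        gaps = []
        for i in range(200):
            base = 30 if i % 2 == 0 else 90
            gaps.append([int(base + rng.integers(-2, 3)) for _ in range(3)])
        m = fit_see(make_gap_cohort(gaps), SeeConfig(seed=1))
        assert m.k_selected == 2
        assert abs(m.median_duration_days[0] - 30) <= 2
        assert abs(m.median_duration_days[1] - 90) <= 2

    def test_trimming_noop_when_no_long_gaps(self):
        gaps = [[30, 30, 60]] * 6 + [[60, 60]] * 4
        m_08 = fit_see(make_gap_cohort(gaps), SeeConfig(ecdf_retention=0.8, seed=5))
        m_10 = fit_see(make_gap_cohort(gaps), SeeConfig(ecdf_retention=1.0, seed=5))
        assert m_08.median_duration_days == m_10.median_duration_days
        assert m_08.k_selected == m_10.k_selected

    def test_no_multifill_patient_errors(self):
        c = cohort_from_days([("a", 0), ("b", 5)], window_days=10)
        with pytest.raises(ValueError):
            fit_see(c)

    def test_scale_equivariance_of_medians(self):
        base = [[28, 30, 32], [30, 60], [58, 62], [60, 90], [88, 92], [30, 90]] * 4
        m1 = fit_see(make_gap_cohort(base), SeeConfig(seed=3))
        scaled = [[2 * g for g in gs] for gs in base]
        m2 = fit_see(make_gap_cohort(scaled), SeeConfig(seed=3))
        assert m2.k_selected == m1.k_selected
        np.testing.assert_allclose(
            np.array(m2.median_duration_days), 2 * np.array(m1.median_duration_days)
        )

    def test_model_invariants(self):
        cohort = make_gap_cohort([[30, 60, 90, 45]] * 30)
        m = fit_see(cohort, SeeConfig(seed=2))
        meds = m.median_duration_days
        assert all(b >= a for a, b in zip(meds, meds[1:]))
        assert all(mm <= m.retention_cutoff_days for mm in meds)
        assert m.k_selected == max(m.silhouette_by_k, key=lambda k: (m.silhouette_by_k[k], -k))


def _toy_model():
    # medians 30/90, centers on the standardized scale for mean 60, sd 30
    return SeeModel(
        retention_cutoff_days=90.0,
        standardization_mean=60.0,
        standardization_sd=30.0,
        k_selected=2,
        centers_std=(-1.0, 1.0),
        median_duration_days=(30.0, 90.0),
    )


class TestAssignDurations:
    def test_nearest_center_and_last_fill_inheritance(self):
        c = cohort_from_days([("p", 0), ("p", 31), ("p", 62)], window_days=200)
        out = assign_durations(c, _toy_model())
        assert list(out["duration_days"]) == [30.0, 30.0, 30.0]
        assert list(out["end_day"]) == [30, 61, 92]
        assert list(out["cluster_id"]) == [0, 0, 0]

    def test_gap_above_cutoff_still_assigned(self):
        c = cohort_from_days([("p", 0), ("p", 200)], window_days=300)
        out = assign_durations(c, _toy_model())
        assert out["duration_days"].iloc[0] == 90.0  # nearest (largest) cluster

    def test_single_cluster_model_assigns_everywhere(self):
        m = SeeModel(
            retention_cutoff_days=30.0,
            standardization_mean=30.0,
            standardization_sd=0.0,
            k_selected=1,
            centers_std=(0.0,),
            median_duration_days=(30.0,),
        )
        c = cohort_from_days([("p", 0), ("p", 40), ("q", 3)], window_days=100)
        out = assign_durations(c, m)
        assert (out["duration_days"] == 30.0).all()

    def test_total_every_fill_gets_duration(self, tiny_cohort):
        out = assign_durations(tiny_cohort, _toy_model())
        assert out["duration_days"].notna().all()
        assert out["end_day"].notna().all()
        # single-fill patient falls back to the median of cluster medians
        assert out.loc[out["patient_id"] == "B", "duration_days"].iloc[0] == 60.0


class TestBuildTimeline:
    def test_adjacent_merge(self):
        assigned = pd.DataFrame(
            {"patient_id": ["p", "p"], "day": [0, 20], "end_day": [30, 50]}
        )
        tl = build_exposure_timeline(assigned)["p"]
        assert tl.intervals == ((0, 50),)

    def test_disjoint_intervals(self):
        assigned = pd.DataFrame(
            {"patient_id": ["p", "p"], "day": [0, 60], "end_day": [30, 90]}
        )
        tl = build_exposure_timeline(assigned)["p"]
        assert tl.intervals == ((0, 30), (60, 90))
        assert not tl.is_exposed(45)

    def test_empty(self):
        assert build_exposure_timeline(pd.DataFrame(columns=["patient_id", "day", "end_day"])) == {}
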