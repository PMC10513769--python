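import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gliometry import (
    PatientSeries,
    TimePointRecord,
    classify_trend,
    compute_ttp,
    expert_ttp,
    icc_consistency,
    pooled_trend_agreement,
    spearman_rho,
    threshold_sweep,
    trend_agreement,
    ttp_os_correlation,
)


def _series(days, volumes, os_days=400, pid="p", nadir_flags=None, ratings=None):
    tps = []
    for i, (d, v) in enumerate(zip(days, volumes)):
        tps.append(
            TimePointRecord(
                days_from_surgery=d,
                measurements={"volume": v, "spd2d": v},
                expert_is_nadir=None if nadir_flags is None else nadir_flags[i],
                expert_rating=None if ratings is None else ratings[i],
            )
        )
    return PatientSeries(patient_id=pid, timepoints=tps, os_days=os_days)


class TestTrends:
    @pytest.mark.parametrize(
        "prev,curr,label",
        [(10, 12, "increasing"), (12, 10, "decreasing"), (10, 10, "constant"), (0, 0, "constant")],
    )
    def test_classify(self, prev, curr, label):
        assert classify_trend(prev, curr) == label

    def test_agreement_identical_series(self):
        assert trend_agreement([1, 5, 2, 7], [1, 5, 2, 7]) == 100.0

    def test_agreement_hand_counted_two_of_three(self):
        # trends [inc, dec, inc] vs [inc, inc, inc] -> 2/3
        assert trend_agreement([1, 2, 1, 2], [1, 2, 3, 4]) == pytest.approx(66.6667, abs=1e-3)

    def test_agreement_reversed_trends_zero(self):
        assert trend_agreement([1, 2, 3], [3, 2, 1]) == 0.0

    def test_agreement_symmetric_and_scale_invariant(self):
        a, b = [1.0, 3.0, 2.0, 5.0], [2.0, 2.5, 2.4, 7.0]
        assert trend_agreement(a, b) == trend_agreement(b, a)
        assert trend_agreement([3.7 * x for x in a], b) == trend_agreement(a, b)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            trend_agreement([1, 2], [1, 2, 3])

    def test_pooled_over_patients(self):
        pairs = [([1, 2], [1, 2]), ([1, 2, 1], [1, 2, 3])]  # 2 of 3 transitions agree
        assert pooled_trend_agreement(pairs) == pytest.approx(100 * 2 / 3, abs=1e-9)


class TestSpearman:
    def test_monotone_is_one(self):
        assert spearman_rho([1, 2, 5], [10, 40, 41]) == 1.0

    def test_reversed_is_minus_one(self):
        assert spearman_rho([1, 2, 3, 4], [4, 3, 2, 1]) == -1.0

    def test_hand_computed_with_ties(self):
        assert spearman_rho([1, 2, 2, 4], [1, 3, 2, 4]) == pytest.approx(0.9487, abs=1e-3)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])

    def test_scale_invariance(self):
        x, y = [1, 3, 2, 8], [4, 1, 5, 9]
        assert spearman_rho([10 * v for v in x], y) == spearman_rho(x, y)


class TestIcc:
    def test_hand_anova_example(self):
        assert icc_consistency([[1, 2], [2, 4], [3, 6]]) == pytest.approx(0.8, abs=1e-12)

    def test_constant_offset_gives_one(self):
        assert icc_consistency([[1, 6], [2, 7], [3, 8]]) == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_near_zero(self, rng):
        scores = rng.normal(size=(200, 2))
        assert abs(icc_consistency(scores)) < 0.2

    def test_offset_invariance(self, rng):
        scores = rng.normal(size=(30, 3)) + rng.normal(size=(30, 1)) * 2
        base = icc_consistency(scores)
        shifted = scores.copy()
        shifted[:, 1] += 123.4
        assert icc_consistency(shifted) == pytest.approx(base, abs=1e-9)

    def test_incomplete_table_rejected(self):
        bad = np.array([[1.0, 2.0], [np.nan, 4.0], [3.0, 6.0]])
        with pytest.raises(ValueError):
            icc_consistency(bad)

    def test_cross_check_against_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        scores = rng.normal(size=(25, 3)) + rng.normal(size=(25, 1)) * 1.5
        df = pd.DataFrame(scores).reset_index().melt("index", var_name="rater")
        table = pg.intraclass_corr(df, targets="index", raters="rater", ratings="value")
        # two-way consistency, single measurement: labelled ICC3 or ICC(C,1)
        row = table[table["Type"].isin(["ICC3", "ICC(C,1)"])]
        want = float(row["ICC"].iloc[0])
        assert icc_consistency(scores) == pytest.approx(want, abs=1e-9)


class TestComputeTtp:
    def test_hand_traced_nadir_rule(self):
        s = _series([60, 120, 180, 240], [10, 8, 11, 11.3])
        r = compute_ttp(s, "volume", 0.40)
        assert (r.ttp_days, r.progressed, r.progression_index) == (240, True, 3)
        assert r.nadir_trace == [10, 10, 8, 8]

    def test_never_progressing_returns_os(self):
        s = _series([60, 120], [10, 10.5], os_days=400)
        r = compute_ttp(s, "volume", 0.40)
        assert (r.ttp_days, r.progressed) == (400, False)

    def test_doubling_progresses_at_first_followup(self):
        s = _series([30, 90], [10, 20])
        assert compute_ttp(s, "spd2d", 0.25).ttp_days == 90

    def test_threshold_boundary_inclusive(self):
        s = _series([0, 50], [100.0, 140.0])
        assert compute_ttp(s, "volume", 0.40).progressed is True
        s2 = _series([0, 50], [100.0, 139.999])
        assert compute_ttp(s2, "volume", 0.40).progressed is False

    def test_zero_nadir_reappearance_flagged(self):
        s = _series([0, 50, 100], [5.0, 0.0, 2.0])
        r = compute_ttp(s, "volume", 0.40)
        assert r.progressed and r.ttp_days == 100 and r.zero_nadir_call

    def test_expert_nadir_mode_uses_flagged_reference(self):
        # auto nadir would re-reference at the under-segmented day-120 value
        s = _series(
            [60, 120, 180], [10, 2, 11], nadir_flags=[True, False, False]
        )
        auto = compute_ttp(s, "volume", 0.40, nadir_mode="auto")
        exp = compute_ttp(s, "volume", 0.40, nadir_mode="expert")
        assert auto.progressed and auto.ttp_days == 180
        assert not exp.progressed  # 11 < 1.4 * 10
        pref = compute_ttp(s, "volume", 0.40, nadir_mode="prefer-expert")
        assert pref.ttp_days == exp.ttp_days

    def test_expert_mode_requires_flags(self):
        s = _series([0, 50], [10, 20])
        with pytest.raises(ValueError):
            compute_ttp(s, "volume", nadir_mode="expert")

    def test_missing_metric_signalled(self):
        s = _series([0, 50], [10, 20])
        with pytest.raises(KeyError):
            compute_ttp(s, "spd25d")

    @given(
        st.lists(st.floats(1.0, 100.0), min_size=3, max_size=8),
        st.floats(0.05, 0.5),
        st.floats(0.05, 0.5),
    )
    def test_ttp_weakly_monotone_in_threshold(self, values, t1, t2):
        days = [30 * (i + 1) for i in range(len(values))]
        s = _series(days, values, os_days=days[-1] + 100)
        lo, hi = sorted((t1, t2))
        assert compute_ttp(s, "volume", lo).ttp_days <= compute_ttp(s, "volume", hi).ttp_days


class TestSweepAndCorrelation:
    def test_sweep_hand_trace(self):
        s = _series(
            [60, 120, 180, 240], [10, 8, 11, 11.3],
            ratings=[None, None, "PD", None],
        )
        sw = threshold_sweep([s], "volume", [0.30, 0.40])
        # expert PD at day 180; auto: thr 0.30 -> 180 (diff 0), 0.40 -> 240 (diff 60)
        assert sw["mean_diff_days"].tolist() == [0.0, 60.0]
        assert sw["n"].tolist() == [1, 1]

    def test_tiny_threshold_fires_on_first_increase(self):
        s = _series([60, 120, 180], [10, 9, 9.01])
        assert compute_ttp(s, "volume", 1e-9).ttp_days == 180

    def test_expert_ttp_falls_back_to_os(self):
        s = _series([60, 120], [1, 2], os_days=300)
        assert expert_ttp(s) == 300

    def test_ttp_proportional_to_os_gives_rho_one(self):
        cohort = []
        for i in range(6):
            s = _series([10, 20], [10, 20], os_days=100 + 50 * i, pid=f"p{i}")
            cohort.append(s)
        rho, _ = ttp_os_correlation(cohort, ttp_days=[s.os_days // 2 for s in cohort])
        assert rho == 1.0

    def test_exact_permutation_p_small_n(self):
        cohort = [
            _series([10, 20], [10, 20], os_days=100 + 10 * i, pid=f"p{i}") for i in range(4)
        ]
        rho, p = ttp_os_correlation(cohort, ttp_days=[1, 2, 3, 4])
        assert rho == 1.0
        assert p == pytest.approx(1 / 12)

    def test_independent_ttp_low_correlation(self, rng):
        cohort = []
        ttps = []
        for i in range(200):
            cohort.append(_series([10, 20], [1, 2], os_days=int(rng.integers(50, 1000)), pid=f"p{i}"))
            ttps.append(int(rng.integers(10, 2000)))
        rho, _ = ttp_os_correlation(cohort, ttp_days=ttps)
        assert abs(rho) < 0.15

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            ttp_os_correlation([_series([1, 2], [1, 2], pid="a")])
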