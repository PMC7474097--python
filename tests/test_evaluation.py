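"""Evaluation framework: pools, one-sided KS, thresholds, detection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _reference import ks_dplus, ks_permutation_pvalue
from ecogmark.evaluate import (build_pools, compute_thresholds, detect,
                               evaluate_scope, ks_one_sided, max_per_patient,
                               mesiotemporal_contrast)
from ecogmark.io import PatientMeta


def make_table(rows):
    return pd.DataFrame(rows, columns=["patient", "situation", "phase",
                                       "channel", "biomarker", "value",
                                       "resected", "mesiotemporal",
                                       "n_epochs"])


def row(patient, phase, channel, value, biomarker="PAC", resected="resected",
        mesiotemporal=False, situation=None):
    return dict(patient=patient, situation=situation or f"{phase}01",
                phase=phase, channel=channel, biomarker=biomarker,
                value=value, resected=resected, mesiotemporal=mesiotemporal,
                n_epochs=4)


PATIENTS = {
    "p1": PatientMeta("p1", "T", "cured"),
    "p2": PatientMeta("p2", "T", "improved"),
    "p3": PatientMeta("p3", "E", "improved"),
}


class TestBuildPools:
    def test_cured_pre_values_enter_pre_pool(self):
        t = make_table([
            row("p1", "pre", "a", 0.5),
            row("p2", "pre", "b", 0.6),
            row("p1", "post", "c", 0.1),
        ])
        pools = build_pools(t, PATIENTS, "all")
        assert sorted(pools.pre["PAC"]) == [0.5, 0.6]
        assert list(pools.post["PAC"]) == [0.1]

    def test_cut_and_unknown_channels_excluded_from_pre_pool(self):
        t = make_table([
            row("p1", "pre", "a", 0.5),
            row("p1", "pre", "b", 0.9, resected="cut"),
            row("p1", "pre", "c", 0.8, resected="unknown"),
            row("p1", "pre", "d", 0.7, resected="not_resected"),
            row("p1", "post", "e", 0.1),
        ])
        pools = build_pools(t, PATIENTS, "all")
        assert list(pools.pre["PAC"]) == [0.5]

    def test_no_cured_patient_in_scope_is_an_error(self):
        t = make_table([row("p3", "pre", "a", 0.5),
                        row("p3", "post", "b", 0.1)])
        with pytest.raises(ValueError, match="cured"):
            build_pools(t, PATIENTS, "E")

    def test_scope_restricts_to_epilepsy_type(self):
        t = make_table([
            row("p1", "post", "a", 0.1),
            row("p2", "pre", "b", 0.5),
            row("p3", "pre", "c", 0.9),
        ])
        pools = build_pools(t, PATIENTS, "T")
        assert list(pools.pre["PAC"]) == [0.5]  # p3 is extra-temporal


class TestKsOneSided:
    def test_identical_samples_give_zero_statistic_unit_pvalue(self):
        x = np.arange(10.0)
        d, p = ks_one_sided(x, x.copy())
        assert d == 0.0 and p == 1.0

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(0)
        post = rng.standard_normal(200)
        d, p = ks_one_sided(post + 10.0, post)
        assert d == 1.0 and p < 1e-6

    def test_direction_one_sided_pre_larger(self):
        # a *smaller* pre sample must not be significant
        rng = np.random.default_rng(1)
        post = rng.standard_normal(200)
        _, p = ks_one_sided(post - 10.0, post)
        assert p > 0.5

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(2)
        pre = rng.standard_normal(30) + 0.4
        post = rng.standard_normal(30)
        d, p = ks_one_sided(pre, post)
        assert d == pytest.approx(ks_dplus(pre, post), abs=1e-12)
        p_perm = ks_permutation_pvalue(pre, post, 2000,
                                       np.random.default_rng(3))
        se = np.sqrt(p_perm * (1 - p_perm) / 2000)
        assert abs(p - p_perm) <= 3 * se + 0.01


class TestMaxPerPatient:
    def test_maximum_and_patient_count(self):
        t = make_table([
            row("p2", "pre", "a", 0.2), row("p2", "pre", "b", 0.9),
            row("p2", "pre", "c", 0.4), row("p3", "pre", "d", 0.3),
            row("p1", "post", "e", 0.1),
        ])
        m = max_per_patient(t, PATIENTS, "all")
        assert m["PAC"]["pre"]["p2"] == 0.9
        assert len(m["PAC"]["pre"]) == 2
        assert list(m["PAC"]["post"]) == ["p1"]

    def test_invariant_to_within_patient_order(self):
        rows = [row("p2", "pre", f"c{i}", v)
                for i, v in enumerate([0.5, 0.1, 0.8])]
        t1, t2 = make_table(rows), make_table(rows[::-1])
        m1 = max_per_patient(t1, PATIENTS, "all")
        m2 = max_per_patient(t2, PATIENTS, "all")
        assert m1["PAC"]["pre"] == m2["PAC"]["pre"]


class TestDetect:
    def test_strictly_above_counts(self):
        vals = make_table([row("p2", "pre", "a", 0.4),
                           row("p2", "pre", "b", 0.6)])
        flag, n, ch, vmax = detect(vals, 0.5)
        assert flag and n == 1 and ch == "b" and vmax == 0.6

    def test_equality_is_not_detection(self):
        vals = make_table([row("p2", "pre", "a", 0.5)])
        flag, n, _, _ = detect(vals, 0.5)
        assert not flag and n == 0

    def test_all_below_is_no_detection(self):
        vals = make_table([row("p2", "pre", "a", 0.1),
                           row("p2", "pre", "b", 0.2)])
        assert detect(vals, 0.5)[0] is False

    @given(st.lists(st.floats(0, 1, width=32), min_size=1, max_size=20),
           st.floats(0, 1, width=32))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_detection_iff_any_value_strictly_above(self, values, thr):
        vals = make_table([row("p2", "pre", f"c{i}", float(v))
                           for i, v in enumerate(values)])
        flag, n, _, vmax = detect(vals, float(thr))
        assert flag == any(v > thr for v in values)
        assert n == sum(v > thr for v in values)
        assert vmax == max(values)


def scope_table():
    rng = np.random.default_rng(7)
    rows = []
    for pid in PATIENTS:
        for ch in "abcd":
            rows.append(row(pid, "pre", ch, rng.uniform(0.2, 0.6)))
            rows.append(row(pid, "pre", ch + "x", rng.uniform(0.2, 0.6),
                            biomarker="ARR"))
    for ch in "efgh":
        rows.append(row("p1", "post", ch, rng.uniform(0.0, 0.4)))
        rows.append(row("p1", "post", ch + "x", rng.uniform(0.0, 0.4),
                        biomarker="ARR"))
    return make_table(rows)


class TestEvaluateScope:
    def test_threshold_attained_by_post_value(self):
        t = scope_table()
        rep = evaluate_scope(t, PATIENTS, "all")
        pools = build_pools(t, PATIENTS, "all")
        for bm, thr in rep.thresholds.items():
            assert thr in pools.post[bm]

    def test_adding_post_values_never_increases_detections(self):
        t = scope_table()
        base = evaluate_scope(t, PATIENTS, "all")
        extra = make_table([row("p1", "post", "zz", 0.99),
                            row("p1", "post", "zzx", 0.99, biomarker="ARR")])
        grown = evaluate_scope(pd.concat([t, extra], ignore_index=True),
                               PATIENTS, "all")
        for bm in ("PAC", "ARR"):
            assert grown.thresholds[bm] >= base.thresholds[bm]
            assert grown.n_detected(bm) <= base.n_detected(bm)
        assert grown.n_cumulative_detected <= base.n_cumulative_detected

    def test_cumulative_is_or_over_biomarkers(self):
        rep = evaluate_scope(scope_table(), PATIENTS, "all")
        merged = rep.detections.groupby("patient")["detected"].any()
        for _, r in rep.patient_summary.iterrows():
            assert r["cumulative"] == merged[r["patient"]]
        for bm in ("PAC", "ARR"):
            assert rep.n_cumulative_detected >= rep.n_detected(bm)

    def test_temporal_only_cohort_equal_scopes(self):
        t = scope_table()
        pats = {k: v for k, v in PATIENTS.items() if v.epilepsy_type == "T"}
        t = t[t["patient"].isin(pats)]
        rep_all = evaluate_scope(t, pats, "all")
        rep_t = evaluate_scope(t, pats, "T")
        assert rep_all.thresholds == rep_t.thresholds
        assert rep_all.n_cumulative_detected == rep_t.n_cumulative_detected

    def test_leave_one_out_uses_other_patients_reference(self):
        pats = {"p1": PatientMeta("p1", "T", "cured"),
                "p2": PatientMeta("p2", "T", "cured")}
        t = make_table([
            row("p1", "pre", "a", 0.5), row("p2", "pre", "b", 0.5),
            row("p1", "post", "c", 0.9), row("p2", "post", "d", 0.1),
        ])
        rep = evaluate_scope(t, pats, "all", leave_one_out=True)
        det = rep.detections.set_index("patient")
        # p1's own post max (0.9) is withheld -> detected vs 0.1
        assert det.loc["p1", "detected"]
        assert not det.loc["p2", "detected"]


class TestMesiotemporalContrast:
    def test_shifted_mesiotemporal_values_detected(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(30):
            rows.append(row("p2", "pre", f"m{i}", rng.uniform(0.5, 1.0),
                            mesiotemporal=True))
            rows.append(row("p2", "pre", f"n{i}", rng.uniform(0.0, 0.5)))
        res = mesiotemporal_contrast(make_table(rows), PATIENTS)
        assert res["PAC"]["significant"]

    def test_null_values_not_significant(self):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(30):
            rows.append(row("p2", "pre", f"m{i}", rng.uniform(0, 1),
                            mesiotemporal=True))
            rows.append(row("p2", "pre", f"n{i}", rng.uniform(0, 1)))
        res = mesiotemporal_contrast(make_table(rows), PATIENTS)
        assert not res["PAC"]["significant"]

    def test_requires_mesiotemporal_channels(self):
        t = make_table([row("p2", "pre", "a", 0.5)])
        with pytest.raises(ValueError, match="mesiotemporal"):
            mesiotemporal_contrast(t, PATIENTS)


def test_thresholds_require_nonempty_post_pool():
    t = make_table([row("p1", "pre", "a", 0.5), row("p1", "post", "b", 0.1)])
    pools = build_pools(t, PATIENTS, "all")
    assert compute_thresholds(pools) == {"PAC": 0.1}
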