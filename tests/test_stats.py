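"""Exact Wilcoxon, Bonferroni control, exclusions, and persistence classification."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon

from prostate_qmri.simulate import SimConfig, simulate_trajectory_cohort
from prostate_qmri.roi import build_trajectory_table
from prostate_qmri.stats import (
    apply_exclusions,
    bonferroni_threshold,
    classify_persistence,
    combined_fraction,
    summarize_cohort,
    wilcoxon_signed_rank,
)


def brute_force_wilcoxon(d):
    """Two-sided exact p by full enumeration of the 2^n sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    stats = np.array(
        [ranks[np.array(signs, bool)].sum() for signs in product([0, 1], repeat=n)]
    )
    p_le = (stats <= w_obs + 1e-9).mean()
    p_ge = (stats >= w_obs - 1e-9).mean()
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestWilcoxon:
    def test_all_positive_n6(self):
        """Six positive differences: exact two-sided p = 2/64 = 0.03125."""
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 64, abs=1e-15)

    def test_antisymmetric_differences(self):
        res = wilcoxon_signed_rank([3.0, -3.0, 1.5, -1.5])
        assert res.p_value == 1.0

    def test_matches_brute_force_enumeration(self):
        """Exact p equals the 2^n enumeration for random data, ties included."""
        rng = np.random.default_rng(12)
        for _ in range(25):
            n = rng.integers(5, 11)
            d = np.round(rng.normal(0.3, 1.0, n), 1)  # rounding induces ties
            d = d[d != 0]
            if d.size < 2:
                continue
            res = wilcoxon_signed_rank(d)
            assert res.p_value == pytest.approx(brute_force_wilcoxon(d), abs=1e-12)

    def test_matches_scipy_without_ties(self):
        """Cross-check against an independent implementation on tie-free data."""
        rng = np.random.default_rng(13)
        for _ in range(10):
            d = rng.normal(0.4, 1.0, 12)
            assert len(np.unique(np.abs(d))) == 12
            ours = wilcoxon_signed_rank(d)
            ref = scipy_wilcoxon(d, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_zeros_discarded_by_default(self):
        with_zeros = wilcoxon_signed_rank([0.0, 0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        without = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert with_zeros.n_informative == 6
        assert with_zeros.p_value == without.p_value

    def test_pratt_ranks_through_zeros(self):
        """Pratt convention ranks zeros before dropping them, shifting the ranks."""
        d = [0.0, 0.0, 1.0, -2.0, 3.0, -4.0, 5.0]
        wilcox = wilcoxon_signed_rank(d, zero_method="wilcox")
        pratt = wilcoxon_signed_rank(d, zero_method="pratt")
        assert pratt.n_informative == wilcox.n_informative == 5
        # zeros occupy ranks 1-2 under Pratt, shifting every retained rank by 2
        assert pratt.statistic == wilcox.statistic + 2 * 3  # three positive diffs
        assert pratt.p_value != wilcox.p_value

    def test_all_zero_differences(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert res.p_value == 1.0

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(14)
        d = rng.normal(0.4, 1.0, 30)
        approx = wilcoxon_signed_rank(d)  # n=30 -> normal path
        exact = wilcoxon_signed_rank(d, exact_max_n=40)
        assert approx.method == "normal" and exact.method == "exact"
        assert approx.p_value == pytest.approx(exact.p_value, abs=0.01)

    def test_paired_form(self):
        x = np.array([10.0, 12.0, 9.0, 14.0, 11.0, 13.0])
        y = x - np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert (
            wilcoxon_signed_rank(x, y).p_value
            == wilcoxon_signed_rank(x - y).p_value
        )


class TestBonferroni:
    def test_nine_tests_displays_0056(self):
        thr = bonferroni_threshold(0.05, 9)
        assert thr.threshold == pytest.approx(0.05 / 9, abs=1e-15)
        assert thr.display == "0.0056"
        # comparisons use the unrounded quotient
        assert thr.is_significant(0.00555)
        assert not thr.is_significant(0.00556)

    def test_single_test_uncorrected(self):
        assert bonferroni_threshold(0.05, 1).threshold == 0.05

    def test_direct_division(self):
        assert bonferroni_threshold(0.01, 4).threshold == pytest.approx(0.0025)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 9)


def manifest_rows(patient, weeks, dialect="B", has_t2=True, switch_week=None):
    rows = []
    for w in weeks:
        d = dialect if switch_week is None or w < switch_week else "A"
        rows.append(
            {"patient": patient, "ht": True, "week": w, "dialect": d,
             "has_adc": True, "has_t2": has_t2}
        )
    return rows


class TestExclusions:
    def test_insufficient_exams(self):
        manifest = pd.DataFrame(manifest_rows("P1", [0, 3]) + manifest_rows("P2", range(6)))
        rep = apply_exclusions(manifest)
        assert rep.adc_patients == ["P2"]
        assert ("P1", "ADC", "insufficient exams") in rep.excluded

    def test_dialect_switch_excluded(self):
        manifest = pd.DataFrame(
            manifest_rows("P1", range(6), switch_week=2) + manifest_rows("P2", range(6))
        )
        rep = apply_exclusions(manifest)
        assert "P1" not in rep.adc_patients
        assert ("P1", "ADC", "multiple DWI protocols") in rep.excluded

    def test_missing_week0_t2_excludes_t2_only(self):
        rows = manifest_rows("P1", range(6))
        rows[0]["has_t2"] = False
        manifest = pd.DataFrame(rows)
        rep = apply_exclusions(manifest)
        assert rep.adc_patients == ["P1"]
        assert rep.t2_patients == []

    def test_complete_patient_in_both(self):
        manifest = pd.DataFrame(manifest_rows("P1", range(6)))
        rep = apply_exclusions(manifest)
        assert rep.adc_patients == ["P1"] and rep.t2_patients == ["P1"]


class TestPersistence:
    def test_sustained_decrease_with_onset(self):
        series = {0: 1.00, 1: 0.95, 2: 0.90, 3: 0.85, 4: 0.80, 5: 0.78}
        call = classify_persistence(series, 0.11)
        assert call.persistent and call.onset_week == 3
        assert call.direction == "decrease"
        assert not call.imputed_endpoint

    def test_flat_series_not_persistent(self):
        call = classify_persistence({w: 1.0 for w in range(6)}, 0.11)
        assert call.persistent is False

    def test_transient_excursion_rejected_late_onset_kept(self):
        """An early dip that recovers does not count; the final-week dip does."""
        series = {0: 1.0, 1: 0.85, 2: 1.0, 3: 1.0, 4: 1.0, 5: 0.85}
        call = classify_persistence(series, 0.11)
        assert call.persistent and call.onset_week == 5

    def test_missing_week5_uses_last_measured_with_flag(self):
        series = {0: 1.0, 1: 0.80, 2: 0.78, 4: 0.75}
        call = classify_persistence(series, 0.11)
        assert call.persistent and call.imputed_endpoint

    def test_too_few_weeks_undetermined(self):
        call = classify_persistence({0: 1.0, 5: 0.7}, 0.11)
        assert call.persistent is None

    @given(
        ci=st.floats(min_value=0.01, max_value=0.5),
        values=st.lists(
            st.floats(min_value=0.3, max_value=1.8), min_size=5, max_size=5
        ),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_ci(self, ci, values):
        """Persistence at threshold c implies persistence at any smaller threshold."""
        series = {0: 1.0, **{w + 1: v for w, v in enumerate(values)}}
        call_wide = classify_persistence(series, ci)
        if call_wide.persistent:
            call_narrow = classify_persistence(series, ci / 2)
            assert call_narrow.persistent

    def test_overall_fraction_from_stratum_counts(self):
        """14/21 plus 2/3 persistent patients combine to 16/24 = 67 %."""
        frac = combined_fraction([(14, 21), (2, 3)])
        assert frac == pytest.approx(100 * 16 / 24)
        assert round(frac) == 67


class TestSummarizeCohort:
    @pytest.fixture(scope="class")
    def trajectory_table(self):
        cfg = SimConfig(n_patients=40, seed=5, missing_prob=0.1)
        medians = simulate_trajectory_cohort(cfg)
        return build_trajectory_table(medians)

    def test_nine_test_battery(self, trajectory_table):
        result = summarize_cohort(trajectory_table)
        assert len(result.tests) + len(result.skipped_tests) == 9
        for t in result.tests:
            assert t["significant"] == (t["p_value"] < 0.05 / 9)

    def test_injected_effects_recovered(self, trajectory_table):
        result = summarize_cohort(trajectory_table)
        changes = {
            (c["map_type"], c["roi"], c["stratum"]): c["week5_percent_change"]
            for c in result.week5_changes
        }
        assert changes[("ADC", "tumor", "noHT")] == pytest.approx(20.0, abs=3.0)
        assert changes[("T2", "PZ", "HT")] == pytest.approx(-17.0, abs=3.0)
        assert changes[("T2", "CG", "HT")] == pytest.approx(-12.0, abs=3.0)

    def test_no_adc_persistence_at_47_percent(self, trajectory_table):
        """Simulated ADC changes stay within the wide 47 % repeatability interval."""
        result = summarize_cohort(trajectory_table)
        adc_calls = [
            c for c in result.persistence if c.map_type == "ADC" and c.persistent
        ]
        assert adc_calls == []

    def test_interpolated_rows_do_not_change_tests(self, trajectory_table):
        measured_only = trajectory_table[~trajectory_table.interpolated]
        a = summarize_cohort(trajectory_table)
        b = summarize_cohort(measured_only)
        for ta, tb in zip(a.tests, b.tests):
            assert ta["p_value"] == tb["p_value"]
        pers_a = {(c.patient, c.roi, c.map_type): c.persistent for c in a.persistence}
        pers_b = {(c.patient, c.roi, c.map_type): c.persistent for c in b.persistence}
        assert pers_a == pers_b

    def test_strict_endpoint_policy_drops_missing_week5(self, trajectory_table):
        strict = summarize_cohort(trajectory_table, endpoint_policy="strict-week5")
        loose = summarize_cohort(trajectory_table, endpoint_policy="last-measured")
        n_strict = {(t["map_type"], t["roi"], t["stratum"]): t["n_patients"] for t in strict.tests}
        n_loose = {(t["map_type"], t["roi"], t["stratum"]): t["n_patients"] for t in loose.tests}
        assert all(n_strict[k] <= n_loose[k] for k in n_strict if k in n_loose)

    def test_result_json_roundtrip(self, trajectory_table, tmp_path):
        import json

        result = summarize_cohort(trajectory_table)
        text = result.to_json(tmp_path / "r.json")
        parsed = json.loads(text)
        assert parsed["threshold"]["display"] == "0.0056"
        assert len(parsed["tests"]) == len(result.tests)
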