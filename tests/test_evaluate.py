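"""Cohort statistics: tallies, chi-squared, positivity, ROC, combined marker."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strandmeth import reference_data
from strandmeth.evaluate import (bsp_positive, combined_marker, compare_roc,
                                 density_tally, group_tests, msp_positive,
                                 pearson_chi2, roc, sensitivity_specificity)
from strandmeth.genome import ANTISENSE, SENSE
from strandmeth.msp import QuantResult
from strandmeth.traces import CallVector, Category


def _vector(cats, sid="s1", strand=SENSE, qc=True):
    return CallVector(sid, strand, {i + 1: c for i, c in enumerate(cats)}, qc, 1.0)


class TestDensityTally:
    def test_published_hcc_antisense_c_only_fraction(self):
        vectors, groups = reference_data.antisense_call_vectors()
        tally = density_tally(vectors, groups)
        hcc = tally.loc["HCC"]
        readable = hcc[["T_ONLY", "C_LE_T", "C_GT_T", "C_ONLY"]].sum()
        assert (hcc["C_ONLY"], readable) == (295, 640)
        assert hcc["C_ONLY"] / readable == pytest.approx(0.461, abs=5e-4)

    def test_published_adjacent_and_control_tallies(self):
        vectors, groups = reference_data.antisense_call_vectors()
        tally = density_tally(vectors, groups)
        adj = tally.loc["adjacent_non_HCC"]
        ctl = tally.loc["pooled_control"]
        cats = ["T_ONLY", "C_LE_T", "C_GT_T", "C_ONLY"]
        assert (adj["C_ONLY"], adj[cats].sum()) == (29, 542)
        assert (ctl["C_ONLY"], ctl[cats].sum()) == (0, 295)

    def test_single_sample_all_one_category(self):
        tally = density_tally([_vector([Category.T_ONLY] * 5)], {"s1": "g"})
        assert tally.loc["g", "T_ONLY"] == 5
        assert tally.loc["g", ["C_LE_T", "C_GT_T", "C_ONLY", "MISSING"]].sum() == 0

    def test_tally_conservation(self):
        vectors, groups = reference_data.antisense_call_vectors()
        tally = density_tally(vectors, groups)
        for group, (n_samples, _, _) in reference_data.ANTISENSE_TALLIES.items():
            assert tally.loc[group].sum() == n_samples * 20

    def test_complete_cases_drops_sites_missing_anywhere(self):
        a = _vector([Category.C_ONLY, Category.MISSING, Category.C_ONLY], "a")
        b = _vector([Category.T_ONLY, Category.T_ONLY, Category.T_ONLY], "b")
        tally = density_tally([a, b], {"a": "g1", "b": "g2"},
                              mode="complete_cases")
        # site 2 excluded entirely: 2 calls per sample remain
        assert tally.loc["g1"].sum() == 2 and tally.loc["g2"].sum() == 2
        assert tally.loc["g2", "T_ONLY"] == 2

    def test_qc_failures_excluded(self):
        bad = _vector([Category.C_ONLY] * 3, "bad", qc=False)
        tally = density_tally([bad, _vector([Category.T_ONLY] * 3, "ok")],
                              {"bad": "g", "ok": "g"})
        assert tally.loc["g", "C_ONLY"] == 0


class TestPearsonChi2:
    def test_no_association(self):
        res = pearson_chi2([[10, 10], [10, 10]])
        assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_published_c_only_contrast_significant(self):
        res = pearson_chi2([[295, 345], [0, 295]])
        assert res["df"] == 1
        assert res["p"] < 1e-4

    def test_matches_direct_formula_on_random_tables(self, rng):
        """Oracle: chi2 = sum (O-E)^2/E, p = chi2 survival function."""
        for _ in range(100):
            table = rng.integers(1, 200, size=(2, 4)).astype(float)
            res = pearson_chi2(table)
            expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
            chi2 = ((table - expected) ** 2 / expected).sum()
            assert res["chi2"] == pytest.approx(chi2, abs=1e-10)
            assert res["p"] == pytest.approx(stats.chi2.sf(chi2, res["df"]),
                                             abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi2([[5, 0], [10, 0]])


class TestPositivityRules:
    def test_all_c_only_positive(self):
        assert bsp_positive(_vector([Category.C_ONLY] * 20))

    def test_all_t_only_negative(self):
        assert not bsp_positive(_vector([Category.T_ONLY] * 20))

    def test_half_detected_is_positive_boundary(self):
        cats = [Category.C_LE_T] * 10 + [Category.T_ONLY] * 10
        assert bsp_positive(_vector(cats))

    def test_just_under_half_negative(self):
        cats = [Category.C_GT_T] * 9 + [Category.T_ONLY] * 11
        assert not bsp_positive(_vector(cats))

    def test_missing_sites_excluded_from_denominator(self):
        cats = [Category.C_ONLY] * 5 + [Category.MISSING] * 15
        assert bsp_positive(_vector(cats))

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            bsp_positive(_vector([Category.MISSING] * 5))

    @pytest.mark.parametrize("copies,detected,expected", [
        (20.0, True, True), (0.0, False, False), (0.0, False, False)])
    def test_msp_positive_follows_detection(self, copies, detected, expected):
        q = QuantResult("s", "sense", copies, detected)
        assert msp_positive(q) is expected


class TestSensitivitySpecificity:
    def test_perfect_classifier(self):
        res = sensitivity_specificity([True, True, False], [True, True, False])
        assert (res["sensitivity"], res["specificity"]) == (1.0, 1.0)

    def test_all_negative_classifier(self):
        res = sensitivity_specificity([False] * 4, [True, True, False, False])
        assert (res["sensitivity"], res["specificity"]) == (0.0, 1.0)

    def test_flip_maps_both_to_complement(self, rng):
        calls = rng.random(50) < 0.4
        labels = rng.random(50) < 0.5
        if labels.all() or not labels.any():
            labels[0] = True; labels[1] = False
        a = sensitivity_specificity(calls, labels)
        b = sensitivity_specificity(~calls, labels)
        assert b["sensitivity"] == pytest.approx(1 - a["sensitivity"])
        assert b["specificity"] == pytest.approx(1 - a["specificity"])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_specificity([True], [True])


class TestROC:
    def test_perfect_separation(self):
        r = roc([1, 2, 3, 10, 11, 12], [False] * 3 + [True] * 3)
        assert r.auroc == 1.0

    def test_uninformative_constant_values(self):
        with pytest.warns(UserWarning, match="constant"):
            r = roc([5, 5, 5, 5], [True, False, True, False])
        assert r.auroc == 0.5

    def test_auroc_equals_mann_whitney_all_pairs(self, rng):
        """Oracle: brute-force all-pairs count with half weight for ties."""
        for _ in range(100):
            n = int(rng.integers(10, 40))
            values = rng.integers(0, 8, size=n).astype(float)  # heavy ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                labels[0] = True; labels[1] = False
            pos = values[labels]
            neg = values[~labels]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            oracle = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert roc(values, labels).auroc == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        values = rng.normal(size=80)
        labels = np.r_[np.ones(40, bool), np.zeros(40, bool)]
        a = roc(values, labels).auroc
        b = roc(np.exp(3 * values + 1), labels).auroc
        assert a == pytest.approx(b, abs=1e-12)


class TestCompareROC:
    def test_identical_markers_p_one(self):
        values = np.arange(20.0)
        labels = np.r_[np.zeros(10, bool), np.ones(10, bool)]
        res = compare_roc(values, values, labels)
        assert res["p"] == 1.0

    def test_symmetry(self, rng):
        y = np.r_[np.ones(30, bool), np.zeros(30, bool)]
        a = rng.normal(y.astype(float), 1.0)
        b = rng.normal(size=60)
        assert compare_roc(a, b, y)["p"] == pytest.approx(
            compare_roc(b, a, y)["p"], abs=1e-12)

    def test_informative_vs_noise_detected(self):
        """Marker tracking truth beats pure noise in most seeded replicates."""
        hits = 0
        reps = 40
        for k in range(reps):
            rng = np.random.default_rng(3000 + k)
            y = np.r_[np.ones(100, bool), np.zeros(100, bool)]
            a = y.astype(float) + rng.normal(0, 0.5, 200)
            b = rng.normal(size=200)
            hits += compare_roc(a, b, y)["p"] < 0.05
        assert hits >= 0.85 * reps

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_roc([1, 2], [1, 2, 3], [True, False])


class TestCombinedMarker:
    def test_published_quadrants(self):
        records = reference_data.combined_marker_records()
        res = combined_marker(records)
        assert res["n"] == 53
        assert res["pct_mapc_pos"] == pytest.approx(100 * 35 / 53, abs=1e-9)
        assert round(res["pct_mapc_pos"]) == 66
        assert res["pct_union_pos"] == pytest.approx(100 * 44 / 53, abs=1e-9)
        assert round(res["pct_union_pos"]) == 83
        assert res["pct_mapc_pos_afp_neg_of_mapc_pos"] == pytest.approx(60.0)
        assert round(res["pct_additional_over_afp"]) == 40

    def test_all_negative_cohort(self):
        df = pd.DataFrame({"mapc_positive": [False] * 5,
                           "afp_ng_ml": [1.0] * 5})
        res = combined_marker(df)
        assert res["pct_mapc_pos"] == res["pct_union_pos"] == 0.0
        assert res["pct_additional_over_afp"] == 0.0

    def test_missing_afp_rejected(self):
        df = pd.DataFrame({"mapc_positive": [True], "afp_ng_ml": [np.nan]})
        with pytest.raises(ValueError):
            combined_marker(df)

    def test_cutoff_is_inclusive(self):
        df = pd.DataFrame({"mapc_positive": [False, False],
                           "afp_ng_ml": [20.0, 19.99]})
        res = combined_marker(df)
        assert res["quadrants"]["mapc-afp+"] == 1


class TestGroupTests:
    def _cohort(self, rng, n=40):
        stage = rng.choice(["1", "2", "3"], size=n)
        return pd.DataFrame({
            "sample_id": [f"h{i}" for i in range(n)],
            "group": ["HCC"] * (n // 2) + ["hepatitis"] * (n - n // 2),
            "age": rng.normal(58, 10, n).round(1),
            "sex": rng.choice(["M", "F"], size=n),
            "stage": stage, "grade": rng.choice(["1", "2"], size=n),
            "hbv": rng.integers(0, 2, n), "hcv": rng.integers(0, 2, n),
            "afp_ng_ml": np.exp(rng.normal(2.5, 1.5, n)).round(2),
            "sense_msp_value": np.abs(rng.normal(20, 15, n)),
        })

    def test_report_structure(self, rng):
        out = group_tests(self._cohort(rng))
        for key in ("kruskal_stage", "kruskal_grade", "kruskal_hbv",
                    "kruskal_hcv", "kruskal_afp_group", "spearman_mapc_afp",
                    "student_t_age", "fisher_sex"):
            assert key in out

    def test_monotone_marker_gives_spearman_one(self, rng):
        df = self._cohort(rng)
        hcc = df["group"] == "HCC"
        df.loc[hcc, "sense_msp_value"] = np.arange(hcc.sum(), dtype=float)
        df.loc[hcc, "afp_ng_ml"] = np.arange(hcc.sum(), dtype=float) ** 2 + 1
        out = group_tests(df)
        assert out["spearman_mapc_afp"]["rho"] == pytest.approx(1.0)

    def test_identical_age_distributions_give_t_zero(self, rng):
        df = self._cohort(rng)
        df["age"] = np.tile([50.0, 60.0], len(df) // 2)
        out = group_tests(df)
        assert out["student_t_age"]["t"] == pytest.approx(0.0, abs=1e-9)

    def test_null_permutation_p_roughly_uniform(self):
        """Label permutation keeps the Kruskal-Wallis p uniform (KS check)."""
        ps = []
        for k in range(60):
            rng = np.random.default_rng(7000 + k)
            df = self._cohort(rng, n=60)
            out = group_tests(df)
            if out["kruskal_hbv"] is not None:
                ps.append(out["kruskal_hbv"]["p"])
        stat, p = stats.kstest(ps, "uniform")
        assert p > 0.01
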