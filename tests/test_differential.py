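"""Group and single-patient contrasts, significance classes, pathway overlays."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosq import differential as diff
from phosq.io_sitetable import DesignError, StudyDesign
from phosq.normalize import QuantMatrix
from conftest import make_design, make_matrix


def welch_oracle(a, b):
    """Welch t, Satterthwaite df and two-sided p from first principles."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    from scipy.integrate import quad
    from scipy.special import gamma as G

    def t_pdf(x):
        return G((df + 1) / 2) / (math.sqrt(df * math.pi) * G(df / 2)) * (1 + x * x / df) ** (-(df + 1) / 2)

    tail, _ = quad(t_pdf, abs(t), np.inf)
    return t, df, 2 * tail


def two_group_matrix(a_rows, b_rows, n_patients=None):
    """Matrix with columns A1..Ak then B1..Bk and a matching paired design."""
    a_rows, b_rows = np.atleast_2d(a_rows), np.atleast_2d(b_rows)
    na, nb = a_rows.shape[1], b_rows.shape[1]
    samples = [f"A{i + 1}" for i in range(na)] + [f"B{i + 1}" for i in range(nb)]
    data = pd.DataFrame(
        np.hstack([a_rows, b_rows]),
        index=[f"G{i + 1}_S{i + 1}" for i in range(a_rows.shape[0])],
        columns=samples,
    )
    rows = []
    for j, s in enumerate(samples):
        rows.append(
            {
                "batch_id": "B1",
                "channel_id": f"ch{j + 1}",
                "sample_id": s,
                "patient_id": f"P{(j % max(na, nb)) + 1}",
                "tissue": "T",
                "her2": "positive",
                "timepoint": "pre" if s.startswith("B") else "post",
                "is_reference": False,
            }
        )
    rows.append(
        {
            "batch_id": "B1",
            "channel_id": "ref",
            "sample_id": "REF1",
            "patient_id": "none",
            "tissue": "REF",
            "her2": "none",
            "timepoint": "none",
            "is_reference": True,
        }
    )
    design = StudyDesign(pd.DataFrame(rows))
    matrix = QuantMatrix(data, "batch_corrected", pd.Series("B1", index=samples))
    groups = [s for s in samples if s.startswith("A")], [s for s in samples if s.startswith("B")]
    return matrix, design, groups


class TestGroupCompare:
    def test_welch_matches_hand_computed_example(self):
        matrix, design, (ga, gb) = two_group_matrix([[1.0, 2.0, 3.0]], [[2.0, 4.0, 6.0]])
        res = diff.group_compare(matrix, design, ga, gb, mode="welch")
        row = res.table.iloc[0]
        assert row["log2FC"] == pytest.approx(-2.0)
        assert row["t"] == pytest.approx(-1.549193, abs=1e-6)
        assert row["df"] == pytest.approx(2.9412, abs=1e-3)

    def test_welch_p_matches_integrated_tail_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, size=(50, 4))
        b = rng.normal(0.5, 2, size=(50, 5))
        matrix, design, (ga, gb) = two_group_matrix(a, b)
        res = diff.group_compare(matrix, design, ga, gb, mode="welch")
        for i in range(50):
            t, df, p = welch_oracle(a[i], b[i])
            assert res.table["t"].iloc[i] == pytest.approx(t, abs=1e-10)
            assert res.table["p"].iloc[i] == pytest.approx(p, abs=1e-8)

    def test_identical_groups_give_p_one(self):
        matrix, design, (ga, gb) = two_group_matrix([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]])
        res = diff.group_compare(matrix, design, ga, gb, mode="welch")
        row = res.table.iloc[0]
        assert row["log2FC"] == 0.0 and row["t"] == 0.0 and row["p"] == pytest.approx(1.0)

    def test_paired_mode_uses_patient_differences(self):
        # post - pre differences {1.1, 1.2, 1.3}: strong one-sample t signal
        pre = np.array([[0.0, 1.0, 2.0]])
        post = pre + np.array([[1.1, 1.2, 1.3]])
        matrix, design, (ga, gb) = two_group_matrix(post, pre)
        res = diff.group_compare(matrix, design, ga, gb, mode="paired")
        row = res.table.iloc[0]
        assert row["log2FC"] == pytest.approx(1.2)
        from scipy import stats

        t0, p0 = stats.ttest_1samp([1.1, 1.2, 1.3], 0.0)
        assert row["t"] == pytest.approx(t0)
        assert row["p"] == pytest.approx(p0) and row["p"] < 0.05
        assert row["class"] == "significant_up"

    def test_paired_mode_rejects_unpairable_samples(self):
        matrix, design, (ga, gb) = two_group_matrix([[1.0, 2.0]], [[1.0, 2.0]])
        design.table.loc[design.table["sample_id"] == "B2", "patient_id"] = "P99"
        with pytest.raises(DesignError, match="unpairable"):
            diff.group_compare(matrix, design, ga, gb, mode="paired")

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(20, 3)), rng.normal(size=(20, 4))
        matrix, design, (ga, gb) = two_group_matrix(a, b)
        ab = diff.group_compare(matrix, design, ga, gb, mode="welch").table
        ba = diff.group_compare(matrix, design, gb, ga, mode="welch").table
        np.testing.assert_allclose(ab["log2FC"], -ba["log2FC"], atol=1e-12)
        np.testing.assert_allclose(ab["t"], -ba["t"], atol=1e-12)
        np.testing.assert_allclose(ab["p"], ba["p"], atol=1e-12)

    def test_null_calibration_five_percent(self):
        rng = np.random.default_rng(17)
        a = rng.normal(0, 1, size=(1000, 4))
        b = rng.normal(0, 1, size=(1000, 4))
        matrix, design, (ga, gb) = two_group_matrix(a, b)
        res = diff.group_compare(matrix, design, ga, gb, mode="welch")
        frac = float((res.table["p"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_zero_variance_unequal_means_not_testable(self):
        matrix, design, (ga, gb) = two_group_matrix([[1.0, 1.0, 1.0]], [[2.0, 2.0, 2.0]])
        res = diff.group_compare(matrix, design, ga, gb, mode="welch")
        assert res.table["class"].iloc[0] == "not_testable"


class TestClassify:
    @pytest.mark.parametrize(
        "fc,p,expected",
        [
            (1.2, 0.03, "significant_up"),
            (-1.2, 0.03, "significant_down"),
            (1.2, 0.07, "tendency_up"),
            (-1.2, 0.07, "tendency_down"),
            (1.0, 0.001, "ns"),  # strict |FC| > 1
            (1.2, 0.05, "tendency_up"),  # p = 0.05 falls in the tendency band
            (1.2, 0.1, "ns"),  # p = 0.1 is outside the tendency band
            (0.5, 0.001, "ns"),
            (np.nan, np.nan, "not_testable"),
        ],
    )
    def test_threshold_boundaries(self, fc, p, expected):
        table = pd.DataFrame({"log2FC": [fc], "t": [0.0], "df": [4.0], "p": [p]}, index=["G1_S1"])
        res = diff.classify_sites(diff.ComparisonResult("c", table))
        assert res.table["class"].iloc[0] == expected

    @given(
        st.lists(
            st.tuples(st.floats(-3, 3), st.floats(0.001, 1.0)),
            min_size=1,
            max_size=50,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_class_counts_partition_features(self, rows):
        table = pd.DataFrame(
            {
                "log2FC": [r[0] for r in rows],
                "t": 0.0,
                "df": 4.0,
                "p": [r[1] for r in rows],
            },
            index=[f"G{i}_S{i}" for i in range(len(rows))],
        )
        res = diff.classify_sites(diff.ComparisonResult("c", table))
        assert sum(res.counts().values()) == len(rows)

    def test_threshold_validation(self):
        table = pd.DataFrame({"log2FC": [1.0], "t": [0.0], "df": [1.0], "p": [0.5]})
        with pytest.raises(ValueError):
            diff.classify_sites(diff.ComparisonResult("c", table), p_sig=0.2, p_tend=0.1)
        with pytest.raises(ValueError):
            diff.classify_sites(diff.ComparisonResult("c", table), fc_cut=0.0)


class TestIndividualCompare:
    def matrix(self):
        data = [[3.0, 1.5], [2.0, 2.0], [1.0, np.nan]]
        return make_matrix(data, stage="median_centered")

    def test_fold_change_flagging(self):
        out = diff.individual_compare(self.matrix(), "S1", "S2")
        assert out.loc["G1_S1", "log2FC"] == pytest.approx(1.5)
        assert out.loc["G1_S1", "class"] == "differential"
        assert out.loc["G2_S2", "log2FC"] == 0.0
        assert out.loc["G2_S2", "class"] == "ns"

    def test_missing_value_marked_grey(self):
        out = diff.individual_compare(self.matrix(), "S1", "S2")
        assert out.loc["G3_S3", "class"] == "no_quantitative_value"
        assert np.isnan(out.loc["G3_S3", "log2FC"])

    def test_unknown_sample_is_error(self):
        with pytest.raises(KeyError, match="S9"):
            diff.individual_compare(self.matrix(), "S1", "S9")


class TestPathwayOverlay:
    def result(self):
        table = pd.DataFrame(
            {
                "log2FC": [2.0, 0.1, 1.5, 0.2],
                "t": 0.0,
                "df": 4.0,
                "p": [0.01, 0.9, 0.07, 0.5],
                "class": ["significant_up", "ns", "tendency_up", "ns"],
            },
            index=["ERBB2_S1054", "ERBB2_T733", "PAK2_T143", "MYC_S62"],
        )
        return diff.ComparisonResult("c", table)

    def test_strongest_state_wins(self):
        out = diff.pathway_overlay(self.result(), ["ERBB2", "PAK2", "MYC", "EGFR"], "erbb")
        states = dict(zip(out["gene"], out["state"]))
        assert states == {
            "ERBB2": "significant",
            "PAK2": "tendency",
            "MYC": "quantified_only",
            "EGFR": "not_quantified",
        }

    def test_empty_pathway(self):
        out = diff.pathway_overlay(self.result(), [])
        assert len(out) == 0

    def test_individual_table_overlay(self):
        table = diff.individual_compare(
            make_matrix([[3.0, 1.5], [np.nan, 1.0]], stage="median_centered"), "S1", "S2"
        )
        table.index = ["ERBB2_S1054", "MYC_S62"]
        out = diff.pathway_overlay(table, ["ERBB2", "MYC"])
        states = dict(zip(out["gene"], out["state"]))
        assert states == {"ERBB2": "significant", "MYC": "not_quantified"}
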