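"""Normalization stages: log2, reference bridging, centering, imputation, ComBat."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from phosq import normalize as nz
from phosq.io_sitetable import DesignError
from conftest import make_design, make_matrix

NAN = np.nan


class TestLog2:
    def test_elementwise_with_missing(self):
        m = make_matrix([[8.0, 1.0], [NAN, 4.0]], stage="raw")
        out = nz.log2_transform(m)
        expect = np.array([[3.0, 0.0], [NAN, 2.0]])
        np.testing.assert_array_equal(out.data.to_numpy(), expect)
        assert out.stage == "raw_log2"

    def test_nonpositive_value_rejected(self):
        with pytest.raises(ValueError, match="log2"):
            nz.log2_transform(make_matrix([[0.0, 2.0]], stage="raw"))


class TestReferenceSubtract:
    def design(self):
        return make_design(n_batches=1, clinical_per_batch=1, refs_per_batch=2)

    def matrix(self, values):
        design = self.design()
        samples = ["S1", "REF_B1_1", "REF_B1_2"]
        data = pd.DataFrame([values], index=["G1_S1"], columns=samples)
        return nz.QuantMatrix(data, "raw_log2", design.table.set_index("sample_id")["batch_id"]), design

    def test_subtracts_mean_of_batch_references(self):
        m, design = self.matrix([9.5, 6.0, 7.0])
        out = nz.reference_subtract(m, design)
        assert out.data.loc["G1_S1", "S1"] == pytest.approx(3.0)
        assert list(out.data.columns) == ["S1"]  # references dropped

    def test_sample_equal_to_reference_mean_gives_zero(self):
        m, design = self.matrix([6.5, 6.0, 7.0])
        out = nz.reference_subtract(m, design)
        assert out.data.loc["G1_S1", "S1"] == pytest.approx(0.0)

    def test_missing_references_make_batch_missing(self):
        m, design = self.matrix([9.5, NAN, NAN])
        out = nz.reference_subtract(m, design)
        assert np.isnan(out.data.loc["G1_S1", "S1"])

    def test_partially_missing_reference_uses_observed_mean(self):
        m, design = self.matrix([9.5, NAN, 7.0])
        out = nz.reference_subtract(m, design)
        assert out.data.loc["G1_S1", "S1"] == pytest.approx(2.5)


class TestMedianCenter:
    @pytest.mark.parametrize(
        "col,expected",
        [
            ([1.0, 2.0, 3.0], [-1.0, 0.0, 1.0]),
            ([1.0, NAN, 3.0], [-1.0, NAN, 1.0]),
            ([1.0, 2.0, 3.0, 4.0], [-1.5, -0.5, 0.5, 1.5]),
        ],
    )
    def test_column_centering(self, col, expected):
        m = make_matrix(np.array(col)[:, None], stage="raw_log2")
        out = nz.median_center(m)
        np.testing.assert_allclose(out.data.to_numpy()[:, 0], expected)

    def test_all_missing_column_warns_and_unchanged(self):
        m = make_matrix([[NAN], [NAN]], stage="raw_log2")
        with pytest.warns(UserWarning, match="no observed values"):
            out = nz.median_center(m)
        assert out.data.isna().all().all()

    @given(
        arrays(
            float,
            (7, 4),
            elements=st.one_of(
                st.just(np.nan),
                st.floats(min_value=-50, max_value=50, allow_subnormal=False),
            ),
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_observed_column_medians_are_zero(self, values):
        m = make_matrix(values, stage="raw_log2")
        out = nz.median_center(m)
        for s in out.data.columns:
            col = out.data[s].dropna()
            if len(col):
                assert abs(col.median()) < 1e-9


class TestPresenceFilterAndImpute:
    def test_feature_must_appear_in_every_batch(self):
        values = [
            [1.0, NAN, 2.0, NAN],  # observed in both batches
            [1.0, 2.0, NAN, NAN],  # batch 2 entirely missing
        ]
        m = make_matrix(values, stage="median_centered", n_batches=2)
        out = nz.batch_presence_filter(m)
        assert list(out.data.index) == ["G1_S1"]

    def test_single_batch_presence_means_observed_once(self):
        m = make_matrix([[NAN, NAN], [1.0, NAN]], stage="median_centered", n_batches=1)
        out = nz.batch_presence_filter(m)
        assert list(out.data.index) == ["G2_S2"]

    @pytest.mark.parametrize(
        "row,expected",
        [
            ([2.0, NAN, 5.0], [2.0, 2.0, 5.0]),
            ([2.0, 3.0, 5.0], [2.0, 3.0, 5.0]),
            ([-1.0, NAN, NAN], [-1.0, -1.0, -1.0]),
        ],
    )
    def test_impute_row_minimum(self, row, expected):
        m = make_matrix([row], stage="median_centered")
        out = nz.impute_min(m)
        np.testing.assert_allclose(out.data.to_numpy()[0], expected)
        assert out.stage == "imputed"

    def test_fully_missing_feature_is_internal_error(self):
        m = make_matrix([[NAN, NAN]], stage="median_centered")
        with pytest.raises(RuntimeError, match="presence filter"):
            nz.impute_min(m)

    @given(
        arrays(
            float,
            (6, 5),
            elements=st.one_of(
                st.just(np.nan),
                st.floats(min_value=-20, max_value=20, allow_subnormal=False),
            ),
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_impute_preserves_observed_cells_and_row_minimum(self, values):
        if np.isnan(values).all(axis=1).any():
            return
        m = make_matrix(values, stage="median_centered")
        out = nz.impute_min(m)
        observed = ~np.isnan(values)
        np.testing.assert_array_equal(out.data.to_numpy()[observed], values[observed])
        np.testing.assert_allclose(
            out.data.min(axis=1).to_numpy(), np.nanmin(values, axis=1)
        )
        assert not out.data.isna().any().any()


def simulate_two_batches(seed=7, n_features=200, per_batch=10, shift=2.0, sigma=1.0):
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, 1.5, size=(n_features, 1))
    a = base + rng.normal(0.0, sigma, size=(n_features, per_batch))
    b = base + shift + rng.normal(0.0, sigma, size=(n_features, per_batch))
    return make_matrix(np.hstack([a, b]), stage="imputed", n_batches=2)


def combat_no_shrink_closed_form(X: np.ndarray, batch_idx: list[np.ndarray]) -> np.ndarray:
    """Independent per-batch standardization oracle (no EB shrinkage).

    Written directly from the location/scale model with plain loops: center
    each batch at the feature's batch mean, rescale to the batch's
    standardized sd, and map back via pooled sd and grand mean.
    """
    G, N = X.shape
    out = np.empty_like(X)
    for g in range(G):
        batch_means = [X[g, idx].mean() for idx in batch_idx]
        grand = sum(bm * len(idx) for bm, idx in zip(batch_means, batch_idx)) / N
        pooled = sum(((X[g, idx] - bm) ** 2).sum() for bm, idx in zip(batch_means, batch_idx)) / N
        pooled_sd = np.sqrt(pooled)
        for bm, idx in zip(batch_means, batch_idx):
            z = (X[g, idx] - grand) / pooled_sd
            gamma = z.mean()
            delta = z.std(ddof=1)
            out[g, idx] = (z - gamma) / delta * pooled_sd + grand
    return out


class TestCombat:
    def test_single_batch_is_bitwise_identity(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(30, 6)), stage="imputed", n_batches=1)
        out, model = nz.combat_correct(m)
        assert (out.data.to_numpy() == m.data.to_numpy()).all()
        assert model.batches == ["B1"]
        np.testing.assert_array_equal(model.gamma_star["B1"], 0.0)

    def test_no_shrink_matches_closed_form_oracle(self):
        m = simulate_two_batches()
        out, _ = nz.combat_correct(m, shrink=False)
        idx = [np.arange(10), np.arange(10, 20)]
        oracle = combat_no_shrink_closed_form(m.data.to_numpy(), idx)
        np.testing.assert_allclose(out.data.to_numpy(), oracle, atol=1e-8)

    def test_additive_shift_removed(self):
        m = simulate_two_batches(shift=2.0)
        out, model = nz.combat_correct(m)
        a = out.data.to_numpy()[:, :10].mean(axis=1)
        b = out.data.to_numpy()[:, 10:].mean(axis=1)
        assert abs(np.mean(a - b)) < 0.1
        # priors recovered the designed batch gap on the standardized scale
        assert model.priors["B1"]["gamma_bar"] < 0 < model.priors["B2"]["gamma_bar"]

    def test_null_batches_nearly_unchanged(self):
        m = simulate_two_batches(shift=0.0, n_features=300)
        out, _ = nz.combat_correct(m)
        rms = np.sqrt(np.mean((out.data.to_numpy() - m.data.to_numpy()) ** 2))
        assert rms < 0.5  # no systematic adjustment beyond noise rescaling

    def test_grand_mean_preserved(self):
        # exact for the pure location/scale adjustment; EB shrinkage moves
        # batch locations slightly off the per-batch estimates, so the grand
        # mean is only approximately preserved there
        m = simulate_two_batches()
        out_ns, _ = nz.combat_correct(m, shrink=False)
        np.testing.assert_allclose(
            out_ns.data.to_numpy().mean(axis=1), m.data.to_numpy().mean(axis=1), atol=1e-6
        )
        out_eb, _ = nz.combat_correct(m)
        np.testing.assert_allclose(
            out_eb.data.to_numpy().mean(axis=1), m.data.to_numpy().mean(axis=1), atol=0.05
        )

    def test_small_batch_and_missing_rejected(self):
        m = make_matrix([[1.0, 2.0, 3.0]], stage="imputed", n_batches=3)
        with pytest.raises(ValueError, match="scale not estimable"):
            nz.combat_correct(m)
        m2 = make_matrix([[1.0, NAN, 3.0, 4.0]], stage="imputed", n_batches=2)
        with pytest.raises(ValueError, match="complete"):
            nz.combat_correct(m2)

    def test_nonparametric_mode_not_supported(self):
        m = simulate_two_batches()
        with pytest.raises(NotImplementedError):
            nz.combat_correct(m, parametric=False)

    def test_agrees_with_scanpy_port(self):
        anndata = pytest.importorskip("anndata")
        scanpy = pytest.importorskip("scanpy")
        m = simulate_two_batches(seed=11)
        adata = anndata.AnnData(
            m.data.to_numpy().T.copy(),
            obs=pd.DataFrame({"batch": m.sample_batches.loc[m.data.columns].astype("category")}),
        )
        scanpy.pp.combat(adata, key="batch")
        ours, _ = nz.combat_correct(m)
        # scanpy stops the EB iterations at a looser tolerance (1e-4), which
        # leaves ~1e-3 discrepancies; this is a cross-implementation sanity
        # check, not a fixed-point comparison
        np.testing.assert_allclose(ours.data.to_numpy(), adata.X.T, atol=5e-3)


class TestRoutes:
    def test_individual_route_is_median_centering_of_clinical_channels(self):
        design = make_design(n_batches=1, clinical_per_batch=2, refs_per_batch=1)
        samples = ["S1", "S2", "REF_B1_1"]
        data = pd.DataFrame(
            [[1.0, 10.0, 0.0], [2.0, 20.0, 0.0], [3.0, 60.0, 0.0]],
            index=["G1_S1", "G2_S2", "G3_S3"],
            columns=samples,
        )
        m = nz.QuantMatrix(data, "raw_log2", design.table.set_index("sample_id")["batch_id"])
        out = nz.normalize_for_individual(m, design)
        assert list(out.data.columns) == ["S1", "S2"]  # references excluded
        np.testing.assert_allclose(out.data["S1"], [-1.0, 0.0, 1.0])
        np.testing.assert_allclose(out.data["S2"], [-10.0, 0.0, 40.0])

    def test_stage_cannot_go_backwards(self):
        m = make_matrix([[1.0, 2.0]], stage="imputed")
        with pytest.raises(ValueError, match="stage"):
            m._advance(m.data, "raw_log2")

    def test_reference_required_per_batch(self):
        design = make_design(n_batches=1, clinical_per_batch=2, refs_per_batch=1)
        samples = ["S1", "S2"]  # matrix lacks the reference channel
        data = pd.DataFrame([[1.0, 2.0]], index=["G1_S1"], columns=samples)
        m = nz.QuantMatrix(data, "raw_log2", design.table.set_index("sample_id")["batch_id"])
        with pytest.raises(DesignError, match="reference"):
            nz.reference_subtract(m, design)
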