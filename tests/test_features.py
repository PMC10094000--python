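"""Tensorization, last-20 rows, and PCA screening."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from enoseml.features import (
    flatten_tensor,
    last20_matrix,
    last20_rows,
    load_tensors,
    pca_fit,
    pca_transform,
    save_tensors,
    to_tensor,
    to_tensor_set,
)

from conftest import make_measurement


class TestTensorization:
    def test_constant_measurement_gives_constant_tensor(self):
        t = to_tensor(make_measurement(3.0))
        assert t.tensor.shape == (10, 10, 10)
        assert np.all(t.tensor == 3.0)

    def test_time_is_laid_out_row_major_within_each_channel(self):
        values = np.full((100, 10), 1.0)
        values[:, 4] = np.arange(1, 101)  # sensor 5 carries 1..100 in time order
        t = to_tensor(make_measurement(values)).tensor
        assert np.array_equal(t[4, 0], np.arange(1, 11))
        assert np.array_equal(t[4, 9], np.arange(91, 101))

    @given(
        arrays(
            np.float64,
            (100, 10),
            elements=st.floats(0.01, 100.0, allow_nan=False),
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_flatten_is_the_exact_inverse(self, values):
        m = make_measurement(values)
        assert np.array_equal(flatten_tensor(to_tensor(m)), m.responses)

    def test_channel_of_tensor_is_reshape_of_source_column(self):
        rng = np.random.default_rng(0)
        m = make_measurement(rng.uniform(0.5, 3, size=(100, 10)))
        t = to_tensor(m).tensor
        for c in range(10):
            assert np.array_equal(t[c].ravel(), m.responses[:, c])

    def test_set_tensorization_shapes_and_labels(self, tiny_set):
        X, labels, ids = to_tensor_set(tiny_set)
        assert X.shape == (2, 10, 10, 10)
        assert labels == tiny_set.labels()
        assert ids == tiny_set.ids()

    def test_tensor_serialization_round_trip(self, tiny_set, tmp_path):
        X, labels, ids = to_tensor_set(tiny_set)
        path = tmp_path / "tensors.npz"
        save_tensors(path, X, labels, ids)
        X2, labels2, ids2 = load_tensors(path)
        assert np.array_equal(X, X2)
        assert labels2 == labels and ids2 == ids


class TestLast20:
    def test_exactly_20_rows_in_time_order(self):
        rows = last20_rows(make_measurement(2.0))
        assert len(rows) == 20
        assert [r.t for r in rows] == list(range(81, 101))

    def test_constant_measurement_gives_identical_rows(self):
        rows = last20_rows(make_measurement(2.5))
        assert all(np.array_equal(r.values, rows[0].values) for r in rows)

    def test_rows_carry_the_response_values(self):
        rng = np.random.default_rng(1)
        m = make_measurement(rng.uniform(0.5, 3, size=(100, 10)))
        rows = last20_rows(m)
        assert np.array_equal(rows[0].values, m.responses[80])
        assert np.array_equal(rows[-1].values, m.responses[99])

    def test_dataset_a_row_accounting_is_27000(self, protocol_set):
        from enoseml.data import assemble_dataset

        X, labels, ids = last20_matrix(assemble_dataset(protocol_set, "A"))
        assert X.shape == (27_000, 10)
        assert len(labels) == 27_000
        # 20 rows per measurement
        assert len(set(ids)) == 1350


class TestPCA:
    def test_single_axis_variation_explains_everything(self):
        rng = np.random.default_rng(0)
        direction = np.ones(10) / np.sqrt(10)
        rows = 2.0 + rng.normal(size=(200, 1)) * direction
        res = pca_fit(rows, 3)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)
        assert res.explained_variance_ratio[1:] == pytest.approx(0.0, abs=1e-9)

    def test_full_rank_ratios_sum_to_one(self):
        rng = np.random.default_rng(1)
        res = pca_fit(rng.normal(size=(300, 10)), 10)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(res.explained_variance_ratio) <= 1e-12).all()

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(2)
        res = pca_fit(rng.normal(size=(100, 10)), 4)
        assert np.allclose(res.component_loadings @ res.component_loadings.T, np.eye(4), atol=1e-9)

    def test_ratios_invariant_under_row_permutation(self):
        rng = np.random.default_rng(3)
        rows = rng.normal(size=(150, 10))
        r1 = pca_fit(rows, 5)
        r2 = pca_fit(rows[rng.permutation(150)], 5)
        assert np.allclose(
            r1.explained_variance_ratio, r2.explained_variance_ratio, atol=1e-12
        )
        # loadings defined up to sign
        assert np.allclose(
            np.abs(r1.component_loadings), np.abs(r2.component_loadings), atol=1e-9
        )

    def test_score_variances_match_ratios(self):
        rng = np.random.default_rng(4)
        rows = rng.normal(size=(500, 10)) * np.linspace(3, 0.1, 10)
        res = pca_fit(rows, 10)
        scores = pca_transform(res, rows)
        var = scores.var(axis=0, ddof=1)
        assert np.allclose(var / var.sum(), res.explained_variance_ratio, atol=1e-9)

    def test_rank_deficient_input_yields_trailing_zero_ratios(self):
        rng = np.random.default_rng(5)
        thin = rng.normal(size=(100, 2))
        rows = np.hstack([thin, thin @ rng.normal(size=(2, 8))])  # rank 2
        res = pca_fit(rows, 6)
        assert res.explained_variance_ratio[2:] == pytest.approx(0.0, abs=1e-9)

    def test_bad_k_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError):
            pca_fit(rng.normal(size=(50, 10)), 0)
        with pytest.raises(ValueError):
            pca_fit(rng.normal(size=(5, 10)), 6)

    def test_steady_state_screening_on_synthetic_protocol(self, small_protocol_set):
        """The documented screening: last-20 rows, 3 components, mean-centred."""
        X, _, _ = last20_matrix(small_protocol_set)
        res = pca_fit(X, 3)
        cum = res.cumulative_variance_ratio
        assert 0 < cum[0] <= cum[1] <= cum[2] <= 1 + 1e-9
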