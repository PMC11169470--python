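"""Embedding model: codebook growth, layout quality, carry-over, round-trip."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist
from scipy.stats import spearmanr

from ilvis.song import SongConfig, SongModel, init_model


@pytest.fixture(scope="module")
def blob_model():
    """Model fitted on two well-separated 10-D Gaussian blobs."""
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(0, 1, (200, 10)), rng.normal(8, 1, (200, 10))])
    model = init_model(10, seed=0)
    model.partial_fit(X)
    return model, X


class TestInit:
    def test_requires_positive_dimension(self):
        with pytest.raises(ValueError):
            init_model(0)

    def test_same_seed_same_model(self, rng):
        X = rng.normal(size=(50, 7))
        a = init_model(7, seed=3).partial_fit(X)
        b = init_model(7, seed=3).partial_fit(X)
        np.testing.assert_array_equal(a.C, b.C)
        np.testing.assert_array_equal(a.Y, b.Y)
        np.testing.assert_array_equal(a.E, b.E)

    def test_coding_vector_dimension_matches_input(self, rng):
        m = init_model(100, seed=0).partial_fit(rng.normal(size=(60, 100)))
        assert m.C.shape[1] == 100

    def test_empty_fit_is_noop(self):
        m = init_model(5, seed=0)
        m.partial_fit(np.empty((0, 5)))
        assert not m.fitted

    def test_dimension_mismatch_rejected(self, rng):
        m = init_model(5, seed=0)
        with pytest.raises(ValueError):
            m.partial_fit(rng.normal(size=(10, 6)))


class TestStructure:
    def test_bijection_between_codes_and_layout(self, blob_model):
        model, _ = blob_model
        assert model.C.shape[0] == model.Y.shape[0]

    def test_edges_symmetric_nonnegative_zero_diagonal(self, blob_model):
        model, _ = blob_model
        np.testing.assert_array_equal(model.E, model.E.T)
        assert np.all(model.E >= 0)
        assert np.all(np.diag(model.E) == 0)

    def test_cross_entropy_decreases_over_training(self, blob_model):
        model, _ = blob_model
        h = np.asarray(model.objective_history_)
        n10 = max(1, len(h) // 10)
        assert np.median(h[-n10:]) < np.median(h[:n10])

    def test_quantization_error_decreases_with_growth_threshold(self, rng):
        X = rng.normal(size=(400, 10))
        qe = []
        for coeff in (3.0, 1.0):
            cfg = SongConfig(growth_coeff=coeff, max_codes=1000, points_per_code=2)
            m = init_model(10, cfg, seed=3).partial_fit(X)
            qe.append(m.quantization_error(X))
        assert qe[1] < qe[0]


class TestEmbeddingQuality:
    def test_separated_blobs_stay_separated_in_2d(self, blob_model):
        model, X = blob_model
        Y = model.transform(X)
        within = np.concatenate([pdist(Y[:200]), pdist(Y[200:])])
        between = cdist(Y[:200], Y[200:]).ravel()
        assert np.mean(between > np.median(within)) >= 0.95

    def test_curve_in_100d_keeps_its_ordering(self):
        # data on a 1-D curve: 2D arc order must match the curve parameter
        t = np.linspace(0, 1, 300)
        rng = np.random.default_rng(1)
        X = np.outer(t, rng.normal(size=100)) + 3 * np.outer(t**2, rng.normal(size=100))
        model = init_model(100, seed=1).partial_fit(X)
        Y = model.transform(X)
        c = Y - Y.mean(axis=0)
        _, _, vt = np.linalg.svd(c, full_matrices=False)
        rho = abs(spearmanr(t, c @ vt[0]).statistic)
        assert rho >= 0.9


class TestTransform:
    def test_coding_vectors_map_exactly_to_their_layout(self, blob_model):
        model, _ = blob_model
        np.testing.assert_allclose(model.transform(model.C[:10]), model.Y[:10])

    def test_same_cell_inputs_stay_within_cell_radius(self, blob_model):
        model, X = blob_model
        Y = model.transform(X)
        d = cdist(X, model.C)
        win = d.argmin(axis=1)
        for j in np.unique(win):
            nbrs = np.nonzero(model.E[j])[0]
            if nbrs.size == 0:
                continue
            radius = np.max(np.linalg.norm(model.Y[nbrs] - model.Y[j], axis=1))
            spread = np.linalg.norm(Y[win == j] - model.Y[j], axis=1)
            assert np.all(spread <= radius + 1e-9)

    def test_unfitted_model_refuses_transform(self, rng):
        with pytest.raises(RuntimeError):
            init_model(4, seed=0).transform(rng.normal(size=(3, 4)))

    def test_transform_deterministic(self, blob_model):
        model, X = blob_model
        np.testing.assert_array_equal(model.transform(X), model.transform(X))


class TestCarryOver:
    def test_incremental_fit_keeps_old_points_stable(self, rng):
        X1 = rng.normal(0, 1, (300, 20))
        X2 = rng.normal(4, 1, (300, 20))
        m = init_model(20, seed=2).partial_fit(X1)
        before = m.transform(X1)
        m.partial_fit(np.vstack([X1, X2]))
        after = m.transform(X1)
        disp = np.mean(np.linalg.norm(after - before, axis=1))
        diag = np.linalg.norm(np.ptp(m.transform(np.vstack([X1, X2])), axis=0))
        assert disp < 0.2 * diag

    def test_growth_adds_matched_code_layout_pairs(self, rng):
        m = init_model(10, seed=0).partial_fit(rng.normal(size=(100, 10)))
        k1 = m.C.shape[0]
        m.partial_fit(rng.normal(8, 1, size=(100, 10)))
        assert m.C.shape[0] > k1
        assert m.C.shape[0] == m.Y.shape[0] == m.birth_session.size


class TestSerialization:
    def test_roundtrip_is_exact(self, blob_model, tmp_path):
        model, X = blob_model
        path = tmp_path / "model.json"
        model.save(path)
        back = SongModel.load(path)
        np.testing.assert_array_equal(back.C, model.C)
        np.testing.assert_array_equal(back.Y, model.Y)
        np.testing.assert_array_equal(back.E, model.E)
        np.testing.assert_array_equal(back.transform(X), model.transform(X))

    def test_resumed_training_equals_unbroken_run(self, rng):
        X1 = rng.normal(0, 1, (150, 8))
        X2 = rng.normal(5, 1, (150, 8))
        unbroken = init_model(8, seed=4).partial_fit(X1)
        snapshot = SongModel.from_dict(unbroken.to_dict())
        unbroken.partial_fit(np.vstack([X1, X2]))
        snapshot.partial_fit(np.vstack([X1, X2]))
        np.testing.assert_array_equal(unbroken.C, snapshot.C)
        np.testing.assert_array_equal(unbroken.Y, snapshot.Y)
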