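"""Variance loss closed forms, embedding network behaviour, and training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from lspheno.embedding import (
    EmbeddingConfig,
    EmbeddingModel,
    embed_dataset,
    train_embedding,
    variance_loss,
    variance_loss_grad,
)
from lspheno.preprocess import standardize_image


class TestVarianceLoss:
    def test_zero_variance_batch_equals_lambda_to_the_n(self):
        e = np.ones((48, 16)) * 3.7  # identical embeddings: C = lambda * I
        assert variance_loss(e, 0.2) == pytest.approx(0.2**16, rel=1e-12)
        assert variance_loss(e, 0.2) == pytest.approx(6.5536e-12, rel=1e-6)

    def test_hand_computed_two_dimensional_case(self):
        e = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 2.0], [0.0, -2.0]])
        # centered already; C = diag(2/4, 8/4) + 0.2 I = diag(0.7, 2.2)
        assert variance_loss(e, 0.2) == pytest.approx(1.54, rel=1e-12)

    def test_rotation_invariance(self):
        e = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 2.0], [0.0, -2.0]])
        rng = np.random.default_rng(0)
        for _ in range(5):
            q, _ = np.linalg.qr(rng.standard_normal((2, 2)))
            assert variance_loss(e @ q, 0.2) == pytest.approx(1.54, abs=1e-10)

    def test_centering_is_applied(self):
        e = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 2.0], [0.0, -2.0]]) + 17.0
        assert variance_loss(e, 0.2) == pytest.approx(1.54, rel=1e-9)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        arrays(np.float64, (10, 3), elements=st.floats(-50, 50)),
        st.floats(0.01, 2.0),
    )
    def test_lower_bound_lambda_to_the_n(self, e, lam):
        """det(Cov + lam I) >= lam^n, equality iff zero variance (PSD shift)."""
        val = variance_loss(e, lam)
        assert val >= lam**3 - 1e-12 * max(1.0, val)
        if np.allclose(e, e.mean(axis=0), atol=1e-12):
            assert val == pytest.approx(lam**3, rel=1e-9)

    def test_matches_brute_force_determinant(self):
        rng = np.random.default_rng(5)
        e = rng.standard_normal((30, 4)) * 3
        ec = e - e.mean(0)
        c = ec.T @ ec / 30 + 0.2 * np.eye(4)
        # cofactor-expansion determinant as an independent oracle
        def det_rec(m):
            if m.shape[0] == 1:
                return m[0, 0]
            return sum(
                (-1) ** j * m[0, j] * det_rec(np.delete(np.delete(m, 0, 0), j, 1))
                for j in range(m.shape[0])
            )

        assert variance_loss(e, 0.2) == pytest.approx(det_rec(c), rel=1e-10)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        e = rng.standard_normal((12, 4)) * 2
        det, g = variance_loss_grad(e, 0.2)
        eps = 1e-6
        for i in range(0, 12, 3):
            for j in range(4):
                e2 = e.copy()
                e2[i, j] += eps
                fp = variance_loss(e2, 0.2)
                e2[i, j] -= 2 * eps
                fm = variance_loss(e2, 0.2)
                assert g[i, j] == pytest.approx((fp - fm) / (2 * eps), rel=1e-5, abs=1e-8)

    def test_nonfinite_rejected(self):
        e = np.ones((4, 2))
        e[0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            variance_loss(e, 0.2)


class TestForward:
    def test_sequence_forward_is_deterministic_and_n_dimensional(self, tiny_embedding, tiny_dataset):
        seq = tiny_dataset.samples[0].images
        lat1, p1 = tiny_embedding.forward_sequence(seq)
        lat2, p2 = tiny_embedding.forward_sequence(seq)
        assert lat1.shape == (tiny_dataset.n_timepoints, tiny_embedding.config.n)
        assert np.array_equal(lat1, lat2) and p1 == p2
        assert 0.0 <= p1 <= 1.0
        assert np.isfinite(lat1).all()

    def test_default_latent_dimension_is_sixteen(self):
        assert EmbeddingConfig().n == 16

    def test_identical_images_identical_trajectories(self, tiny_embedding, tiny_dataset):
        seq = tiny_dataset.samples[3].images
        lat1, _ = tiny_embedding.forward_sequence(seq.copy())
        lat2, _ = tiny_embedding.forward_sequence(seq.copy())
        assert np.array_equal(lat1, lat2)


class TestTraining:
    def test_separable_circles_converge(self, tiny_embedding):
        assert tiny_embedding.converged
        assert max(tiny_embedding.training_log["val_accuracy"]) >= 0.75

    def test_training_log_reproducible_for_fixed_seed(self, tiny_split):
        train, val = tiny_split
        cfg = EmbeddingConfig(max_steps=20, early_stop_patience=3, seed=77, cnn_channels=(8, 8, 16, 16))
        a = train_embedding(train, val, cfg)
        b = train_embedding(train, val, cfg)
        assert a.training_log["step_loss"] == b.training_log["step_loss"]
        assert a.training_log["val_loss"] == b.training_log["val_loss"]

    def test_single_condition_split_rejected(self, tiny_dataset):
        from lspheno.datamodel import Condition, Dataset, DatasetValidationError

        treated_only = [s for s in tiny_dataset.samples if s.condition is Condition.treated]
        # the Dataset type itself refuses single-condition studies …
        with pytest.raises(DatasetValidationError, match="treated and one control"):
            Dataset(samples=treated_only, image_shape=tiny_dataset.image_shape)
        # … and train_embedding double-checks each split as a safety net
        bad = object.__new__(Dataset)
        bad.samples = treated_only
        bad.image_shape = tiny_dataset.image_shape
        bad.condition_pairing = None
        with pytest.raises(ValueError, match="condition"):
            train_embedding(bad, tiny_dataset, EmbeddingConfig(max_steps=5))

    def test_loss_decreases_over_first_epochs(self, tiny_embedding):
        """Smoothed training loss trends down on separable data."""
        losses = np.array(tiny_embedding.training_log["step_loss"])
        k = max(5, len(losses) // 10)
        early = losses[:k].mean()
        late = losses[-k:].mean()
        assert late < early


class TestEmbedDataset:
    def test_one_row_per_individual_timepoint(self, tiny_embedding, tiny_dataset):
        table = embed_dataset(tiny_embedding, tiny_dataset)
        assert len(table) == len(tiny_dataset.samples) * tiny_dataset.n_timepoints
        assert {f"z{i}" for i in range(16)} <= set(table.columns)

    def test_duplicate_individuals_get_equal_embeddings(self, tiny_embedding, tiny_dataset):
        s = tiny_dataset.samples[0]
        std = np.stack([standardize_image(im) for im in s.images])
        a = tiny_embedding.embed_images(std)
        b = tiny_embedding.embed_images(std)
        assert np.array_equal(a, b)

    def test_variance_term_concentrates_latent_spectrum(self, tiny_split):
        """With the generalized-variance penalty, fewer latent directions carry
        more than 1% of total variance than without it."""
        train, val = tiny_split
        base = dict(max_steps=200, early_stop_patience=10, seed=33, cnn_channels=(8, 16, 32, 64))
        with_lv = train_embedding(train, val, EmbeddingConfig(use_variance_loss=True, **base))
        without_lv = train_embedding(train, val, EmbeddingConfig(use_variance_loss=False, **base))

        def effective_dims(model):
            table = embed_dataset(model, train)
            z = table[[f"z{i}" for i in range(16)]].to_numpy()
            ev = np.linalg.eigvalsh(np.cov((z - z.mean(0)).T))
            return int((ev > 0.01 * ev.sum()).sum())

        assert effective_dims(with_lv) <= effective_dims(without_lv)


class TestPersistence:
    def test_checkpoint_round_trip(self, tiny_embedding, tiny_dataset, tmp_path):
        path = tmp_path / "emb.npz"
        tiny_embedding.save(path)
        back = EmbeddingModel.load(path)
        seq = tiny_dataset.samples[0].images
        lat1, p1 = tiny_embedding.forward_sequence(seq)
        lat2, p2 = back.forward_sequence(seq)
        assert np.array_equal(lat1, lat2) and p1 == p2
        assert back.converged == tiny_embedding.converged
        assert back.training_log["val_loss"] == tiny_embedding.training_log["val_loss"]
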