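"""Vertex planning, path initialization/optimization, and trait computation.

The key oracle: with a *linear* decoder g(z) = A z, the chain objective
sum_i ||A(z_i - z_{i-1})||^2 with fixed endpoints has the closed-form
optimum ||A (z_end - z_start)||^2 / j at equally spaced vertices, which the
gradient-based optimizer must reproduce.
"""

import numpy as np
import pytest

from lspheno.geodesic import (
    GeodesicPath,
    PathOptConfig,
    PathSpec,
    compute_traits,
    initialize_path,
    optimize_path,
    optimize_paths,
    path_trait,
    plan_vertices,
)


class LinearDecoder:
    """g(z) = A z — analytic stand-in implementing the decoder protocol."""

    def __init__(self, a: np.ndarray):
        self.a = a.astype(np.float32)

    def decode_flat(self, z):
        return z @ self.a.T

    def vjp(self, dflat):
        return dflat @ self.a


class TestPlanVertices:
    @pytest.mark.parametrize(
        "u,max_v,total,k",
        [(6, 30, 26, 4), (7, 30, 25, 3), (30, 30, 30, 0), (2, 30, 30, 28), (5, 30, 29, 6)],
    )
    def test_max_vertices_rule(self, u, max_v, total, k):
        assert plan_vertices(u, max_v) == (total, k)

    def test_budget_below_stationary_count_rejected(self):
        with pytest.raises(ValueError, match="max_vertices"):
            plan_vertices(10, 8)


class TestInitializePath:
    def test_identical_endpoints_give_degenerate_zero_path(self):
        z = np.ones((2, 4))
        path = initialize_path(z, k=4)
        assert path.n_vertices == 6
        assert np.allclose(path.vertices, 1.0)
        dec = LinearDecoder(np.eye(4))
        assert path_trait(path, dec) == 0.0

    def test_single_intermediate_is_midpoint(self):
        z0, z1 = np.zeros(3), np.array([2.0, 4.0, -2.0])
        path = initialize_path(np.stack([z0, z1]), k=1)
        assert np.allclose(path.vertices[1], (z0 + z1) / 2)

    def test_three_stationary_two_intermediates_mask(self):
        pts = np.array([[0.0], [3.0], [9.0]])
        path = initialize_path(pts, k=2)
        assert path.n_vertices == 7
        assert path.stationary_mask.tolist() == [True, False, False, True, False, False, True]
        assert np.allclose(path.vertices[:, 0], [0, 1, 2, 3, 5, 7, 9])

    def test_endpoints_must_be_stationary(self):
        with pytest.raises(ValueError, match="stationary"):
            GeodesicPath(vertices=np.zeros((3, 2)), stationary_mask=np.array([False, False, True]))


class TestOptimizeLinearOracle:
    def test_matches_closed_form_and_equal_spacing(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((6, 3))
        z0, z1 = rng.standard_normal(3), rng.standard_normal(3)
        j = 5  # segments (k=4 free vertices)
        path = initialize_path(np.stack([z0, z1]), k=j - 1)
        dec = LinearDecoder(a)
        out = optimize_path(path, dec, PathOptConfig(lr=5e-2, max_iters=800, tol=0))
        expect = float(((a @ (z1 - z0)) ** 2).sum()) / j
        assert out.trait_value == pytest.approx(expect, rel=1e-3)
        steps = np.diff(out.vertices @ a.T, axis=0)
        assert np.allclose(steps, steps[0], atol=1e-2 * np.abs(steps).max())

    def test_matches_brute_force_gradient_descent(self):
        """Independent plain-GD oracle on the same quadratic chain."""
        rng = np.random.default_rng(1)
        a = rng.standard_normal((4, 2))
        z0, z1 = rng.standard_normal(2), rng.standard_normal(2) + 2.0
        k = 3
        path = initialize_path(np.stack([z0, z1]), k=k)
        out = optimize_path(path, LinearDecoder(a), PathOptConfig(lr=5e-2, max_iters=600, tol=0))

        # brute force: flatten free vertices, descend the exact gradient
        g = a.T @ a
        verts = initialize_path(np.stack([z0, z1]), k=k).vertices.astype(np.float64)
        for _ in range(8000):
            grad = np.zeros_like(verts)
            d = verts[1:] - verts[:-1]
            grad[:-1] -= 2 * d @ g
            grad[1:] += 2 * d @ g
            grad[[0, -1]] = 0
            verts -= 0.02 * grad
        brute = sum(float((a @ (verts[i + 1] - verts[i])) @ (a @ (verts[i + 1] - verts[i]))) for i in range(k + 1))
        assert out.trait_value == pytest.approx(brute, rel=1e-3)

    def test_identical_endpoints_objective_stays_zero(self):
        z = np.full((2, 3), 2.0)
        path = initialize_path(z, k=3)
        out = optimize_path(path, LinearDecoder(np.eye(3)), PathOptConfig(max_iters=50))
        assert out.trait_value == 0.0

    def test_scaling_decoder_scales_squared_trait_quadratically(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((5, 3))
        z = rng.standard_normal((2, 3))
        cfg = PathOptConfig(lr=5e-2, max_iters=400, tol=0)
        t1 = optimize_path(initialize_path(z, 2), LinearDecoder(a), cfg).trait_value
        t3 = optimize_path(initialize_path(z, 2), LinearDecoder(3.0 * a), cfg).trait_value
        assert t3 == pytest.approx(9.0 * t1, rel=1e-3)


class TestOptimizeTrainedDecoder:
    def test_objective_trace_non_increasing(self, tiny_embedding, tiny_decoder, tiny_dataset):
        from lspheno.embedding import embed_dataset

        table = embed_dataset(tiny_embedding, tiny_dataset)
        zc = [f"z{i}" for i in range(16)]
        lat = table[table.individual_id == tiny_dataset.samples[0].individual_id].sort_values("timepoint")[zc].to_numpy()
        path = initialize_path(lat.astype(np.float32), k=2)
        out = optimize_path(path, tiny_decoder, PathOptConfig(max_iters=40))
        trace = np.array(out.objective_trace)
        assert np.all(np.diff(trace) <= 1e-9)
        assert out.trait_value <= trace[0] + 1e-9

    def test_optimized_never_worse_than_linear_init(self, tiny_decoder):
        rng = np.random.default_rng(4)
        paths, inits = [], []
        dec = tiny_decoder
        for _ in range(20):
            z = rng.standard_normal((2, 16)).astype(np.float32) * 2
            p = initialize_path(z, k=4)
            inits.append(path_trait(p, dec))
            paths.append(initialize_path(z, k=4))
        outs = optimize_paths(paths, dec, PathOptConfig(max_iters=30))
        for init_obj, out in zip(inits, outs):
            assert out.trait_value <= init_obj + 1e-6 * max(1.0, init_obj)


class TestComputeTraits:
    def test_longitudinal_one_row_per_individual(self, tiny_embedding, tiny_decoder, tiny_dataset):
        table = compute_traits(
            tiny_dataset, tiny_embedding, tiny_decoder, PathSpec(max_vertices=10), PathOptConfig(max_iters=10)
        )
        assert len(table) == len(tiny_dataset.samples)
        assert (table["trait_sq"] >= 0).all()
        assert (table["trait_len"] >= 0).all()

    def test_phase_traits_partition_total(self, tiny_embedding, tiny_decoder, tiny_dataset):
        spec = PathSpec(max_vertices=10, phases=[0, 2, 3])
        table = compute_traits(tiny_dataset, tiny_embedding, tiny_decoder, spec, PathOptConfig(max_iters=10))
        total = table["trait_sq"]
        parts = table[["trait_sq_phase0", "trait_sq_phase1"]].sum(axis=1)
        assert np.allclose(total, parts, rtol=1e-6)

    def test_cross_sectional_one_row_per_genotype(self, tiny_embedding, tiny_decoder, tiny_dataset):
        table = compute_traits(
            tiny_dataset, tiny_embedding, tiny_decoder,
            PathSpec(mode="cross_sectional", max_vertices=8), PathOptConfig(max_iters=10),
        )
        assert len(table) == len(tiny_dataset.genotype_ids())
        assert "genotype_id" in table.columns

    def test_cross_sectional_reversal_symmetry(self, tiny_embedding, tiny_decoder, tiny_dataset):
        """Swapping the endpoint order changes the trait by < 1%."""
        from lspheno.datamodel import Dataset

        flipped_pairing = {g: (c, t) for g, (t, c) in tiny_dataset.condition_pairing.items()}
        ds_flip = Dataset(
            samples=tiny_dataset.samples, image_shape=tiny_dataset.image_shape, condition_pairing=flipped_pairing
        )
        cfg = PathOptConfig(max_iters=60)
        spec = PathSpec(mode="cross_sectional", max_vertices=8)
        fwd = compute_traits(tiny_dataset, tiny_embedding, tiny_decoder, spec, cfg)
        rev = compute_traits(ds_flip, tiny_embedding, tiny_decoder, spec, cfg)
        f = fwd.set_index("genotype_id")["trait_sq"]
        r = rev.set_index("genotype_id")["trait_sq"]
        assert np.allclose(f, r[f.index], rtol=0.01)

    def test_missing_pairing_names_genotype(self, tiny_embedding, tiny_decoder, tiny_dataset):
        from lspheno.datamodel import Dataset

        pairing = dict(tiny_dataset.condition_pairing)
        victim = tiny_dataset.genotype_ids()[2]
        del pairing[victim]
        ds = Dataset(samples=tiny_dataset.samples, image_shape=tiny_dataset.image_shape, condition_pairing=pairing)
        with pytest.raises(ValueError, match=victim):
            compute_traits(ds, tiny_embedding, tiny_decoder, PathSpec(mode="cross_sectional"))

    def test_phases_invalid_boundaries_rejected(self, tiny_embedding, tiny_decoder, tiny_dataset):
        with pytest.raises(ValueError, match="phase"):
            compute_traits(
                tiny_dataset, tiny_embedding, tiny_decoder, PathSpec(phases=[0, 3, 2]), PathOptConfig(max_iters=2)
            )
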