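"""Patch extraction, angle encoding, layer schedule, and feature maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quanvnet.quantum_core import QuantumState, expect_z, full_unitary, ground_state
from quanvnet.quanvolution import (
    FeatureMap,
    PatchVector,
    VariationalParams,
    apply_layer,
    circuit_ops,
    encode,
    entangler_pairs,
    extract_patches,
    image_to_phis,
    load_feature_map,
    quanvolve_image,
    quanvolve_patch,
    quanvolve_phis,
    save_feature_map,
)


def zero_params(n_layers=1, entangler="CZ"):
    return VariationalParams(np.zeros((n_layers, 4, 3)), entangler)


def random_params(rng, n_layers=None, entangler=None):
    L = n_layers or int(rng.integers(1, 6))
    ent = entangler or ("CNOT", "CZ")[rng.integers(2)]
    return VariationalParams(rng.uniform(-np.pi, np.pi, (L, 4, 3)), ent)


class TestPatches:
    def test_single_patch_flattening_order(self):
        img = np.array([[0.1, 0.2], [0.3, 0.4]])
        (patch,) = extract_patches(img)
        assert np.allclose(patch.phi, [0.1, 0.2, 0.3, 0.4])
        assert patch.origin == (0, 0)

    def test_four_by_four_origins(self):
        patches = extract_patches(np.zeros((4, 4)))
        assert [p.origin for p in patches] == [(0, 0), (0, 2), (2, 0), (2, 2)]

    def test_patch_count(self):
        assert len(extract_patches(np.full((10, 10), 0.5))) == 25

    @settings(deadline=None, derandomize=True)
    @given(st.integers(1, 5), st.integers(1, 5), st.integers(0, 2**31 - 1))
    def test_patches_reassemble_image(self, hh, ww, seed):
        img = np.random.default_rng(seed).uniform(size=(2 * hh, 2 * ww))
        rebuilt = np.empty_like(img)
        for p in extract_patches(img):
            j, k = p.origin
            rebuilt[j : j + 2, k : k + 2] = p.phi.reshape(2, 2)
        assert np.array_equal(rebuilt, img)

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError, match="even"):
            extract_patches(np.zeros((3, 4)))

    def test_out_of_range_pixels_rejected_not_clamped(self):
        img = np.full((2, 2), 0.5)
        img[0, 0] = 1.5
        with pytest.raises(ValueError, match="normalize"):
            extract_patches(img)

    def test_patch_vector_validation(self):
        with pytest.raises(ValueError):
            PatchVector([0.1, 0.2, 0.3])
        with pytest.raises(ValueError):
            PatchVector([0.1, 0.2, 0.3, 1.4])
        with pytest.raises(ValueError):
            PatchVector([0.1] * 4, origin=(1, 0))


class TestEncoding:
    def test_zero_patch_gives_plus_states(self):
        state = encode(PatchVector([0, 0, 0, 0]))
        # H|0> per qubit: uniform positive amplitudes
        assert np.allclose(state.amplitudes, np.full(16, 0.25), atol=1e-12)
        for q in range(4):
            assert expect_z(state, q) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "value,expected", [(0.0, 0.0), (0.5, 1.0), (1.0, 0.0), (0.25, np.sqrt(2) / 2)]
    )
    def test_encoding_z_expectation_is_sine(self, value, expected):
        # closed form: <Z> after H.RY(pi x)|0> equals sin(pi x)
        state = encode(PatchVector([value] * 4))
        for q in range(4):
            assert expect_z(state, q) == pytest.approx(expected, abs=1e-12)


class TestSchedule:
    def test_printed_pair_lists(self):
        assert entangler_pairs(1) == [(0, 1), (1, 2), (2, 3), (3, 0)]
        assert entangler_pairs(2) == [(0, 2), (1, 3), (2, 0), (3, 1)]
        assert entangler_pairs(3) == [(0, 1), (2, 3), (1, 2), (3, 0)]
        assert entangler_pairs(4) == entangler_pairs(1)
        assert entangler_pairs(5) == entangler_pairs(2)

    @pytest.mark.parametrize("l", [0, 6, -1])
    def test_out_of_schedule_layer_rejected(self, l):
        with pytest.raises(ValueError):
            entangler_pairs(l)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            VariationalParams(np.zeros((6, 4, 3)))
        with pytest.raises(ValueError):
            VariationalParams(np.zeros((1, 3, 3)))
        with pytest.raises(ValueError):
            VariationalParams(np.full((1, 4, 3), np.inf))
        with pytest.raises(ValueError):
            VariationalParams(np.zeros((1, 4, 3)), "ISWAP")


class TestLayers:
    def test_zero_angle_cz_layer_preserves_z_expectations(self, rng):
        params = zero_params(n_layers=5)
        a = rng.normal(size=16) + 1j * rng.normal(size=16)
        a /= np.linalg.norm(a)
        state = QuantumState(a)
        before = [expect_z(state, q) for q in range(4)]
        for l in range(1, 6):
            out = apply_layer(state, params, l)
            after = [expect_z(out, q) for q in range(4)]
            assert np.allclose(after, before, atol=1e-12)

    def test_zero_angle_cnot_layer_hand_propagation(self):
        # |1000> -> (0,1) |1100> -> (1,2) |1110> -> (2,3) |1111> -> (3,0) |0111>
        a = np.zeros(16, dtype=complex)
        a[0b1000] = 1.0
        out = apply_layer(QuantumState(a), zero_params(entangler="CNOT"), 1)
        expected = np.zeros(16)
        expected[0b0111] = 1.0
        assert np.allclose(out.amplitudes, expected, atol=1e-12)

    def test_layer_preserves_norm(self, rng):
        params = random_params(rng)
        state = encode(PatchVector(rng.uniform(size=4)))
        out = apply_layer(state, params, 1)
        assert abs(out.norm - 1.0) < 1e-9

    def test_layer_index_beyond_depth_rejected(self):
        with pytest.raises(ValueError):
            apply_layer(ground_state(), zero_params(n_layers=2), 3)


class TestQuanvolvePatch:
    def test_zero_angle_cz_closed_form(self):
        phi = np.array([0.25, 0.5, 0.75, 1.0])
        for L in range(1, 6):
            feats = quanvolve_patch(PatchVector(phi), zero_params(n_layers=L))
            assert np.allclose(feats, np.sin(np.pi * phi), atol=1e-9)

    def test_plus_states_through_cnot_give_zero_features(self):
        feats = quanvolve_patch(PatchVector([0, 0, 0, 0]), zero_params(entangler="CNOT"))
        assert np.allclose(feats, 0.0, atol=1e-12)

    def test_matches_dense_oracle(self, rng):
        for _ in range(25):
            params = random_params(rng)
            phi = rng.uniform(size=4)
            feats = quanvolve_patch(PatchVector(phi), params)
            u = full_unitary(circuit_ops(params)).matrix
            final = QuantumState(u @ encode(PatchVector(phi)).amplitudes)
            oracle = np.array([expect_z(final, q) for q in range(4)])
            assert np.max(np.abs(feats - oracle)) < 1e-9

    def test_batched_path_matches_patch_path(self, rng):
        params = random_params(rng)
        phis = rng.uniform(size=(20, 4))
        batched = quanvolve_phis(phis, params)
        for row, phi in zip(batched, phis):
            assert np.allclose(row, quanvolve_patch(PatchVector(phi), params), atol=1e-12)

    def test_features_bounded(self, rng):
        feats = quanvolve_phis(rng.uniform(size=(50, 4)), random_params(rng))
        assert np.all(np.isfinite(feats))
        assert np.all(np.abs(feats) <= 1 + 1e-9)

    def test_deterministic(self, rng):
        params = random_params(rng)
        phi = PatchVector(rng.uniform(size=4))
        f1 = quanvolve_patch(phi, params)
        f2 = quanvolve_patch(phi, params)
        assert np.array_equal(f1, f2)


class TestQuanvolveImage:
    def test_constant_half_image_gives_all_ones(self):
        fmap = quanvolve_image(np.full((8, 8), 0.5), zero_params())
        assert np.allclose(fmap.values, 1.0, atol=1e-9)

    @pytest.mark.parametrize("size,expected", [((10, 10), (5, 5, 4)), ((28, 28), (14, 14, 4))])
    def test_output_shape_halves_spatial_dims(self, size, expected):
        fmap = quanvolve_image(np.full(size, 0.3), zero_params())
        assert fmap.shape == expected

    def test_locality_one_patch_changes_one_pixel(self, rng):
        params = random_params(rng)
        img = rng.uniform(size=(8, 8))
        base = quanvolve_image(img, params).values
        img2 = img.copy()
        img2[2:4, 4:6] = rng.uniform(size=(2, 2))  # patch at (2, 4) -> pixel (1, 2)
        changed = quanvolve_image(img2, params).values
        diff = np.abs(changed - base).sum(axis=2) > 1e-12
        assert diff[1, 2]
        diff[1, 2] = False
        assert not diff.any()

    def test_feature_map_roundtrip(self, tmp_path, rng):
        params = random_params(rng)
        fmap = quanvolve_image(rng.uniform(size=(6, 6)), params)
        path = tmp_path / "fmap.npz"
        save_feature_map(path, fmap, params)
        loaded, lparams = load_feature_map(path)
        assert np.array_equal(loaded.values, fmap.values)
        assert lparams.entangler == params.entangler
        assert np.array_equal(lparams.theta, params.theta)

    def test_odd_image_rejected(self):
        with pytest.raises(ValueError):
            quanvolve_image(np.zeros((7, 8)), zero_params())

    def test_image_to_phis_row_major(self):
        img = np.arange(16).reshape(4, 4) / 16.0
        phis = image_to_phis(img)
        assert np.allclose(phis[0], img[0:2, 0:2].ravel())
        assert np.allclose(phis[1], img[0:2, 2:4].ravel())
        assert np.allclose(phis[2], img[2:4, 0:2].ravel())
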