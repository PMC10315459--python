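import numpy as np
import pytest
from hypothesis import given, strategies as st

from facesym.io import LandmarkConfiguration, SymmetryMap
from facesym.symmetry import (
    AlignmentError,
    align_pair,
    centroid_size,
    mirror_relabel,
    object_symmetry_fit,
    reflect_relabel,
)
from tests.conftest import random_configs, small_sim


class TestMirrorRelabel:
    def test_symmetric_triangle_is_fixed_point(self, toy_map):
        cfg = LandmarkConfiguration("t", [[-1, 0], [1, 0], [0, 1]])
        out = mirror_relabel(cfg, toy_map)
        np.testing.assert_array_equal(out.coords, cfg.coords)

    def test_hand_example(self, toy_map):
        # l←reflect(r), r←reflect(l), midline reflected in place
        cfg = LandmarkConfiguration("t", [[-1, 0], [1, 0.2], [0.1, 1]])
        out = mirror_relabel(cfg, toy_map)
        np.testing.assert_allclose(
            out.coords, [[-1, 0.2], [1, 0], [-0.1, 1]], atol=1e-15
        )

    @given(st.integers(0, 10_000))
    def test_involution(self, seed):
        smap = SymmetryMap(pairs=((0, 3), (1, 4)), midline=(2, 5))
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-5, 5, size=(6, 2))
        twice = reflect_relabel(reflect_relabel(coords, smap), smap)
        np.testing.assert_array_equal(twice, coords)


class TestAlignPair:
    def test_recovers_rotation(self, rng):
        A = rng.standard_normal((7, 2))
        A -= A.mean(axis=0)
        theta = np.deg2rad(30.0)
        c, s = np.cos(theta), np.sin(theta)
        Rtrue = np.array([[c, s], [-s, c]])
        R = align_pair(A, A @ Rtrue)
        np.testing.assert_allclose(R, Rtrue, atol=1e-12)
        assert np.isclose(np.linalg.det(R), 1.0)

    def test_identity_when_equal(self, rng):
        A = rng.standard_normal((5, 2))
        A -= A.mean(axis=0)
        np.testing.assert_allclose(align_pair(A, A), np.eye(2), atol=1e-12)

    def test_beats_degree_grid(self, rng):
        # closed form must match a 1°-grid brute-force search
        for _ in range(5):
            A = rng.standard_normal((5, 2))
            B = rng.standard_normal((5, 2))
            A -= A.mean(axis=0)
            B -= B.mean(axis=0)
            resid = np.linalg.norm(A @ align_pair(A, B) - B)
            thetas = np.deg2rad(np.arange(360.0))
            best = np.inf
            for t in thetas:
                c, s = np.cos(t), np.sin(t)
                R = np.array([[c, s], [-s, c]])
                best = min(best, np.linalg.norm(A @ R - B))
            assert resid <= best + 1e-12

    def test_degenerate(self):
        with pytest.raises(AlignmentError):
            align_pair(np.zeros((4, 2)), np.ones((4, 2)) - 1.0)


class TestObjectSymmetryFit:
    def test_symmetric_dataset_has_zero_asymmetry(self, toy_map, rng):
        base = np.array([[-1.0, 0.0], [1.0, 0.0], [0.0, 1.5]])
        base -= base.mean(axis=0)
        configs = []
        for i in range(6):
            theta = rng.uniform(0, 2 * np.pi)
            c, s = np.cos(theta), np.sin(theta)
            scale = rng.uniform(0.5, 2.0)
            shift = rng.uniform(-3, 3, 2)
            stretched = base * (1 + 0.1 * i)  # size varies, shape identical
            configs.append(
                LandmarkConfiguration(
                    f"s{i}",
                    scale * (stretched @ np.array([[c, s], [-s, c]])) + shift,
                )
            )
        dec = object_symmetry_fit(configs, toy_map)
        assert np.abs(dec.asymmetric_components).max() < 1e-9
        assert np.abs(dec.directional_asymmetry).max() < 1e-9

    def test_decomposition_identities(self, small_map, rng):
        configs = random_configs(rng, small_map, 12)
        dec = object_symmetry_fit(configs, small_map)
        S, A = dec.symmetric_components, dec.asymmetric_components
        np.testing.assert_allclose(S + A, dec.original_aligned, atol=1e-9)
        np.testing.assert_allclose(S - A, dec.mirror_aligned, atol=1e-9)
        # consensus symmetric, unit size; configs centered
        assert (
            np.linalg.norm(
                dec.consensus - reflect_relabel(dec.consensus, small_map)
            )
            < 1e-8
        )
        assert abs(centroid_size(dec.consensus) - 1.0) < 1e-12
        assert np.abs(dec.original_aligned.mean(axis=1)).max() < 1e-9

    def test_ss_orthogonal_decomposition(self, small_map, rng):
        # Σ over 2n ‖X − grand mean‖² = 2Σ‖S_i − S̄‖² + 2Σ‖A_i‖² exactly
        configs = random_configs(rng, small_map, 10)
        dec = object_symmetry_fit(configs, small_map)
        Z = np.concatenate([dec.original_aligned, dec.mirror_aligned])
        grand = Z.mean(axis=0)
        total = np.sum((Z - grand) ** 2)
        S, A = dec.symmetric_components, dec.asymmetric_components
        split = 2 * np.sum((S - S.mean(axis=0)) ** 2) + 2 * np.sum(A**2)
        assert np.isclose(total, split, rtol=1e-12)

    def test_similarity_invariance(self, small_map):
        configs, _, _ = small_sim(seed=3, n=15, nuisance=False)
        dec1 = object_symmetry_fit(configs, small_map)
        rng = np.random.default_rng(8)
        moved = []
        for cfg in configs:
            theta = rng.uniform(0, 2 * np.pi)
            c, s = np.cos(theta), np.sin(theta)
            R = np.array([[c, s], [-s, c]])
            scale = rng.uniform(0.2, 5.0)
            shift = rng.uniform(-10, 10, 2)
            moved.append(
                LandmarkConfiguration(
                    cfg.specimen_id, scale * (cfg.coords @ R) + shift
                )
            )
        dec2 = object_symmetry_fit(moved, small_map)
        assert (
            np.abs(
                dec1.asymmetric_components - dec2.asymmetric_components
            ).max()
            < 1e-6
        )
        assert (
            np.abs(dec1.symmetric_components - dec2.symmetric_components).max()
            < 1e-6
        )

    def test_idempotence(self, small_map, rng):
        configs = random_configs(rng, small_map, 8)
        dec1 = object_symmetry_fit(configs, small_map)
        realigned = object_symmetry_fit(
            [
                LandmarkConfiguration(sid, dec1.original_aligned[i])
                for i, sid in enumerate(dec1.specimen_ids)
            ],
            small_map,
        )
        np.testing.assert_allclose(
            realigned.asymmetric_components,
            dec1.asymmetric_components,
            atol=1e-8,
        )
        np.testing.assert_allclose(
            realigned.consensus, dec1.consensus, atol=1e-8
        )

    def test_monotone_residuals(self, small_map, rng):
        configs = random_configs(rng, small_map, 20, spread=0.3)
        dec = object_symmetry_fit(configs, small_map)
        h = np.asarray(dec.residual_history)
        assert np.all(np.diff(h) <= 1e-12)

    def test_asymmetry_subspace_rank(self, small_map):
        # flattened A_i concentrate in a (2p+m−2)-dimensional subspace
        configs, _, _ = small_sim(seed=5, n=60)
        dec = object_symmetry_fit(configs, small_map)
        s = np.linalg.svd(dec.asym_flat, compute_uv=False)
        rank = int(np.sum(s > 1e-8 * s[0]))
        assert rank <= 2 * small_map.p + small_map.m - 2

    def test_requires_two_specimens(self, toy_map):
        cfg = LandmarkConfiguration("a", [[-1, 0], [1, 0], [0, 1]])
        with pytest.raises(ValueError, match="at least 2"):
            object_symmetry_fit([cfg], toy_map)

    def test_all_midline_degenerate_case(self):
        # p=0 is allowed: reflection only flips x
        smap = SymmetryMap(pairs=(), midline=(0, 1, 2, 3))
        rng = np.random.default_rng(4)
        configs = [
            LandmarkConfiguration(
                f"s{i}",
                np.column_stack(
                    [0.05 * rng.standard_normal(4), [0.0, 1.0, 2.0, 3.5]]
                ),
            )
            for i in range(5)
        ]
        dec = object_symmetry_fit(configs, smap)
        # symmetric component of a p=0 shape has zero x throughout
        assert np.abs(dec.symmetric_components[:, :, 0]).max() < 1e-9
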