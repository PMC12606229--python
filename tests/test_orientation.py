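"""Orientation tensors, eigen-systems, Westin measures, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctfiber import (
    StructureClass,
    Volume3D,
    WestinTriple,
    classify_structure,
    eigensystem,
    encode_tensor_rgb,
    lattice_directions,
    orientation_tensor,
    tensor_field,
    westin_measures,
)
from ctfiber.orientation import classify_field, eigensystem_field, westin_field
from oracles import naive_orientation_tensor

D1 = lattice_directions(1, antipodal_reduced=False)


def _isolated(shape=(7, 7, 7)):
    vals = np.zeros(shape, np.uint8)
    centre = tuple(s // 2 for s in shape)
    vals[centre] = 1
    return Volume3D(vals), centre


class TestOrientationTensor:
    def test_isolated_voxel_is_isotropic(self):
        mask, centre = _isolated()
        A = orientation_tensor(mask, centre, D1, cap=16)
        np.testing.assert_allclose(A, (26.0 / 3.0) * np.eye(3), atol=1e-12)
        assert np.trace(A) == pytest.approx(26.0)

    def test_infinite_fibre_hand_derived_tensor(self):
        """Fibre along z spanning the grid: diag(26/3, 26/3, 26/3 + 576)."""
        vals = np.zeros((5, 5, 40), np.uint8)
        vals[2, 2, :] = 1
        A = orientation_tensor(Volume3D(vals), (2, 2, 20), D1, cap=16)
        expected = np.diag([26.0 / 3.0, 26.0 / 3.0, 26.0 / 3.0 + 576.0])
        np.testing.assert_allclose(A, expected, atol=1e-9)

    def test_matches_naive_loop_on_random_masks(self, random_masks):
        dirs = lattice_directions(2, antipodal_reduced=False)
        (mask,) = random_masks(1, shape=(12, 12, 12))
        for idx in np.argwhere(mask.values > 0)[::37]:
            A = orientation_tensor(mask, idx, dirs, cap=8)
            np.testing.assert_allclose(
                A, naive_orientation_tensor(mask.values, tuple(idx), dirs.generators, 8),
                rtol=1e-12,
            )

    def test_psd_on_random_masks(self, random_masks):
        (mask,) = random_masks(1, shape=(10, 10, 10))
        for idx in np.argwhere(mask.values > 0)[::23]:
            A = orientation_tensor(mask, idx, D1, cap=8)
            assert np.linalg.eigvalsh(A).min() >= -1e-9

    def test_background_voxel_rejected(self):
        mask, _ = _isolated()
        with pytest.raises(ValueError, match="background"):
            orientation_tensor(mask, (0, 0, 0), D1)

    def test_reduced_directions_rejected(self):
        mask, centre = _isolated()
        with pytest.raises(ValueError, match="unreduced"):
            orientation_tensor(mask, centre, lattice_directions(1, True))


class TestTensorField:
    def test_bin1_matches_per_voxel_tensors(self, random_masks):
        (mask,) = random_masks(1, shape=(8, 8, 8))
        field = tensor_field(mask, D1, cap=4, output_bin=1)
        m = field.as_matrices()
        for idx in np.argwhere(mask.values > 0)[::11]:
            A = orientation_tensor(mask, idx, D1, cap=4)
            np.testing.assert_allclose(m[tuple(idx)], A, rtol=1e-6, atol=1e-9)

    def test_background_voxels_zero(self, random_masks):
        (mask,) = random_masks(1, shape=(8, 8, 8))
        field = tensor_field(mask, D1, cap=4, output_bin=1)
        assert np.all(field.values[mask.values == 0] == 0)

    def test_uniform_region_bin2_equals_member_tensor(self):
        # grid-spanning slab: every voxel in a mid-plane sees identical rays
        vals = np.zeros((8, 8, 8), np.uint8)
        vals[:, :, 3:6] = 1
        f1 = tensor_field(Volume3D(vals), D1, cap=16, output_bin=1)
        f2 = tensor_field(Volume3D(vals), D1, cap=16, output_bin=2)
        assert f2.spacing == pytest.approx((2.0, 2.0, 2.0))
        # block z=4..5 lies in layers 4,5 of the slab (distances to faces differ)
        member_mean = f1.values[0:2, 0:2, 4:6][vals[0:2, 0:2, 4:6] > 0].reshape(-1, 6).mean(0)
        np.testing.assert_allclose(f2.values[0, 0, 2], member_mean, rtol=1e-6)

    def test_empty_block_gives_zero_tensor(self):
        vals = np.zeros((4, 4, 4), np.uint8)
        vals[0, 0, 0] = 1
        f = tensor_field(Volume3D(vals), D1, cap=4, output_bin=2)
        assert np.all(f.values[1, 1, 1] == 0)
        assert np.any(f.values[0, 0, 0] != 0)

    def test_axis_permutation_covariance(self):
        """Swapping mask axes permutes eigenvectors and preserves eigenvalues."""
        vals = np.zeros((16, 16, 16), np.uint8)
        vals[8, 8, 2:14] = 1  # fibre along z
        A_z = orientation_tensor(Volume3D(vals), (8, 8, 8), D1, cap=8)
        A_x = orientation_tensor(Volume3D(vals.transpose(2, 1, 0)), (8, 8, 8), D1, cap=8)
        np.testing.assert_allclose(np.sort(np.linalg.eigvalsh(A_z)),
                                   np.sort(np.linalg.eigvalsh(A_x)), rtol=1e-12)
        np.testing.assert_allclose(A_x, A_z[[2, 1, 0]][:, [2, 1, 0]], rtol=1e-12, atol=1e-12)


class TestNeighborhoodMode:
    def test_fibre_still_reads_fibrous_along_axis(self):
        vals = np.zeros((9, 9, 40), np.uint8)
        vals[4, 4, :] = 1
        field = tensor_field(Volume3D(vals), D1, cap=16, mode="neighborhood",
                             neighborhood_radius=2)
        A = field.as_matrices()[4, 4, 20].astype(np.float64)
        eig = eigensystem(A)
        np.testing.assert_allclose(np.abs(eig.e1), [0, 0, 1], atol=1e-9)
        w = westin_measures(eig)
        assert classify_structure(w) == StructureClass.FIBROUS

    def test_background_stays_zero(self):
        vals = np.zeros((8, 8, 8), np.uint8)
        vals[4, 4, 4] = 1
        field = tensor_field(Volume3D(vals), D1, cap=4, mode="neighborhood")
        assert np.all(field.values[0, 0, 0] == 0)
        assert np.any(field.values[4, 4, 4] != 0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            tensor_field(Volume3D(np.ones((4, 4, 4), np.uint8)), D1, mode="spaghetti")


class TestEigensystem:
    def test_diagonal_matrix(self):
        eig = eigensystem(np.diag([2.0, 1.0, 0.0]))
        np.testing.assert_allclose(eig.eigenvalues, [2.0, 1.0, 0.0])
        np.testing.assert_allclose(np.abs(eig.e1), [1, 0, 0], atol=1e-12)

    def test_isotropic_tensor(self):
        eig = eigensystem((26.0 / 3.0) * np.eye(3))
        np.testing.assert_allclose(eig.eigenvalues, [26 / 3] * 3)

    def test_reconstruction_identity_random_dyadic_sums(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            x = rng.normal(size=(6, 3))
            A = x.T @ x
            eig = eigensystem(A)
            recon = (eig.eigenvectors * eig.eigenvalues) @ eig.eigenvectors.T
            assert np.abs(A - recon).max() <= 1e-8 * max(1.0, eig.eigenvalues[0])

    def test_orthonormal_right_handed_frame(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(5, 3))
        eig = eigensystem(x.T @ x)
        v = eig.eigenvectors
        np.testing.assert_allclose(v.T @ v, np.eye(3), atol=1e-9)
        assert np.linalg.det(v) == pytest.approx(1.0)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            eigensystem(np.array([[1.0, 1.0, 0], [0, 1, 0], [0, 0, 1]]))


class TestWestin:
    @pytest.mark.parametrize(
        "lams,expected",
        [
            ((1.0, 0.0, 0.0), (1.0, 0.0, 0.0)),
            ((1.0, 1.0, 1.0), (0.0, 0.0, 1.0)),
            ((3.0, 2.0, 1.0), (1 / 6, 1 / 3, 1 / 2)),
        ],
    )
    def test_known_triples(self, lams, expected):
        w = westin_measures(np.asarray(lams))
        assert (w.c_l, w.c_p, w.c_s) == pytest.approx(expected, abs=1e-12)

    def test_zero_trace_gives_sentinel(self):
        w = westin_measures(np.zeros(3))
        assert w.is_sentinel

    @given(
        st.tuples(
            st.floats(0.0, 1e6), st.floats(0.0, 1e6), st.floats(0.0, 1e6)
        ).filter(lambda t: sum(t) > 1e-12)
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_partition_of_unity(self, lams):
        lams = tuple(sorted(lams, reverse=True))
        w = westin_measures(np.asarray(lams))
        assert abs(w.c_l + w.c_p + w.c_s - 1.0) < 1e-9
        for c in (w.c_l, w.c_p, w.c_s):
            assert -1e-12 <= c <= 1.0 + 1e-12


class TestClassify:
    @pytest.mark.parametrize(
        "triple,theta,expected",
        [
            ((0.6, 0.3, 0.1), 0.0, StructureClass.FIBROUS),
            ((0.0, 0.0, 1.0), 0.0, StructureClass.SPHERICAL),
            ((0.4, 0.35, 0.25), 0.5, StructureClass.UNCLASSIFIED),
            ((0.4, 0.4, 0.2), 0.0, StructureClass.FIBROUS),  # tie -> fibrous
            ((0.1, 0.45, 0.45), 0.0, StructureClass.PLANAR),  # tie -> planar
        ],
    )
    def test_rules(self, triple, theta, expected):
        assert classify_structure(WestinTriple(*triple), theta) == expected

    def test_sentinel_unclassified(self):
        assert classify_structure(WestinTriple(0, 0, 0)) == StructureClass.UNCLASSIFIED

    def test_field_agrees_with_scalar(self):
        rng = np.random.default_rng(13)
        w = rng.dirichlet((1, 1, 1), size=40)
        field = classify_field(w.reshape(4, 10, 3), threshold=0.4).ravel()
        for triple, code in zip(w, field):
            assert classify_structure(WestinTriple(*triple), 0.4) == code


class TestEncodeRGB:
    def _fibre_field(self):
        vals = np.zeros((5, 5, 40), np.uint8)
        vals[2, 2, :] = 1
        return tensor_field(Volume3D(vals), D1, cap=16, output_bin=1)

    def test_e1_mode_colours_fibre_blue(self):
        rgb = encode_tensor_rgb(self._fibre_field(), "e1")
        assert tuple(rgb.values[2, 2, 8]) == (0, 0, 255)

    def test_westin_mode_pure_linear_is_red(self):
        field = self._fibre_field()
        rgb = encode_tensor_rgb(field, "westin")
        r, g, b = rgb.values[2, 2, 8]
        assert r > 200 and b < 30  # strongly linear fibre

    def test_rank_mode_palette(self):
        rgb = encode_tensor_rgb(self._fibre_field(), "rank")
        assert tuple(rgb.values[2, 2, 8]) == (255, 0, 0)  # fibrous = red
        assert tuple(rgb.values[0, 0, 0]) == (0, 0, 0)  # background = black

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            encode_tensor_rgb(self._fibre_field(), "e3")


def test_eigensystem_field_matches_scalar(random_masks):
    (mask,) = random_masks(1, shape=(6, 6, 6))
    field = tensor_field(mask, D1, cap=4)
    w, v = eigensystem_field(field)
    for idx in np.argwhere(mask.values > 0)[::9]:
        eig = eigensystem(field.as_matrices()[tuple(idx)].astype(np.float64))
        np.testing.assert_allclose(w[tuple(idx)], eig.eigenvalues, rtol=1e-5, atol=1e-5)
        # eigenvectors may differ by sign under degeneracy; compare projectors
        P1 = np.outer(v[tuple(idx)][:, 0], v[tuple(idx)][:, 0])
        P2 = np.outer(eig.e1, eig.e1)
        if w[tuple(idx)][0] - w[tuple(idx)][1] > 1e-6 * w[tuple(idx)][0]:
            np.testing.assert_allclose(P1, P2, atol=1e-4)
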