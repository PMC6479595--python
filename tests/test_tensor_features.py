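import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from phyto3d import (
    NeighborhoodSpec,
    PointCloud,
    compute_tensor_field,
    find_neighbors,
    first_order_tensor,
    saliency_decompose,
    saliency_tensors,
    second_order_tensor,
    spectral_decompose,
)


def _cloud(points):
    return PointCloud(points=np.asarray(points, dtype=float), frame="metric")


def _disc_cloud(n=600, radius=0.1, sigma=0.0, seed=0):
    rng = np.random.default_rng(seed)
    r = radius * np.sqrt(rng.uniform(0, 1, n))
    phi = rng.uniform(0, 2 * np.pi, n)
    z = rng.normal(0, sigma, n) if sigma > 0 else np.zeros(n)
    return _cloud(np.column_stack([r * np.cos(phi), r * np.sin(phi), z]))


class TestNeighbors:
    def test_collinear_points_take_line_neighbors(self):
        cloud = _cloud([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        nbrs = find_neighbors(cloud, NeighborhoodSpec(k=2, min_neighbors=3))
        assert sorted(nbrs.indices[0].tolist()) == [1, 2]
        assert sorted(nbrs.indices[1].tolist()) == [0, 2]
        assert sorted(nbrs.indices[3].tolist()) == [1, 2]

    def test_radius_below_spacing_flags_all_degenerate(self):
        cloud = _cloud([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        nbrs = find_neighbors(
            cloud, NeighborhoodSpec(mode="radius", r=0.5, min_neighbors=3)
        )
        assert nbrs.degenerate.all()

    def test_knn_matches_brute_force_sort(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(size=(200, 3))
        cloud = _cloud(pts)
        nbrs = find_neighbors(cloud, NeighborhoodSpec(k=10, min_neighbors=3))
        d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        for i in range(200):
            expected = set(np.argsort(d2[i])[:10].tolist())
            assert set(nbrs.indices[i].tolist()) == expected

    def test_cloud_smaller_than_k_raises(self):
        cloud = _cloud(np.eye(3))
        with pytest.raises(ValueError, match="k\\+1"):
            find_neighbors(cloud, NeighborhoodSpec(k=5, min_neighbors=3))


def _manual_neighborhood(center, neighbors):
    """Cloud with one query point and explicit neighbors via radius mode."""
    pts = np.vstack([center, neighbors])
    cloud = _cloud(pts)
    spec = NeighborhoodSpec(mode="radius", r=1e6, min_neighbors=3)
    return cloud, find_neighbors(cloud, spec)


class TestFirstOrder:
    def test_symmetric_neighbors_cancel(self):
        cloud, nbrs = _manual_neighborhood(
            [0, 0, 0], [[0.3, 0, 0], [-0.3, 0, 0], [0, 0.3, 0], [0, -0.3, 0]]
        )
        t = first_order_tensor(cloud, nbrs)
        np.testing.assert_allclose(t[0], 0.0, atol=1e-12)

    def test_single_neighbor_sign_convention(self):
        # t_i = sum(x_i - x_j): a neighbor at +x gives t = -x
        cloud, nbrs = _manual_neighborhood(
            [0, 0, 0], [[1, 0, 0], [0, 1e-9, 0], [0, 0, 1e-9]]
        )
        t = first_order_tensor(cloud, nbrs)
        np.testing.assert_allclose(t[0], [-1, -1e-9, -1e-9], atol=1e-15)

    def test_asymmetric_neighbors_match_hand_summation(self):
        rng = np.random.default_rng(3)
        center = np.array([0.2, -0.1, 0.5])
        neigh = center + rng.normal(scale=0.05, size=(5, 3))
        cloud, nbrs = _manual_neighborhood(center, neigh)
        t = first_order_tensor(cloud, nbrs)
        expected = np.sum(center - neigh, axis=0)
        np.testing.assert_allclose(t[0], expected, atol=1e-12)


class TestSecondOrder:
    def test_axial_pair_gives_single_eigendirection(self):
        cloud, nbrs = _manual_neighborhood([0, 0, 0], [[1, 0, 0], [-1, 0, 0], [0.5, 0, 0]])
        T = second_order_tensor(cloud, nbrs)
        np.testing.assert_allclose(T[0], np.diag([2.25, 0, 0]), atol=1e-12)

    def test_planar_quad_gives_two_eigendirections(self):
        cloud, nbrs = _manual_neighborhood(
            [0, 0, 0], [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]]
        )
        T = second_order_tensor(cloud, nbrs)
        np.testing.assert_allclose(T[0], np.diag([2, 2, 0]), atol=1e-12)

    def test_matches_brute_force_outer_products(self):
        rng = np.random.default_rng(8)
        center = rng.normal(size=3)
        neigh = center + rng.normal(size=(8, 3))
        cloud, nbrs = _manual_neighborhood(center, neigh)
        T = second_order_tensor(cloud, nbrs)
        expected = np.zeros((3, 3))
        for p in neigh:
            d = p - center
            expected += np.outer(d, d)
        np.testing.assert_allclose(T[0], expected, atol=1e-12)


class TestSpectral:
    def test_known_diagonal_eigenvalues(self):
        vals, vecs = spectral_decompose(np.diag([2.0, 2.0, 0.0]))
        np.testing.assert_allclose(vals, [2, 2, 0], atol=1e-12)
        np.testing.assert_allclose(vecs @ vecs.T, np.eye(3), atol=1e-10)

    def test_rotation_preserves_eigenvalues(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(3, 3))
        T = A @ A.T
        R = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        vals, _ = spectral_decompose(T)
        vals_rot, _ = spectral_decompose(R @ T @ R.T)
        np.testing.assert_allclose(vals, vals_rot, atol=1e-10)

    def test_reconstruction_of_random_psd(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            A = rng.normal(size=(3, 3))
            T = A @ A.T
            vals, vecs = spectral_decompose(T)
            recon = vecs @ np.diag(vals) @ vecs.T
            assert np.linalg.norm(recon - T) < 1e-8 * max(np.linalg.norm(T), 1)
            assert (vals >= 0).all()
            assert (np.diff(vals) <= 1e-12).all()

    def test_non_finite_tensor_raises(self):
        T = np.full((3, 3), np.nan)
        with pytest.raises(ValueError, match="finite"):
            spectral_decompose(T)


class TestSaliency:
    def test_pure_stick(self):
        s = saliency_decompose(np.array([5.0, 0.0, 0.0]))
        np.testing.assert_allclose(s, [5, 0, 0])

    def test_pure_plate(self):
        s = saliency_decompose(np.array([3.0, 3.0, 0.0]))
        np.testing.assert_allclose(s, [0, 3, 0])

    def test_unsorted_eigenvalues_raise(self):
        with pytest.raises(ValueError, match="descending"):
            saliency_decompose(np.array([1.0, 3.0, 0.0]))

    def test_component_tensors_sum_back(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(3, 3))
        T = A @ A.T
        vals, vecs = spectral_decompose(T)
        stick, plate, sphere = saliency_tensors(vals, vecs)
        np.testing.assert_allclose(stick + plate + sphere, T, atol=1e-9)

    def test_disc_patch_is_plate_dominated(self):
        cloud = _disc_cloud()
        field = compute_tensor_field(cloud, NeighborhoodSpec(k=30))
        sal = field.saliencies
        r = np.linalg.norm(cloud.points[:, :2], axis=1)
        interior = (r < 0.08) & ~field.degenerate  # rim neighborhoods are
        plate_wins = (                             # legitimately stick-like
            (sal[interior, 1] > sal[interior, 0])
            & (sal[interior, 1] > sal[interior, 2])
        )
        assert plate_wins.mean() > 0.9


class TestFieldInvariances:
    def test_translation_leaves_tensors_unchanged(self):
        cloud = _disc_cloud(n=200, sigma=0.002)
        spec = NeighborhoodSpec(k=15)
        f0 = compute_tensor_field(cloud, spec)
        shifted = PointCloud(points=cloud.points + [5.0, -3.0, 11.0], frame="metric")
        f1 = compute_tensor_field(shifted, spec)
        np.testing.assert_allclose(f1.T, f0.T, atol=1e-9)
        np.testing.assert_allclose(
            np.linalg.norm(f1.t, axis=1), np.linalg.norm(f0.t, axis=1), atol=1e-9
        )

    def test_rotation_preserves_eigenvalues_and_rotates_frames(self):
        cloud = _disc_cloud(n=200, sigma=0.002, seed=9)
        spec = NeighborhoodSpec(k=15)
        f0 = compute_tensor_field(cloud, spec)
        R = Rotation.from_rotvec([0.5, 0.2, -0.9]).as_matrix()
        f1 = compute_tensor_field(
            PointCloud(points=cloud.points @ R.T, frame="metric"), spec
        )
        np.testing.assert_allclose(f1.eigvals, f0.eigvals, atol=1e-9)
        # rotated tensors are conjugate by R
        np.testing.assert_allclose(
            f1.T, np.einsum("ij,njk,lk->nil", R, f0.T, R), atol=1e-9
        )

    def test_collinear_neighborhood_has_single_eigenvalue(self):
        pts = np.column_stack([np.linspace(0, 1, 30), np.zeros(30), np.zeros(30)])
        field = compute_tensor_field(_cloud(pts), NeighborhoodSpec(k=5, min_neighbors=3))
        ok = ~field.degenerate
        assert (field.eigvals[ok, 1] <= 1e-10 * field.eigvals[ok, 0]).all()
        assert (field.eigvals[ok, 2] <= 1e-10 * field.eigvals[ok, 0]).all()

    def test_coplanar_neighborhood_has_zero_third_eigenvalue(self):
        field = compute_tensor_field(_disc_cloud(n=200), NeighborhoodSpec(k=10))
        ok = ~field.degenerate
        assert (field.eigvals[ok, 2] <= 1e-10 * field.eigvals[ok, 0]).all()

    def test_noisy_lamina_flatness_stays_below_ten_percent(self):
        # interior points of a planar patch keep lambda3 <= 0.1 lambda1
        # when the neighborhood footprint dominates the surface noise
        cloud = _disc_cloud(n=900, radius=0.15, sigma=0.002, seed=1)
        field = compute_tensor_field(cloud, NeighborhoodSpec(k=30))
        r = np.linalg.norm(cloud.points[:, :2], axis=1)
        interior = (r < 0.15 - 0.035) & ~field.degenerate
        ratio = field.eigvals[interior, 2] / field.eigvals[interior, 0]
        assert (ratio <= 0.1).mean() >= 0.95
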