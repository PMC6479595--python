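"""First- and second-order tensor fields over local point neighborhoods.

Each point x_i gets a first-order tensor t_i = sum_{j in sigma} (x_i - x_j)
(a vector whose magnitude grows with the asymmetry of the neighborhood) and
an unnormalized second-order tensor T_i = sum_{j} (x_j - x_i)(x_j - x_i)^T.
The sorted eigenvalues lambda1 >= lambda2 >= lambda3 >= 0 of T_i encode the
local shape: one dominant eigenvalue means an elongated, axial arrangement
(stem), two comparable ones with a small third mean a surface patch (leaf
lamina), and three comparable ones an isotropic blob.  The saliencies
(stick, plate, sphere) = (l1 - l2, l2 - l3, l3) weight the corresponding
rank-1/2/3 component tensors, which sum back to T_i.

Tensors are left unnormalized; every classification criterion downstream is
a ratio of eigenvalues (or a normalized first-order magnitude), so the
overall scale cancels and the results are invariant to a global rescaling
of the cloud.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .pointcloud_io import PointCloud

__all__ = [
    "NeighborhoodSpec",
    "Neighborhoods",
    "TensorField",
    "find_neighbors",
    "first_order_tensor",
    "second_order_tensor",
    "spectral_decompose",
    "saliency_decompose",
    "saliency_tensors",
    "compute_tensor_field",
]


@dataclass
class NeighborhoodSpec:
    """How to pick the neighborhood sigma of each point.

    knn mode takes the k nearest points (excluding the point itself) and is
    density-adaptive, which suits multi-view-stereo clouds whose sampling
    density varies with viewing geometry.  radius mode takes every point
    within r meters.  Points ending up with fewer than ``min_neighbors``
    are flagged degenerate and excluded from classification.
    """

    mode: str = "knn"
    k: int = 30
    r: float = 0.02
    min_neighbors: int = 8

    def __post_init__(self) -> None:
        if self.mode not in ("knn", "radius"):
            raise ValueError(f"mode must be 'knn' or 'radius'; got {self.mode!r}")
        if self.mode == "knn" and self.k < 1:
            raise ValueError("k must be >= 1")
        if self.mode == "radius" and self.r <= 0:
            raise ValueError("radius must be positive")
        if self.min_neighbors < 3:
            raise ValueError("min_neighbors must be >= 3")


@dataclass
class Neighborhoods:
    """Per-point neighbor index lists plus degeneracy bookkeeping."""

    indices: list[np.ndarray]
    counts: np.ndarray
    degenerate: np.ndarray  # True where count < min_neighbors
    mean_dist: np.ndarray  # mean Euclidean distance to the neighbors

    def __len__(self) -> int:
        return len(self.indices)


def find_neighbors(cloud: PointCloud, spec: NeighborhoodSpec) -> Neighborhoods:
    """Neighbor index lists for every point (self always excluded)."""
    pts = cloud.points
    n = pts.shape[0]
    tree = cKDTree(pts)
    if spec.mode == "knn":
        if n < spec.k + 1:
            raise ValueError(
                f"knn mode needs at least k+1={spec.k + 1} points; cloud has {n}"
            )
        dist, idx = tree.query(pts, k=spec.k + 1)
        indices, mean_dist = [], np.empty(n)
        for i in range(n):
            row, drow = idx[i], dist[i]
            keep = row != i
            # with exact duplicates the self column may not be first; always
            # trim back to exactly k neighbors
            row, drow = row[keep][: spec.k], drow[keep][: spec.k]
            indices.append(row)
            mean_dist[i] = drow.mean() if row.size else np.nan
        counts = np.full(n, spec.k)
    else:
        balls = tree.query_ball_point(pts, spec.r)
        indices, mean_dist = [], np.empty(n)
        counts = np.empty(n, dtype=np.int64)
        for i, ball in enumerate(balls):
            row = np.asarray([j for j in ball if j != i], dtype=np.int64)
            indices.append(row)
            counts[i] = row.size
            mean_dist[i] = (
                np.linalg.norm(pts[row] - pts[i], axis=1).mean()
                if row.size
                else np.nan
            )
    degenerate = counts < spec.min_neighbors
    return Neighborhoods(indices, counts, degenerate, mean_dist)


def _uniform_index_array(nbrs: Neighborhoods) -> np.ndarray | None:
    """(N, k) index matrix when every point has the same neighbor count."""
    counts = nbrs.counts
    if counts.size and (counts == counts[0]).all() and counts[0] > 0:
        return np.vstack(nbrs.indices)
    return None


def first_order_tensor(cloud: PointCloud, nbrs: Neighborhoods) -> np.ndarray:
    """t_i = sum_{j in sigma} (x_i - x_j); NaN for degenerate points."""
    pts = cloud.points
    t = np.full((len(nbrs), 3), np.nan)
    idx = _uniform_index_array(nbrs)
    if idx is not None:
        k = idx.shape[1]
        t = k * pts - pts[idx].sum(axis=1)
    else:
        for i, row in enumerate(nbrs.indices):
            if row.size:
                t[i] = row.size * pts[i] - pts[row].sum(axis=0)
    t[nbrs.degenerate] = np.nan
    return t


def second_order_tensor(cloud: PointCloud, nbrs: Neighborhoods) -> np.ndarray:
    """T_i = sum_{j in sigma} (x_j - x_i)(x_j - x_i)^T, unnormalized."""
    pts = cloud.points
    T = np.full((len(nbrs), 3, 3), np.nan)
    idx = _uniform_index_array(nbrs)
    if idx is not None:
        d = pts[idx] - pts[:, None, :]  # (N, k, 3)
        T = np.einsum("nkj,nkl->njl", d, d)
    else:
        for i, row in enumerate(nbrs.indices):
            if row.size:
                d = pts[row] - pts[i]
                T[i] = d.T @ d
    T[nbrs.degenerate] = np.nan
    return T


def spectral_decompose(T: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of one or many symmetric PSD 3x3 tensors.

    Returns eigenvalues sorted descending and the matching eigenvectors as
    matrix columns (``vecs[..., :, m]`` is the m-th eigenvector).  The
    input is symmetrized defensively; tiny negative eigenvalues from
    round-off are clamped to zero; eigenvector signs follow the
    first-nonzero-component-positive convention so decompositions are
    reproducible under eigenvalue ties.
    """
    T = np.asarray(T, dtype=np.float64)
    single = T.ndim == 2
    if single:
        T = T[None]
    if T.shape[-2:] != (3, 3):
        raise ValueError(f"expected (..., 3, 3) tensors; got shape {T.shape}")
    finite = np.isfinite(T).all(axis=(-2, -1))
    if single and not finite[0]:
        raise ValueError("tensor contains non-finite entries")
    Ts = 0.5 * (T + np.swapaxes(T, -1, -2))
    vals = np.full(T.shape[:-2] + (3,), np.nan)
    vecs = np.full(T.shape, np.nan)
    if finite.any():
        w, v = np.linalg.eigh(Ts[finite])
        w = w[:, ::-1]  # descending
        v = v[:, :, ::-1]
        scale = np.maximum(np.abs(w[:, 0]), 1.0)
        w = np.where(w < 0, np.where(w >= -1e-10 * scale[:, None], 0.0, w), w)
        # sign convention: first component of magnitude > tol positive
        for m in range(3):
            col = v[:, :, m]
            lead = np.where(
                np.abs(col[:, 0]) > 1e-12,
                col[:, 0],
                np.where(np.abs(col[:, 1]) > 1e-12, col[:, 1], col[:, 2]),
            )
            v[:, :, m] = col * np.where(lead < 0, -1.0, 1.0)[:, None]
        vals[finite] = w
        vecs[finite] = v
    if single:
        return vals[0], vecs[0]
    return vals, vecs


def saliency_decompose(
    eigvals: np.ndarray, eigvecs: np.ndarray | None = None
) -> np.ndarray:
    """(stick, plate, sphere) = (l1 - l2, l2 - l3, l3) saliencies.

    Input eigenvalues must already be sorted descending.
    """
    w = np.asarray(eigvals, dtype=np.float64)
    finite = np.isfinite(w).all(axis=-1)
    sorted_ok = (np.diff(w, axis=-1) <= 1e-12 * np.maximum(
        np.abs(w[..., :1]), 1e-300)).all(axis=-1)
    if not np.logical_or(~finite, sorted_ok).all():
        raise ValueError("eigenvalues must be sorted in descending order")
    return np.stack(
        [w[..., 0] - w[..., 1], w[..., 1] - w[..., 2], w[..., 2]], axis=-1
    )


def saliency_tensors(
    eigvals: np.ndarray, eigvecs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stick, plate and sphere component tensors; they sum back to T.

    stick  = (l1-l2) v1 v1^T
    plate  = (l2-l3) (v1 v1^T + v2 v2^T)
    sphere =  l3     (v1 v1^T + v2 v2^T + v3 v3^T)
    """
    s = saliency_decompose(eigvals)
    v1, v2, v3 = (eigvecs[..., :, m] for m in range(3))
    P1 = np.einsum("...i,...j->...ij", v1, v1)
    P2 = P1 + np.einsum("...i,...j->...ij", v2, v2)
    P3 = P2 + np.einsum("...i,...j->...ij", v3, v3)
    return (
        s[..., 0, None, None] * P1,
        s[..., 1, None, None] * P2,
        s[..., 2, None, None] * P3,
    )


@dataclass
class TensorField:
    """The full per-point tensor description of a cloud."""

    t: np.ndarray  # (N, 3) first-order tensors
    T: np.ndarray  # (N, 3, 3) second-order tensors
    eigvals: np.ndarray  # (N, 3) descending
    eigvecs: np.ndarray  # (N, 3, 3), columns are eigenvectors
    saliencies: np.ndarray  # (N, 3) stick, plate, sphere
    neighborhoods: Neighborhoods
    spec: NeighborhoodSpec = field(default_factory=NeighborhoodSpec)

    def __len__(self) -> int:
        return self.t.shape[0]

    @property
    def t_mag(self) -> np.ndarray:
        return np.linalg.norm(self.t, axis=1)

    @property
    def t_mag_normalized(self) -> np.ndarray:
        """|t_i| / (neighbor count x mean neighbor distance), in [0, 1].

        An interior point of a uniformly sampled surface has a nearly
        symmetric neighborhood and a normalized magnitude close to 0; a
        point on a surface boundary approaches ~0.6.
        """
        nb = self.neighborhoods
        denom = nb.counts * nb.mean_dist
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.t_mag / denom

    @property
    def degenerate(self) -> np.ndarray:
        return self.neighborhoods.degenerate


def compute_tensor_field(
    cloud: PointCloud, spec: NeighborhoodSpec | None = None
) -> TensorField:
    """Neighborhoods, both tensors and the spectral/saliency decomposition."""
    spec = spec or NeighborhoodSpec()
    nbrs = find_neighbors(cloud, spec)
    t = first_order_tensor(cloud, nbrs)
    T = second_order_tensor(cloud, nbrs)
    eigvals, eigvecs = spectral_decompose(T)
    sal = np.full_like(eigvals, np.nan)
    ok = np.isfinite(eigvals).all(axis=1)
    if ok.any():
        sal[ok] = saliency_decompose(eigvals[ok])
    return TensorField(
        t=t, T=T, eigvals=eigvals, eigvecs=eigvecs, saliencies=sal,
        neighborhoods=nbrs, spec=spec,
    )
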