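"""Whole-plant morphology: height, width and voxel-occupancy volume.

Height is the difference between the maximal and minimal z ordinates.
Width is the planar diameter: project every point onto the x-y plane and
take the maximal pairwise distance.  Volume is estimated by partitioning
space into cubic voxels, discarding connected voxel sets smaller than
five cells as reconstruction noise, and summing the surviving occupied
cells.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from warnings import warn

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .pointcloud_io import PointCloud

__all__ = [
    "VoxelGrid",
    "MorphologyReport",
    "plant_height",
    "plant_width",
    "voxelize",
    "filter_voxel_noise",
    "plant_volume",
    "morphology_report",
]


@dataclass
class VoxelGrid:
    """Occupied cubic cells of a spatial partition of the cloud.

    ``occupied`` holds the integer (i, j, k) indices of cells containing
    at least one point; ``components`` partitions them into connected
    sets under the stated connectivity (26 = faces+edges+corners,
    6 = faces only).
    """

    voxel_size: float
    origin: np.ndarray  # (3,) minimum corner of the cloud
    occupied: np.ndarray  # (M, 3) integer indices, unique
    connectivity: int = 26
    components: list[np.ndarray] | None = None  # index arrays into occupied

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")

    @property
    def n_occupied(self) -> int:
        return self.occupied.shape[0]

    def with_components(self) -> "VoxelGrid":
        """Label connected components of the occupied set."""
        if self.components is not None:
            return self
        if self.n_occupied == 0:
            return replace(self, components=[])
        lo = self.occupied.min(axis=0)
        shape = self.occupied.max(axis=0) - lo + 1
        dense = np.zeros(shape, dtype=bool)
        rel = self.occupied - lo
        dense[rel[:, 0], rel[:, 1], rel[:, 2]] = True
        structure = ndimage.generate_binary_structure(
            3, 3 if self.connectivity == 26 else 1
        )
        labeled, ncomp = ndimage.label(dense, structure=structure)
        comp_of_voxel = labeled[rel[:, 0], rel[:, 1], rel[:, 2]]
        components = [
            np.flatnonzero(comp_of_voxel == c) for c in range(1, ncomp + 1)
        ]
        return replace(self, components=components)


@dataclass
class MorphologyReport:
    """The four morphology parameters of one plant at one session."""

    height: float  # m
    width: float  # m
    volume: float  # m^3
    first_internode: float | None = None  # m
    plant_id: str | None = None
    group: str | None = None
    gdd: float | None = None

    def to_dict(self) -> dict:
        """Flat record with lengths in cm, as printed in reports."""
        return {
            "plant_id": self.plant_id,
            "group": self.group,
            "gdd": self.gdd,
            "height_cm": self.height * 100.0,
            "width_cm": self.width * 100.0,
            "volume_m3": self.volume,
            "first_internode_cm": (
                None if self.first_internode is None
                else self.first_internode * 100.0
            ),
        }


def plant_height(cloud: PointCloud) -> float:
    """max(z) - min(z) of the cropped, metric plant cloud."""
    cloud.require_metric()
    z = cloud.points[:, 2]
    return float(z.max() - z.min())


def plant_width(cloud: PointCloud) -> float:
    """Planar diameter: maximal pairwise distance of the x-y projection.

    Computed on the planar convex hull vertices, which is equivalent to
    the brute-force maximum over all point pairs.
    """
    cloud.require_metric()
    xy = cloud.points[:, :2]
    n = xy.shape[0]
    if n == 1:
        return 0.0
    if n > 4:
        try:
            xy = xy[ConvexHull(xy).vertices]
        except QhullError:
            pass  # degenerate (collinear) projection: brute force below
    d2 = np.sum((xy[:, None, :] - xy[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def voxelize(cloud: PointCloud, voxel_size: float, connectivity: int = 26) -> VoxelGrid:
    """Partition the cloud into cubic cells anchored at its minimum corner."""
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    cloud.require_metric()
    origin = cloud.points.min(axis=0)
    idx = np.floor((cloud.points - origin) / voxel_size).astype(np.int64)
    occupied = np.unique(idx, axis=0)
    return VoxelGrid(
        voxel_size=voxel_size,
        origin=origin,
        occupied=occupied,
        connectivity=connectivity,
    )


def filter_voxel_noise(grid: VoxelGrid, min_cells: int = 5) -> VoxelGrid:
    """Discard connected voxel sets smaller than ``min_cells`` cells.

    Sets of connected voxels below the five-cell default are treated as
    reconstruction noise.  Surviving components are untouched, so the
    filter is idempotent.
    """
    grid = grid.with_components()
    keep_components = [c for c in grid.components if c.size >= min_cells]
    if not keep_components:
        warn("voxel noise filter removed every component", stacklevel=2)
        return replace(
            grid,
            occupied=np.empty((0, 3), dtype=np.int64),
            components=[],
        )
    keep = np.concatenate(keep_components)
    keep.sort()
    occupied = grid.occupied[keep]
    # re-index components into the compacted occupied array
    pos = np.empty(grid.occupied.shape[0], dtype=np.int64)
    pos[keep] = np.arange(keep.size)
    components = [np.sort(pos[c]) for c in keep_components]
    return replace(grid, occupied=occupied, components=components)


def plant_volume(grid: VoxelGrid) -> float:
    """Occupied-cell count x cell volume, on a noise-filtered grid."""
    if grid.n_occupied == 0:
        warn("empty voxel grid: volume is 0", stacklevel=2)
        return 0.0
    return float(grid.n_occupied * grid.voxel_size**3)


def morphology_report(
    cloud: PointCloud,
    voxel_size: float = 0.01,
    first_internode: float | None = None,
    min_cells: int = 5,
    connectivity: int = 26,
    **meta,
) -> MorphologyReport:
    """Height, width and noise-filtered voxel volume of one plant cloud.

    Volume uses all plant points (stem, leaf and unassigned alike); the
    default 1 cm voxel roughly matches multi-view-stereo point spacing at
    a ~1 m imaging range.
    """
    grid = filter_voxel_noise(
        voxelize(cloud, voxel_size, connectivity), min_cells=min_cells
    )
    return MorphologyReport(
        height=plant_height(cloud),
        width=plant_width(cloud),
        volume=plant_volume(grid),
        first_internode=first_internode,
        **meta,
    )
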