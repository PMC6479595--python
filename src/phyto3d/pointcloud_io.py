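"""Point-cloud input/output, metric scaling and scene cropping.

Multi-view-stereo reconstructions cover the whole scene (plant, pot, soil,
background) in an arbitrary, dimensionless coordinate frame.  Downstream
morphology needs a metric, plant-only cloud with gravity along +z.  This
module reads/writes the common exchange formats (PLY ascii/binary, XYZ,
CSV), rescales the cloud from one known reference length, and crops the
plant with an axis-aligned box plus an optional soil elevation cut.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "PointCloud",
    "CropSpec",
    "read_cloud",
    "write_cloud",
    "scale_cloud",
    "crop_cloud",
    "estimate_soil_z",
]

# PLY scalar type names -> numpy little-endian dtypes
_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "<i2", "int16": "<i2",
    "ushort": "<u2", "uint16": "<u2",
    "int": "<i4", "int32": "<i4",
    "uint": "<u4", "uint32": "<u4",
    "float": "<f4", "float32": "<f4",
    "double": "<f8", "float64": "<f8",
}


@dataclass
class PointCloud:
    """An ordered set of 3-D points, optionally coloured.

    ``frame`` records whether coordinates are still in the arbitrary
    reconstruction units (``"raw"``) or in meters (``"metric"``); every
    geometric operation downstream requires a metric cloud.  ``z_up``
    asserts that gravity is along +z (clouds reconstructed in another
    convention must be rotated before use).
    """

    points: np.ndarray
    colors: np.ndarray | None = None
    frame: str = "raw"
    z_up: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"points must be (N, 3); got shape {pts.shape}")
        if pts.shape[0] < 1:
            raise ValueError("point cloud must contain at least one point")
        if not np.isfinite(pts).all():
            raise ValueError("point coordinates must be finite")
        if self.frame not in ("raw", "metric"):
            raise ValueError(f"frame must be 'raw' or 'metric'; got {self.frame!r}")
        self.points = pts
        if self.colors is not None:
            col = np.asarray(self.colors, dtype=np.uint8)
            if col.shape != (pts.shape[0], 3):
                raise ValueError("colors must be (N, 3) to match points")
            self.colors = col

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def is_metric(self) -> bool:
        return self.frame == "metric"

    def require_metric(self) -> None:
        if not self.is_metric:
            raise ValueError(
                "operation requires a metric cloud; apply scale_cloud first"
            )


@dataclass
class CropSpec:
    """Axis-aligned crop box (meters) with an optional soil cut.

    Points strictly below ``soil_z`` are discarded in addition to points
    outside the box.  Bounds are inclusive.
    """

    min_corner: tuple[float, float, float] = (-np.inf, -np.inf, -np.inf)
    max_corner: tuple[float, float, float] = (np.inf, np.inf, np.inf)
    soil_z: float | None = None
    _lo: np.ndarray = field(init=False, repr=False)
    _hi: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        lo = np.asarray(self.min_corner, dtype=np.float64)
        hi = np.asarray(self.max_corner, dtype=np.float64)
        if lo.shape != (3,) or hi.shape != (3,):
            raise ValueError("crop corners must be 3-vectors")
        if not (lo < hi).all():
            raise ValueError("crop box must satisfy min < max on every axis")
        self._lo, self._hi = lo, hi

    def mask(self, points: np.ndarray) -> np.ndarray:
        """Boolean keep-mask for an (N, 3) coordinate array."""
        keep = ((points >= self._lo) & (points <= self._hi)).all(axis=1)
        if self.soil_z is not None:
            keep &= points[:, 2] >= self.soil_z
        return keep


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_cloud(path: str | Path, format: str | None = None) -> PointCloud:
    """Read a point cloud from PLY, XYZ or CSV.

    ``format`` is inferred from the file suffix when not given.  The
    returned cloud is in the raw frame and preserves file point order.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "ply":
        points, colors = _read_ply(path)
    elif fmt == "xyz":
        points, colors = _read_xyz(path), None
    elif fmt == "csv":
        points, colors = _read_csv(path), None
    else:
        raise ValueError(f"unsupported point-cloud format: {fmt!r}")
    if points.shape[0] == 0:
        raise ValueError(f"{path}: empty point cloud")
    return PointCloud(points=points, colors=colors, frame="raw")


def write_cloud(
    path: str | Path,
    cloud: PointCloud,
    format: str | None = None,
    binary: bool = False,
) -> None:
    """Write a cloud to PLY (ascii or binary little-endian), XYZ or CSV."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "ply":
        _write_ply(path, cloud, binary=binary)
    elif fmt == "xyz":
        np.savetxt(path, cloud.points, fmt="%.9g")
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["x", "y", "z"])
            for p in cloud.points:
                writer.writerow([f"{v:.9g}" for v in p])
    else:
        raise ValueError(f"unsupported point-cloud format: {fmt!r}")


def _read_ply(path: Path) -> tuple[np.ndarray, np.ndarray | None]:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise ValueError(f"{path}: not a PLY file (missing 'ply' magic)")
        encoding = None
        elements: list[tuple[str, int, list[tuple[str, str]]]] = []
        lineno = 1
        while True:
            line = fh.readline()
            lineno += 1
            if not line:
                raise ValueError(f"{path}:{lineno}: unexpected EOF in header")
            tokens = line.decode("ascii", errors="replace").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                encoding = tokens[1]
            elif tokens[0] == "element":
                elements.append((tokens[1], int(tokens[2]), []))
            elif tokens[0] == "property":
                if tokens[1] == "list":
                    raise ValueError(
                        f"{path}:{lineno}: list properties are not supported"
                    )
                if not elements:
                    raise ValueError(f"{path}:{lineno}: property before element")
                elements[-1][2].append((tokens[2], tokens[1]))
            elif tokens[0] == "end_header":
                break
        if encoding not in ("ascii", "binary_little_endian"):
            raise ValueError(f"{path}: unsupported PLY format {encoding!r}")
        vertex = next((e for e in elements if e[0] == "vertex"), None)
        if vertex is None:
            raise ValueError(f"{path}: no vertex element")
        _, count, props = vertex
        names = [name for name, _ in props]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise ValueError(f"{path}: vertex element lacks property {axis!r}")
        dtype = np.dtype([(name, _PLY_DTYPES[typ]) for name, typ in props])
        if encoding == "ascii":
            rows = []
            for i in range(count):
                line = fh.readline()
                lineno += 1
                vals = line.split()
                if len(vals) != len(props):
                    raise ValueError(
                        f"{path}:{lineno}: expected {len(props)} values, "
                        f"got {len(vals)} (vertex record {i})"
                    )
                rows.append(tuple(vals))
            data = np.array(rows, dtype=dtype)
        else:
            buf = fh.read(count * dtype.itemsize)
            if len(buf) < count * dtype.itemsize:
                raise ValueError(
                    f"{path}: truncated binary vertex data "
                    f"({len(buf)} of {count * dtype.itemsize} bytes)"
                )
            data = np.frombuffer(buf, dtype=dtype, count=count)
    points = np.column_stack(
        [data["x"], data["y"], data["z"]]
    ).astype(np.float64)
    colors = None
    if all(c in names for c in ("red", "green", "blue")):
        colors = np.column_stack(
            [data["red"], data["green"], data["blue"]]
        ).astype(np.uint8)
    return points, colors


def _write_ply(path: Path, cloud: PointCloud, binary: bool) -> None:
    n = len(cloud)
    has_color = cloud.colors is not None
    header = io.StringIO()
    header.write("ply\n")
    header.write(
        "format binary_little_endian 1.0\n" if binary else "format ascii 1.0\n"
    )
    header.write(f"element vertex {n}\n")
    header.write("property double x\nproperty double y\nproperty double z\n")
    if has_color:
        header.write(
            "property uchar red\nproperty uchar green\nproperty uchar blue\n"
        )
    header.write("end_header\n")
    with open(path, "wb") as fh:
        fh.write(header.getvalue().encode("ascii"))
        if binary:
            fields = [("x", "<f8"), ("y", "<f8"), ("z", "<f8")]
            if has_color:
                fields += [("red", "u1"), ("green", "u1"), ("blue", "u1")]
            rec = np.empty(n, dtype=np.dtype(fields))
            rec["x"], rec["y"], rec["z"] = cloud.points.T
            if has_color:
                rec["red"], rec["green"], rec["blue"] = cloud.colors.T
            fh.write(rec.tobytes())
        else:
            for i in range(n):
                x, y, z = cloud.points[i]
                line = f"{x:.12g} {y:.12g} {z:.12g}"
                if has_color:
                    r, g, b = cloud.colors[i]
                    line += f" {r} {g} {b}"
                fh.write((line + "\n").encode("ascii"))


def _read_xyz(path: Path) -> np.ndarray:
    try:
        data = np.loadtxt(path, dtype=np.float64, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: malformed XYZ file: {exc}") from exc
    if data.size and data.shape[1] < 3:
        raise ValueError(f"{path}: XYZ rows need at least 3 columns")
    return data[:, :3] if data.size else data.reshape(0, 3)


def _read_csv(path: Path) -> np.ndarray:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty CSV file") from None
        cols = [h.strip().lower() for h in header]
        try:
            idx = [cols.index(a) for a in ("x", "y", "z")]
        except ValueError:
            raise ValueError(
                f"{path}:1: CSV header must contain columns x, y, z; got {cols}"
            ) from None
        rows = []
        for recno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                rows.append([float(row[i]) for i in idx])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{recno}: bad CSV record: {exc}") from exc
    return np.asarray(rows, dtype=np.float64).reshape(-1, 3)


# ---------------------------------------------------------------------------
# scaling and cropping
# ---------------------------------------------------------------------------

def scale_cloud(
    cloud: PointCloud, measured_len: float, true_len: float
) -> PointCloud:
    """Rescale a raw cloud to meters from one known reference length.

    ``measured_len`` is a distance read off the raw cloud (any units);
    ``true_len`` is the same distance in meters.  Every coordinate is
    multiplied by ``true_len / measured_len`` and the frame becomes metric.
    """
    if measured_len <= 0 or true_len <= 0:
        raise ValueError("reference lengths must be positive")
    factor = true_len / measured_len
    return replace(cloud, points=cloud.points * factor, frame="metric")


def crop_cloud(cloud: PointCloud, spec: CropSpec) -> PointCloud:
    """Keep the points inside the crop box and above the soil cut."""
    cloud.require_metric()
    keep = spec.mask(cloud.points)
    if not keep.any():
        raise ValueError("crop removed every point: no plant in the region")
    colors = cloud.colors[keep] if cloud.colors is not None else None
    return replace(cloud, points=cloud.points[keep], colors=colors)


def estimate_soil_z(
    cloud: PointCloud, bin_width: float = 0.005, lower_fraction: float = 0.25
) -> float:
    """Estimate the soil elevation as the modal z among the low points.

    Looks at the lowest ``lower_fraction`` of the z range, histograms it at
    ``bin_width`` resolution and returns the upper edge of the fullest bin.
    Adequate for potted single plants where the soil disc dominates the low
    elevations; full plane fitting is deliberately avoided.
    """
    cloud.require_metric()
    z = cloud.points[:, 2]
    zmin, zmax = z.min(), z.max()
    cut = zmin + lower_fraction * (zmax - zmin)
    low = z[z <= cut]
    nbins = max(1, int(np.ceil((cut - zmin) / bin_width)))
    hist, edges = np.histogram(low, bins=nbins)
    return float(edges[np.argmax(hist) + 1])
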