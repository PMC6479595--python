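"""Stem extraction, node detection and internode-length measurement.

Nodes are the junctions where petioles meet the stem.  Unlike ordinary
stem points, the point distribution at a junction spreads beyond a single
axis, so the second-order tensor there carries a larger second eigenvalue
lambda2 than on a clean stem segment.  Node detection therefore recomputes
the tensor field on the stem-related points alone, keeps the points whose
lambda2/lambda1 exceeds a threshold, and groups them into candidate
regions along the vertical axis.

On sparse clouds the candidate regions climb the petioles (every junction
neighborhood above the node is contaminated), so a raw region centroid
overshoots the node by centimeters.  Each detected region is therefore
localized by the off-axis petiole structure itself: a rising petiole
satisfies z = z_node + rho * tan(elevation) in (radial distance, height)
coordinates about the trunk axis, so regressing height on radial distance
and evaluating at the trunk surface recovers the attachment height.

The first internode is measured from the stem base (lateral position of
the lowest 1 cm slab at the height of the lowest stem point) to the first
node; subsequent internode lengths are distances between consecutive node
centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .pointcloud_io import PointCloud
from .segmentation import LABEL_STEM, OrganLabels
from .tensor_features import NeighborhoodSpec, compute_tensor_field

__all__ = [
    "NodeDetectionConfig",
    "NodeSet",
    "InternodeReport",
    "extract_stem",
    "detect_nodes",
    "internode_lengths",
    "measure_internodes",
]


@dataclass
class NodeDetectionConfig:
    """Parameters of the lambda2-based node detector.

    tau_node:    stem points with lambda2/lambda1 >= tau_node are node
                 candidates (junction regions have elevated lambda2).
    gap_z:       a jump larger than this along z (meters) starts a new
                 candidate region.
    min_support: regions with fewer candidate points are discarded.
    connect_radius: radius (meters) used to connect stem points into
                 components when extracting the main stem axis.
    axis_radius: points within this distance of the trunk axis are treated
                 as trunk when tracking the axis (about the stem radius
                 plus reconstruction noise).
    off_radius:  points farther than this from the trunk axis belong to
                 off-axis structures (petioles) and localize the node.
    off_band:    only off-axis points within this radial band beyond
                 off_radius are used for localization; the band covers the
                 petiole bases but excludes lamina edges near the tips.
    cluster_radius / min_cluster: single-linkage radius and minimum size
                 when splitting a region's off-axis points into petioles.
    reclaim_radius: non-stem points this close to the stem component are
                 added to the localization point set (junction zones are
                 where the classifier leaves points unassigned).
    merge_z:     node estimates closer than this in z are one node.

    On sparse clouds the raw candidate centroid overshoots the node: the
    high-lambda2 points climb the petioles, which all leave the junction
    upward.  Each petiole cluster is therefore extrapolated back to its
    attachment by regressing point height on radial distance from the
    trunk axis; this keeps node estimates inside the stem bounding tube.
    """

    tau_node: float = 0.2
    gap_z: float = 0.02
    min_support: int = 10
    connect_radius: float = 0.05
    axis_radius: float = 0.009
    off_radius: float = 0.011
    off_band: float = 0.03
    cluster_radius: float = 0.015
    reclaim_radius: float = 0.025
    min_cluster: int = 5
    merge_z: float = 0.025
    neighborhood: NeighborhoodSpec = field(default_factory=NeighborhoodSpec)
    base_slab: float = 0.01


@dataclass
class NodeSet:
    """Detected node centroids, ordered by ascending z."""

    nodes: np.ndarray  # (M, 3) centroids, meters
    support_counts: np.ndarray  # (M,) candidate points per region
    lambda2_threshold_used: float

    def __len__(self) -> int:
        return self.nodes.shape[0]


@dataclass
class InternodeReport:
    """First internode plus consecutive internode lengths (meters).

    ``internode_lengths[0]`` is the first internode (stem base to node 1);
    subsequent entries are distances between consecutive node centroids,
    so the list length equals the node count.
    """

    first_internode: float
    internode_lengths: list[float]
    base_point: np.ndarray


def extract_stem(
    labels: OrganLabels,
    cloud: PointCloud,
    config: NodeDetectionConfig | None = None,
) -> tuple[PointCloud, np.ndarray, list[np.ndarray]]:
    """Stem-related points, keeping the largest connected component.

    Returns the main-axis stem cloud, the indices of its points in the
    input cloud, and the minor fragments (lists of input indices) that
    were split off.  Petioles connect to the stem and ride along with the
    main component by design.
    """
    config = config or NodeDetectionConfig()
    stem_idx = np.flatnonzero(labels.labels == LABEL_STEM)
    if stem_idx.size == 0:
        raise ValueError("no stem-labeled points: segmentation failed")
    pts = cloud.points[stem_idx]
    n = pts.shape[0]
    if n == 1:
        comp_labels = np.zeros(1, dtype=int)
        ncomp = 1
    else:
        tree = cKDTree(pts)
        pairs = tree.query_pairs(config.connect_radius, output_type="ndarray")
        data = np.ones(pairs.shape[0])
        graph = coo_matrix(
            (data, (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        ncomp, comp_labels = connected_components(graph, directed=False)
    sizes = np.bincount(comp_labels, minlength=ncomp)
    main = int(np.argmax(sizes))
    keep = comp_labels == main
    fragments = [stem_idx[comp_labels == c] for c in range(ncomp) if c != main]
    main_idx = stem_idx[keep]
    colors = cloud.colors[main_idx] if cloud.colors is not None else None
    stem_cloud = PointCloud(
        points=cloud.points[main_idx], colors=colors, frame=cloud.frame
    )
    return stem_cloud, main_idx, fragments


def detect_nodes(
    stem: PointCloud,
    config: NodeDetectionConfig | None = None,
    cloud: PointCloud | None = None,
    labels: OrganLabels | None = None,
) -> NodeSet:
    """Locate nodes from high-lambda2 regions along the stem.

    The tensor field is recomputed on the stem subset so junction regions
    stand out against clean stem segments.  Candidate points are grouped
    by 1-D gap clustering on z; each sufficiently supported region is
    localized to one node (or, if it spans two whorls, several).  An
    empty NodeSet (bare stem, no petioles) is a valid outcome.

    When the original ``cloud`` and its ``labels`` are given, non-stem
    points lying within ``reclaim_radius`` of the stem (and radially close
    to the trunk) are added to the localization point set, not to the
    candidate detection: junction neighborhoods are exactly where the
    eigenvalue classifier mislabels points, and reclaiming them anchors
    the petiole fits close to the node.
    """
    config = config or NodeDetectionConfig()
    spec = config.neighborhood
    n = len(stem)
    if spec.mode == "knn" and n <= spec.k:
        spec = NeighborhoodSpec(
            mode="knn",
            k=max(3, n - 1),
            min_neighbors=min(spec.min_neighbors, max(3, n - 1)),
        )
    field_ = compute_tensor_field(stem, spec)
    w = field_.eigvals
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(w[:, 0] > 0, w[:, 1] / w[:, 0], np.nan)
    cand = np.flatnonzero(
        ~field_.degenerate & np.isfinite(ratio) & (ratio >= config.tau_node)
    )
    if cand.size == 0:
        return NodeSet(
            nodes=np.empty((0, 3)),
            support_counts=np.empty(0, dtype=int),
            lambda2_threshold_used=config.tau_node,
        )
    z = stem.points[cand, 2]
    order = np.argsort(z, kind="stable")
    cand, z = cand[order], z[order]
    breaks = np.flatnonzero(np.diff(z) > config.gap_z)
    all_groups = [g for g in np.split(cand, breaks + 1) if g.size >= 3]
    # regions below min_support are kept as weak evidence: they yield a
    # node only when an off-axis petiole fit independently confirms one
    if not all_groups:
        return NodeSet(
            nodes=np.empty((0, 3)),
            support_counts=np.empty(0, dtype=int),
            lambda2_threshold_used=config.tau_node,
        )
    spans = [
        (stem.points[g, 2].min(), stem.points[g, 2].max(), g.size)
        for g in all_groups
    ]
    strong = [g.size >= config.min_support for g in all_groups]
    # junction slabs are petiole-dominated and would drag the axis medians
    # sideways; skip them and interpolate the axis across the junction
    exclude = [(s_lo - 0.01, s_hi + 0.01) for s_lo, s_hi, _ in spans]
    axis = _TrunkAxis.fit(stem.points, config, exclude_spans=exclude)
    aug_points = stem.points
    if cloud is not None and labels is not None:
        extra = cloud.points[labels.labels != LABEL_STEM]
        if extra.size:
            tree = cKDTree(stem.points)
            d, _ = tree.query(extra, k=1)
            near = (d <= config.reclaim_radius) & (
                axis.rho(extra) <= config.off_radius + config.off_band + 0.005
            )
            if near.any():
                aug_points = np.vstack([stem.points, extra[near]])
    # localize from the off-axis (petiole) structure, then validate each
    # estimate against the candidate regions
    estimates = _petiole_apexes(aug_points, axis, config)
    by_region: list[list[tuple[float, int]]] = [[] for _ in spans]
    for z0, npts in estimates:
        # candidate regions sit at and above their node; one junction may
        # split into several regions, all claimed by the same apex
        matches = [
            i
            for i, (s_lo, s_hi, _size) in enumerate(spans)
            if s_lo - 0.05 <= z0 <= s_hi + 0.01
        ]
        if matches:
            by_region[matches[0]].append((z0, npts))
            for i in matches[1:]:
                by_region[i].append((z0, 0))
    nodes, supports = [], []
    for i, (s_lo, s_hi, size) in enumerate(spans):
        claims = by_region[i]
        if claims:
            # a real node is backed by both its petioles; fragments with
            # much weaker support than a NEARBY estimate are refit
            # artifacts (distant claims may be distinct whorls sharing a
            # merged candidate region and must coexist)
            for z0, npts in claims:
                rivals = [
                    m for zr, m in claims if abs(zr - z0) <= 0.06 and m > npts
                ]
                if not rivals or npts >= 0.5 * max(rivals):
                    nodes.append(axis.point_at(z0))
                    supports.append(size)
        elif strong[i]:
            # no petiole fit localized this region; fall back to the
            # symmetric candidate mean, but only when off-axis (petiole)
            # points confirm an actual junction -- a chain of stray
            # candidates on bare trunk has none
            zw = aug_points[:, 2]
            window = aug_points[(zw >= s_lo - 0.02) & (zw <= s_hi + 0.01)]
            rho_w = axis.rho(window)
            n_off = int(
                (
                    (rho_w > config.off_radius)
                    & (rho_w <= config.off_radius + config.off_band)
                ).sum()
            )
            if n_off >= config.min_cluster:
                g = all_groups[i]
                nodes.append(axis.point_at(float(stem.points[g, 2].mean())))
                supports.append(size)
    if not nodes:
        return NodeSet(
            nodes=np.empty((0, 3)),
            support_counts=np.empty(0, dtype=int),
            lambda2_threshold_used=config.tau_node,
        )
    nodes = np.asarray(nodes)
    order = np.argsort(nodes[:, 2], kind="stable")
    nodes = nodes[order]
    supports = np.asarray(supports, dtype=int)[order]
    # collapse duplicate estimates of one node
    keep_nodes, keep_supports = [nodes[0]], [int(supports[0])]
    for p, s in zip(nodes[1:], supports[1:]):
        if p[2] - keep_nodes[-1][2] <= config.merge_z:
            keep_nodes[-1] = 0.5 * (keep_nodes[-1] + p)
            keep_supports[-1] = max(keep_supports[-1], int(s))
        else:
            keep_nodes.append(p)
            keep_supports.append(int(s))
    return NodeSet(
        nodes=np.asarray(keep_nodes),
        support_counts=np.asarray(keep_supports, dtype=int),
        lambda2_threshold_used=config.tau_node,
    )


class _TrunkAxis:
    """Stem centerline as xy(z), tracked by slab medians of trunk points."""

    def __init__(self, z_knots: np.ndarray, xy_knots: np.ndarray, r_surface: float):
        self.z_knots = z_knots
        self.xy_knots = xy_knots
        self.r_surface = r_surface

    @classmethod
    def fit(
        cls,
        points: np.ndarray,
        config: NodeDetectionConfig,
        slab: float = 0.02,
        exclude_spans: list[tuple[float, float]] | None = None,
    ) -> "_TrunkAxis":
        z = points[:, 2]
        edges = np.arange(z.min(), z.max() + slab, slab)
        exclude_spans = exclude_spans or []
        centers, xy = [], []
        keep = np.ones(len(points), dtype=bool)
        for _ in range(2):  # second pass drops off-axis (petiole) points
            centers, xy = [], []
            for lo in edges[:-1]:
                mid = lo + 0.5 * slab
                if any(a <= mid <= b for a, b in exclude_spans):
                    continue  # petiole-dominated junction slab
                m = keep & (z >= lo) & (z < lo + slab)
                if m.sum() >= 3:
                    centers.append(mid)
                    xy.append(np.median(points[m, :2], axis=0))
            if not centers:
                break
            rho = _rho(points, np.asarray(centers), np.asarray(xy))
            keep = rho <= config.off_radius
        if not centers:
            centers = [float(z.mean())]
            xy = [np.median(points[:, :2], axis=0)]
        z_knots, xy_knots = np.asarray(centers), np.asarray(xy)
        rho = _rho(points, z_knots, xy_knots)
        on = rho <= config.axis_radius
        r_surface = float(np.median(rho[on])) if on.any() else config.axis_radius / 2
        return cls(z_knots, xy_knots, r_surface)

    def xy_at(self, z: np.ndarray | float) -> np.ndarray:
        zq = np.atleast_1d(np.asarray(z, dtype=np.float64))
        x = np.interp(zq, self.z_knots, self.xy_knots[:, 0])
        y = np.interp(zq, self.z_knots, self.xy_knots[:, 1])
        out = np.stack([x, y], axis=-1)
        return out[0] if np.isscalar(z) or np.ndim(z) == 0 else out

    def point_at(self, z: float) -> np.ndarray:
        xy = self.xy_at(float(z))
        return np.array([xy[0], xy[1], float(z)])

    def rho(self, points: np.ndarray) -> np.ndarray:
        return _rho(points, self.z_knots, self.xy_knots)


def _rho(points: np.ndarray, z_knots: np.ndarray, xy_knots: np.ndarray) -> np.ndarray:
    x = np.interp(points[:, 2], z_knots, xy_knots[:, 0])
    y = np.interp(points[:, 2], z_knots, xy_knots[:, 1])
    return np.hypot(points[:, 0] - x, points[:, 1] - y)


def _single_linkage_clusters(
    pts: np.ndarray, radius: float, min_size: int
) -> list[np.ndarray]:
    if len(pts) == 0:
        return []
    tree = cKDTree(pts)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    graph = coo_matrix(
        (np.ones(pairs.shape[0]), (pairs[:, 0], pairs[:, 1])),
        shape=(len(pts), len(pts)),
    )
    _, lab = connected_components(graph, directed=False)
    return [
        np.flatnonzero(lab == c)
        for c in np.unique(lab)
        if (lab == c).sum() >= min_size
    ]


def _petiole_apexes(
    points: np.ndarray,
    axis: _TrunkAxis,
    config: NodeDetectionConfig,
) -> list[tuple[float, int]]:
    """Node height estimates from the off-axis (petiole) structures.

    Points in a radial band around the trunk are split into petiole
    clusters (single linkage, then azimuth gaps, so opposite petioles of
    one whorl separate).  Each cluster is fitted by a line constrained to
    leave the trunk surface at an unknown height; clusters whose
    individual heights agree within ``merge_z`` describe one node and are
    jointly refitted with a Huber loss, which lets a well-sampled petiole
    anchor its fragmentary partner.  Returns (height, point count) pairs.
    """
    rho = axis.rho(points)
    off = points[
        (rho > config.off_radius) & (rho <= config.off_radius + config.off_band)
    ]
    clusters: list[tuple[float, np.ndarray]] = []
    for cluster_idx in _single_linkage_clusters(
        off, config.cluster_radius, config.min_cluster
    ):
        for sub_idx in _azimuth_split(off[cluster_idx], axis, config.min_cluster):
            cl = off[cluster_idx][sub_idx]
            z0 = _apex_height(cl, axis, config.off_radius)
            if z0 is not None:
                clusters.append((z0, cl))
    if not clusters:
        return []
    clusters.sort(key=lambda t: t[0])
    groups: list[list[tuple[float, np.ndarray]]] = [[clusters[0]]]
    for z0, cl in clusters[1:]:
        if z0 - groups[-1][-1][0] <= config.merge_z:
            groups[-1].append((z0, cl))
        else:
            groups.append([(z0, cl)])
    out: list[tuple[float, int]] = []
    for grp in groups:
        z0s = np.array([g[0] for g in grp])
        sizes = np.array([len(g[1]) for g in grp], dtype=float)
        out.append((float(np.average(z0s, weights=sizes)), int(sizes.sum())))
    return out


def _azimuth_split(
    pts: np.ndarray, axis: _TrunkAxis, min_size: int, gap_deg: float = 60.0
) -> list[np.ndarray]:
    """Split a spatial cluster into petioles by angular gaps about the axis.

    Opposite petioles of one whorl can chain through the junction into a
    single spatial component; their azimuths about the trunk are well
    separated, so circular gap clustering takes them apart again.
    """
    if len(pts) < min_size:
        return []
    xy_axis = axis.xy_at(pts[:, 2])
    ang = np.arctan2(pts[:, 1] - xy_axis[:, 1], pts[:, 0] - xy_axis[:, 0])
    order = np.argsort(ang, kind="stable")
    gaps = np.diff(ang[order], append=ang[order[0]] + 2 * np.pi)
    cut = np.flatnonzero(gaps > np.radians(gap_deg))
    if cut.size == 0:
        return [np.arange(len(pts))]
    start = (cut[-1] + 1) % len(pts)
    rolled = np.roll(order, -start)
    rolled_gaps = np.roll(gaps, -start)
    out, current = [], []
    for pos, idx in enumerate(rolled):
        current.append(idx)
        if rolled_gaps[pos] > np.radians(gap_deg):
            out.append(np.asarray(current))
            current = []
    if current:
        out.append(np.asarray(current))
    return [c for c in out if c.size >= min_size]


def _radial_weights(cluster: np.ndarray, axis: _TrunkAxis, off_radius: float) -> np.ndarray:
    """Confidence that a point is petiole rather than trunk-noise tail.

    Points just outside the trunk tube are ambiguous (junction shoulder
    points reach there through reconstruction noise); points a further
    centimeter out can only be petiole.
    """
    rho = axis.rho(cluster)
    return np.clip((rho - off_radius) / 0.01, 0.05, 1.0)


def _apex_height(
    cluster: np.ndarray, axis: _TrunkAxis, off_radius: float = 0.011
) -> float | None:
    """Height at which a petiole's points extrapolate back to the trunk.

    A rising petiole satisfies z = z_node + rho * tan(elevation) up to
    the tube radius and surface noise, where rho is the radial distance
    from the trunk axis.  Height is regressed on rho (weighted by
    petiole confidence) and evaluated at the trunk-surface radius.
    Regressing z on rho keeps the estimate unbiased under the radial
    band selection, which truncates rho but not z given rho.
    """
    z = cluster[:, 2]
    rho = axis.rho(cluster)
    w = _radial_weights(cluster, axis, off_radius)
    wsum = w.sum()
    mr = float((w * rho).sum() / wsum)
    mz = float((w * z).sum() / wsum)
    var = float((w * (rho - mr) ** 2).sum() / wsum)
    if var <= 1e-12:
        return None
    slope = float((w * (rho - mr) * (z - mz)).sum() / wsum) / var
    if slope < 0.09:  # petioles rise at more than ~5 degrees
        return None
    z0 = mz + slope * (axis.r_surface - mr)
    if not z.min() - 0.045 <= z0 <= z.min() + 0.015:
        return None  # a node sits at the base of its petiole
    return z0


def _slab_centroids(stem: PointCloud, slab: float) -> np.ndarray:
    """Centroids of consecutive z slabs (ordered stem polyline)."""
    z = stem.points[:, 2]
    idx = np.floor((z - z.min()) / slab).astype(int)
    out = []
    for s in np.unique(idx):
        out.append(stem.points[idx == s].mean(axis=0))
    return np.asarray(out)


def internode_lengths(
    nodes: NodeSet,
    stem: PointCloud,
    config: NodeDetectionConfig | None = None,
    method: str = "euclidean",
) -> InternodeReport:
    """Internode lengths from the detected node set.

    ``method='euclidean'`` (default) uses straight-line distances between
    centroids; ``method='polyline'`` measures along the stem through
    ordered 1 cm slab centroids, for curved stems.
    """
    config = config or NodeDetectionConfig()
    if len(nodes) == 0:
        raise ValueError("no nodes detected")
    z = stem.points[:, 2]
    base_mask = z <= z.min() + config.base_slab
    # lateral position from the whole base slab, height from the lowest
    # reconstructed point (slab-mean z would sit half a slab too high)
    base = stem.points[base_mask].mean(axis=0)
    base[2] = z.min()
    anchors = np.vstack([base, nodes.nodes])
    if method == "euclidean":
        lengths = np.linalg.norm(np.diff(anchors, axis=0), axis=1)
    elif method == "polyline":
        poly = _slab_centroids(stem, config.base_slab)
        seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        # arc-length position of the nearest polyline vertex to each anchor
        pos = [
            arc[int(np.argmin(np.linalg.norm(poly - a, axis=1)))]
            for a in anchors
        ]
        lengths = np.abs(np.diff(pos))
    else:
        raise ValueError(f"unknown distance method {method!r}")
    if not (lengths > 0).all():
        raise ValueError("degenerate internode of non-positive length")
    return InternodeReport(
        first_internode=float(lengths[0]),
        internode_lengths=[float(v) for v in lengths],
        base_point=base,
    )


def measure_internodes(
    cloud: PointCloud,
    seg_config=None,
    node_config: NodeDetectionConfig | None = None,
    method: str = "euclidean",
):
    """Full organ-level pipeline: segment, extract stem, detect, measure.

    Returns ``(report, nodes, labels)``.  Raises if segmentation finds no
    stem or no nodes are detected.
    """
    from .segmentation import segment_plant

    node_config = node_config or NodeDetectionConfig()
    labels = segment_plant(cloud, seg_config)
    stem, _idx, _fragments = extract_stem(labels, cloud, node_config)
    nodes = detect_nodes(stem, node_config, cloud=cloud, labels=labels)
    report = internode_lengths(nodes, stem, node_config, method=method)
    return report, nodes, labels
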