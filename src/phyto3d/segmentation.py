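"""Leaf/stem segmentation from the eigen-structure of local tensors.

Classification is a straightforward analysis of the first two eigenvalues
of the second-order tensor: on a leaf lamina the points spread evenly in a
plane, so lambda1 and lambda2 are comparable while lambda3 (deviation from
planarity) stays small — in practice rarely above 10% of lambda1.  On a
stem the arrangement is elongated and axial, so lambda2 is much smaller
than lambda1.  Points falling between the two regimes stay unassigned.

The second-order classifier systematically errs on leaf boundaries: there
the truncated neighborhood looks elongated and the point is mislabeled
stem (or left unassigned).  The first-order tensor repairs this — its
magnitude is near zero in symmetric interiors but large at boundaries,
while even the edge points of a stem keep a small magnitude because of the
stem's symmetric elongated form.  Refinement therefore relabels
high-magnitude stem/unassigned points adjacent to leaf regions as leaf.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .pointcloud_io import PointCloud
from .tensor_features import NeighborhoodSpec, TensorField, compute_tensor_field

__all__ = [
    "LABEL_UNASSIGNED",
    "LABEL_STEM",
    "LABEL_LEAF",
    "LABEL_NAMES",
    "SegmentationConfig",
    "OrganLabels",
    "classify_second_order",
    "refine_first_order",
    "segment_plant",
]

LABEL_UNASSIGNED = 0
LABEL_STEM = 1
LABEL_LEAF = 2
LABEL_NAMES = {LABEL_UNASSIGNED: "unassigned", LABEL_STEM: "stem", LABEL_LEAF: "leaf"}


@dataclass
class SegmentationConfig:
    """Ratio thresholds for the two classification stages.

    All criteria are dimensionless ratios of eigenvalues (or the
    normalized first-order magnitude), so labels do not change under a
    global rescaling of the cloud even though the tensors themselves are
    unnormalized.

    tau_planar: leaf requires lambda2/lambda1 >= tau_planar
    tau_flat:   leaf requires lambda3/lambda1 <= tau_flat (the "10%" regime)
    tau_linear: stem requires lambda2/lambda1 <= tau_linear
    tau_mag:    refinement flips stem/unassigned points whose normalized
                first-order magnitude exceeds tau_mag
    leaf_neighbor_frac: ...and at least this fraction of whose neighbors
                are already leaf (prevents flipping isolated stem points)
    """

    tau_planar: float = 0.4
    tau_flat: float = 0.1
    tau_linear: float = 0.35
    tau_mag: float = 0.5
    leaf_neighbor_frac: float = 0.6
    neighborhood: NeighborhoodSpec = field(default_factory=NeighborhoodSpec)

    def __post_init__(self) -> None:
        if self.tau_linear >= self.tau_planar:
            raise ValueError(
                "overlapping thresholds: tau_linear must be < tau_planar"
            )
        for name in ("tau_planar", "tau_flat", "tau_linear", "tau_mag"):
            if not 0 <= getattr(self, name):
                raise ValueError(f"{name} must be non-negative")


@dataclass
class OrganLabels:
    """Per-point organ labels with per-point classifier scores."""

    labels: np.ndarray  # int8, LABEL_* constants
    stage: str  # "second_order" | "refined"
    planar_ratio: np.ndarray  # lambda2/lambda1
    linear_ratio: np.ndarray  # (lambda1-lambda2)/lambda1
    flatness: np.ndarray  # lambda3/lambda1
    first_order_mag: np.ndarray  # normalized |t|

    def __len__(self) -> int:
        return self.labels.shape[0]

    @property
    def stem_mask(self) -> np.ndarray:
        return self.labels == LABEL_STEM

    @property
    def leaf_mask(self) -> np.ndarray:
        return self.labels == LABEL_LEAF

    @property
    def unassigned_mask(self) -> np.ndarray:
        return self.labels == LABEL_UNASSIGNED

    @property
    def unassigned_fraction(self) -> float:
        return float(self.unassigned_mask.mean())

    def counts(self) -> dict[str, int]:
        return {
            name: int((self.labels == code).sum())
            for code, name in LABEL_NAMES.items()
        }


def _ratios(field_: TensorField) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    w = field_.eigvals
    with np.errstate(invalid="ignore", divide="ignore"):
        l1 = np.where(w[:, 0] > 0, w[:, 0], np.nan)
        return w[:, 1] / l1, (w[:, 0] - w[:, 1]) / l1, w[:, 2] / l1


def classify_second_order(
    field_: TensorField, config: SegmentationConfig | None = None
) -> OrganLabels:
    """Label each point leaf/stem/unassigned from eigenvalue ratios alone."""
    config = config or SegmentationConfig()
    planar, linear, flat = _ratios(field_)
    labels = np.full(len(field_), LABEL_UNASSIGNED, dtype=np.int8)
    valid = ~field_.degenerate & np.isfinite(planar)
    leaf = valid & (planar >= config.tau_planar) & (flat <= config.tau_flat)
    stem = valid & (planar <= config.tau_linear)
    labels[leaf] = LABEL_LEAF
    labels[stem] = LABEL_STEM
    return OrganLabels(
        labels=labels,
        stage="second_order",
        planar_ratio=planar,
        linear_ratio=linear,
        flatness=flat,
        first_order_mag=field_.t_mag_normalized,
    )


def refine_first_order(
    labels: OrganLabels,
    field_: TensorField,
    config: SegmentationConfig | None = None,
) -> OrganLabels:
    """Repair leaf-boundary misclassifications with the first-order tensor.

    A stem or unassigned point is relabeled leaf when its normalized
    first-order magnitude exceeds ``tau_mag`` (asymmetric neighborhood,
    i.e. a boundary) and at least ``leaf_neighbor_frac`` of its neighbors
    are leaf.  Stem points with small magnitude are retained regardless.
    Applying refinement to an already refined labeling changes nothing.
    """
    config = config or SegmentationConfig()
    if labels.stage == "refined":
        return replace(labels, labels=labels.labels.copy())
    base = labels.labels
    mag = labels.first_order_mag
    nbrs = field_.neighborhoods
    new = base.copy()
    candidates = np.flatnonzero(
        ((base == LABEL_STEM) | (base == LABEL_UNASSIGNED))
        & ~field_.degenerate
        & np.isfinite(mag)
        & (mag > config.tau_mag)
    )
    for i in candidates:
        row = nbrs.indices[i]
        if row.size == 0:
            continue
        leaf_frac = (base[row] == LABEL_LEAF).mean()
        if leaf_frac >= config.leaf_neighbor_frac:
            new[i] = LABEL_LEAF
    return replace(labels, labels=new, stage="refined")


def segment_plant(
    cloud: PointCloud,
    config: SegmentationConfig | None = None,
    return_field: bool = False,
) -> OrganLabels | tuple[OrganLabels, TensorField]:
    """Full pipeline: neighborhoods -> tensors -> classify -> refine."""
    cloud.require_metric()
    config = config or SegmentationConfig()
    field_ = compute_tensor_field(cloud, config.neighborhood)
    labels = classify_second_order(field_, config)
    refined = refine_first_order(labels, field_, config)
    if return_field:
        return refined, field_
    return refined
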