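# Methods

## Problem setting

A multi-view-stereo reconstruction of a potted single plant is an
unordered 3-D point cloud covering the whole scene in arbitrary units.
After rescaling from one user-supplied reference length and cropping to
the plant, the pipeline answers four questions about the plant at each
imaging session: how tall is it, how wide, how much space does it occupy,
and how long is its first internode.  Height and first-internode length
are the parameters of interest for early parasitism detection; the
package also carries the below-ground side of such a study (attachment
counts against thermal time) and the statistics for comparing infected
and control groups.

## Local tensor analysis

For each point, the neighborhood σ is its k = 30 nearest neighbors
(density-adaptive, which suits photogrammetric clouds; a fixed-radius
mode is available).  Points with fewer than 8 neighbors are degenerate
and stay unassigned.  The first-order tensor t = Σ (x_i − x_j) measures
neighborhood asymmetry; the unnormalized second-order tensor
T = Σ (x_j − x_i)(x_j − x_i)ᵀ carries local shape in its eigenvalues
λ₁ ≥ λ₂ ≥ λ₃ ≥ 0.  Normalization is immaterial because every criterion
downstream is a ratio; labels are therefore invariant to a global
rescaling of the cloud, and translation/rotation behave as expected
(tests assert all three).  Eigenvalue ties are broken by forcing the
first nonzero eigenvector component positive, so runs are reproducible.

## Leaf/stem classification

A point is leaf if λ₂/λ₁ ≥ 0.4 and λ₃/λ₁ ≤ 0.1, stem if λ₂/λ₁ ≤ 0.35,
otherwise unassigned.  The flatness bound 0.1 reflects the operating
regime of surface patches, where the third eigenvalue rarely exceeds a
tenth of the first.  The planar threshold 0.4 and the linear threshold
0.35 were set from the finite-sample behavior of 30-point neighborhoods:
the λ₂/λ₁ of an ideal plane sampled with k = 30 has median ≈ 0.67 and
lower decile ≈ 0.47, so demanding 0.5 would discard a seventh of genuine
lamina interiors, and raising the stem bound to 0.35 keeps
junction-adjacent stem points (λ₂ elevated by the petioles) in the stem
class at no cost — lamina points in that band were misclassified under
either rule.  All four thresholds are exposed in `SegmentationConfig`.

Refinement flips stem/unassigned points to leaf when their normalized
first-order magnitude ‖t‖ / (k × mean neighbor distance) exceeds 0.5
(interior points of a uniform surface sit near 0; boundary points near
0.6) and at least 60% of their neighbors are already leaf.  These two
values were chosen by measuring flip precision on synthetic plants: at
(0.5, 0.6) about 18 points flip per plant with ≈ 91% precision, which
makes refined accuracy ≥ second-order accuracy on every seed tested.

Accuracy is reported as the fraction of all points whose label equals
the ground truth, with unassigned counted as wrong.  On the default
synthetic suite this is ≈ 86.5% for the second-order stage (the errors
sit in leaf-edge and junction bands), rising slightly after refinement.

## Stem extraction and node detection

Stem-labeled points are linked at 5 cm and the largest connected
component is kept (petioles ride along).  The tensor field is recomputed
on this subset; points with λ₂/λ₁ ≥ 0.2 are junction candidates, grouped
into regions by 2 cm gap clustering on z, with regions of ≥ 10 points
counting as firm detections.

Localization needs care at desk-scale sampling density.  The 30-neighbor
footprint is ≈ 2 cm, so every stem and petiole point within ≈ 2 cm of a
junction has a mixed neighborhood: the candidates climb the petioles
(which all leave the junction upward) and a plain region centroid
overshoots the node by 3–4 cm.  Each region is therefore localized from
the off-axis structure itself:

1. The trunk axis is tracked as slab medians of the stem subset,
   skipping slabs inside candidate regions (petiole-dominated medians
   would drag the axis sideways) and interpolating across them.
2. Non-stem-labeled points within 2.5 cm of the stem and radially close
   to the trunk are reclaimed for localization only — junction
   neighborhoods are exactly where the classifier mislabels points, and
   reclaiming them anchors the petiole geometry near the node.
3. Points in a radial band 1.1–4.1 cm from the axis are clustered
   (single linkage at 1.5 cm, then azimuthal gap splitting, so opposite
   petioles of one whorl separate).
4. A rising petiole satisfies z ≈ z_node + ρ·tan(elevation), with ρ the
   radial distance from the axis.  Height is regressed on ρ, weighted by
   a petiole-confidence ramp over the ambiguous inner centimeter, and
   evaluated at the trunk-surface radius.  Regressing z on ρ keeps the
   estimate unbiased under the radial band selection, which truncates ρ
   but not z given ρ (a constrained total-least-squares variant was
   rejected: its cost decreases monotonically as the anchor recedes down
   the trunk, biasing estimates several millimeters low).
5. Estimates agreeing within 2.5 cm are one node; among estimates
   claiming the same region, fragments with less than half the support
   of a nearby rival are dropped.  A region with no petiole fit falls
   back to its symmetric candidate mean, but only when off-axis points
   confirm an actual junction — stray candidate chains on bare trunk
   yield nothing.

The first internode runs from the stem base (lateral position of the
lowest 1 cm slab, height of the lowest stem point) to the first node;
later internodes are centroid-to-centroid distances, optionally measured
along a slab-centroid polyline for curved stems.  On the standard suite
(first internodes 10–30 cm, 2 mm surface noise) the RMSE against ground
truth is ≈ 2–4 mm, and estimated-on-actual regression gives slope ≈ 1.0
with R² > 0.99.

## Whole-plant morphology

Height is max(z) − min(z).  Width is the planar diameter — the maximal
pairwise distance of the x-y projection, computed on the convex hull but
equal to the brute-force maximum (oracle-tested), an interpretation of
"maximal planar difference" recorded as a design choice.  Volume
partitions space into cubic voxels (1 cm default, exposed), discards
connected components smaller than five cells (26-connectivity default)
as reconstruction noise, and sums the survivors.  Volume uses all plant
points regardless of organ label.

## Synthetic plants

The generator emulates a close-range photogrammetric reconstruction of a
young single-stem sunflower: a gently bowed vertical stem (50 cm tall,
4 mm radius, 1 cm maximal bow), three petiole whorls (two opposite 7 cm
petioles of 3 mm radius rising at 55°), elliptical planar laminae
(semi-axes 12 × 7.2 cm, tilted 10°, optional paraboloid bend), uniform
surface sampling at 20,000 points/m², Gaussian noise of σ = 2 mm along
the local surface normal, and 2% of points removed in small spherical
voids.  The density was chosen so the 30-neighbor footprint (≈ 2 cm)
comfortably dominates the noise — the regime the tensor classifier
expects; thicker stems were rejected because a wrapped cylinder feeds
r²/2 into both transverse eigenvalues and destroys the leaf/stem
contrast the method relies on.  The stem extremes are pinned so the
nominal height is exact by construction.  Every point carries an organ
label (petioles count as stem), and node positions, internode lengths,
height, width and a reference voxel volume are recorded.

What the generator does not emulate: view-dependent density variation,
occlusion shadows, outlier blobs away from surfaces, leaf curling and
serration, and multi-stem architectures.  Passing tests therefore show
the pipeline is correct in its intended operating regime, not that field
clouds of arbitrary quality will reach the same accuracy.

Scene generation adds a pot (cylinder below the soil line) and a noisy
soil disc, recording the exact plant bounding box for crop tests.
Cohort generation follows linear-in-thermal-time interpolation through
per-group anchors for height, first internode and width at 550–1120 GDD
— a calibration device for exercising the statistics pipeline, not a
growth law — with 5% between-plant variation; at zero variation the
replicates share one spec but keep independent sampling seeds.

## Attachment dynamics and statistics

Thermal time accumulates max(0, daily mean soil temperature − T_base)
with T_base = 5 °C by default (configurable per crop); days with missing
hours are flagged.  The attachment curve is the three-parameter
log-logistic y = a/(1 + (x/x₀)ᵇ), the standard dose-response form for
germination and emergence dynamics: a is the upper asymptote
(attachments per tube), x₀ the inflection (y(x₀) = a/2), and b < 0 gives
an increasing sigmoid.  Fitting is least squares with multi-start
initialization over both sigmoid orientations; noiseless series are
recovered to machine precision, constant series are flagged degenerate
rather than fit.  Standard errors are asymptotic; the p-value is the
F-test against a constant-mean model.

Group comparison is one-way ANOVA plus Tukey-HSD at α = 0.05; with two
groups Tukey reduces to the studentized-range equivalent of the t-test
and both p-values are reported.  Zero-variance identical groups return
p = 1 rather than an error.  Accuracy regression is ordinary least
squares of estimated on actual values with residual RMSE and percent
error (RMSE over mean actual).  Percent differences between groups take
an explicit reference argument because reported conventions differ by
parameter; displayed values truncate toward zero, matching how such
session tables are printed.

## Numerical choices and degenerate inputs

Eigen-decomposition symmetrizes defensively and clamps round-off
negatives within −1e−10·λ₁ to zero; reconstruction is verified to 1e−8.
Empty node sets, empty filtered voxel grids, clutter-only crops, and
clouds smaller than k+1 all raise or warn explicitly rather than
returning silent zeros.  All randomness flows from explicit integer
seeds; every generator is bit-reproducible under a fixed seed.

## Known limitations

- Single-stem topology only; branching plants violate the one-trunk
  axis model of node localization.
- Node detection assumes petioles rise (elevation ≳ 5°); fully drooping
  petioles would be rejected by the slope guard.
- The classifier's operating regime couples neighborhood size, sampling
  density and noise; clouds much denser than ~10× the default need a
  larger k or a radius neighborhood to keep laminae in the flatness
  band.
- Voxel volume depends on the chosen cell size; only ratios between
  groups at a fixed size are meaningful.
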