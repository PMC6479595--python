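# phyto3d

Organ-level phenotyping of single plants from 3-D point clouds, built for
early detection of sunflower broomrape (*Orobanche cumana*) parasitism.
Most of the parasite's life cycle happens below the soil surface, but its
drain on the host shows up above ground first as reduced height and
shorter internodes.  Given a multi-view-stereo reconstruction of a potted
plant, this package segments the cloud into leaf and stem points, finds
the stem nodes, and extracts four morphological parameters — height,
width, voxel-occupancy volume and first internode length — plus the
thermal-time attachment-dynamics fit and the group statistics needed to
compare infected and control cohorts.  A built-in synthetic labeled-plant
generator makes every stage testable without field data.

## Method

Each point **x**ᵢ gets two local tensors over its neighborhood σ (30
nearest neighbors by default):

- first order: **t**ᵢ = Σ_{j∈σ} (**x**ᵢ − **x**ⱼ) — its magnitude grows
  with neighborhood asymmetry, i.e. at surface boundaries;
- second order: **T**ᵢ = Σ_{j∈σ} (**x**ⱼ − **x**ᵢ)(**x**ⱼ − **x**ᵢ)ᵀ,
  with spectral decomposition **T** = **V Λ V**ᵀ, λ₁ ≥ λ₂ ≥ λ₃ ≥ 0,
  and saliencies (stick, plate, sphere) = (λ₁−λ₂, λ₂−λ₃, λ₃).

Leaf laminae are surface-like (λ₁ ≈ λ₂, λ₃ small); stems are elongated
(λ₂ ≪ λ₁).  Classification thresholds the ratios λ₂/λ₁ and λ₃/λ₁; a
refinement pass uses ‖**t**ᵢ‖ to repair leaf-boundary points that the
eigenvalue rule mislabels.  Nodes (stem–petiole junctions) appear along
the extracted stem as regions of elevated λ₂; each region is localized by
extrapolating its petiole points back to the trunk axis.  Height is the
z-extent, width the planar diameter of the x-y projection, and volume the
count of occupied voxels after discarding connected sets smaller than
five cells.  Attachment counts per observation tube are regressed on
growing degree days (GDD) with the three-parameter log-logistic
y = a / (1 + (x/x₀)ᵇ); groups are compared per session with one-way ANOVA
and Tukey-HSD at α = 0.05.

## Worked example

```python
from phyto3d import (PlantSpec, generate_plant, measure_internodes,
                     morphology_report)

cloud, truth = generate_plant(PlantSpec(seed=7))   # 3,591 labeled points
report, nodes, labels = measure_internodes(cloud)
print(labels.counts())
print([round(float(p[2]), 3) for p in nodes.nodes])
print(morphology_report(cloud, first_internode=report.first_internode).to_dict())
```

prints

```
{'unassigned': 335, 'stem': 283, 'leaf': 2973}
[0.151, 0.254, 0.35]
{'plant_id': None, 'group': None, 'gdd': None,
 'height_cm': 50.0, 'width_cm': 54.83, 'volume_m3': 0.001886,
 'first_internode_cm': 15.13}
```

The generated plant has whorls at z = 0.15, 0.25 and 0.35 m; all three
nodes are recovered within a few millimeters, and the estimated first
internode (15.13 cm) is 1.1 mm off the ground-truth 15.02 cm.  Height,
width and the 1-cm-voxel volume agree with the generator's records.

The same steps are available from a shell:

```sh
phyto3d synth plant --seed 7 --out demo/
phyto3d segment  --in demo/plant.ply --out demo/labeled.ply
phyto3d phenotype --in demo/plant.ply
phyto3d synth attachments --noise-sd 0 --out demo/att.csv
phyto3d fit-dynamics --in demo/att.csv
```

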