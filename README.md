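# synaptomap

Volumetric synapse detection and eye-specific spatial analysis for
aligned multi-channel super-resolution image stacks of the developing
dorsal lateral geniculate nucleus (dLGN).

During eye-specific competition, retinal ganglion cell axons from the two
eyes form synapses onto dLGN relay neurons. Each retinogeniculate input is
one contiguous presynaptic vesicle cluster (VGluT2) carrying one or more
active zones — Bassoon clusters paired with postsynaptic Homer1. Inputs
with a single active zone are **sAZ** synapses; inputs whose vesicle
cluster feeds 2–4 active zones are **mAZ** inputs. Eye-of-origin is read
out from an anterograde tracer (CTB) injected into one eye. The questions
this package quantifies: how many inputs of each class does each eye form,
how does the vesicle pool scale with active-zone count, and do like-eye
synapses cluster in space beyond chance?

`synaptomap` turns four-channel 8-bit voxel volumes (Homer1, Bassoon,
VGluT2, CTB; anisotropic geometry, e.g. 15.5 nm lateral pixels and 70 nm
sections) into:

- per-channel **labeled clusters** via per-section histogram
  normalization, cell-body exclusion, two-level (three-class) Otsu
  thresholding, 3D connected components, watershed splitting, and
  section-span/edge filters;
- **synapses**, by pairing Homer1 and Bassoon clusters in a 2D feature
  space (centroid distance, opposing-channel intensity in a 140-nm
  surface shell) with OPTICS density clustering;
- **retinogeniculate inputs**, by associating Homer-paired active zones to
  VGluT2 clusters through a 140-nm surface shell and classifying sAZ/mAZ,
  with a 70-nm shell VGluT2 volume as a docked-vesicle proxy and CTB
  colocalization for eye-of-origin;
- **spatial clustering statistics**: like-eye sAZ neighbor counts in 1–4 µm
  expansion shells around each input, a clustered/isolated label at
  1.5 µm, nearest-clustered-mAZ distances, near/far sAZ classes, and an
  empirical null in which sAZ positions are shuffled uniformly within the
  neuropil mask (convex hull of CTB signal minus cell bodies);
- **replicate-level statistics**: two-tailed paired t-tests across
  biological replicates with Cohen's d and 5/95% confidence intervals,
  two-sample Kolmogorov–Smirnov tests with epsilon-squared effect sizes,
  and Benjamini–Hochberg FDR correction (α = 0.05) within each condition.

A first-class **synthetic-scene generator** plants ground-truth inputs
with the statistical structure the analysis assumes (Poisson counts per
class and eye, linear vesicle-volume scaling, like-eye clustering within
1.5 µm, imperfect tracer efficiency, cell-body blobs, background labels)
and renders them as four-channel volumes, so the entire pipeline is
buildable and testable without imaging data.

## Worked example

Simulate a 40 × 40 × 4.2 µm volume (512 × 512 × 60 voxels, 78 nm lateral
pixels, 70 nm sections) at full tracer efficiency, run every stage, and
test clustering against a 200-iteration shuffled null:

```yaml
# config.yaml
geometry: {voxel_xy: 78.125, voxel_z: 70.0, shape: [512, 512, 60]}
scene: {ctb_label_efficiency: 1.0}
n_iterations: 200
seed: 42
```

```bash
synaptomap run-all --config config.yaml --out run/ --verbose
```

The manifest reports, among other counts:

```
"clusters_homer1": 213, "clusters_bassoon": 213, "clusters_vglut2": 143,
"paired_synapses": 212, "inputs": 143, "maz_inputs": 58,
"clustered_fraction_r1.5": 0.4196
```

Of 143 detected inputs, 58 are mAZ; 212 of 213 Homer clusters found a
Bassoon partner. `run/null_rep0.csv` compares the observed clustered
fraction with the shuffle null at each search radius:

```
radius_um,null_mean,null_sd,observed,p_empirical
1.0,0.1024,0.0272,0.1329,0.1841
1.5,0.2108,0.0377,0.4196,0.0050
2.0,0.3436,0.0442,0.5455,0.0050
```

At the 1.5-µm cutoff, 42% of inputs have a like-eye sAZ neighbor versus
21% expected under a uniform repositioning of sAZ synapses within the
neuropil — the generator planted 70% of sAZ synapses near a like-eye mAZ
input, and the analysis detects that excess (empirical p = 0.005 at 200
iterations). With `n_replicates: 3` the pipeline additionally emits
replicate summaries and the FDR-corrected paired eye comparisons in
`stats.csv`.

Each stage is also available separately (`synaptomap simulate`,
`synaptomap segment`) and as library functions (`synaptomap.segment_volume`,
`synaptomap.pair_channels`, `synaptomap.build_inputs`,
`synaptomap.shuffle_null`, ...).

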