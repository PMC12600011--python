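# Methods

This note documents the models, conventions, and numerical choices behind
`synaptomap`, and what its synthetic benchmarks do and do not demonstrate
about real serial-section localization data.

## Geometry and units

All volumes are anisotropic voxel grids: lateral pitch set by the
super-resolution rendering (default 15.5 nm), axial pitch by the physical
section thickness (default 70 nm). Every sigma, shell, and search radius
is specified in nanometres and converted per axis
(`sigma_vox = sigma_nm / pitch_axis`); distance transforms and KD-tree
queries use physical sampling. Internally arrays and coordinates are
(z, y, x); user-facing tables are x/y/z in nm, volumes in µm³, clustering
radii in µm. The desk-scale test geometry (512 × 512 × 60 voxels at
78.125 nm × 70 nm ≈ 40 × 40 × 4.2 µm) keeps runtimes in minutes; because
all thresholds are physical, the method is unchanged across pitches.

## Segmentation chain

1. **Per-section histogram normalization.** Serial sections vary in
   overall intensity (gain); each section's positive-intensity histogram
   is quantile-mapped to the cross-section average, then the channel is
   rescaled to the full 8-bit range. Matching acts on the positive mass
   only and anchors each level at the midpoint of its own probability
   mass: the dominant zero-background level stays fixed, sections already
   sharing the average histogram map to themselves, and the quantile map
   stays stable on sparse sections (on synthetic volumes the bright tail
   holds a ~10⁻³ fraction of the voxels; a raw-CDF map amplifies tiny
   count fluctuations there into multi-level jumps that fragment blobs).
2. **Cell-body exclusion.** Non-specific somatic labeling in the Homer1
   channel is smoothed at σ = 140 nm, binarized at the lower three-class
   Otsu threshold, and connected components larger than
   `cellbody_min_voxels` (default 10⁵) are masked from all channels. Cell
   bodies are orders of magnitude larger than synaptic clusters, so the
   mask is insensitive to the exact threshold (tested over an order of
   magnitude).
3. **Background mask.** The diffraction-limited (conventional) image of
   each channel, thresholded at the lower three-class Otsu level,
   restricts the super-resolution image to regions with real labeling.
   The synthetic renderer emits a blurred, rescaled copy of each channel
   as its conventional counterpart; real-data users can supply their own.
4. **Clusters.** Channels are smoothed at σ = 77.5 nm, binarized at the
   *higher* Otsu threshold, and 26-connected 3D components are labeled.
   Components above the 99th volume percentile (or twice a configurable
   blob scale) are split by marker-controlled watershed on the
   anisotropic Euclidean distance transform; markers are EDT maxima, with
   candidates below half the component's peak distance suppressed (a thin
   neck must not seed a fragment) and survivors ≥ 200 nm apart. Clusters
   spanning fewer than two physical sections of raw signal, or touching
   any volume face, are dropped. All measurements (volume, total
   intensity, signal density = fraction of member voxels with positive
   raw intensity, intensity-weighted centroid) are taken on raw
   pre-smoothing intensities.
5. **Population gate.** Synaptic clusters and residual non-specific
   labels form two populations in (log₁₀ volume, signal density). A
   two-component Gaussian mixture on standardized features keeps the
   component greater on both axes; if neither dominates both axes, all
   clusters are kept with a warning. A manual polygon gate is available
   in config for users who prefer drawn gates; the automatic gate exists
   for reproducibility.

**Two-level Otsu.** Implemented exactly: prefix sums over the 256-level
histogram, exhaustive maximization of between-class variance over all
threshold pairs under the convention "a threshold t separates v ≤ t from
v > t", ties resolved to the lexicographically smallest pair. Requires
three distinct occupied levels.

## Pairing and eye assignment

For every cluster in channel A the features are (i) centroid distance to
the nearest B cluster and (ii) mean B-channel intensity in the 140-nm
shell outside the cluster surface (shell = voxels whose anisotropic
distance to the cluster's voxel set lies in (0, 140] nm). Features are
standardized and ordered by OPTICS reachability
(`min_samples` = max(5, 4% of features)); components are extracted at a
reachability cut of 2.5 × the median core reachability. A component is
labeled *paired* when its mean sits at low distance / high shell
intensity (within 0.25 sd of the grand mean or better on both axes) *and*
its mean distance is on the trans-synaptic apposition scale (≤ 250 nm
with positive shell signal). The absolute cap matters: a purely relative
rule would accept any homogeneous feature cloud, including
position-shuffled controls. Points OPTICS leaves unassigned are rescued
when they dominate an accepted pair on both features. Fewer than five
features fall back to hard thresholds (distance ≤ 140 nm, shell > 0); a
single feature is never paired. Homer–Bassoon pairing is reconciled
one-to-one (nearest claimant wins; the loser re-queries its next-nearest
unclaimed partner within the paired population's distance range).

Eye assignment applies the same machinery to (VGluT2, CTB), but without
one-to-one reconciliation: tracer colocalization is not exclusive, and
neighboring like-eye boutons can share one merged tracer cluster.
CTB-paired vesicle clusters are dominant-eye; the rest non-dominant.

## Input assembly

Active zones are Bassoon clusters that retained a Homer1 partner. Each is
associated to the VGluT2 cluster whose 140-nm surface shell contains its
weighted centroid (nearest surface wins when shells overlap; each AZ
counts once). Vesicle clusters with ≥ 2 AZs are mAZ inputs, with exactly
1 are sAZ; with 0 they are not retinogeniculate inputs. Inputs with more
than four AZs are kept but flagged. The docked-vesicle proxy is the
volume of segmented VGluT2 voxels within 70 nm outside each AZ's surface
(the AZ's own voxels are excluded; whether interior voxels should count
is unobservable here since Bassoon and VGluT2 are different channels).

## Spatial analysis

Distances follow one asymmetric convention throughout: shells expand from
the *surface* of the center input's vesicle cluster (implemented as
minimum anisotropic distance to the cluster's voxel centres — equal to
surface distance for solid clusters up to half-voxel quantization), and
the neighbor membership test uses the neighbor's weighted *centroid*. At
each radius r ∈ {1, 1.5, 2, 3, 4} µm the like-eye sAZ neighbors of every
input are counted; an input is *clustered* when at least one lies within
1.5 µm, *isolated* otherwise. Each sAZ is *near* when the nearest
like-eye mAZ surface is ≤ 1.5 µm from its centroid (boundary inclusive),
else *far*. Nearest-clustered-mAZ distances use the same convention and
exclude the input itself; with no clustered like-eye mAZ they are
undefined and flagged.

The null model redraws every sAZ position uniformly within the neuropil
mask (a uniformly drawn mask voxel plus uniform within-voxel jitter, so
the sample is continuously uniform over the masked region) while center
inputs stay fixed; shuffled sAZ are treated as points. Empirical
p-values are (1 + #{null ≥ observed}) / (1 + n_iterations), never zero at
finite iterations. Default 1000 iterations, config-exposed. Calibration
is verified against the Poisson closed form for complete spatial
randomness, P(≥ 1 neighbor within r) = 1 − exp(−λ 4/3 π r³), with
point-like centers kept ≥ 4 µm from the volume faces so spheres are not
truncated.

## Replicate statistics

Measurements are summarized per biological replicate and arm (eye or
input class): class densities over the neuropil volume, mAZ fraction,
median vesicle volume, mean AZ count, mean volume per AZ, docked volume,
clustered fractions, and mean nearby-sAZ counts. Arms are compared with
two-tailed paired t-tests across replicates (Cohen's d = mean/sd of
differences; 5/95% CI of the mean difference); cumulative distributions
with two-sample KS tests (rank-based epsilon squared,
ε² = H (n + 1)/(n² − 1) from the Kruskal–Wallis H). p-values are
Benjamini–Hochberg adjusted within each condition family at α = 0.05.
Pooled per-input comparisons via linear mixed models are intentionally
out of scope; the replicate-paired analysis is the primary reporting
path. Zero-variance difference vectors are rejected as degenerate rather
than silently returning p = NaN.

## Synthetic scenes: what they emulate, and what they do not

The generator draws Poisson counts per (class, eye) at configured
densities over the physical volume. Defaults describe a
contralateral-region neuropil during competition: total input density
≈ 0.0225 /µm³ with a dominant-eye excess, mAZ AZ-count mix
{2: 0.8, 3: 0.15, 4: 0.05}, vesicle volume = 0.35 µm³ × AZ count,
70% of sAZ synapses placed within 1.5 µm (surface-to-centroid) of a
like-eye mAZ input, 97% tracer efficiency, and 5% per-section gain
variance. Densities are free parameters of the generator, not published
values. Placements are rejection-sampled against a 200-nm minimum
surface separation and a margin that keeps planted structure clear of the
volume faces (so the edge filter removes nothing planted); mAZ inputs are
placed first and anchor clustered sAZ placement.

Rendering: vesicle clusters are axis-aligned ellipsoids with mild random
eccentricity (volume preserved exactly) and a near-constant intensity
plateau; AZ and Homer1 puncta are anisotropic Gaussian spots (σ = 60 nm
lateral) thresholded at render time; Homer1 puncta sit 50–150 nm outside
their AZ along the outward normal; CTB copies the vesicle ellipsoid
(+60 nm, the tracer filling the bouton slightly beyond the vesicle
cloud) for labeled inputs; cell bodies are bright spheres in
Homer1/Bassoon; background labels are small sparse speckles. Ellipsoids
are painted with a 40-nm surface inflation that compensates the erosion
of the smoothing + upper-Otsu segmentation (threshold offset ≈ 0.4 σ
above the edge half-height, plus a σ²/r curvature term), so the
segmented blob volume tracks the planted volume within a few percent —
this keeps the generator's volume and scaling contracts meaningful.

Not modelled: optical PSFs, localization precision, drift, chromatic
aberration, section loss or folds, and alignment errors — the renderer
emits an already-aligned stack because the analysis consumes aligned
stacks. Consequently, passing tests demonstrate the correctness and
calibration of the measurement and statistics chain on well-formed
aligned volumes; they do not certify robustness to acquisition artifacts
that upstream alignment and correction pipelines are responsible for.

## Determinism

Every stochastic stage receives a child seed spawned deterministically
from the master seed (`numpy` SeedSequence, kept below 2³¹); identical
config + seed reproduces all tables, volumes, and manifests
byte-identically. Data-dependent thresholds (Otsu levels, watershed
splits, population-gate means) are logged in the run manifest.

## Known limitations

- The synaptic-population gate assumes background labels are both smaller
  and sparser than synapses; heavy structured background would need the
  manual polygon gate.
- Two inputs whose vesicle clouds genuinely touch segment as one input
  unless the watershed trigger fires; the trigger is percentile-based and
  deliberately conservative.
- The shuffle null repositions sAZ synapses as points and does not forbid
  landing inside existing clusters; at realistic densities the overlap
  volume fraction is ≪ 1% and the effect on clustered fractions is far
  below Monte-Carlo error.
- Cluster "surface" distances are voxel-centre distances; all distance
  conventions are therefore consistent to half a voxel.
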