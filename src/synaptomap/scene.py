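"""Synthetic ground-truth scenes for retinogeniculate input analysis.

The generator plants retinogeniculate inputs with the statistical structure
the downstream analysis assumes: each input is one presynaptic vesicle
cluster (VGluT2) carrying one active zone (sAZ input) or 2-4 active zones
(mAZ input), each active zone being a Bassoon punctum apposed by exactly one
postsynaptic Homer1 punctum.  Vesicle-pool volume scales linearly with
active-zone count; inputs from the tracer-injected eye carry co-extensive
CTB signal with imperfect labeling efficiency; a configurable fraction of
single-active-zone inputs is placed near a like-eye multi-active-zone input
to emulate eye-specific synaptic clustering; nuisance structure (cell-body
blobs in the Homer1/Bassoon channels, small non-specific background labels
in every channel) exercises the cell-body and population filters.

The renderer emits an already-aligned anisotropic voxel stack: vesicle
clusters as solid ellipsoids with mild random eccentricity, active-zone and
Homer1 puncta as anisotropic Gaussian spots thresholded at render time, plus
a blurred "conventional" (diffraction-limited) counterpart of each channel.
Section-acquisition physics (drift, section loss, chromatic aberration) is
deliberately not modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .geometry import ImagingGeometry
from .volume import ALL_CHANNELS, MultiChannelVolume

__all__ = [
    "SceneParams",
    "PlantedInput",
    "GroundTruthScene",
    "generate_scene",
    "render_volume",
    "simulate",
]

UM3_TO_NM3 = 1e9


@dataclass
class SceneParams:
    """Generator configuration.

    Densities are inputs per um^3 of imaged volume; all lengths are um
    unless suffixed ``_nm``.  Defaults describe a contralateral-region
    neuropil during eye-specific competition: a modest excess of
    dominant-eye (eye A) inputs, mAZ inputs mostly carrying two active
    zones, ~70% of sAZ synapses placed near a like-eye mAZ input, and >97%
    tracer labeling efficiency.
    """

    density_sAZ_eyeA: float = 0.007
    density_sAZ_eyeB: float = 0.0055
    density_mAZ_eyeA: float = 0.006
    density_mAZ_eyeB: float = 0.004
    az_count_pmf: dict[int, float] = field(
        default_factory=lambda: {2: 0.8, 3: 0.15, 4: 0.05}
    )
    vesicle_volume_per_az: float = 0.35  # um^3 per active zone
    clustering_fraction: float = 0.7
    cluster_radius: float = 1.5  # um, surface-to-centroid
    ctb_label_efficiency: float = 0.97
    cell_body_count: int = 0
    cell_body_radius: float = 3.0  # um
    background_label_rate: float = 0.0  # spurious labels per um^3 per channel
    noise_sd: float = 0.0
    #: sd of the multiplicative per-section intensity gain (serial-section
    #: acquisition variance; corrected downstream by histogram normalization)
    section_gain_sd: float = 0.05
    seed: int = 0
    # rendering knobs (shape of planted structure, not study conditions)
    az_sigma_nm: float = 60.0
    homer_offset_range_nm: tuple[float, float] = (50.0, 150.0)
    min_separation_nm: float = 200.0
    eccentricity_range: tuple[float, float] = (0.85, 1.2)

    def validate(self) -> None:
        dens = (
            self.density_sAZ_eyeA,
            self.density_sAZ_eyeB,
            self.density_mAZ_eyeA,
            self.density_mAZ_eyeB,
        )
        if any(d < 0 for d in dens):
            raise ValueError("densities must be >= 0")
        total = sum(self.az_count_pmf.values())
        if self.az_count_pmf and abs(total - 1.0) > 1e-9:
            raise ValueError("az_count_pmf must sum to 1")
        if not all(2 <= k <= 4 for k in self.az_count_pmf):
            raise ValueError("az_count_pmf support must be within {2,3,4}")
        if not 0.0 <= self.clustering_fraction <= 1.0:
            raise ValueError("clustering_fraction must be in [0, 1]")
        if not 0.0 <= self.ctb_label_efficiency <= 1.0:
            raise ValueError("ctb_label_efficiency must be in [0, 1]")
        if self.vesicle_volume_per_az <= 0:
            raise ValueError("vesicle_volume_per_az must be positive")

    @classmethod
    def from_yaml(cls, path: str) -> "SceneParams":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        if "az_count_pmf" in raw:
            raw["az_count_pmf"] = {int(k): float(v) for k, v in raw["az_count_pmf"].items()}
        for key in ("homer_offset_range_nm", "eccentricity_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        params = cls(**raw)
        params.validate()
        return params


@dataclass
class PlantedInput:
    """Ground-truth record of one planted retinogeniculate input.

    Coordinates are (z, y, x) nm.  ``semi_axes_nm`` are the vesicle
    ellipsoid's axis-aligned semi-axes (z, y, x).
    """

    input_id: int
    input_class: str  # "sAZ" | "mAZ"
    eye: str  # "A" | "B"
    ctb_labeled: bool
    centroid_nm: np.ndarray
    semi_axes_nm: np.ndarray
    az_centroids_nm: list[np.ndarray]
    homer_centroids_nm: list[np.ndarray]
    vesicle_volume_um3: float

    @property
    def az_count(self) -> int:
        return len(self.az_centroids_nm)


@dataclass
class GroundTruthScene:
    """All planted inputs plus nuisance structure of one synthetic volume."""

    params: SceneParams
    geometry: ImagingGeometry
    inputs: list[PlantedInput]
    cell_bodies: list[tuple[np.ndarray, float]]  # (centroid nm, radius nm)
    neuropil_extent_nm: tuple[tuple[float, float], ...]  # per-axis (lo, hi)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.inputs:
            z, y, x = p.centroid_nm
            rows.append(
                dict(
                    id=p.input_id,
                    input_class=p.input_class,
                    eye=p.eye,
                    ctb=int(p.ctb_labeled),
                    x_nm=x,
                    y_nm=y,
                    z_nm=z,
                    az_count=p.az_count,
                    vesicle_volume_um3=p.vesicle_volume_um3,
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "id", "input_class", "eye", "ctb", "x_nm", "y_nm", "z_nm",
                "az_count", "vesicle_volume_um3",
            ],
        )

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str) -> None:
        payload = {
            "params": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.params).items()
            },
            "inputs": [
                dict(
                    id=p.input_id,
                    input_class=p.input_class,
                    eye=p.eye,
                    ctb=bool(p.ctb_labeled),
                    centroid_nm=[float(v) for v in p.centroid_nm],
                    az_centroids_nm=[[float(v) for v in c] for c in p.az_centroids_nm],
                    homer_centroids_nm=[[float(v) for v in c] for c in p.homer_centroids_nm],
                    az_count=p.az_count,
                    vesicle_volume_um3=p.vesicle_volume_um3,
                )
                for p in self.inputs
            ],
            "cell_bodies": [
                dict(centroid_nm=[float(v) for v in c], radius_nm=float(r))
                for c, r in self.cell_bodies
            ],
        }
        with open(path, "w") as f:
            json.dump(payload, f, indent=1)


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------


def _ellipsoid_radius_nm(semi_axes: np.ndarray, direction: np.ndarray) -> float:
    """Radius of an axis-aligned ellipsoid along a unit direction."""
    return 1.0 / np.sqrt(np.sum((direction / semi_axes) ** 2))


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _semi_axes_for_volume(
    volume_um3: float, rng: np.random.Generator, ecc: tuple[float, float]
) -> np.ndarray:
    r0 = (3.0 * volume_um3 * UM3_TO_NM3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    scales = rng.uniform(ecc[0], ecc[1], size=3)
    scales /= np.prod(scales) ** (1.0 / 3.0)  # preserve volume exactly
    return r0 * scales


def _surface_distance_nm(p: PlantedInput, point_nm: np.ndarray) -> float:
    """Approximate distance from a point to the input's ellipsoid surface."""
    d = point_nm - p.centroid_nm
    r = np.linalg.norm(d)
    if r == 0:
        return 0.0
    return max(0.0, r - _ellipsoid_radius_nm(p.semi_axes_nm, d / r))


def generate_scene(
    params: SceneParams, geometry: ImagingGeometry
) -> GroundTruthScene:
    """Plant retinogeniculate inputs according to ``params``.

    Realized per-class/per-eye counts are Poisson draws at the requested
    densities over the physical volume.  mAZ inputs are placed first; sAZ
    inputs are then placed near a random like-eye mAZ input (within
    ``cluster_radius`` surface-to-centroid) with probability
    ``clustering_fraction``, otherwise uniformly.  All placements are
    rejection-sampled against a minimum surface separation between inputs
    and against the volume margin, so planted structure survives the edge
    filter downstream.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 0]))
    vol_um3 = geometry.volume_um3
    total_density = (
        params.density_sAZ_eyeA
        + params.density_sAZ_eyeB
        + params.density_mAZ_eyeA
        + params.density_mAZ_eyeB
    )
    if total_density > 2.0:
        raise ValueError("overcrowded scene")

    ext = np.asarray(geometry.physical_size_nm)  # (z, y, x)
    counts = {
        ("mAZ", "A"): rng.poisson(params.density_mAZ_eyeA * vol_um3),
        ("mAZ", "B"): rng.poisson(params.density_mAZ_eyeB * vol_um3),
        ("sAZ", "A"): rng.poisson(params.density_sAZ_eyeA * vol_um3),
        ("sAZ", "B"): rng.poisson(params.density_sAZ_eyeB * vol_um3),
    }

    az_counts = sorted(params.az_count_pmf)
    az_probs = np.array([params.az_count_pmf[k] for k in az_counts], dtype=float)

    inputs: list[PlantedInput] = []
    next_id = 0

    def margin_for(semi_axes: np.ndarray) -> np.ndarray:
        pad = params.homer_offset_range_nm[1] + 4.0 * params.az_sigma_nm + 50.0
        return semi_axes + pad

    def placement_ok(centroid: np.ndarray, semi_axes: np.ndarray) -> bool:
        m = margin_for(semi_axes)
        if np.any(centroid < m) or np.any(centroid > ext - m):
            return False
        r_new = float(np.max(semi_axes))
        for q in inputs:
            gap = (
                np.linalg.norm(centroid - q.centroid_nm)
                - r_new
                - float(np.max(q.semi_axes_nm))
            )
            if gap < params.min_separation_nm:
                return False
        return True

    def place_uniform(semi_axes: np.ndarray) -> np.ndarray | None:
        m = margin_for(semi_axes)
        if np.any(ext - 2 * m <= 0):
            raise ValueError("overcrowded scene")  # blobs do not fit the volume
        for _ in range(2000):
            c = rng.uniform(m, ext - m)
            if placement_ok(c, semi_axes):
                return c
        return None

    def place_clustered(
        semi_axes: np.ndarray, anchors: list[PlantedInput]
    ) -> np.ndarray | None:
        for _ in range(2000):
            a = anchors[rng.integers(len(anchors))]
            u = _random_unit(rng)
            dist = rng.uniform(
                params.min_separation_nm + float(np.max(semi_axes)),
                params.cluster_radius * 1000.0,
            )
            c = a.centroid_nm + u * (
                _ellipsoid_radius_nm(a.semi_axes_nm, u) + dist
            )
            if placement_ok(c, semi_axes) and (
                _surface_distance_nm(a, c) <= params.cluster_radius * 1000.0
            ):
                return c
        return None

    def build_input(
        input_class: str, eye: str, centroid: np.ndarray, semi_axes: np.ndarray,
        n_az: int,
    ) -> PlantedInput:
        nonlocal next_id
        vesicle_volume = n_az * params.vesicle_volume_per_az
        # active zones sit just outside the ellipsoid surface, mutually
        # separated in angle so their puncta segment as distinct clusters
        directions: list[np.ndarray] = []
        for _ in range(n_az):
            for _ in range(200):
                u = _random_unit(rng)
                if all(float(np.dot(u, v)) < 0.45 for v in directions):
                    directions.append(u)
                    break
            else:
                directions.append(_random_unit(rng))
        az_centroids = []
        homer_centroids = []
        lo, hi = params.homer_offset_range_nm
        for u in directions:
            r_surf = _ellipsoid_radius_nm(semi_axes, u)
            az_c = centroid + u * (r_surf + 30.0)
            az_centroids.append(az_c)
            homer_centroids.append(az_c + u * rng.uniform(lo, hi))
        ctb = bool(eye == "A" and rng.random() < params.ctb_label_efficiency)
        planted = PlantedInput(
            input_id=next_id,
            input_class=input_class,
            eye=eye,
            ctb_labeled=ctb,
            centroid_nm=centroid,
            semi_axes_nm=semi_axes,
            az_centroids_nm=az_centroids,
            homer_centroids_nm=homer_centroids,
            vesicle_volume_um3=vesicle_volume,
        )
        next_id += 1
        return planted

    # mAZ inputs first: they anchor clustered sAZ placement
    for eye in ("A", "B"):
        for _ in range(counts[("mAZ", eye)]):
            n_az = int(rng.choice(az_counts, p=az_probs)) if az_counts else 2
            semi = _semi_axes_for_volume(
                n_az * params.vesicle_volume_per_az, rng, params.eccentricity_range
            )
            c = place_uniform(semi)
            if c is None:
                raise ValueError("overcrowded scene")
            inputs.append(build_input("mAZ", eye, c, semi, n_az))

    for eye in ("A", "B"):
        anchors = [p for p in inputs if p.input_class == "mAZ" and p.eye == eye]
        for _ in range(counts[("sAZ", eye)]):
            semi = _semi_axes_for_volume(
                params.vesicle_volume_per_az, rng, params.eccentricity_range
            )
            c = None
            if anchors and rng.random() < params.clustering_fraction:
                c = place_clustered(semi, anchors)
            if c is None:
                c = place_uniform(semi)
            if c is None:
                raise ValueError("overcrowded scene")
            inputs.append(build_input("sAZ", eye, c, semi, 1))

    cell_bodies = []
    for _ in range(params.cell_body_count):
        r_nm = params.cell_body_radius * 1000.0
        lo = np.minimum(r_nm * 0.5, ext / 2)
        hi = np.maximum(ext - r_nm * 0.5, ext / 2)
        # keep nuisance blobs off the planted synapses
        for _ in range(500):
            c = rng.uniform(lo, hi)
            if all(
                np.linalg.norm(c - q.centroid_nm)
                > r_nm + float(np.max(q.semi_axes_nm)) + 500.0
                for q in inputs
            ):
                break
        cell_bodies.append((c, r_nm))

    extent = tuple((0.0, float(e)) for e in ext)
    return GroundTruthScene(params, geometry, inputs, cell_bodies, extent)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _crop_slices(
    center_vox: np.ndarray, half_vox: np.ndarray, grid: tuple[int, int, int]
):
    lo = np.maximum(np.floor(center_vox - half_vox).astype(int), 0)
    hi = np.minimum(np.ceil(center_vox + half_vox).astype(int) + 1, grid)
    if np.any(hi <= lo):
        return None, None
    slices = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return slices, lo


def _paint_ellipsoid(
    arr: np.ndarray,
    geometry: ImagingGeometry,
    centroid_nm: np.ndarray,
    semi_axes_nm: np.ndarray,
    rng: np.random.Generator,
    inflate_nm: float = 0.0,
) -> None:
    """Solid ellipsoid with a near-constant interior intensity plateau.

    ``inflate_nm`` grows the painted surface; the default rendering uses a
    small inflation to compensate the curvature erosion of the smoothing +
    threshold segmentation so the segmented blob volume tracks the planted
    volume.
    """
    spacing = np.asarray(geometry.spacing_nm)
    semi = semi_axes_nm + inflate_nm
    c_vox = centroid_nm / spacing - 0.5
    half = semi / spacing + 1
    slices, lo = _crop_slices(c_vox, half, arr.shape)
    if slices is None:
        return
    zz, yy, xx = np.meshgrid(
        *[np.arange(s.start, s.stop) for s in slices], indexing="ij"
    )
    pts = (np.stack([zz, yy, xx], axis=-1) + 0.5) * spacing
    d = (pts - centroid_nm) / semi
    inside = np.sum(d * d, axis=-1) <= 1.0
    vals = rng.integers(215, 236, size=inside.shape, dtype=np.int64)
    sub = arr[slices]
    sub[inside] = np.maximum(sub[inside], vals[inside])


def _paint_punctum(
    arr: np.ndarray,
    geometry: ImagingGeometry,
    centroid_nm: np.ndarray,
    sigma_nm: float,
    amplitude: float = 255.0,
    cutoff: float = 45.0,
) -> None:
    """Anisotropic Gaussian spot thresholded at render time (compact punctum)."""
    spacing = np.asarray(geometry.spacing_nm)
    sigma = np.array([max(sigma_nm, 0.9 * geometry.voxel_z), sigma_nm, sigma_nm])
    c_vox = centroid_nm / spacing - 0.5
    half = 3.0 * sigma / spacing + 1
    slices, lo = _crop_slices(c_vox, half, arr.shape)
    if slices is None:
        return
    zz, yy, xx = np.meshgrid(
        *[np.arange(s.start, s.stop) for s in slices], indexing="ij"
    )
    pts = (np.stack([zz, yy, xx], axis=-1) + 0.5) * spacing
    d = (pts - centroid_nm) / sigma
    vals = amplitude * np.exp(-0.5 * np.sum(d * d, axis=-1))
    vals[vals < cutoff] = 0.0
    sub = arr[slices]
    np.maximum(sub, vals.astype(arr.dtype), out=sub)


def render_volume(
    scene: GroundTruthScene,
    geometry: ImagingGeometry | None = None,
    params: SceneParams | None = None,
) -> MultiChannelVolume:
    """Render a ground-truth scene as a four-channel 8-bit voxel stack.

    VGluT2 carries the vesicle ellipsoids, Bassoon the active-zone puncta,
    Homer1 the apposed postsynaptic puncta, and CTB a copy of the vesicle
    signal for tracer-labeled inputs.  Cell bodies are bright spheres in the
    Homer1 and Bassoon channels; background labels are small sparse voxel
    speckles in every channel.  A blurred, rescaled copy of each channel is
    emitted as its diffraction-limited "conventional" counterpart.
    Deterministic given (scene, params.seed).
    """
    geometry = geometry or scene.geometry
    params = params or scene.params
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 1]))
    grid = geometry.grid_shape
    work = {name: np.zeros(grid, dtype=np.float32) for name in ALL_CHANNELS}

    for p in scene.inputs:
        _paint_ellipsoid(
            work["vglut2"], geometry, p.centroid_nm, p.semi_axes_nm, rng,
            inflate_nm=40.0,
        )
        if p.ctb_labeled:
            # tracer fills the bouton slightly beyond the vesicle cloud, so
            # tracer signal reaches the colocalization shell
            _paint_ellipsoid(
                work["ctb"], geometry, p.centroid_nm, p.semi_axes_nm, rng,
                inflate_nm=60.0,
            )
        for az_c in p.az_centroids_nm:
            _paint_punctum(work["bassoon"], geometry, az_c, params.az_sigma_nm)
        for h_c in p.homer_centroids_nm:
            _paint_punctum(work["homer1"], geometry, h_c, params.az_sigma_nm)

    for centroid_nm, radius_nm in scene.cell_bodies:
        semi = np.array([radius_nm] * 3)
        for name in ("homer1", "bassoon"):
            _paint_ellipsoid(work[name], geometry, centroid_nm, semi, rng)

    n_bg = rng.poisson(params.background_label_rate * geometry.volume_um3, size=4)
    ext = np.asarray(geometry.physical_size_nm)
    spacing = np.asarray(geometry.spacing_nm)
    for name, count in zip(ALL_CHANNELS, n_bg):
        for _ in range(int(count)):
            center = rng.uniform(0, ext)
            k = int(rng.integers(4, 11))
            offsets = rng.normal(scale=120.0, size=(k, 3))
            pts = np.round((center + offsets) / spacing - 0.5).astype(int)
            pts = pts[np.all((pts >= 0) & (pts < grid), axis=1)]
            for z, y, x in pts:
                work[name][z, y, x] = max(
                    work[name][z, y, x], float(rng.integers(90, 180))
                )

    channels = {}
    conventional = {}
    blur_sigma_vox = geometry.sigma_to_voxels(300.0)
    for name in ALL_CHANNELS:
        arr = work[name]
        if params.section_gain_sd > 0:
            gains = rng.normal(1.0, params.section_gain_sd, size=grid[0])
            arr = arr * np.clip(gains, 0.5, 1.5)[:, None, None]
        if params.noise_sd > 0:
            arr = arr + rng.normal(scale=params.noise_sd, size=arr.shape)
        storm = np.clip(np.round(arr), 0, geometry.intensity_max).astype(np.uint8)
        channels[name] = storm
        conv = ndimage.gaussian_filter(storm.astype(np.float32), blur_sigma_vox)
        peak = conv.max()
        if peak > 0:
            conv = conv * (geometry.intensity_max / peak)
        conventional[name] = np.clip(np.round(conv), 0, geometry.intensity_max).astype(
            np.uint8
        )

    return MultiChannelVolume(geometry, channels, conventional)


def simulate(
    params: SceneParams, geometry: ImagingGeometry
) -> tuple[GroundTruthScene, MultiChannelVolume]:
    """Generate and render in one call."""
    scene = generate_scene(params, geometry)
    return scene, render_volume(scene, geometry, params)
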