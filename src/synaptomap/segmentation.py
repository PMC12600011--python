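"""Per-channel cluster segmentation of aligned multi-channel volumes.

The segmentation path mirrors the image-processing chain used for
serial-section localization volumes of synaptic immunolabels:

1. per-section histogram normalization to the cross-section average,
2. cell-body exclusion from a heavily smoothed Homer1 channel,
3. a coarse background mask from the conventional (diffraction-limited)
   image at the lower threshold of a three-class Otsu partition,
4. Gaussian smoothing (sigma = 77.5 nm) and binarization at the higher
   Otsu threshold,
5. 3D connected components, watershed splitting of oversized components,
6. section-span and volume-edge filters,
7. a two-population gate in (log volume, signal density) space separating
   synaptic clusters from non-specific labeling.

All sigmas and distances are physical (nm) and converted per axis, since
the voxel grid is anisotropic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image
from skimage.segmentation import watershed
from sklearn.mixture import GaussianMixture

from .geometry import ImagingGeometry
from .volume import MultiChannelVolume

__all__ = [
    "SegmentationConfig",
    "LabeledCluster",
    "two_level_otsu",
    "normalize_section_histograms",
    "cell_body_mask",
    "neuropil_mask",
    "split_touching_clusters",
    "detect_clusters",
    "select_synaptic_population",
    "segment_volume",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegmentationConfig:
    """Tunable segmentation parameters (all lengths in nm)."""

    sigma_cellbody_nm: float = 140.0
    sigma_cluster_nm: float = 77.5
    cellbody_min_voxels: int = 100_000
    min_section_span: int = 2
    watershed_enabled: bool = True
    #: components above this volume percentile are watershed candidates
    watershed_trigger_percentile: float = 99.0
    #: optional absolute scale; components > 2x this volume are candidates
    watershed_blob_scale_um3: float | None = None
    marker_min_separation_nm: float = 200.0
    population_mode: str = "auto"  # "auto" | "manual"
    #: manual mode: polygon vertices in (log10 volume_um3, signal_density)
    population_polygon: list[tuple[float, float]] | None = None
    normalize: bool = True


@dataclass
class LabeledCluster:
    """One connected component in one channel, measured on raw intensities."""

    id: int
    channel: str
    voxels: np.ndarray  # (n, 3) int indices (z, y, x)
    volume_voxels: int
    volume_um3: float
    total_intensity: float
    signal_density: float
    weighted_centroid_nm: np.ndarray  # (z, y, x)
    section_span: int
    is_edge: bool

    def voxel_coords_nm(self, geometry: ImagingGeometry) -> np.ndarray:
        """Physical voxel-centre coordinates (n, 3) in nm."""
        return geometry.voxel_to_nm(self.voxels)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------


def two_level_otsu(values: np.ndarray, nbins: int = 256) -> tuple[int, int]:
    """Three-class Otsu thresholds ``(t_low, t_high)`` on integer intensities.

    The pair maximizes between-class variance over all threshold pairs with
    the convention that a threshold ``t`` separates ``v <= t`` from
    ``v > t``; ties resolve to the lexicographically smallest pair, so
    ``t_low`` is the lowest intensity of the middle class minus anything
    below it.  Requires at least three distinct occupied intensity levels.
    """
    values = np.asarray(values)
    if values.dtype.kind == "f":
        values = np.round(values).astype(np.int64)
    flat = values.ravel()
    if flat.size == 0 or len(np.unique(flat)) < 3:
        raise ValueError("degenerate histogram")
    hist = np.bincount(flat, minlength=nbins).astype(np.float64)
    n_levels = hist.size
    total = hist.sum()
    levels = np.arange(n_levels, dtype=np.float64)
    cum_w = np.cumsum(hist)
    cum_s = np.cumsum(hist * levels)

    # classes for pair (t1 < t2): [0..t1], (t1..t2], (t2..end]
    t1 = np.arange(n_levels - 2)[:, None]
    t2 = np.arange(1, n_levels - 1)[None, :]
    valid = t1 < t2
    w0 = cum_w[t1] * np.ones_like(t2, dtype=float)
    s0 = cum_s[t1] * np.ones_like(t2, dtype=float)
    w1 = cum_w[t2] - cum_w[t1]
    s1 = cum_s[t2] - cum_s[t1]
    w2 = total - cum_w[t2] * np.ones_like(t1, dtype=float)
    s2 = cum_s[-1] - cum_s[t2] * np.ones_like(t1, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b = (
            np.where(w0 > 0, s0 * s0 / np.where(w0 > 0, w0, 1), 0.0)
            + np.where(w1 > 0, s1 * s1 / np.where(w1 > 0, w1, 1), 0.0)
            + np.where(w2 > 0, s2 * s2 / np.where(w2 > 0, w2, 1), 0.0)
        )
    var_b[~valid] = -np.inf
    idx = int(np.argmax(var_b))  # first max = lexicographically smallest pair
    i, j = divmod(idx, var_b.shape[1])
    return int(i), int(j + 1)


def _lower_otsu_mask(arr: np.ndarray, context: str) -> np.ndarray:
    """Binary mask at the lower three-class Otsu threshold, or all-True."""
    try:
        t_low, _ = two_level_otsu(arr)
    except ValueError:
        warnings.warn(f"{context}: degenerate histogram, mask skipped")
        return np.ones(arr.shape, dtype=bool)
    return arr > t_low


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def _match_to_average_histogram(stack: np.ndarray, n_levels: int) -> np.ndarray:
    """Quantile-map each z-section to the average histogram of all sections.

    Matching acts on the positive-intensity mass only (the zero background
    level is left fixed): serial-section gain variance scales the signal,
    not the empty background, and excluding the dominant zero level keeps
    the tail of the quantile map stable on sparse sections.  Each level is
    matched at the midpoint of its own probability mass via interpolation,
    so sections that already share the average histogram map to themselves.
    """
    nz = stack.shape[0]
    hists = np.stack(
        [np.bincount(stack[z].ravel(), minlength=n_levels) for z in range(nz)]
    )
    pos = hists[:, 1:].astype(float)  # levels 1..n_levels-1
    avg = pos.mean(axis=0)
    if avg.sum() == 0:
        return stack.copy()
    avg_pmf = avg / avg.sum()
    avg_cdf = np.cumsum(avg_pmf)
    avg_mid = avg_cdf - avg_pmf / 2.0
    levels = np.arange(1, n_levels, dtype=float)
    occ = avg_pmf > 0
    xp, fp = avg_mid[occ], levels[occ]
    out = stack.copy()
    for z in range(nz):
        total = pos[z].sum()
        if total == 0:
            continue
        pmf = pos[z] / total
        mid = np.cumsum(pmf) - pmf / 2.0
        mapped = np.clip(np.round(np.interp(mid, xp, fp)), 1, n_levels - 1)
        lut = np.concatenate([[0], mapped]).astype(stack.dtype)
        out[z] = lut[stack[z]]
    return out


def normalize_section_histograms(volume: MultiChannelVolume) -> MultiChannelVolume:
    """Histogram-match every section to the cross-section average, per channel.

    Corrects the per-section intensity variance inherent to serial-section
    acquisition, then rescales each channel to the full bit-depth range.
    Constant channels are returned unchanged with a warning.
    """
    n_levels = volume.geometry.intensity_max + 1

    def _normalize(name: str, arr: np.ndarray) -> np.ndarray:
        if arr.min() == arr.max():
            warnings.warn(f"channel {name!r} is constant; not normalized")
            return arr.copy()
        matched = _match_to_average_histogram(arr.astype(np.int64), n_levels)
        lo, hi = int(matched.min()), int(matched.max())
        if lo == hi:
            scaled = matched
        else:
            scaled = np.round(
                (matched - lo) * ((n_levels - 1) / (hi - lo))
            ).astype(np.int64)
        return scaled.astype(arr.dtype)

    channels = {k: _normalize(k, v) for k, v in volume.channels.items()}
    conventional = {k: _normalize(k, v) for k, v in volume.conventional.items()}
    return MultiChannelVolume(
        volume.geometry, channels, conventional, list(volume.section_ids)
    )


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


def cell_body_mask(
    channel: np.ndarray,
    geometry: ImagingGeometry,
    config: SegmentationConfig | None = None,
) -> np.ndarray:
    """Mask of non-specific cell-body labeling in a (Homer1) channel.

    The channel is Gaussian-smoothed at sigma = 140 nm, binarized at the
    lower three-class Otsu threshold, and 3D connected components larger
    than ``cellbody_min_voxels`` form the mask.  Cell bodies are orders of
    magnitude larger than synaptic clusters, so the result is robust to the
    exact voxel threshold.
    """
    config = config or SegmentationConfig()
    sigma = geometry.sigma_to_voxels(config.sigma_cellbody_nm)
    smoothed = np.round(
        ndimage.gaussian_filter(channel.astype(np.float32), sigma)
    ).astype(np.int64)
    try:
        t_low, _ = two_level_otsu(smoothed)
    except ValueError:
        return np.zeros(channel.shape, dtype=bool)
    binary = smoothed > t_low
    labels, n = ndimage.label(binary, structure=_STRUCT26)
    if n == 0:
        return np.zeros(channel.shape, dtype=bool)
    sizes = np.bincount(labels.ravel())
    big = np.flatnonzero(sizes > config.cellbody_min_voxels)
    big = big[big != 0]
    return np.isin(labels, big)


def neuropil_mask(
    ctb_channel: np.ndarray, cell_bodies: np.ndarray | None = None
) -> np.ndarray:
    """Analysis region: per-plane convex hull of CTB signal minus cell bodies.

    The tracer fills the labeled projection's territory; its convex hull
    per z-plane delimits the neuropil in which synapses are counted and
    positions are shuffled.
    """
    if ctb_channel.max() == 0:
        raise ValueError("cannot define neuropil")
    positive = _lower_otsu_mask(ctb_channel, "neuropil CTB")
    if positive.all():
        hull = positive
    else:
        hull = np.zeros(ctb_channel.shape, dtype=bool)
        for z in range(ctb_channel.shape[0]):
            if positive[z].any():
                hull[z] = convex_hull_image(positive[z])
    if cell_bodies is not None:
        hull = hull & ~cell_bodies
    return hull


# ---------------------------------------------------------------------------
# components and watershed
# ---------------------------------------------------------------------------


def split_touching_clusters(
    component_mask: np.ndarray,
    geometry: ImagingGeometry,
    min_separation_nm: float = 200.0,
) -> list[np.ndarray]:
    """Marker-controlled watershed split of one binary component.

    Markers are maxima of the anisotropic Euclidean distance transform,
    suppressed below half the component's peak distance (a thin neck
    between two blobs must not seed its own fragment), then merged so that
    surviving markers are >= ``min_separation_nm`` apart (highest-distance
    marker wins).  With a single marker the component is returned
    unchanged.  The returned voxel arrays partition the input exactly.
    """
    spacing = np.asarray(geometry.spacing_nm)
    dist = ndimage.distance_transform_edt(component_mask, sampling=spacing)
    foot = tuple(
        max(1, int(np.floor(min_separation_nm / s)) * 2 + 1) for s in spacing
    )
    local_max = (
        (ndimage.maximum_filter(dist, size=foot) == dist)
        & component_mask
        & (dist >= 0.5 * dist.max())
    )
    peaks = np.argwhere(local_max)
    if len(peaks) == 0:
        return [np.argwhere(component_mask)]
    order = np.argsort(-dist[tuple(peaks.T)], kind="stable")
    peaks = peaks[order]
    peaks_nm = peaks * spacing
    # greedy suppression: highest-distance peak wins within min_separation
    from scipy.spatial import cKDTree

    tree = cKDTree(peaks_nm)
    suppressed = np.zeros(len(peaks), dtype=bool)
    kept: list[int] = []
    for i in range(len(peaks)):
        if suppressed[i]:
            continue
        kept.append(i)
        for j in tree.query_ball_point(peaks_nm[i], min_separation_nm):
            if j != i:
                suppressed[j] = True
    if len(kept) <= 1:
        return [np.argwhere(component_mask)]
    markers = np.zeros(component_mask.shape, dtype=np.int32)
    for rank, i in enumerate(kept, start=1):
        markers[tuple(peaks[i])] = rank
    labels = watershed(-dist, markers, mask=component_mask)
    return [np.argwhere(labels == k) for k in range(1, len(kept) + 1)]


def _measure_cluster(
    cid: int,
    channel_name: str,
    voxels: np.ndarray,
    raw: np.ndarray,
    geometry: ImagingGeometry,
    section_ids: list[int],
) -> LabeledCluster:
    vals = raw[tuple(voxels.T)].astype(np.float64)
    total = float(vals.sum())
    coords_nm = geometry.voxel_to_nm(voxels)
    if total > 0:
        centroid = (coords_nm * vals[:, None]).sum(axis=0) / total
    else:
        centroid = coords_nm.mean(axis=0)
    nz, ny, nx = geometry.grid_shape
    zs = voxels[:, 0]
    # span counts sections carrying raw image information, not smoothed spill
    span_z = np.unique(zs[vals > 0]) if (vals > 0).any() else np.unique(zs)
    span = len({section_ids[z] for z in span_z})
    is_edge = bool(
        (voxels == 0).any()
        or (zs == nz - 1).any()
        or (voxels[:, 1] == ny - 1).any()
        or (voxels[:, 2] == nx - 1).any()
    )
    return LabeledCluster(
        id=cid,
        channel=channel_name,
        voxels=voxels,
        volume_voxels=len(voxels),
        volume_um3=len(voxels) * geometry.voxel_volume_um3,
        total_intensity=total,
        signal_density=float(np.mean(vals > 0)),
        weighted_centroid_nm=centroid,
        section_span=span,
        is_edge=is_edge,
    )


def detect_clusters(
    channel: np.ndarray,
    conventional_channel: np.ndarray | None,
    geometry: ImagingGeometry,
    config: SegmentationConfig | None = None,
    exclusion_mask: np.ndarray | None = None,
    channel_name: str = "",
    section_ids: list[int] | None = None,
    log: dict | None = None,
) -> list[LabeledCluster]:
    """Segment one normalized channel into labeled clusters.

    Pipeline order: exclusion (cell-body) masking; conventional-image
    lower-Otsu background mask; Gaussian smoothing at sigma = 77.5 nm and
    binarization at the higher Otsu threshold; 3D connected components
    (26-connectivity); watershed splitting of oversized components; drop of
    clusters spanning < ``min_section_span`` physical sections; drop of
    clusters touching the volume border.  All measurements are taken on the
    raw pre-smoothing intensities.
    """
    config = config or SegmentationConfig()
    section_ids = section_ids or list(range(geometry.grid_shape[0]))
    raw = channel.astype(np.int64)
    if exclusion_mask is not None:
        raw = np.where(exclusion_mask, 0, raw)
    work = raw
    if conventional_channel is not None:
        conv = conventional_channel
        if exclusion_mask is not None:
            conv = np.where(exclusion_mask, 0, conv)
        conv_mask = _lower_otsu_mask(conv, f"conventional {channel_name}")
        work = np.where(conv_mask, work, 0)
    smoothed = np.round(
        ndimage.gaussian_filter(
            work.astype(np.float32), geometry.sigma_to_voxels(config.sigma_cluster_nm)
        )
    ).astype(np.int64)
    try:
        t_low, t_high = two_level_otsu(smoothed)
    except ValueError:
        return []
    if log is not None:
        log[f"otsu_{channel_name}"] = (int(t_low), int(t_high))
    binary = smoothed > t_high
    labels, n = ndimage.label(binary, structure=_STRUCT26)
    if n == 0:
        return []

    slices = ndimage.find_objects(labels)
    voxel_sets: list[np.ndarray] = []
    sizes = np.bincount(labels.ravel())[1:]
    if config.watershed_enabled and n >= 2:
        trigger = np.percentile(sizes, config.watershed_trigger_percentile)
        if config.watershed_blob_scale_um3 is not None:
            trigger = min(
                trigger,
                2.0 * config.watershed_blob_scale_um3 / geometry.voxel_volume_um3,
            )
    else:
        trigger = np.inf
    n_split = 0
    for i, sl in enumerate(slices, start=1):
        comp = labels[sl] == i
        offset = np.array([s.start for s in sl])
        if sizes[i - 1] > trigger:
            parts = split_touching_clusters(
                comp, geometry, config.marker_min_separation_nm
            )
            n_split += len(parts) > 1
            voxel_sets.extend(p + offset for p in parts)
        else:
            voxel_sets.append(np.argwhere(comp) + offset)
    if log is not None:
        log[f"watershed_splits_{channel_name}"] = n_split

    clusters = []
    cid = 0
    for vox in voxel_sets:
        c = _measure_cluster(cid, channel_name, vox, raw, geometry, section_ids)
        if c.section_span < config.min_section_span or c.is_edge:
            continue
        c.id = cid = len(clusters)
        clusters.append(c)
        cid += 1
    return clusters


# ---------------------------------------------------------------------------
# population selection
# ---------------------------------------------------------------------------


def _point_in_polygon(px: float, py: float, poly: list[tuple[float, float]]) -> bool:
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_int:
                inside = not inside
    return inside


def select_synaptic_population(
    clusters: list[LabeledCluster],
    config: SegmentationConfig | None = None,
    log: dict | None = None,
) -> tuple[list[LabeledCluster], list[LabeledCluster]]:
    """Separate synaptic clusters from non-specific labeling.

    Clusters fall in two populations in (log10 volume, signal density)
    space: true synaptic structures are larger and denser than non-specific
    labels.  Auto mode fits a two-component Gaussian mixture and keeps the
    component whose mean is greater on both axes; if no component dominates
    on both axes every cluster is kept (with a warning).  Manual mode
    applies a config-supplied polygon gate instead.
    """
    config = config or SegmentationConfig()
    if len(clusters) < 2:
        return list(clusters), []
    feats = np.array(
        [[np.log10(c.volume_um3), c.signal_density] for c in clusters]
    )
    if config.population_mode == "manual":
        if not config.population_polygon:
            raise ValueError("manual mode requires population_polygon")
        keep = np.array(
            [_point_in_polygon(f[0], f[1], config.population_polygon) for f in feats]
        )
        if log is not None:
            log["population_mode"] = "manual"
    else:
        mu = feats.mean(axis=0)
        sd = feats.std(axis=0)
        sd[sd == 0] = 1.0
        z = (feats - mu) / sd
        gm = GaussianMixture(n_components=2, random_state=0, n_init=3)
        try:
            labels = gm.fit_predict(z)
        except ValueError:
            labels = np.zeros(len(clusters), dtype=int)
        means = gm.means_ * sd + mu if hasattr(gm, "means_") else None
        keep = None
        if means is not None and len(np.unique(labels)) == 2:
            if np.all(means[0] > means[1]):
                keep = labels == 0
            elif np.all(means[1] > means[0]):
                keep = labels == 1
        if keep is None:
            warnings.warn("population gate not separable; keeping all clusters")
            keep = np.ones(len(clusters), dtype=bool)
        if log is not None:
            log["population_mode"] = "auto"
            if means is not None:
                log["population_means"] = means.tolist()
    kept = [c for c, k in zip(clusters, keep) if k]
    rejected = [c for c, k in zip(clusters, keep) if not k]
    return kept, rejected


# ---------------------------------------------------------------------------
# channel orchestration
# ---------------------------------------------------------------------------


def segment_volume(
    volume: MultiChannelVolume,
    config: SegmentationConfig | None = None,
    log: dict | None = None,
) -> tuple[dict[str, list[LabeledCluster]], np.ndarray, np.ndarray]:
    """Full segmentation of a four-channel volume.

    Returns per-channel synaptic cluster lists, the cell-body mask and the
    neuropil mask.  CTB clusters are not population-gated (the tracer fills
    vesicle clusters of labeled inputs; the gate is applied to the synaptic
    immunolabels whose non-specific background it is designed to remove).
    """
    config = config or SegmentationConfig()
    vol = normalize_section_histograms(volume) if config.normalize else volume
    bodies = cell_body_mask(vol.channel("homer1"), vol.geometry, config)
    ctb_for_mask = vol.conventional.get("ctb", vol.channel("ctb"))
    try:
        neuropil = neuropil_mask(ctb_for_mask, bodies)
    except ValueError:
        warnings.warn("no CTB signal; neuropil defaults to the full volume")
        neuropil = ~bodies
    clusters: dict[str, list[LabeledCluster]] = {}
    for name in ("homer1", "bassoon", "vglut2", "ctb"):
        found = detect_clusters(
            vol.channel(name),
            vol.conventional.get(name),
            vol.geometry,
            config,
            exclusion_mask=bodies,
            channel_name=name,
            section_ids=vol.section_ids,
            log=log,
        )
        if name != "ctb":
            kept, rejected = select_synaptic_population(found, config, log=log)
        else:
            kept, rejected = found, []
        if log is not None:
            log[f"clusters_{name}"] = len(found)
            log[f"kept_{name}"] = len(kept)
        clusters[name] = kept
    return clusters, bodies, neuropil
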