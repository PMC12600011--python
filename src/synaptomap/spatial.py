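"""Eye-specific spatial clustering analysis of retinogeniculate inputs.

Neighborhood counting follows an asymmetric surface/centroid convention: a
search shell is expanded from the *surface* of each center input's vesicle
cluster, and a candidate sAZ synapse counts as a neighbor when its VGluT2
weighted *centroid* falls inside the expanded volume.  A center input is
"clustered" at the 1.5-um cutoff when at least one like-eye sAZ synapse
lies within that distance, "isolated" otherwise.  Observed statistics are
compared against a null ensemble in which sAZ positions are re-drawn
uniformly within the neuropil mask while mAZ inputs stay fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import ImagingGeometry
from .inputs import RetinogeniculateInput
from .segmentation import LabeledCluster

__all__ = [
    "InputPoint",
    "ClusteringRecord",
    "NullEnsemble",
    "points_from_inputs",
    "surface_distances",
    "shell_neighbor_counts",
    "label_clustered",
    "shuffle_null",
    "nearest_clustered_maz_distance",
    "near_far_saz",
]

DEFAULT_RADII_UM = (1.0, 1.5, 2.0, 3.0, 4.0)
CLUSTER_CUTOFF_UM = 1.5


@dataclass
class InputPoint:
    """Light-weight spatial view of one input.

    ``coords_nm`` holds the vesicle cluster's voxel-centre coordinates; a
    point-like input (no rendered cluster) has ``coords_nm = None`` and its
    surface collapses to the centroid.
    """

    input_id: int
    eye: str
    input_class: str  # "sAZ" | "mAZ"
    centroid_nm: np.ndarray
    coords_nm: np.ndarray | None = None

    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def surface_tree(self) -> cKDTree:
        if self._tree is None:
            pts = self.coords_nm if self.coords_nm is not None else self.centroid_nm[None, :]
            self._tree = cKDTree(pts)
        return self._tree


@dataclass
class ClusteringRecord:
    input_id: int
    eye: str
    input_class: str
    neighbor_counts: dict[float, int]  # radius um -> like-eye sAZ count
    clustered: bool | None = None
    n_nearby_saz: int | None = None
    dist_to_nearest_clustered_maz_um: float | None = None
    near_far: str | None = None  # sAZ only: "near" | "far"


def points_from_inputs(
    inputs: list[RetinogeniculateInput],
    vglut2_by_id: dict[int, LabeledCluster],
    geometry: ImagingGeometry,
) -> list[InputPoint]:
    pts = []
    for p in inputs:
        c = vglut2_by_id[p.vglut2_id]
        pts.append(
            InputPoint(
                input_id=p.input_id,
                eye=p.eye,
                input_class=p.input_class,
                centroid_nm=c.weighted_centroid_nm,
                coords_nm=c.voxel_coords_nm(geometry),
            )
        )
    return pts


def surface_distances(center: InputPoint, targets_nm: np.ndarray) -> np.ndarray:
    """Distance from the center's cluster surface to each target point (nm).

    Implemented as the minimum anisotropic-physical distance from each
    target to the cluster's voxel centres (equivalent to surface distance
    for solid clusters, up to half-voxel quantization).
    """
    if len(targets_nm) == 0:
        return np.empty(0)
    d, _ = center.surface_tree().query(np.atleast_2d(targets_nm))
    return d


def shell_neighbor_counts(
    centers: list[InputPoint],
    saz_points: list[InputPoint],
    radii_um: tuple[float, ...] = DEFAULT_RADII_UM,
    same_eye: bool = True,
) -> list[ClusteringRecord]:
    """Count sAZ synapses within expansion shells around each center input.

    For each center and radius r, counts sAZ synapses (of the same eye when
    ``same_eye``, of the opposite eye otherwise; always excluding the
    center itself) whose weighted centroid lies within r of the center's
    cluster surface.
    """
    radii_nm = np.asarray(sorted(radii_um)) * 1000.0
    records = []
    for center in centers:
        cands = [
            s
            for s in saz_points
            if s.input_id != center.input_id
            and ((s.eye == center.eye) == same_eye)
        ]
        if cands:
            targets = np.array([s.centroid_nm for s in cands])
            d = surface_distances(center, targets)
            counts = {
                float(r / 1000.0): int(np.count_nonzero(d <= r)) for r in radii_nm
            }
        else:
            counts = {float(r / 1000.0): 0 for r in radii_nm}
        records.append(
            ClusteringRecord(
                input_id=center.input_id,
                eye=center.eye,
                input_class=center.input_class,
                neighbor_counts=counts,
            )
        )
    return records


def label_clustered(
    records: list[ClusteringRecord], cutoff_um: float = CLUSTER_CUTOFF_UM
) -> list[ClusteringRecord]:
    """Set the clustered/isolated flag at the cutoff radius (>= 1 rule)."""
    for r in records:
        if cutoff_um not in r.neighbor_counts:
            raise ValueError(f"no neighbor count at cutoff {cutoff_um} um")
        r.n_nearby_saz = r.neighbor_counts[cutoff_um]
        r.clustered = r.n_nearby_saz >= 1
    return records


def clustered_fraction(records: list[ClusteringRecord], radius_um: float) -> float:
    if not records:
        return float("nan")
    return float(np.mean([r.neighbor_counts[radius_um] >= 1 for r in records]))


@dataclass
class NullEnsemble:
    """Shuffle-null distribution of clustered fractions per radius."""

    radii_um: tuple[float, ...]
    n_iterations: int
    seed: int
    #: (n_iterations, n_radii) clustered fraction of centers per iteration
    clustered_fractions: np.ndarray

    @property
    def mean(self) -> np.ndarray:
        return self.clustered_fractions.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.clustered_fractions.std(axis=0, ddof=1)

    def empirical_p(self, observed: np.ndarray) -> np.ndarray:
        """(1 + #{null >= observed}) / (1 + n) per radius."""
        obs = np.asarray(observed)
        ge = (self.clustered_fractions >= obs[None, :]).sum(axis=0)
        return (1.0 + ge) / (1.0 + self.n_iterations)

    def central_band(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        lo = np.quantile(self.clustered_fractions, (1 - level) / 2, axis=0)
        hi = np.quantile(self.clustered_fractions, 1 - (1 - level) / 2, axis=0)
        return lo, hi

    def summary_frame(self, observed: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            dict(radius_um=self.radii_um, null_mean=self.mean, null_sd=self.sd)
        )
        if observed is not None:
            df["observed"] = np.asarray(observed)
            df["p_empirical"] = self.empirical_p(np.asarray(observed))
        return df


def shuffle_null(
    centers: list[InputPoint],
    saz_points: list[InputPoint],
    neuropil_mask: np.ndarray,
    geometry: ImagingGeometry,
    radii_um: tuple[float, ...] = DEFAULT_RADII_UM,
    n_iterations: int = 1000,
    seed: int = 0,
    same_eye: bool = True,
) -> NullEnsemble:
    """Null ensemble: sAZ centroids re-drawn uniformly within the neuropil.

    Each iteration resamples every sAZ position (a uniformly drawn mask
    voxel plus a uniform within-voxel jitter, i.e. uniform over the masked
    region) while center inputs stay fixed, then recomputes the clustered
    fraction at every radius.  Shuffled sAZ synapses are treated as points.
    Deterministic given the seed.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    mask_vox = np.argwhere(neuropil_mask)
    if len(mask_vox) == 0:
        raise ValueError("empty neuropil mask")
    if len(saz_points) > len(mask_vox):
        raise ValueError("more sAZ synapses than neuropil voxels")
    rng = np.random.default_rng(seed)
    spacing = np.asarray(geometry.spacing_nm)
    radii = tuple(sorted(radii_um))
    radii_nm = np.asarray(radii) * 1000.0
    n_saz = len(saz_points)
    saz_eyes = np.array([s.eye for s in saz_points])
    fractions = np.empty((n_iterations, len(radii)))
    trees = [c.surface_tree() for c in centers]
    center_eyes = [c.eye for c in centers]
    center_ids = [c.input_id for c in centers]
    saz_ids = np.array([s.input_id for s in saz_points])
    for it in range(n_iterations):
        pick = rng.integers(0, len(mask_vox), size=n_saz)
        jitter = rng.uniform(0.0, 1.0, size=(n_saz, 3))
        pos = (mask_vox[pick] + jitter) * spacing
        clustered = np.zeros((len(centers), len(radii)), dtype=bool)
        for ci, (tree, eye, cid) in enumerate(zip(trees, center_eyes, center_ids)):
            sel = ((saz_eyes == eye) == same_eye) & (saz_ids != cid)
            if not sel.any():
                continue
            d, _ = tree.query(pos[sel])
            dmin = d.min() if d.size else np.inf
            clustered[ci] = dmin <= radii_nm
        fractions[it] = clustered.mean(axis=0)
    return NullEnsemble(radii, n_iterations, seed, fractions)


def nearest_clustered_maz_distance(
    maz_records: list[ClusteringRecord],
    maz_points: dict[int, InputPoint],
) -> list[ClusteringRecord]:
    """Distance from each mAZ input to the nearest like-eye clustered mAZ.

    Measured surface-to-centroid (center surface to neighbor centroid),
    excluding the input itself.  Inputs of an eye with no clustered mAZ
    keep ``None`` (flagged undefined).
    """
    for rec in maz_records:
        others = [
            o
            for o in maz_records
            if o.eye == rec.eye and o.clustered and o.input_id != rec.input_id
        ]
        if not others:
            rec.dist_to_nearest_clustered_maz_um = None
            continue
        targets = np.array([maz_points[o.input_id].centroid_nm for o in others])
        d = surface_distances(maz_points[rec.input_id], targets)
        rec.dist_to_nearest_clustered_maz_um = float(d.min() / 1000.0)
    return maz_records


def near_far_saz(
    saz_records: list[ClusteringRecord],
    maz_points: list[InputPoint],
    saz_points: dict[int, InputPoint],
    cutoff_um: float = CLUSTER_CUTOFF_UM,
) -> list[ClusteringRecord]:
    """Classify each sAZ synapse near (<= cutoff) / far from like-eye mAZ.

    Distance is from the nearest like-eye mAZ input's surface to the sAZ
    centroid (the same asymmetric convention as the expansion search).
    Without any like-eye mAZ input, every sAZ is far.
    """
    by_eye: dict[str, list[InputPoint]] = {}
    for m in maz_points:
        by_eye.setdefault(m.eye, []).append(m)
    for rec in saz_records:
        centers = by_eye.get(rec.eye, [])
        if not centers:
            rec.near_far = "far"
            continue
        centroid = saz_points[rec.input_id].centroid_nm
        dmin = min(
            float(surface_distances(m, centroid[None, :])[0]) for m in centers
        )
        rec.near_far = "near" if dmin <= cutoff_um * 1000.0 else "far"
    return saz_records


def records_to_frame(records: list[ClusteringRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = dict(
            input_id=r.input_id,
            eye=r.eye,
            input_class=r.input_class,
            clustered=r.clustered,
            n_nearby_saz=r.n_nearby_saz,
            dist_to_nearest_clustered_maz_um=r.dist_to_nearest_clustered_maz_um,
            near_far=r.near_far,
        )
        for radius, count in r.neighbor_counts.items():
            row[f"count_r{radius:g}um"] = count
        rows.append(row)
    return pd.DataFrame(rows)
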