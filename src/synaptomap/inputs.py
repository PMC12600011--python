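"""Retinogeniculate input assembly and sAZ/mAZ classification.

A retinogeniculate input is one contiguous VGluT2 vesicle cluster together
with all its associated active zones — Bassoon clusters that carry a Homer1
partner and whose weighted centroid lies within a 140-nm shell extended
from the VGluT2 cluster surface.  Inputs with a single associated active
zone are sAZ synapses; inputs with two or more are mAZ inputs.  The
VGluT2 volume within a 70-nm shell around each active zone serves as a
proxy for the docked (readily releasable) vesicle pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import ImagingGeometry
from .segmentation import LabeledCluster

__all__ = [
    "RetinogeniculateInput",
    "associate_azs",
    "classify_inputs",
    "docked_vesicle_volume",
    "build_inputs",
    "inputs_to_frame",
    "summarize_by_group",
]


@dataclass
class RetinogeniculateInput:
    input_id: int
    vglut2_id: int
    az_ids: list[int]
    homer_ids: list[int]
    eye: str  # "dominant" | "non_dominant"
    vesicle_volume_um3: float
    docked_volume_per_az: list[float] = field(default_factory=list)
    flagged_high_az: bool = False

    @property
    def az_count(self) -> int:
        return len(self.az_ids)

    @property
    def input_class(self) -> str:
        return "mAZ" if self.az_count >= 2 else "sAZ"

    @property
    def volume_per_az(self) -> float:
        return self.vesicle_volume_um3 / self.az_count

    @property
    def mean_docked_volume(self) -> float:
        return float(np.mean(self.docked_volume_per_az)) if self.docked_volume_per_az else 0.0


def associate_azs(
    vglut2_clusters: list[LabeledCluster],
    bassoon_clusters: list[LabeledCluster],
    geometry: ImagingGeometry,
    shell_nm: float = 140.0,
) -> dict[int, list[int]]:
    """Assign each active zone to at most one vesicle cluster.

    A Bassoon cluster is associated with a VGluT2 cluster when its weighted
    centroid lies within ``shell_nm`` of the VGluT2 cluster's voxel set
    (anisotropic Euclidean surface distance; centroids inside the cluster
    count as distance 0).  When a centroid falls within the shell of
    several vesicle clusters it is assigned to the nearest surface only.
    Returns vglut2_id -> list of associated bassoon ids (possibly empty).
    """
    result: dict[int, list[int]] = {c.id: [] for c in vglut2_clusters}
    if not vglut2_clusters or not bassoon_clusters:
        return result
    b_centroids = np.array([b.weighted_centroid_nm for b in bassoon_clusters])
    n_b = len(bassoon_clusters)
    best_dist = np.full(n_b, np.inf)
    best_v = np.full(n_b, -1, dtype=int)
    for v in vglut2_clusters:
        tree = cKDTree(v.voxel_coords_nm(geometry))
        d, _ = tree.query(b_centroids)
        better = (d <= shell_nm) & (d < best_dist)
        best_dist[better] = d[better]
        best_v[better] = v.id
    for j, b in enumerate(bassoon_clusters):
        if best_v[j] >= 0:
            result[int(best_v[j])].append(b.id)
    return result


def docked_vesicle_volume(
    az: LabeledCluster,
    vglut2_mask: np.ndarray,
    geometry: ImagingGeometry,
    shell_nm: float = 70.0,
) -> float:
    """VGluT2 volume (um^3) within ``shell_nm`` of the active zone surface.

    Counts segmented-VGluT2 voxels whose distance to the AZ voxel set lies
    in (0, shell_nm]; the AZ's own voxels are excluded.  Computed on a
    padded bounding-box crop.
    """
    spacing = np.asarray(geometry.spacing_nm)
    pad = np.ceil(shell_nm / spacing).astype(int) + 1
    grid = np.asarray(geometry.grid_shape)
    lo = np.maximum(az.voxels.min(axis=0) - pad, 0)
    hi = np.minimum(az.voxels.max(axis=0) + pad + 1, grid)
    member = np.zeros(tuple(hi - lo), dtype=bool)
    member[tuple((az.voxels - lo).T)] = True
    dist = ndimage.distance_transform_edt(~member, sampling=spacing)
    shell = (dist > 0) & (dist <= shell_nm)
    crop = vglut2_mask[tuple(slice(a, b) for a, b in zip(lo, hi))]
    return float(np.count_nonzero(crop & shell)) * geometry.voxel_volume_um3


def classify_inputs(
    associations: dict[int, list[int]],
    vglut2_by_id: dict[int, LabeledCluster],
    eye_by_vglut2: dict[int, str],
    homer_by_bassoon: dict[int, int],
) -> list[RetinogeniculateInput]:
    """Assemble inputs from AZ associations; clusters with no AZ are dropped.

    Inputs with more than four active zones are retained but flagged (they
    are rare and usually reflect segmentation merges).
    """
    inputs = []
    for vid in sorted(associations):
        az_ids = sorted(associations[vid])
        if not az_ids:
            continue
        inputs.append(
            RetinogeniculateInput(
                input_id=len(inputs),
                vglut2_id=vid,
                az_ids=az_ids,
                homer_ids=[homer_by_bassoon.get(a, -1) for a in az_ids],
                eye=eye_by_vglut2.get(vid, "non_dominant"),
                vesicle_volume_um3=vglut2_by_id[vid].volume_um3,
                flagged_high_az=len(az_ids) > 4,
            )
        )
    return inputs


def build_inputs(
    vglut2_clusters: list[LabeledCluster],
    bassoon_clusters: list[LabeledCluster],
    paired_bassoon_ids: set[int],
    homer_by_bassoon: dict[int, int],
    eye_by_vglut2: dict[int, str],
    geometry: ImagingGeometry,
    vglut2_mask: np.ndarray | None = None,
    shell_nm: float = 140.0,
    docked_shell_nm: float = 70.0,
) -> list[RetinogeniculateInput]:
    """Full assembly: restrict AZs to Homer-paired Bassoon clusters,
    associate them with vesicle clusters, classify, and (optionally)
    measure docked-vesicle volume against the segmented VGluT2 mask."""
    paired = [b for b in bassoon_clusters if b.id in paired_bassoon_ids]
    associations = associate_azs(vglut2_clusters, paired, geometry, shell_nm)
    vglut2_by_id = {c.id: c for c in vglut2_clusters}
    inputs = classify_inputs(associations, vglut2_by_id, eye_by_vglut2, homer_by_bassoon)
    if vglut2_mask is not None:
        az_by_id = {b.id: b for b in paired}
        for inp in inputs:
            inp.docked_volume_per_az = [
                docked_vesicle_volume(az_by_id[a], vglut2_mask, geometry, docked_shell_nm)
                for a in inp.az_ids
            ]
    return inputs


def inputs_to_frame(
    inputs: list[RetinogeniculateInput],
    vglut2_by_id: dict[int, LabeledCluster] | None = None,
) -> pd.DataFrame:
    rows = []
    for p in inputs:
        row = dict(
            input_id=p.input_id,
            vglut2_id=p.vglut2_id,
            eye=p.eye,
            input_class=p.input_class,
            az_count=p.az_count,
            vesicle_volume_um3=p.vesicle_volume_um3,
            volume_per_az=p.volume_per_az,
            mean_docked_volume_um3=p.mean_docked_volume,
            flagged_high_az=p.flagged_high_az,
        )
        if vglut2_by_id is not None:
            z, y, x = vglut2_by_id[p.vglut2_id].weighted_centroid_nm
            row.update(x_nm=x, y_nm=y, z_nm=z)
        rows.append(row)
    cols = [
        "input_id", "vglut2_id", "eye", "input_class", "az_count",
        "vesicle_volume_um3", "volume_per_az", "mean_docked_volume_um3",
        "flagged_high_az",
    ]
    if vglut2_by_id is not None:
        cols += ["x_nm", "y_nm", "z_nm"]
    return pd.DataFrame(rows, columns=cols)


def summarize_by_group(
    inputs: list[RetinogeniculateInput],
    neuropil_volume_um3: float,
    group_keys: tuple[str, ...] = ("eye", "input_class"),
) -> pd.DataFrame:
    """Per-group densities and presynaptic measurements.

    Densities use the neuropil mask volume as denominator; the mAZ fraction
    is computed within each eye (mAZ inputs / all inputs of that eye).
    """
    if neuropil_volume_um3 <= 0:
        raise ValueError("neuropil volume must be positive")
    df = inputs_to_frame(inputs)
    if df.empty:
        return pd.DataFrame()
    eye_totals = df.groupby("eye").size()
    rows = []
    for keys, g in df.groupby(list(group_keys)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        rec = dict(zip(group_keys, keys))
        rec.update(
            n_inputs=len(g),
            density_per_um3=len(g) / neuropil_volume_um3,
            median_vesicle_volume_um3=float(g.vesicle_volume_um3.median()),
            mean_vesicle_volume_um3=float(g.vesicle_volume_um3.mean()),
            mean_az_count=float(g.az_count.mean()),
            mean_volume_per_az=float(g.volume_per_az.mean()),
            mean_docked_volume_um3=float(g.mean_docked_volume_um3.mean()),
        )
        if "eye" in group_keys and "input_class" in group_keys:
            eye = rec["eye"]
            maz = len(df[(df.eye == eye) & (df.input_class == "mAZ")])
            rec["maz_fraction_of_eye"] = maz / eye_totals[eye]
        rows.append(rec)
    return pd.DataFrame(rows)
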