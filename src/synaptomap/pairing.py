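"""Trans-synaptic cluster pairing and eye-of-origin assignment.

Synapses are defined as paired pre/postsynaptic clusters: for every cluster
in one channel we measure (i) the centroid-to-centroid distance to the
nearest opposing-channel cluster and (ii) the opposing-channel signal within
a 140-nm shell around the cluster surface.  In this two-dimensional feature
space, genuine pairs form a dense component at low distance and high shell
signal which is extracted with the OPTICS density-clustering algorithm;
everything not reachable from that component stays unpaired.  The same
machinery applied to (VGluT2, CTB) assigns eye-of-origin: tracer-paired
vesicle clusters are dominant-eye, the rest non-dominant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn.cluster import OPTICS, cluster_optics_dbscan

from .geometry import ImagingGeometry
from .segmentation import LabeledCluster

__all__ = [
    "PairingConfig",
    "PairFeature",
    "PairDecision",
    "shell_mean_intensity",
    "compute_pair_features",
    "select_pairs",
    "assign_eye",
]


@dataclass
class PairingConfig:
    shell_nm: float = 140.0
    #: OPTICS min_samples; a fraction of the feature count when < 1
    min_samples: float = 0.04
    min_samples_floor: int = 5
    #: reachability cut = eps_reachability_factor x median core reachability
    eps_reachability_factor: float = 2.5
    #: acceptance margin (in sd units) for the paired component's mean
    accept_margin: float = 0.25
    #: absolute plausibility cap: an accepted component's mean centroid
    #: distance must be on the trans-synaptic apposition scale
    pair_distance_cap_nm: float = 250.0
    #: hard-threshold fallback when fewer than ``min_samples`` features exist
    fallback_distance_nm: float = 140.0

    def resolve_min_samples(self, n: int) -> int:
        ms = self.min_samples
        if ms < 1:
            ms = max(self.min_samples_floor, round(ms * n))
        return int(min(ms, max(n - 1, 2)))


@dataclass
class PairFeature:
    cluster_id: int
    partner_id: int
    centroid_distance: float  # nm
    shell_intensity: float  # mean opposing-channel intensity in the shell


@dataclass
class PairDecision:
    cluster_id: int
    partner_id: int | None
    is_paired: bool
    method_tag: str = ""


def shell_mean_intensity(
    cluster: LabeledCluster,
    opposing_raw: np.ndarray,
    geometry: ImagingGeometry,
    shell_nm: float = 140.0,
) -> float:
    """Mean opposing-channel intensity within ``shell_nm`` of the cluster surface.

    The shell contains voxels whose anisotropic Euclidean distance to the
    cluster's voxel set is in (0, shell_nm]; the cluster's own voxels are
    excluded.  Computed on a padded bounding-box crop.
    """
    spacing = np.asarray(geometry.spacing_nm)
    pad = np.ceil(shell_nm / spacing).astype(int) + 1
    grid = np.asarray(geometry.grid_shape)
    lo = np.maximum(cluster.voxels.min(axis=0) - pad, 0)
    hi = np.minimum(cluster.voxels.max(axis=0) + pad + 1, grid)
    crop_shape = tuple(hi - lo)
    member = np.zeros(crop_shape, dtype=bool)
    member[tuple((cluster.voxels - lo).T)] = True
    dist = ndimage.distance_transform_edt(~member, sampling=spacing)
    shell = (dist > 0) & (dist <= shell_nm)
    n_shell = int(shell.sum())
    if n_shell == 0:
        return 0.0
    crop = opposing_raw[tuple(slice(a, b) for a, b in zip(lo, hi))]
    return float(crop[shell].sum()) / n_shell


def compute_pair_features(
    clusters_a: list[LabeledCluster],
    clusters_b: list[LabeledCluster],
    raw_b: np.ndarray,
    geometry: ImagingGeometry,
    shell_nm: float = 140.0,
) -> list[PairFeature]:
    """Pairing features for every A-cluster against the B channel."""
    if not clusters_b:
        raise ValueError("no opposing clusters")
    b_centroids = np.array([c.weighted_centroid_nm for c in clusters_b])
    tree = cKDTree(b_centroids)
    features = []
    for c in clusters_a:
        d, j = tree.query(c.weighted_centroid_nm)
        features.append(
            PairFeature(
                cluster_id=c.id,
                partner_id=clusters_b[int(j)].id,
                centroid_distance=float(d),
                shell_intensity=shell_mean_intensity(c, raw_b, geometry, shell_nm),
            )
        )
    return features


def _reconcile(
    decisions: list[PairDecision],
    features_by_id: dict[int, PairFeature],
    a_centroids: dict[int, np.ndarray] | None,
    b_centroids: dict[int, np.ndarray] | None,
    max_distance: float,
) -> None:
    """Enforce one-to-one pairing: closest claimant keeps a contested partner.

    Losers re-query their next-nearest unclaimed partner and stay paired
    only if that partner lies within the paired population's distance range.
    """
    paired = [d for d in decisions if d.is_paired]
    paired.sort(key=lambda d: features_by_id[d.cluster_id].centroid_distance)
    claimed: set[int] = set()
    for d in paired:
        if d.partner_id not in claimed:
            claimed.add(d.partner_id)
            continue
        # contested: re-query nearest unclaimed partner
        reassigned = False
        if a_centroids is not None and b_centroids is not None:
            free = [(bid, c) for bid, c in b_centroids.items() if bid not in claimed]
            if free:
                pos = a_centroids[d.cluster_id]
                dists = [float(np.linalg.norm(pos - c)) for _, c in free]
                k = int(np.argmin(dists))
                if dists[k] <= max_distance:
                    d.partner_id = free[k][0]
                    d.method_tag += "+requeried"
                    claimed.add(d.partner_id)
                    reassigned = True
        if not reassigned:
            d.partner_id = None
            d.is_paired = False
            d.method_tag = "conflict_unpaired"


def select_pairs(
    features: list[PairFeature],
    config: PairingConfig | None = None,
    a_centroids: dict[int, np.ndarray] | None = None,
    b_centroids: dict[int, np.ndarray] | None = None,
    one_to_one: bool = True,
) -> list[PairDecision]:
    """Label each feature paired/unpaired by density clustering.

    Features are standardized and ordered canonically (so decisions do not
    depend on input list order), then ordered by OPTICS reachability;
    components are extracted at a data-driven reachability cut (a multiple
    of the median core reachability).  A component is labeled paired when
    its mean sits at low centroid distance and high shell intensity
    (within ``accept_margin`` sd of the grand mean or better on both
    axes) and its mean distance lies on the trans-synaptic apposition
    scale (``pair_distance_cap_nm``), which rejects homogeneous clouds of
    far distractors.  Points left unassigned are rescued if they dominate
    an accepted pair on both features.  With fewer than ``min_samples``
    features a hard threshold (distance <= 140 nm, shell intensity > 0)
    is used instead.  After labeling, pairing is reconciled one-to-one.
    """
    config = config or PairingConfig()
    if not features:
        return []
    order = sorted(
        range(len(features)),
        key=lambda i: (
            features[i].centroid_distance,
            -features[i].shell_intensity,
            features[i].cluster_id,
        ),
    )
    feats = [features[i] for i in order]
    X = np.array([[f.centroid_distance, f.shell_intensity] for f in feats])

    min_samples = config.resolve_min_samples(len(feats))
    if len(feats) == 1:
        # a lone feature cannot form a density cluster
        f = feats[0]
        return [PairDecision(f.cluster_id, None, False, "singleton")]
    if len(feats) < config.min_samples_floor:
        is_paired = (X[:, 0] <= config.fallback_distance_nm) & (X[:, 1] > 0)
        tag = "threshold_fallback"
    elif np.allclose(X, X[0]):
        warnings.warn("all pairing features identical; nothing paired")
        is_paired = np.zeros(len(feats), dtype=bool)
        tag = "degenerate"
    else:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        optics = OPTICS(min_samples=min_samples)
        optics.fit(Z)
        reach = optics.reachability_[np.isfinite(optics.reachability_)]
        eps = config.eps_reachability_factor * float(np.median(reach))
        labels = cluster_optics_dbscan(
            reachability=optics.reachability_,
            core_distances=optics.core_distances_,
            ordering=optics.ordering_,
            eps=eps,
        )
        is_paired = np.zeros(len(feats), dtype=bool)
        m = config.accept_margin
        for lab in np.unique(labels):
            if lab < 0:
                continue
            sel = labels == lab
            if (
                Z[sel, 0].mean() <= m
                and Z[sel, 1].mean() >= -m
                and X[sel, 0].mean() <= config.pair_distance_cap_nm
                and X[sel, 1].mean() > 0
            ):
                is_paired |= sel
        if is_paired.any():
            # fringe rescue: points dominating an accepted pair on both axes
            dmax = X[is_paired, 0].max()
            smin = X[is_paired, 1].min()
            rescue = (~is_paired) & (X[:, 0] <= dmax) & (X[:, 1] >= smin)
            is_paired |= rescue
        tag = "optics"

    decisions = [
        PairDecision(
            cluster_id=f.cluster_id,
            partner_id=f.partner_id if p else None,
            is_paired=bool(p),
            method_tag=tag if p else "",
        )
        for f, p in zip(feats, is_paired)
    ]
    if one_to_one:
        features_by_id = {f.cluster_id: f for f in feats}
        paired_d = [
            features_by_id[d.cluster_id].centroid_distance
            for d in decisions
            if d.is_paired
        ]
        max_distance = max(paired_d) if paired_d else config.fallback_distance_nm
        _reconcile(decisions, features_by_id, a_centroids, b_centroids, max_distance)
    decisions.sort(key=lambda d: d.cluster_id)
    return decisions


def pair_channels(
    clusters_a: list[LabeledCluster],
    clusters_b: list[LabeledCluster],
    raw_b: np.ndarray,
    geometry: ImagingGeometry,
    config: PairingConfig | None = None,
) -> tuple[list[PairFeature], list[PairDecision]]:
    """Convenience wrapper: features + decisions with re-query support."""
    config = config or PairingConfig()
    features = compute_pair_features(
        clusters_a, clusters_b, raw_b, geometry, config.shell_nm
    )
    a_centroids = {c.id: c.weighted_centroid_nm for c in clusters_a}
    b_centroids = {c.id: c.weighted_centroid_nm for c in clusters_b}
    decisions = select_pairs(features, config, a_centroids, b_centroids)
    return features, decisions


def assign_eye(
    vglut2: list[LabeledCluster],
    ctb: list[LabeledCluster],
    raw_ctb: np.ndarray,
    geometry: ImagingGeometry,
    config: PairingConfig | None = None,
) -> dict[int, str]:
    """Eye-of-origin per vesicle cluster via tracer colocalization.

    CTB-paired VGluT2 clusters are ``dominant`` (tracer-injected eye);
    unpaired clusters are ``non_dominant``.  Unlike trans-synaptic pairing,
    tracer colocalization is not exclusive: neighboring like-eye vesicle
    clusters may legitimately share one tracer cluster, so no one-to-one
    reconciliation is applied.  With no CTB clusters at all, every input is
    non-dominant (with a warning).
    """
    if not ctb:
        warnings.warn("no CTB clusters; all inputs assigned non_dominant")
        return {c.id: "non_dominant" for c in vglut2}
    features = compute_pair_features(
        vglut2, ctb, raw_ctb, geometry, (config or PairingConfig()).shell_nm
    )
    decisions = select_pairs(features, config, one_to_one=False)
    by_id = {d.cluster_id: d for d in decisions}
    return {
        c.id: "dominant" if by_id[c.id].is_paired else "non_dominant"
        for c in vglut2
    }
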