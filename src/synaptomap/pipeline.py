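"""End-to-end orchestration: simulate -> segment -> pair -> classify ->
spatial -> stats, with deterministic seeding and a provenance manifest.

Stage interfaces are file-based (volumes + CSV tables) so stages can be
re-run independently; the in-memory chaining used here is an optimization,
not the contract.  All randomness flows from ``RunConfig.seed`` through
spawned child seeds; re-running an identical config reproduces every output
byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import warnings

import numpy as np
import pandas as pd
import yaml

from .geometry import ImagingGeometry
from .inputs import build_inputs, inputs_to_frame
from .pairing import PairingConfig, assign_eye, pair_channels
from .scene import GroundTruthScene, SceneParams, generate_scene, render_volume
from .segmentation import SegmentationConfig, segment_volume
from .spatial import (
    DEFAULT_RADII_UM,
    CLUSTER_CUTOFF_UM,
    clustered_fraction,
    label_clustered,
    near_far_saz,
    nearest_clustered_maz_distance,
    points_from_inputs,
    records_to_frame,
    shell_neighbor_counts,
    shuffle_null,
)
from .stats import paired_family_tests, replicate_summary
from .volume import MultiChannelVolume, read_volume, write_volume

__all__ = ["RunConfig", "ReplicateResult", "run_replicate", "run_pipeline"]


@dataclasses.dataclass
class RunConfig:
    geometry: ImagingGeometry = dataclasses.field(default_factory=ImagingGeometry)
    scene: SceneParams = dataclasses.field(default_factory=SceneParams)
    segmentation: SegmentationConfig = dataclasses.field(
        default_factory=SegmentationConfig
    )
    pairing: PairingConfig = dataclasses.field(default_factory=PairingConfig)
    radii_um: tuple[float, ...] = DEFAULT_RADII_UM
    cutoff_um: float = CLUSTER_CUTOFF_UM
    n_iterations: int = 1000
    alpha: float = 0.05
    n_replicates: int = 1
    condition: str = "default"
    seed: int = 0
    input_volume: str | None = None  # path to a real volume instead of simulation
    save_volumes: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "geometry" in kwargs:
            g = dict(kwargs["geometry"])
            if "shape" in g:
                g["shape"] = tuple(g["shape"])
            kwargs["geometry"] = ImagingGeometry(**g)
        if "scene" in kwargs:
            s = dict(kwargs["scene"])
            if "az_count_pmf" in s:
                s["az_count_pmf"] = {int(k): float(v) for k, v in s["az_count_pmf"].items()}
            kwargs["scene"] = SceneParams(**s)
        if "segmentation" in kwargs:
            kwargs["segmentation"] = SegmentationConfig(**kwargs["segmentation"])
        if "pairing" in kwargs:
            kwargs["pairing"] = PairingConfig(**kwargs["pairing"])
        if "radii_um" in kwargs:
            kwargs["radii_um"] = tuple(kwargs["radii_um"])
        cfg = cls(**kwargs)
        if cfg.input_volume is None:
            cfg.scene.validate()
        return cfg

    def to_canonical_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): clean(v) for k, v in obj.items()}
            if isinstance(obj, (tuple, list)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return clean(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_canonical_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclasses.dataclass
class ReplicateResult:
    replicate_id: int
    scene: GroundTruthScene | None
    inputs_frame: pd.DataFrame
    records_frame: pd.DataFrame
    neuropil_volume_um3: float
    counts: dict
    null_summary: pd.DataFrame | None = None


def _spawn_seed(master: int, *path: int) -> int:
    """Deterministic child seed below 2**31."""
    ss = np.random.SeedSequence([int(master), *[int(p) for p in path]])
    return int(ss.generate_state(1)[0] % (2**31))


def run_replicate(
    config: RunConfig,
    replicate_id: int = 0,
    out_dir: str | None = None,
    run_null: bool = True,
) -> ReplicateResult:
    """One replicate: simulate (or load), segment, pair, classify, spatial."""
    counts: dict = {"replicate_id": replicate_id}
    scene = None
    if config.input_volume is not None:
        volume = read_volume(config.input_volume, config.geometry)
    else:
        scene_params = dataclasses.replace(
            config.scene, seed=_spawn_seed(config.seed, 10, replicate_id)
        )
        scene = generate_scene(scene_params, config.geometry)
        volume = render_volume(scene, config.geometry, scene_params)
        counts["planted_inputs"] = len(scene.inputs)
    if out_dir and config.save_volumes:
        write_volume(os.path.join(out_dir, f"volume_rep{replicate_id}.h5"), volume)
    if out_dir and scene is not None:
        scene.to_csv(os.path.join(out_dir, f"ground_truth_rep{replicate_id}.csv"))

    log: dict = {}
    clusters, bodies, neuropil = segment_volume(volume, config.segmentation, log=log)
    geometry = volume.geometry
    neuropil_volume = float(neuropil.sum()) * geometry.voxel_volume_um3
    counts["neuropil_volume_um3"] = neuropil_volume
    counts.update({k: v for k, v in log.items()})

    raw = {name: volume.channel(name).astype(np.int64) for name in clusters}
    # synapses: Homer1 <-> Bassoon pairing
    if clusters["homer1"] and clusters["bassoon"]:
        h_feats, h_dec = pair_channels(
            clusters["homer1"], clusters["bassoon"], raw["bassoon"],
            geometry, config.pairing,
        )
        paired_bassoon = {d.partner_id for d in h_dec if d.is_paired}
        homer_by_bassoon = {
            d.partner_id: d.cluster_id for d in h_dec if d.is_paired
        }
    else:
        warnings.warn("no clusters in a synaptic channel; no synapses")
        paired_bassoon, homer_by_bassoon = set(), {}
    counts["paired_synapses"] = len(paired_bassoon)

    eye_by_vglut2 = (
        assign_eye(
            clusters["vglut2"], clusters["ctb"], raw["ctb"], geometry, config.pairing
        )
        if clusters["vglut2"]
        else {}
    )

    vglut2_mask = np.zeros(geometry.grid_shape, dtype=bool)
    for c in clusters["vglut2"]:
        vglut2_mask[tuple(c.voxels.T)] = True
    inputs = build_inputs(
        clusters["vglut2"],
        clusters["bassoon"],
        paired_bassoon,
        homer_by_bassoon,
        eye_by_vglut2,
        geometry,
        vglut2_mask=vglut2_mask,
        shell_nm=config.pairing.shell_nm,
    )
    counts["inputs"] = len(inputs)
    counts["maz_inputs"] = sum(1 for p in inputs if p.input_class == "mAZ")
    vglut2_by_id = {c.id: c for c in clusters["vglut2"]}
    inputs_frame = inputs_to_frame(inputs, vglut2_by_id)

    # spatial analysis
    points = points_from_inputs(inputs, vglut2_by_id, geometry)
    saz_points = [p for p in points if p.input_class == "sAZ"]
    records = shell_neighbor_counts(points, saz_points, config.radii_um)
    label_clustered(records, config.cutoff_um)
    maz_records = [r for r in records if r.input_class == "mAZ"]
    saz_records = [r for r in records if r.input_class == "sAZ"]
    points_by_id = {p.input_id: p for p in points}
    nearest_clustered_maz_distance(maz_records, points_by_id)
    near_far_saz(
        saz_records,
        [p for p in points if p.input_class == "mAZ"],
        points_by_id,
        config.cutoff_um,
    )
    records_frame = records_to_frame(records)
    for radius in config.radii_um:
        counts[f"clustered_fraction_r{radius:g}"] = clustered_fraction(
            records, radius
        )

    null_summary = None
    if run_null and records and saz_points and config.n_iterations > 0:
        ensemble = shuffle_null(
            points,
            saz_points,
            neuropil,
            geometry,
            config.radii_um,
            config.n_iterations,
            seed=_spawn_seed(config.seed, 20, replicate_id),
        )
        observed = np.array(
            [clustered_fraction(records, r) for r in ensemble.radii_um]
        )
        null_summary = ensemble.summary_frame(observed)

    if out_dir:
        inputs_frame.to_csv(
            os.path.join(out_dir, f"inputs_rep{replicate_id}.csv"), index=False
        )
        records_frame.to_csv(
            os.path.join(out_dir, f"clustering_rep{replicate_id}.csv"), index=False
        )
        if null_summary is not None:
            null_summary.to_csv(
                os.path.join(out_dir, f"null_rep{replicate_id}.csv"), index=False
            )
    return ReplicateResult(
        replicate_id, scene, inputs_frame, records_frame, neuropil_volume,
        counts, null_summary,
    )


def run_pipeline(config: RunConfig, out_dir: str) -> dict:
    """Run every stage for every replicate and write a manifest.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "config.yaml"), "w") as f:
        yaml.safe_dump(config.to_canonical_dict(), f, sort_keys=True)

    results = [
        run_replicate(config, rep, out_dir=out_dir)
        for rep in range(config.n_replicates)
    ]
    summary = replicate_summary(
        [
            dict(
                replicate_id=r.replicate_id,
                condition=config.condition,
                inputs=r.inputs_frame,
                records=r.records_frame,
                neuropil_volume_um3=r.neuropil_volume_um3,
            )
            for r in results
        ]
    )
    summary.to_csv(os.path.join(out_dir, "replicate_summary.csv"), index=False)
    stats_frame = paired_family_tests(summary, alpha=config.alpha)
    stats_frame.to_csv(os.path.join(out_dir, "stats.csv"), index=False)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_replicates": config.n_replicates,
        "replicates": [r.counts for r in results],
        "n_measurements": int(len(summary)),
        "n_tests": int(len(stats_frame)),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=1, sort_keys=True)
    return manifest
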