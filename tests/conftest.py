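import warnings

import numpy as np
import pytest
from scipy.spatial import cKDTree

from synaptomap import (
    ImagingGeometry,
    SceneParams,
    generate_scene,
    render_volume,
)
from synaptomap.segmentation import _measure_cluster

warnings.filterwarnings("ignore", message="population gate not separable")


@pytest.fixture(scope="session")
def desk_geom():
    """Desk-scale anisotropic geometry: 78 nm lateral pixels, 70 nm sections."""
    return ImagingGeometry(voxel_xy=78.125, voxel_z=70.0, shape=(192, 192, 40))


@pytest.fixture(scope="session")
def small_scene(desk_geom):
    """A small clean rendered scene shared by read-only tests."""
    params = SceneParams(ctb_label_efficiency=1.0, seed=3)
    scene = generate_scene(params, desk_geom)
    volume = render_volume(scene, desk_geom, params)
    return scene, volume


def make_cluster(voxels, geometry, channel="test", cid=0, raw=None):
    """Build a LabeledCluster from voxel indices with uniform raw intensity."""
    voxels = np.asarray(voxels, dtype=int)
    if raw is None:
        raw = np.zeros(geometry.grid_shape, dtype=np.int64)
        raw[tuple(voxels.T)] = 200
    return _measure_cluster(
        cid, channel, voxels, raw, geometry, list(range(geometry.grid_shape[0]))
    )


def match_detections(truth_df, det_df, tol_nm=400.0):
    """Match detected inputs to planted ground truth by centroid distance.

    Returns (recall, precision, truth_index_per_matched_detection,
    matched_mask_over_detections).
    """
    tpos = truth_df[["z_nm", "y_nm", "x_nm"]].to_numpy()
    dpos = det_df[["z_nm", "y_nm", "x_nm"]].to_numpy()
    if len(dpos) == 0:
        return 0.0, 0.0, np.empty(0, int), np.empty(0, bool)
    d, j = cKDTree(tpos).query(dpos)
    matched = d < tol_nm
    recall = len(set(j[matched])) / len(truth_df)
    precision = matched.mean()
    return recall, precision, j, matched
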