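import numpy as np
import pytest

from agdist import (
    NetworkConfig,
    SyntheticCohortConfig,
    VoxelSeriesSet,
    build_graph,
    extract_voxel_series,
    make_atlas,
    simulate_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def two_roi_voxel_set(n_timepoints: int = 60) -> VoxelSeriesSet:
    """Six voxels: two per ROI sharing one latent series (high amplitude,
    slightly different gains so powers are distinct) plus two unlabeled
    low-power filler voxels."""
    t = np.arange(n_timepoints)
    latent = np.sin(0.3 * t) + 0.5 * np.cos(0.11 * t)
    latent -= latent.mean()
    series = np.stack(
        [
            10.0 * latent,
            9.0 * latent,
            8.5 * latent,
            8.0 * latent,
            0.01 * np.cos(0.7 * t),
            0.02 * np.sin(0.9 * t),
        ]
    )
    coords = np.array(
        [[0, 0, 0], [1, 0, 0], [5, 5, 5], [5, 5, 6], [9, 9, 9], [9, 9, 8]]
    )
    return VoxelSeriesSet(
        coords_voxel=coords,
        coords_world=coords * 4.0,
        series=series,
        labels=np.array([1, 1, 2, 2, 0, 0]),
    )


@pytest.fixture
def small_cohort():
    """A compact simulated cohort shared across protocol tests: 6+6
    subjects with a strong planted effect and a held-out test third."""
    cfg = SyntheticCohortConfig(
        n_per_group=6, n_timepoints=80, test_fraction=0.34, seed=7
    )
    atlas, mask = make_atlas(cfg)
    pairs = []
    for vol, rec in simulate_cohort(cfg):
        pairs.append((extract_voxel_series(vol, mask, atlas), rec))
    return cfg, pairs


def cohort_graphs(seed: int, effect_size: float, corr_threshold: float = 0.5,
                  n_per_group: int = 20, roiwise: bool = False):
    """Simulate, build and label one cohort's graphs."""
    cfg = SyntheticCohortConfig(
        seed=seed, effect_size=effect_size, n_per_group=n_per_group
    )
    atlas, mask = make_atlas(cfg)
    graphs, labels = [], []
    net = NetworkConfig(corr_threshold=corr_threshold, roiwise_selection=roiwise)
    for vol, rec in simulate_cohort(cfg):
        vs = extract_voxel_series(vol, mask, atlas)
        graphs.append(build_graph(vs, cfg=net, subject_id=rec.subject_id))
        labels.append(rec.label)
    return graphs, labels
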