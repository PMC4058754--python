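"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates preprocessed resting-state BOLD: a small 3D grid
with a spherical brain mask and spatially compact ROI blobs; per-ROI
latent zero-mean time series drawn from a group-dependent correlation
structure (real inputs are bandpass filtered, so zero-mean latents are
the faithful emulation and signal power reflects variance); a small
fraction of voxels carry a high-amplitude copy of their ROI latent so
the power-percentile selection step has something to find, while the
rest are low-amplitude noise. The case group's latent correlations are
shifted on selected cross-block ROI pairs by ``effect_size``; at 0 the
two groups are exchangeable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import BrainMask, FmriVolume, RoiAtlas, SubjectRecord
from .network import AttributedGraph, Node, compute_signature

__all__ = [
    "SyntheticCohortConfig",
    "make_atlas",
    "simulate_cohort",
    "toy_graph_pair",
    "write_cohort",
]


@dataclass
class SyntheticCohortConfig:
    """Study conditions for one simulated cohort.

    effect_size is the additive shift of the case group's latent
    correlation on the planted cross-block ROI pairs (0 = null cohort);
    active_fraction is the fraction of in-mask voxels given the
    high-amplitude latent, sized to match a 98th-percentile selection;
    noise_sd and active_amplitude set the power contrast that makes the
    selection step near-deterministic.
    """

    grid_shape: tuple[int, int, int] = (12, 12, 12)
    n_rois: int = 8
    voxels_per_roi: int = 20
    n_timepoints: int = 120
    n_per_group: int = 20
    effect_size: float = 0.6
    active_fraction: float = 0.02
    noise_sd: float = 0.5
    active_amplitude: float = 3.0
    ar_coeff: float = 0.3
    base_within: float = 0.35  # within-block latent correlation
    base_cross: float = 0.05  # cross-block latent correlation
    sex_effect: float = 0.0  # extra correlation shift for female cases
    test_fraction: float = 0.0
    voxel_size_mm: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must lie in [0, 1]")

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0] = a[1, 1] = a[2, 2] = self.voxel_size_mm
        return a


def make_atlas(cfg: SyntheticCohortConfig) -> tuple[RoiAtlas, BrainMask]:
    """Spherical brain mask with ``n_rois`` compact, disjoint ROI blobs.

    ROI seeds sit on a coarse lattice inside the mask; each ROI claims
    the ``voxels_per_roi`` nearest unclaimed in-mask voxels, leaving a
    margin of unlabeled in-mask voxels around the blobs.
    """
    shape = np.asarray(cfg.grid_shape)
    center = (shape - 1) / 2.0
    radius = float(shape.min()) / 2.0 - 0.25
    grid = np.indices(cfg.grid_shape).reshape(3, -1).T
    inside = np.linalg.norm(grid - center, axis=1) <= radius
    mask = np.zeros(cfg.grid_shape, dtype=bool)
    mask[tuple(grid[inside].T)] = True
    n_mask = int(mask.sum())
    if cfg.n_rois * cfg.voxels_per_roi > n_mask:
        raise ValueError(
            f"{cfg.n_rois} ROIs x {cfg.voxels_per_roi} voxels exceed the "
            f"{n_mask}-voxel mask"
        )

    # seed positions: corners of a coarse lattice around the center
    m = max(2, math.ceil(cfg.n_rois ** (1 / 3)))
    offsets = np.linspace(-1.0, 1.0, m) * radius / 2.0
    seeds = []
    for dx in offsets:
        for dy in offsets:
            for dz in offsets:
                seeds.append(center + (dx, dy, dz))
    seeds = np.asarray(seeds[: cfg.n_rois])

    labels = np.zeros(cfg.grid_shape, dtype=np.int16)
    mask_vox = grid[inside]
    claimed = np.zeros(len(mask_vox), dtype=bool)
    for lab, seed in enumerate(seeds, start=1):
        d = np.linalg.norm(mask_vox - seed, axis=1)
        d[claimed] = np.inf
        take = np.argsort(d, kind="stable")[: cfg.voxels_per_roi]
        claimed[take] = True
        labels[tuple(mask_vox[take].T)] = lab
    return (
        RoiAtlas(data=labels, affine=cfg.affine),
        BrainMask(data=mask, affine=cfg.affine),
    )


def _latent_correlation(cfg: SyntheticCohortConfig, group: str, sex: str) -> np.ndarray:
    n = cfg.n_rois
    half = n // 2
    C = np.full((n, n), cfg.base_cross)
    C[:half, :half] = cfg.base_within
    C[half:, half:] = cfg.base_within
    np.fill_diagonal(C, 1.0)
    if group == "case":
        shift = cfg.effect_size + (cfg.sex_effect if sex == "female" else 0.0)
        for i in range(half):
            j = i + half
            C[i, j] = C[j, i] = min(0.95, cfg.base_cross + shift)
    ev = np.linalg.eigvalsh(C)
    if ev.min() < 1e-8:
        raise ValueError(
            "latent correlation matrix not positive definite; lower effect_size"
        )
    return C


def _latent_series(rng: np.random.Generator, C: np.ndarray, t: int, ar: float) -> np.ndarray:
    """(t, n_rois) zero-mean series with cross-correlation C; AR(1)
    smoothing preserves the marginal covariance."""
    L = np.linalg.cholesky(C)
    x = rng.standard_normal((t, C.shape[0])) @ L.T
    if ar > 0:
        out = np.empty_like(x)
        out[0] = x[0]
        scale = math.sqrt(1.0 - ar**2)
        for i in range(1, t):
            out[i] = ar * out[i - 1] + scale * x[i]
        x = out
    return x


def simulate_cohort(
    cfg: SyntheticCohortConfig,
) -> list[tuple[FmriVolume, SubjectRecord]]:
    """Simulate ``2 * n_per_group`` subjects (controls then cases).

    Active voxels — ``active_fraction`` of the mask, spread round-robin
    across ROIs — get amplitude-scaled copies of their ROI latent plus
    voxel noise; all other in-mask voxels are pure low-amplitude noise.
    Sexes alternate within each group; the trailing ``test_fraction`` of
    each group is assigned to the test split. A fixed seed reproduces the
    volumes bit-exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    atlas, mask = make_atlas(cfg)
    mask_idx = np.argwhere(mask.data)
    n_mask = len(mask_idx)
    vox_labels = atlas.data[mask.data]

    n_active = max(cfg.n_rois, round(cfg.active_fraction * n_mask))
    # round-robin over ROIs: first voxels of each ROI in label order
    per_roi: dict[int, list[int]] = {
        int(lab): list(np.flatnonzero(vox_labels == lab)) for lab in atlas.labels
    }
    active: list[int] = []
    rank = 0
    while len(active) < n_active:
        added = False
        for lab in sorted(per_roi):
            if rank < len(per_roi[lab]) and len(active) < n_active:
                active.append(per_roi[lab][rank])
                added = True
        if not added:
            break
        rank += 1
    active_set = np.zeros(n_mask, dtype=bool)
    active_set[active] = True

    n_test = round(cfg.test_fraction * cfg.n_per_group)
    subjects: list[tuple[FmriVolume, SubjectRecord]] = []
    sid = 0
    for group in ("control", "case"):
        for k in range(cfg.n_per_group):
            sex = "male" if k % 2 == 0 else "female"
            C = _latent_correlation(cfg, group, sex)
            latents = _latent_series(rng, C, cfg.n_timepoints, cfg.ar_coeff)
            data = np.zeros((*cfg.grid_shape, cfg.n_timepoints))
            noise = rng.normal(scale=cfg.noise_sd, size=(n_mask, cfg.n_timepoints))
            series = noise
            for v in range(n_mask):
                if active_set[v]:
                    series[v] += cfg.active_amplitude * latents[:, vox_labels[v] - 1]
            data[mask.data] = series
            rec = SubjectRecord(
                subject_id=f"S{sid:03d}",
                site="SYN",
                sex=sex,
                label=group,
                qc_pass=True,
                split="test" if k >= cfg.n_per_group - n_test else "train",
            )
            vol = FmriVolume(
                data=data,
                affine=cfg.affine,
                voxel_size=(cfg.voxel_size_mm,) * 3,
            )
            subjects.append((vol, rec))
            sid += 1
    return subjects


def write_cohort(cfg: SyntheticCohortConfig, out_dir: str | Path) -> None:
    """Write the cohort to disk in exactly the formats the readers accept:
    one 4D NIfTI per subject, shared mask and atlas NIfTIs, and a
    phenotype CSV."""
    from .io import write_label_volume, write_volume

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas, mask = make_atlas(cfg)
    write_label_volume(atlas.data, atlas.affine, out / "atlas.nii.gz")
    write_label_volume(mask.data.astype(np.int16), mask.affine, out / "mask.nii.gz")
    rows = ["subject_id,site,sex,dx,qc,split"]
    for vol, rec in simulate_cohort(cfg):
        write_volume(vol, out / f"{rec.subject_id}.nii.gz")
        rows.append(
            f"{rec.subject_id},{rec.site},{rec.sex},{rec.label},"
            f"{int(rec.qc_pass)},{rec.split}"
        )
    (out / "phenotype.csv").write_text("\n".join(rows) + "\n")


def _hand_graph(subject_id, coords, powers, edges) -> AttributedGraph:
    nodes = [
        Node(
            node_id=i,
            roi_label=i + 1,
            member_voxels=[i],
            mean_coord=np.asarray(c, float),
            mean_series=None,
            power=float(p),
        )
        for i, (c, p) in enumerate(zip(coords, powers))
    ]
    g = AttributedGraph(subject_id=subject_id, nodes=nodes, edges=list(edges))
    g.signatures = {n.node_id: compute_signature(g, n.node_id) for n in g.nodes}
    return g


def toy_graph_pair(seed: int = 0):
    """Two small hand-scaled graphs (3 and 4 nodes) plus their expected
    node-to-node cost matrix under default weights.

    The expected matrix is computed here by plain scalar arithmetic —
    sorting, zero-padding and the sigmoid written out directly — so tests
    can hold the distance module against an independent evaluation. The
    seed jitters the coordinates slightly so repeated draws exercise
    different geometry.

    Returns (g_small, g_large, expected_cost, constants) where constants
    is the (max_degree, max_power) pair the expected matrix assumed.
    """
    rng = np.random.default_rng(seed)
    jit = lambda: rng.uniform(-0.5, 0.5, size=3)
    coords1 = [np.array(c, float) + jit() for c in ((0, 0, 0), (10, 0, 0), (0, 10, 0))]
    coords2 = [
        np.array(c, float) + jit()
        for c in ((0, 0, 2), (12, 0, 0), (0, 12, 0), (20, 20, 20))
    ]
    powers1 = (0.9, 0.6, 0.3)
    powers2 = (0.85, 0.5, 0.4, 0.2)
    edges1 = [(0, 1, 0.8), (1, 2, 0.5)]
    edges2 = [(0, 1, 0.7), (0, 2, 0.6), (2, 3, 0.4)]
    g1 = _hand_graph("toyA", coords1, powers1, edges1)
    g2 = _hand_graph("toyB", coords2, powers2, edges2)

    # independent scalar evaluation of every cost entry
    def wdeg(edges, i):
        return sum(w for a, b, w in edges if i in (a, b))

    def nbrs(edges, i):
        return [b if a == i else a for a, b, w in edges if i in (a, b)]

    deg1 = [wdeg(edges1, i) for i in range(3)]
    deg2 = [wdeg(edges2, i) for i in range(4)]
    max_deg = max(deg1 + deg2)
    max_pow = max(powers1 + powers2)
    W = (0.2, 0.1, 0.2, 0.1, 0.4)

    def prof_dist(a, b, mx):
        a = sorted(a, reverse=True)
        b = sorted(b, reverse=True)
        L = max(len(a), len(b))
        if L == 0:
            return 0.0
        a = a + [0.0] * (L - len(a))
        b = b + [0.0] * (L - len(b))
        return sum(abs(x - y) for x, y in zip(a, b)) / (mx * L)

    expected = np.zeros((3, 4))
    for i in range(3):
        for j in range(4):
            d1 = abs(deg1[i] - deg2[j]) / max_deg
            d2 = prof_dist(
                [deg1[k] for k in nbrs(edges1, i)],
                [deg2[k] for k in nbrs(edges2, j)],
                max_deg,
            )
            d3 = abs(powers1[i] - powers2[j]) / max_pow
            d4 = prof_dist(
                [powers1[k] for k in nbrs(edges1, i)],
                [powers2[k] for k in nbrs(edges2, j)],
                max_pow,
            )
            gap = math.dist(coords1[i], coords2[j])
            d5 = 1.0 / (1.0 + 300.0 * math.exp(-gap / 4.0))
            expected[i, j] = (
                W[0] * d1 + W[1] * d2 + W[2] * d3 + W[3] * d4 + W[4] * d5
            )
    return g1, g2, expected, (max_deg, max_pow)
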