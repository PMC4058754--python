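"""Reading and writing the volumes, masks, atlases and phenotype tables
the pipeline consumes.

All volumes are NIfTI-1 (plain or gzip-compressed), loaded through nibabel.
Voxel indices are 0-based; world coordinates are millimetres obtained by
applying the image affine, and every spatial distance downstream is
Euclidean in world mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.affines import apply_affine

__all__ = [
    "FmriVolume",
    "BrainMask",
    "RoiAtlas",
    "SubjectRecord",
    "VoxelSeriesSet",
    "read_volume",
    "write_volume",
    "read_label_volume",
    "write_label_volume",
    "extract_voxel_series",
    "read_phenotype_table",
]


@dataclass
class FmriVolume:
    """A 4D BOLD scalar field (x, y, z, t) with its spatial metadata."""

    data: np.ndarray
    affine: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 timepoints")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class BrainMask:
    """Binary in-brain mask; nonzero voxels are inside the brain."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = (np.asarray(self.data) != 0)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D")
        if not self.data.any():
            raise ValueError("empty mask: no nonzero voxel")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class RoiAtlas:
    """Integer-labelled parcellation; 0 is background."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"expected 3D atlas, got {arr.ndim}D")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.rint(arr)
            if not np.allclose(arr, rounded, atol=1e-6):
                raise ValueError("atlas labels are not integers")
            arr = rounded.astype(np.int64)
        if (arr < 0).any():
            raise ValueError("atlas labels must be nonnegative")
        self.data = arr.astype(np.int64)
        if self.n_labels < 1:
            raise ValueError("atlas has no nonzero labels")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def labels(self) -> np.ndarray:
        lab = np.unique(self.data)
        return lab[lab > 0]

    @property
    def n_labels(self) -> int:
        return int(len(np.unique(self.data[self.data > 0])))


@dataclass
class SubjectRecord:
    subject_id: str
    site: str
    sex: str  # "male" | "female"
    label: str  # "control" | "case"
    qc_pass: bool = True
    split: str = "train"  # "train" | "test"


@dataclass
class VoxelSeriesSet:
    """Per-voxel time series for the in-mask voxels of one subject."""

    coords_voxel: np.ndarray  # (n, 3) int
    coords_world: np.ndarray  # (n, 3) mm
    series: np.ndarray  # (n, t)
    labels: np.ndarray | None = None  # (n,) atlas label per voxel, 0 = none

    def __len__(self) -> int:
        return self.series.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[1]


def read_volume(path: str | Path) -> FmriVolume:
    """Load a 4D NIfTI time-series volume.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the image is not 4-dimensional.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"expected 4D image, got {img.ndim}D: {path}")
    zooms = img.header.get_zooms()[:3]
    return FmriVolume(
        data=np.asanyarray(img.dataobj, dtype=float),
        affine=img.affine,
        voxel_size=tuple(float(z) for z in zooms),
    )


def write_volume(vol: FmriVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_zooms((*vol.voxel_size, 1.0))
    nib.save(img, str(path))


def read_label_volume(path: str | Path, kind: str) -> BrainMask | RoiAtlas:
    """Load a 3D label volume as a brain mask or an ROI atlas.

    ``kind`` is ``"mask"`` (binarized, nonzero -> inside) or ``"atlas"``
    (integer labels preserved).
    """
    if kind not in ("mask", "atlas"):
        raise ValueError(f"kind must be 'mask' or 'atlas', got {kind!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"expected 3D image, got {img.ndim}D: {path}")
    data = np.asanyarray(img.dataobj)
    if kind == "mask":
        return BrainMask(data=data, affine=img.affine)
    return RoiAtlas(data=data, affine=img.affine)


def write_label_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data).astype(np.int16), affine), str(path))


def extract_voxel_series(
    vol: FmriVolume, mask: BrainMask, atlas: RoiAtlas | None = None
) -> VoxelSeriesSet:
    """Pull out the time series of every in-mask voxel.

    World coordinates come from the volume affine. When an atlas is given,
    each voxel also records the ROI label it sits in (0 outside any ROI).
    """
    if vol.data.shape[:3] != mask.data.shape:
        raise ValueError(
            f"volume spatial shape {vol.data.shape[:3]} != mask shape {mask.data.shape}"
        )
    idx = np.argwhere(mask.data)
    world = apply_affine(vol.affine, idx)
    series = vol.data[mask.data]  # (n, t), same voxel order as argwhere
    labels = None
    if atlas is not None:
        if atlas.data.shape != mask.data.shape:
            raise ValueError("atlas shape does not match mask shape")
        labels = atlas.data[mask.data]
    return VoxelSeriesSet(
        coords_voxel=idx, coords_world=world, series=series, labels=labels
    )


# Phenotype sheets differ per site; this maps our canonical field names onto
# whatever the file's header uses.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "subject_id": "subject_id",
    "site": "site",
    "sex": "sex",
    "dx": "dx",
    "qc": "qc",
    "split": "split",
}

_SEX_CODES = {
    "male": "male", "m": "male", "1": "male",
    "female": "female", "f": "female", "0": "female", "2": "female",
}
_DX_CODES = {
    "control": "control", "0": "control", "td": "control",
    "case": "case", "adhd": "case", "1": "case", "2": "case", "3": "case",
}


def read_phenotype_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    exclude_qc_failures: bool = True,
    sep: str | None = None,
) -> list[SubjectRecord]:
    """Parse a delimited phenotype sheet into subject records.

    The sheet needs columns for subject id, site, sex and diagnosis; qc and
    split columns are optional (defaults: qc passes, split "train"). Column
    names are remapped through ``column_map`` so site-specific sheets can be
    read without editing. Subjects whose qc flag is falsy are dropped when
    ``exclude_qc_failures`` is on.
    """
    cm = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cm.update(column_map)
    df = pd.read_csv(path, sep=sep, engine="python")
    df.columns = [str(c).strip() for c in df.columns]
    for needed in ("subject_id", "site", "sex", "dx"):
        if cm[needed] not in df.columns:
            raise ValueError(f"phenotype table missing required column {cm[needed]!r}")

    records: list[SubjectRecord] = []
    for _, row in df.iterrows():
        sex_raw = str(row[cm["sex"]]).strip().lower()
        if sex_raw not in _SEX_CODES:
            raise ValueError(f"unknown sex code {sex_raw!r}")
        dx_raw = str(row[cm["dx"]]).strip().lower()
        if dx_raw not in _DX_CODES:
            raise ValueError(f"unknown diagnosis code {dx_raw!r}")
        qc = True
        if cm["qc"] in df.columns:
            qc = str(row[cm["qc"]]).strip().lower() not in ("0", "false", "fail", "0.0")
        split = "train"
        if cm["split"] in df.columns:
            split = str(row[cm["split"]]).strip().lower()
        rec = SubjectRecord(
            subject_id=str(row[cm["subject_id"]]),
            site=str(row[cm["site"]]),
            sex=_SEX_CODES[sex_raw],
            label=_DX_CODES[dx_raw],
            qc_pass=qc,
            split=split,
        )
        if exclude_qc_failures and not rec.qc_pass:
            continue
        records.append(rec)
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids in phenotype table")
    return records
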