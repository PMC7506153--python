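"""NIfTI and CSV round-trip helpers.

Volumes travel as NIfTI-1 (via nibabel) with the voxel spacing encoded in a
diagonal affine; tables as UTF-8 CSV with ``subject_id`` as the first column.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import ROIMask, VoxelGrid

__all__ = ["read_volume", "write_volume", "read_mask", "write_mask",
           "read_table", "write_table"]


def write_volume(path: str | os.PathLike, grid: VoxelGrid) -> None:
    affine = np.diag(list(grid.spacing_mm) + [1.0])
    affine[:3, 3] = grid.origin_mm
    img = nib.Nifti1Image(np.asarray(grid.values, dtype=np.float32), affine)
    img.header.set_zooms(grid.spacing_mm)
    nib.save(img, os.fspath(path))


def read_volume(path: str | os.PathLike) -> VoxelGrid:
    try:
        img = nib.load(os.fspath(path))
        values = np.asanyarray(img.dataobj, dtype=np.float32)
    except Exception as exc:  # corrupt or unreadable file
        raise OSError(f"cannot read NIfTI volume {path!r}: {exc}") from exc
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path!r} has no usable voxel spacing: {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VoxelGrid(values, spacing_mm=tuple(float(z) for z in zooms),
                     origin_mm=origin)


def write_mask(path: str | os.PathLike, mask: ROIMask) -> None:
    write_volume(path, VoxelGrid(mask.values.astype(np.float32),
                                 spacing_mm=mask.spacing_mm,
                                 origin_mm=mask.origin_mm))


def read_mask(path: str | os.PathLike) -> ROIMask:
    grid = read_volume(path)
    return ROIMask(grid.values > 0.5, spacing_mm=grid.spacing_mm,
                   origin_mm=grid.origin_mm)


def write_table(path: str | os.PathLike, table: pd.DataFrame) -> None:
    """Write a subject table; ``subject_id`` must be the index or first column."""
    df = table
    if df.index.name == "subject_id":
        df = df.reset_index()
    if df.columns[0] != "subject_id":
        raise ValueError("first column of a subject table must be 'subject_id'")
    df.to_csv(os.fspath(path), index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(os.fspath(path))
    if df.columns[0] != "subject_id":
        raise ValueError(f"{path!r}: first column must be 'subject_id'")
    return df.set_index("subject_id")
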