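"""NIfTI and plain-text readers/writers for the domain types.

Volumes, masks and label grids travel as NIfTI-1 (.nii / .nii.gz) via
nibabel; affine transforms as 4x4 whitespace-separated text; deformation
fields use the NIfTI vector convention (5D, shape (i,j,k,1,3)); tabular
results are TSV via pandas.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import (AffineTransform, BinaryMask, DeformationField,
                    ProbabilityMap, TissueLabels, Volume)

__all__ = [
    "read_volume", "write_volume",
    "read_mask", "write_mask",
    "read_probmap", "write_probmap",
    "read_labels", "write_labels",
    "read_affine_transform", "write_affine_transform",
    "read_deformation_field", "write_deformation_field",
    "read_table", "write_table",
]


def _load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    return data, np.asarray(img.affine, dtype=float)


def read_volume(path: str | Path) -> Volume:
    data, affine = _load_nifti(path)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    data = data.astype(np.float64)
    n_bad = int(data.size - np.count_nonzero(np.isfinite(data)))
    if n_bad:
        raise ValueError(f"{path}: {n_bad} non-finite voxel(s)")
    return Volume(data, affine)


def write_volume(v: Volume, path: str | Path) -> None:
    img = nib.Nifti1Image(v.data.astype(np.float64), v.affine)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> BinaryMask:
    data, affine = _load_nifti(path)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got shape {data.shape}")
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{path}: mask values outside {{0,1}}: {vals[:10]}")
    return BinaryMask(data.astype(np.uint8), affine)


def write_mask(m: BinaryMask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(m.data.astype(np.uint8), m.affine), str(path))


def read_probmap(path: str | Path) -> ProbabilityMap:
    data, affine = _load_nifti(path)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D map, got shape {data.shape}")
    return ProbabilityMap(data.astype(np.float64), affine)


def write_probmap(p: ProbabilityMap, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(p.data.astype(np.float64), p.affine), str(path))


def read_labels(path: str | Path) -> TissueLabels:
    data, affine = _load_nifti(path)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label image, got shape {data.shape}")
    return TissueLabels(data.astype(np.uint8), affine)


def write_labels(labels: TissueLabels, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(labels.data.astype(np.uint8), labels.affine), str(path))


def read_affine_transform(path: str | Path) -> AffineTransform:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such transform: {path}")
    m = np.loadtxt(str(path), dtype=float)
    if m.shape != (4, 4):
        raise ValueError(f"{path}: expected 4 rows x 4 numbers, got {m.shape}")
    return AffineTransform(m)


def write_affine_transform(t: AffineTransform, path: str | Path) -> None:
    np.savetxt(str(path), t.matrix, fmt="%.17g")


def read_deformation_field(path: str | Path) -> DeformationField:
    data, affine = _load_nifti(path)
    if data.ndim == 5 and data.shape[3] == 1 and data.shape[4] == 3:
        u = data[:, :, :, 0, :]
    elif data.ndim == 4 and data.shape[3] == 3:
        u = data
    else:
        raise ValueError(
            f"{path}: expected a (i,j,k,1,3) or (i,j,k,3) vector image, got {data.shape}"
        )
    return DeformationField(u.astype(np.float64), affine)


def write_deformation_field(d: DeformationField, path: str | Path) -> None:
    data = d.displacements[:, :, :, np.newaxis, :].astype(np.float64)
    img = nib.Nifti1Image(data, d.affine)
    img.header.set_intent("vector")
    nib.save(img, str(path))


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
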