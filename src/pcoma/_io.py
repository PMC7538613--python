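"""NIfTI and provenance-stamped CSV input/output."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd


def save_nifti(path: str | Path, data: np.ndarray, voxel_size: Sequence[float]) -> Path:
    """Write an array as NIfTI-1 with the voxel size in the header (mm)."""
    path = Path(path)
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_zooms(tuple(float(v) for v in voxel_size))
    nib.save(img, path)
    return path


def load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns (array, voxel_size in mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def write_csv(path: str | Path, frame: pd.DataFrame, provenance: Iterable[str] = ()) -> Path:
    """CSV with '#'-prefixed provenance header lines before the table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False)
    return path


def read_csv(path: str | Path) -> pd.DataFrame:
    """Read a CSV, ignoring '#' provenance comment lines."""
    return pd.read_csv(path, comment="#")
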