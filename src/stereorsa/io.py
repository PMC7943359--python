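"""File interchange: labeled DM CSVs, events TSVs, and NIfTI volumes."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import CONDITIONS, DissimilarityMatrix


def write_dm_csv(path, dm: DissimilarityMatrix) -> None:
    pd.DataFrame(dm.values, index=dm.labels, columns=dm.labels).to_csv(path)


def read_dm_csv(path) -> DissimilarityMatrix:
    df = pd.read_csv(path, index_col=0)
    return DissimilarityMatrix(df.to_numpy(dtype=float),
                               tuple(df.columns))


def write_events_tsv(path, schedule: pd.DataFrame) -> None:
    """BIDS-style events table (onset, duration, trial_type, run, masking)."""
    out = schedule.rename(columns={"condition": "trial_type"})
    out.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.rename(columns={"trial_type": "condition"})


def write_nifti(path, data: np.ndarray, voxel_size_mm: float = 2.0) -> None:
    """Save an array as NIfTI-1 with an isotropic affine.  Condition-first
    4-D pattern volumes (4, x, y, z) are stored as (x, y, z, 4)."""
    data = np.asarray(data)
    if data.ndim == 4 and data.shape[0] == len(CONDITIONS):
        data = np.moveaxis(data, 0, -1)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def read_nifti(path, conditions_first: bool = False) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if conditions_first and data.ndim == 4:
        data = np.moveaxis(data, -1, 0)
    return data


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
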