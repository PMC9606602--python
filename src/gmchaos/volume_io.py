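"""Volume and covariate-table I/O.

This module owns the coordinate contract used everywhere downstream:
voxel indices are 0-based integer triples, and the world position (mm) of
voxel ``v`` is ``affine @ [v, 1]``.  Gray-matter intensities are kept in
the units in which they are stored (modulated probability maps are not
restricted to [0, 1]); negative values, which can appear from
interpolation ringing in warped images, are clipped to 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from gmchaos.errors import (
    AffineError,
    CovariateTableError,
    NonThreeDimensionalError,
    VolumeReadError,
)

logger = logging.getLogger(__name__)

#: Binary covariate columns encoded as 0/1 indicators when read from text.
#: sex: F=0, M=1; yes/no style columns: no=0, yes=1.
BINARY_ENCODINGS = {
    "sex": {"f": 0, "m": 1, "female": 0, "male": 1, "0": 0, "1": 1},
    "alcohol": {"no": 0, "yes": 1, "n": 0, "y": 1, "0": 0, "1": 1},
}


@dataclass
class GMVolume:
    """A 3D gray-matter intensity volume with its voxel-to-world affine.

    Attributes
    ----------
    data : ndarray, shape (nx, ny, nz)
        Non-negative GM intensity (modulated units, not restricted to [0,1]).
    affine : ndarray, shape (4, 4)
        Voxel-index -> world-mm transform (NIfTI convention, 0-based indices).
    subject_id : str
        Identifier carried through the pipeline.
    """

    data: np.ndarray
    affine: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise NonThreeDimensionalError(
                f"expected a 3D volume, got {self.data.ndim} dimensions"
            )
        if self.affine.shape != (4, 4):
            raise AffineError(f"affine must be 4x4, got {self.affine.shape}")
        if not np.all(np.isfinite(self.data)):
            raise VolumeReadError("volume contains non-finite values")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise AffineError("affine is not invertible")

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the 3x3 affine block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """World-mm positions of voxel indices (rows of ``indices``, shape (n, 3))."""
        idx = np.atleast_2d(np.asarray(indices, dtype=np.float64))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


def read_gm_volume(path: str | Path) -> GMVolume:
    """Read a 3D NIfTI GM volume.

    Negative intensities are clipped to 0 and the clip count is logged.

    Raises
    ------
    VolumeReadError
        If the file is missing or not readable as NIfTI.
    NonThreeDimensionalError
        If the image does not have exactly 3 spatial dimensions.
    AffineError
        If the stored affine is singular.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeReadError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise VolumeReadError(f"could not read {path} as NIfTI: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float64)
    squeezed = np.squeeze(data)
    if squeezed.ndim != 3:
        raise NonThreeDimensionalError(
            f"non-3D image: {path} has shape {data.shape}"
        )
    data = squeezed
    n_negative = int(np.count_nonzero(data < 0))
    if n_negative:
        logger.warning("clipped %d negative voxels to 0 in %s", n_negative, path)
        data = np.clip(data, 0.0, None)
    subject_id = path.name
    for suffix in (".gz", ".nii"):
        if subject_id.endswith(suffix):
            subject_id = subject_id[: -len(suffix)]
    vol = GMVolume(data=data, affine=np.asarray(img.affine), subject_id=subject_id)
    vol.n_clipped = n_negative
    return vol


def write_volume(vol: GMVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1; round-trips data (float64) and affine exactly."""
    path = Path(path)
    img = nib.Nifti1Image(vol.data.astype(np.float64), vol.affine)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise VolumeReadError(f"could not write {path}: {exc}") from exc


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read a covariate table (CSV or TSV with header).

    Requires ``subject_id`` and ``group`` columns; one row per subject.
    Binary covariates listed in :data:`BINARY_ENCODINGS` (sex, alcohol) are
    encoded as 0/1 indicators deterministically.

    Returns a DataFrame indexed by row order, with ``subject_id`` as str and
    ``group`` as a categorical column.
    """
    path = Path(path)
    if not path.exists():
        raise CovariateTableError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    table = pd.read_csv(path, sep=sep)
    return _validate_covariates(table)


def _validate_covariates(table: pd.DataFrame) -> pd.DataFrame:
    for col in ("subject_id", "group"):
        if col not in table.columns:
            raise CovariateTableError(f"missing required column: {col}")
    table = table.copy()
    table["subject_id"] = table["subject_id"].astype(str)
    if table["subject_id"].duplicated().any():
        dups = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise CovariateTableError(f"duplicated subject_id: {dups}")
    table["group"] = table["group"].astype("category")
    for col, mapping in BINARY_ENCODINGS.items():
        if col in table.columns and not pd.api.types.is_numeric_dtype(table[col]):
            lowered = table[col].astype(str).str.strip().str.lower()
            unknown = sorted(set(lowered) - set(mapping))
            if unknown:
                raise CovariateTableError(
                    f"column {col!r}: unrecognized values {unknown}"
                )
            table[col] = lowered.map(mapping).astype(np.int64)
    return table
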