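"""Weighted-distance spatial series extraction.

A GM volume is reduced to a 1D "spatial series": for every voxel, the
Euclidean distance (in world mm) from the intensity-weighted center of
mass is multiplied by the voxel's GM intensity; the products are sorted
from highest to lowest and the top-K voxels are kept.  A point of
intensity 1 at 3 mm and a point of intensity 3 at 1 mm thus receive the
same series value.  The voxel indices of the selected points are retained
so per-point quantities computed downstream (lambda values) can be
scattered back into 3D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from gmchaos.errors import EmptyVolumeError, SelectionError, ShapeMismatchError
from gmchaos.volume_io import GMVolume

#: Number of top-weighted voxels kept by default (~1% of nonzero GM voxels
#: in a 1.5 mm whole-brain map).
DEFAULT_K = 5000


@dataclass(frozen=True)
class CenterOfMass:
    """Intensity-weighted center of mass, in fractional voxel and world-mm coordinates."""

    voxel_continuous: np.ndarray  # (3,) fractional voxel index
    world_mm: np.ndarray  # (3,) mm


@dataclass
class WeightedSeries:
    """Sorted weighted-distance series with voxel bookkeeping.

    ``values[i]`` is the i-th largest weighted distance (mm * intensity);
    ``voxel_indices[i]`` is its (i, j, k) voxel index.  Values are
    non-increasing; ties are broken by ascending row-major linear index so
    the series is a deterministic function of the map.
    """

    values: np.ndarray  # (K,) float, non-increasing
    voxel_indices: np.ndarray  # (K, 3) int
    order: str = "sorted_desc"

    def __len__(self) -> int:
        return len(self.values)


def center_of_mass(vol: GMVolume) -> CenterOfMass:
    """Gray-level-weighted center of mass of a volume.

    ``voxel_continuous[a] = sum(w * index_a) / sum(w)`` per axis ``a``;
    ``world_mm`` is the affine applied to the fractional voxel index.

    Raises
    ------
    EmptyVolumeError
        If the volume has no strictly positive voxel.
    """
    w = vol.data
    total = w.sum()
    if total <= 0:
        raise EmptyVolumeError("center of mass undefined for an all-zero volume")
    grids = np.meshgrid(*(np.arange(n, dtype=np.float64) for n in w.shape), indexing="ij")
    voxel = np.array([(w * g).sum() / total for g in grids])
    world = vol.affine[:3, :3] @ voxel + vol.affine[:3, 3]
    return CenterOfMass(voxel_continuous=voxel, world_mm=world)


def weighted_distance_map(vol: GMVolume, com: CenterOfMass) -> np.ndarray:
    """Per-voxel (distance in mm from the center of mass) x (GM intensity).

    Distances are computed in world coordinates through the affine, so the
    result is correct for anisotropic voxels; it is exactly zero wherever
    the intensity is zero.
    """
    if com.world_mm.shape != (3,):
        raise ShapeMismatchError("center of mass must be a 3-vector")
    shape = vol.data.shape
    A = vol.affine[:3, :3]
    b = vol.affine[:3, 3]
    # world(v) - com = A @ v + (b - com); accumulate squared distance axis by
    # axis via broadcasting to avoid materializing an (nx, ny, nz, 3) array.
    offset = b - com.world_mm
    dist_sq = np.zeros(shape, dtype=np.float64)
    coords = [np.arange(n, dtype=np.float64) for n in shape]
    for world_axis in range(3):
        comp = (
            A[world_axis, 0] * coords[0][:, None, None]
            + A[world_axis, 1] * coords[1][None, :, None]
            + A[world_axis, 2] * coords[2][None, None, :]
            + offset[world_axis]
        )
        dist_sq += comp**2
    return np.sqrt(dist_sq) * vol.data


def sort_and_select(wd_map: np.ndarray, K: int = DEFAULT_K) -> WeightedSeries:
    """Top-K weighted distances, sorted from highest to lowest.

    Ties are broken by ascending row-major linear voxel index, making the
    output deterministic and independent of array storage order.

    Raises
    ------
    SelectionError
        If the map has fewer than K strictly positive voxels.
    """
    wd_map = np.ascontiguousarray(wd_map, dtype=np.float64)
    if K <= 0:
        raise SelectionError(f"K must be positive, got {K}")
    flat = wd_map.ravel()
    positive = np.flatnonzero(flat > 0)
    if positive.size < K:
        raise SelectionError(
            f"requested K={K} but only {positive.size} strictly positive voxels"
        )
    # stable sort on descending value; stability gives the ascending-linear-
    # index tie break since `positive` is already ascending
    order = positive[np.argsort(-flat[positive], kind="stable")][:K]
    values = flat[order]
    voxel_indices = np.column_stack(np.unravel_index(order, wd_map.shape)).astype(np.int64)
    return WeightedSeries(values=values, voxel_indices=voxel_indices)


def series_to_table(series: WeightedSeries):
    """Series as a DataFrame with columns rank, i, j, k, weighted_distance."""
    import pandas as pd

    return pd.DataFrame(
        {
            "rank": np.arange(len(series)),
            "i": series.voxel_indices[:, 0],
            "j": series.voxel_indices[:, 1],
            "k": series.voxel_indices[:, 2],
            "weighted_distance": series.values,
        }
    )
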