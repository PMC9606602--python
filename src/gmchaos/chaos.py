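"""Largest-Lyapunov-Exponent estimation on the weighted-distance series.

The sorted weighted-distance series is treated as the scalar observation
of a dynamical system and delay-embedded (Takens reconstruction) into an
m-dimensional state space.  The Rosenstein small-data-set procedure then
tracks, for every state, the log-distance to its nearest neighbor
(outside a Theiler exclusion window) as both are advanced step by step;
the slope of the mean log-divergence over its initially linear region is
the global Lyapunov exponent lambda.  A per-point (spatially localized)
lambda is obtained from the one-step finite difference of each reference
pair's own log-divergence, and mapped back to the selected voxels.

Units: lambda is an exponential divergence rate per embedding step
(divided by the state-space sampling interval ``T_step``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from gmchaos.errors import (
    DegenerateFitError,
    DegenerateSeriesError,
    SeriesTooShortError,
    ShapeMismatchError,
)
from gmchaos.spatial_series import WeightedSeries

logger = logging.getLogger(__name__)

_FWHM_TO_SIGMA = np.sqrt(8.0 * np.log(2.0))


@dataclass(frozen=True)
class EmbeddingConfig:
    """Parameters of the delay embedding and divergence fit.

    Attributes
    ----------
    m : int
        Embedding dimension (number of delayed copies per state vector).
    tau : int
        Embedding delay in series steps.
    theiler : int or None
        Minimum index separation in the nearest-neighbor search; ``None``
        selects ``tau * (m - 1)``, the span of one state vector.
    T_step : float
        State-space sampling interval; lambda is a rate per ``T_step``.
    fit_range : (int, int)
        Inclusive step range over which the log-divergence slope is fitted.
    max_steps : int
        Horizon of the divergence curve.
    """

    m: int = 5
    tau: int = 1
    theiler: int | None = None
    T_step: float = 1.0
    fit_range: tuple[int, int] = (1, 20)
    max_steps: int = 50

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        if self.T_step <= 0:
            raise ValueError(f"T_step must be positive, got {self.T_step}")
        start, end = self.fit_range
        if not (0 <= start < end <= self.max_steps):
            raise ValueError(
                f"fit_range must satisfy 0 <= start < end <= max_steps, "
                f"got {self.fit_range} with max_steps={self.max_steps}"
            )

    @property
    def effective_theiler(self) -> int:
        return self.tau * (self.m - 1) if self.theiler is None else self.theiler


@dataclass
class Trajectory:
    """Delay-embedded state-space matrix; row k is (x_k, x_{k+tau}, ..., x_{k+(m-1)tau})."""

    states: np.ndarray  # (M, m)

    @property
    def n_states(self) -> int:
        return self.states.shape[0]


@dataclass
class DivergenceCurve:
    """Mean log-divergence of neighbor pairs as a function of step.

    ``per_reference[k, s]`` holds ln ||X_{k+s} - X_{j+s}|| for reference k
    with nearest neighbor j, NaN where the pair leaves the trajectory or
    the distance is exactly zero; ``mean_log_div[s]`` averages the finite
    entries and ``counts[s]`` is how many contributed.
    """

    steps: np.ndarray  # (S,) int, 0..max_steps
    mean_log_div: np.ndarray  # (S,) float, NaN where counts == 0
    counts: np.ndarray  # (S,) int
    per_reference: np.ndarray  # (M, S) float with NaN flags
    n_zero_excluded: int = 0


@dataclass(frozen=True)
class LambdaEstimate:
    """Global lambda: slope of the mean log-divergence over the fit range."""

    lambda_global: float
    intercept: float
    fit_r2: float


@dataclass
class LambdaSeries:
    """Per-point lambda values aligned to the weighted-series order.

    ``values[i]`` is NaN where no localized estimate exists (reference
    without an admissible neighbor, zero distances, or series positions
    beyond the last embedded state); ``defined`` marks valid entries.
    """

    values: np.ndarray  # (N,) float, NaN = flagged-missing
    voxel_indices: np.ndarray | None = None  # (N, 3) int

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class LambdaMap:
    """3D lambda map; zero outside the selected voxels."""

    data: np.ndarray
    affine: np.ndarray


def _series_values(series) -> np.ndarray:
    if isinstance(series, WeightedSeries):
        return np.asarray(series.values, dtype=np.float64)
    return np.asarray(series, dtype=np.float64)


def embed(series, cfg: EmbeddingConfig) -> Trajectory:
    """Delay-embed a scalar series into an (M, m) trajectory, M = N - (m-1) tau.

    Raises
    ------
    SeriesTooShortError
        If N <= (m - 1) tau + 1 (fewer than 2 states).
    """
    x = _series_values(series)
    n = x.size
    span = (cfg.m - 1) * cfg.tau
    if n <= span + 1:
        raise SeriesTooShortError(
            f"series of length {n} too short for m={cfg.m}, tau={cfg.tau} "
            f"(need N > {span + 1})"
        )
    m_rows = n - span
    idx = np.arange(m_rows)[:, None] + cfg.tau * np.arange(cfg.m)[None, :]
    return Trajectory(states=x[idx])


def nearest_neighbors(traj: Trajectory, theiler: int = 0) -> np.ndarray:
    """Nearest neighbor of each state outside the Theiler window.

    Returns an (M,) integer array; entry k is the index j minimizing
    ||X_k - X_j|| subject to |k - j| > theiler, ties broken by smaller j.
    Entries with no admissible candidate are -1.
    """
    X = traj.states
    m_rows = X.shape[0]
    neighbors = np.full(m_rows, -1, dtype=np.int64)
    if theiler >= m_rows - 1:
        return neighbors
    # chunked O(M^2) search; argmin is tie-broken toward smaller j by numpy
    sq_norms = np.einsum("ij,ij->i", X, X)
    chunk = max(1, int(2e7) // max(m_rows, 1))
    for start in range(0, m_rows, chunk):
        stop = min(start + chunk, m_rows)
        block = X[start:stop]
        d2 = (
            sq_norms[start:stop, None]
            - 2.0 * block @ X.T
            + sq_norms[None, :]
        )
        rows = np.arange(start, stop)
        band = np.abs(rows[:, None] - np.arange(m_rows)[None, :]) <= theiler
        d2[band] = np.inf
        best = np.argmin(d2, axis=1)
        exhausted = ~np.isfinite(d2[np.arange(stop - start), best])
        best[exhausted] = -1
        neighbors[start:stop] = best
    return neighbors


def divergence_curve(
    traj: Trajectory, neighbors: np.ndarray, cfg: EmbeddingConfig
) -> DivergenceCurve:
    """Mean log-divergence of reference/neighbor pairs over 0..max_steps.

    At step s the pair (k, j) contributes ln ||X_{k+s} - X_{j+s}|| when
    both advanced indices are in range and the distance is strictly
    positive; exact-tie (zero-distance) pairs are excluded from that
    step's mean and counted in ``n_zero_excluded``.

    Raises
    ------
    DegenerateSeriesError
        If no pair has a positive distance at step 0.
    """
    X = traj.states
    m_rows = X.shape[0]
    if neighbors.shape != (m_rows,):
        raise ShapeMismatchError("neighbors length must equal the state count")
    valid_ref = neighbors >= 0
    if not valid_ref.any():
        raise DegenerateSeriesError("no reference state has an admissible neighbor")
    refs = np.flatnonzero(valid_ref)
    nbrs = neighbors[refs]
    n_steps = cfg.max_steps + 1
    per_ref = np.full((m_rows, n_steps), np.nan)
    n_zero = 0
    for s in range(n_steps):
        in_range = (refs + s < m_rows) & (nbrs + s < m_rows)
        if not in_range.any():
            break
        r = refs[in_range]
        j = nbrs[in_range]
        diff = X[r + s] - X[j + s]
        dist = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        positive = dist > 0
        n_zero += int(np.count_nonzero(~positive))
        per_ref[r[positive], s] = np.log(dist[positive])
    finite = np.isfinite(per_ref)
    counts = finite.sum(axis=0)
    sums = np.where(finite, per_ref, 0.0).sum(axis=0)
    mean_log = np.full(n_steps, np.nan)
    np.divide(sums, counts, out=mean_log, where=counts > 0)
    if counts[0] == 0:
        raise DegenerateSeriesError("no positive neighbor distances at step 0")
    return DivergenceCurve(
        steps=np.arange(n_steps),
        mean_log_div=mean_log,
        counts=counts.astype(np.int64),
        per_reference=per_ref,
        n_zero_excluded=n_zero,
    )


def lambda_global(curve: DivergenceCurve, cfg: EmbeddingConfig) -> LambdaEstimate:
    """Least-squares slope of mean log-divergence vs step * T_step over the fit range."""
    start, end = cfg.fit_range
    sel = (curve.steps >= start) & (curve.steps <= end) & (curve.counts > 0)
    if np.count_nonzero(sel) < 2:
        raise DegenerateFitError(
            f"fewer than 2 valid divergence points in fit range {cfg.fit_range}"
        )
    x = curve.steps[sel] * cfg.T_step
    y = curve.mean_log_div[sel]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - np.sum(resid**2) / ss_tot)
    return LambdaEstimate(lambda_global=float(slope), intercept=float(intercept), fit_r2=float(r2))


def lambda_local(
    curve: DivergenceCurve,
    cfg: EmbeddingConfig,
    voxel_indices: np.ndarray | None = None,
    n_points: int | None = None,
) -> LambdaSeries:
    """Spatially localized lambda per reference point.

    ``lambda(k) = (ln d_k(1) - ln d_k(0)) / T_step`` where ``d_k(s)`` is
    the distance between reference k and its nearest neighbor after s
    steps — the one-step finite difference of that pair's own
    log-divergence.  Points where either step is undefined are flagged
    NaN, as are series positions beyond the last embedded state when
    ``n_points`` exceeds the state count.
    """
    per_ref = curve.per_reference
    m_rows = per_ref.shape[0]
    if n_points is None:
        n_points = m_rows if voxel_indices is None else len(voxel_indices)
    values = np.full(n_points, np.nan)
    upto = min(m_rows, n_points)
    values[:upto] = (per_ref[:upto, 1] - per_ref[:upto, 0]) / cfg.T_step
    if voxel_indices is not None and len(voxel_indices) != n_points:
        raise ShapeMismatchError("voxel_indices length must match n_points")
    return LambdaSeries(values=values, voxel_indices=voxel_indices)


def lambda_map(ls: LambdaSeries, shape: tuple[int, int, int], affine: np.ndarray) -> LambdaMap:
    """Scatter a lambda series into a 3D map; unselected voxels stay 0.

    Flagged-missing values are written as 0 and their count logged.
    """
    if ls.voxel_indices is None:
        raise ShapeMismatchError("lambda series carries no voxel indices")
    idx = np.asarray(ls.voxel_indices, dtype=np.int64)
    if idx.size and (idx.min() < 0 or np.any(idx >= np.asarray(shape)[None, :])):
        raise ShapeMismatchError(f"voxel index out of bounds for shape {shape}")
    data = np.zeros(shape, dtype=np.float64)
    defined = ls.defined
    n_flagged = int(np.count_nonzero(~defined))
    if n_flagged:
        logger.info("lambda_map: %d flagged-missing values written as 0", n_flagged)
    if idx.size:
        sel = idx[defined]
        data[sel[:, 0], sel[:, 1], sel[:, 2]] = ls.values[defined]
    return LambdaMap(data=data, affine=np.asarray(affine, dtype=np.float64))


def smooth_map(lmap: LambdaMap, fwhm_mm=8.0) -> LambdaMap:
    """Gaussian-smooth a lambda map; FWHM given in mm per axis.

    Sigma per axis is ``fwhm / (voxel_size * sqrt(8 ln 2))`` voxels;
    boundaries are zero-padded, so the total sum is preserved up to
    boundary loss.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=np.float64), (3,))
    if np.any(fwhm <= 0):
        raise ValueError(f"fwhm must be positive, got {fwhm_mm}")
    voxel_size = np.linalg.norm(lmap.affine[:3, :3], axis=0)
    sigma = fwhm / (voxel_size * _FWHM_TO_SIGMA)
    smoothed = ndimage.gaussian_filter(lmap.data, sigma=sigma, mode="constant", cval=0.0)
    return LambdaMap(data=smoothed, affine=lmap.affine.copy())


def lyapunov_from_series(series, cfg: EmbeddingConfig):
    """Convenience: embed, find neighbors, build the curve, fit lambda.

    Returns ``(LambdaEstimate, DivergenceCurve)``.
    """
    traj = embed(series, cfg)
    nbrs = nearest_neighbors(traj, cfg.effective_theiler)
    curve = divergence_curve(traj, nbrs, cfg)
    return lambda_global(curve, cfg), curve
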