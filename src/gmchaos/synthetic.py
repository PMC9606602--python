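"""Synthetic cortical phantoms and two-group cohorts.

A phantom is a noisy corrugated spherical shell standing in for a
normalized gray-matter map: intensity falls off as a Gaussian of the
distance between each voxel's radius and an angular shell radius

    R(theta, phi) = r0 * (1 + a * B(theta, phi)),

where ``B`` is band-limited, unit-variance angular noise built from a
random mixture of real spherical harmonics up to degree
``corrugation_freq``.  The corrugation amplitude ``a`` is the surface-
complexity dial: larger ``a`` means a rougher shell, emulating stronger
cortical relief.  Cohorts draw per-subject shells from seeded generators
and shift group B's amplitude by ``group_effect``; covariates are
sampled independently of group unless a confound is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import sph_harm_y

from gmchaos.errors import PhantomConfigError
from gmchaos.volume_io import GMVolume


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, corrugation and noise of one synthetic GM shell.

    Lengths are in mm; the affine is diagonal with ``voxel_mm`` spacing.
    Defaults give a 64^3 grid at 1.5 mm (96 mm box) holding a 24 mm
    reference shell (a quarter of the box extent, leaving headroom for
    corrugation) of 3 mm width — proportions loosely matched to a
    cortical sheet inside a head-sized field of view.  The default shell
    is uncorrugated: ``corrugation_amp`` is the surface-complexity dial
    and is set explicitly by cohort studies.  ``noise_sd`` models the
    small residual intensity noise of denoised, probability-derived GM
    maps; anatomical (surface) variation, not scanner noise, is the
    dominant variance source the phantom emulates.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_mm: float = 1.5
    r0: float = 24.0
    shell_width: float = 3.0
    corrugation_amp: float = 0.0
    corrugation_freq: int = 6
    noise_sd: float = 0.02
    seed: int = 0


@dataclass(frozen=True)
class CohortConfig:
    """Two-group cohort: sizes, group effect on corrugation, master seed.

    Per-subject corrugation amplitude is jittered around the group mean
    (reflected normal with sd ``amp_sd``), emulating population
    variability in gyrification; group B's mean amplitude is shifted by
    ``group_effect``.
    """

    n_per_group: int = 8
    group_effect: float = 0.1
    amp_sd: float = 0.02
    seed: int = 0
    confound_covariate: str | None = None  # covariate made group-dependent

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")


def _harmonic_basis(theta: np.ndarray, phi: np.ndarray, band_limit: int) -> np.ndarray:
    """Real spherical-harmonic basis, rows ordered (l, m=0), (l, m, re), (l, m, im).

    Rows are orthonormal over the sphere (the m > 0 real/imaginary parts
    carry the usual sqrt(2) factor).  Shape: (n_terms, n_points).
    """
    rows = []
    sqrt2 = np.sqrt(2.0)
    for ell in range(1, band_limit + 1):
        rows.append(sph_harm_y(ell, 0, theta, phi).real)
        for m in range(1, ell + 1):
            y = sph_harm_y(ell, m, theta, phi)
            rows.append(sqrt2 * y.real)
            rows.append(sqrt2 * y.imag)
    return np.stack([np.ravel(r) for r in rows])


def _draw_coefficients(band_limit: int, rng: np.random.Generator) -> np.ndarray:
    """iid standard-normal coefficients in the `_harmonic_basis` row order."""
    n_terms = band_limit * (band_limit + 2)
    return rng.standard_normal(n_terms)


def _angular_noise(theta: np.ndarray, phi: np.ndarray, band_limit: int,
                   rng: np.random.Generator,
                   basis: np.ndarray | None = None) -> np.ndarray:
    """Band-limited unit-variance random field on the sphere.

    Random mixture of real spherical harmonics for degrees
    1..band_limit; normalized analytically (orthonormal basis, so the
    variance over the sphere is sum(c^2) / (4 pi)).
    """
    coeffs = _draw_coefficients(band_limit, rng)
    if basis is None:
        basis = _harmonic_basis(theta, phi, band_limit)
    norm = np.sqrt(np.sum(np.square(coeffs)) / (4.0 * np.pi))
    return (coeffs @ basis).reshape(np.shape(theta)) / norm


_GRID_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _phantom_grid(shape: tuple[int, ...], voxel_mm: float, band_limit: int):
    """Radius grid and harmonic basis for a phantom geometry; cached.

    The basis depends only on the grid, not the seed, so cohorts of many
    phantoms on the same grid reuse it.
    """
    key = (tuple(shape), float(voxel_mm), int(band_limit))
    if key in _GRID_CACHE:
        return _GRID_CACHE[key]
    shape_arr = np.asarray(shape, dtype=np.int64)
    center = voxel_mm * (shape_arr - 1) / 2.0
    coords = [voxel_mm * np.arange(n) - c for n, c in zip(shape_arr, center)]
    xg = coords[0][:, None, None]
    yg = coords[1][None, :, None]
    zg = coords[2][None, None, :]
    r = np.sqrt(xg**2 + yg**2 + zg**2)
    with np.errstate(invalid="ignore"):
        theta = np.arccos(np.clip(np.where(r > 0, zg / np.where(r > 0, r, 1.0), 1.0), -1, 1))
    phi = np.arctan2(yg, xg) + np.zeros_like(r)
    basis = _harmonic_basis(theta, phi, band_limit)
    if len(_GRID_CACHE) > 4:  # bound memory across many grid sizes
        _GRID_CACHE.clear()
    _GRID_CACHE[key] = (r, basis)
    return r, basis


def make_phantom(cfg: PhantomConfig) -> GMVolume:
    """Build one corrugated-shell phantom volume; deterministic given the seed."""
    rng = np.random.default_rng(cfg.seed)
    shape = np.asarray(cfg.shape, dtype=np.int64)
    affine = np.diag([cfg.voxel_mm, cfg.voxel_mm, cfg.voxel_mm, 1.0])
    r, basis = _phantom_grid(cfg.shape, cfg.voxel_mm, cfg.corrugation_freq)
    coeffs = _draw_coefficients(cfg.corrugation_freq, rng)
    if cfg.corrugation_amp > 0:
        norm = np.sqrt(np.sum(np.square(coeffs)) / (4.0 * np.pi))
        B = (coeffs @ basis).reshape(r.shape) / norm
        radius = cfg.r0 * (1.0 + cfg.corrugation_amp * B)
    else:
        radius = np.full_like(r, cfg.r0)
    half_extent = float(np.min(cfg.voxel_mm * (shape - 1) / 2.0))
    if float(np.max(radius)) + cfg.shell_width > half_extent:
        raise PhantomConfigError(
            f"shell (max radius {np.max(radius):.1f} mm + width) exceeds the "
            f"grid half-extent {half_extent:.1f} mm"
        )
    intensity = np.exp(-((r - radius) ** 2) / (2.0 * cfg.shell_width**2))
    if cfg.noise_sd > 0:
        noise = np.clip(rng.normal(0.0, cfg.noise_sd, size=intensity.shape), 0.0, None)
        intensity = intensity + noise
    return GMVolume(data=intensity, affine=affine, subject_id=f"phantom_seed{cfg.seed}")


def subject_seed(master_seed: int, subject_index: int) -> int:
    """Deterministic per-subject seed derived from (master seed, index)."""
    ss = np.random.SeedSequence([int(master_seed), int(subject_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def make_cohort(
    cfg: CohortConfig, phantom_cfg: PhantomConfig | None = None
) -> tuple[list[GMVolume], pd.DataFrame]:
    """Two groups of phantoms plus a covariate table.

    Group A's mean amplitude is ``phantom_cfg.corrugation_amp``; group B
    adds ``cfg.group_effect``; each subject's amplitude is the group mean
    plus reflected-normal jitter with sd ``cfg.amp_sd``.  Covariates
    (age, sex, education_years, smoking, alcohol) are sampled
    independently of group from the master seed, so the default cohort
    has null covariates.
    """
    phantom_cfg = phantom_cfg or PhantomConfig()
    n = cfg.n_per_group
    cov_rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 987654321]))
    volumes: list[GMVolume] = []
    rows = []
    for i in range(2 * n):
        group = "A" if i < n else "B"
        mean_amp = phantom_cfg.corrugation_amp + (cfg.group_effect if group == "B" else 0.0)
        jitter_rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), i, 555]))
        amp = abs(mean_amp + jitter_rng.normal(0.0, cfg.amp_sd)) if cfg.amp_sd > 0 else mean_amp
        p_cfg = replace(phantom_cfg, corrugation_amp=amp, seed=subject_seed(cfg.seed, i))
        vol = make_phantom(p_cfg)
        sid = f"S{i:03d}"
        vol.subject_id = sid
        volumes.append(vol)
        row = {
            "subject_id": sid,
            "group": group,
            "age": float(cov_rng.uniform(18, 35)),
            "sex": int(cov_rng.integers(0, 2)),
            "education_years": float(np.clip(cov_rng.normal(13, 2.5), 8, 20)),
            "smoking": float(np.clip(cov_rng.normal(5, 4), 0, None)),
            "alcohol": int(cov_rng.random() < 0.4),
        }
        rows.append(row)
    table = pd.DataFrame(rows)
    if cfg.confound_covariate is not None:
        name = cfg.confound_covariate
        if name not in table.columns:
            raise ValueError(f"unknown covariate: {name}")
        table.loc[table["group"] == "B", name] = table.loc[
            table["group"] == "B", name
        ] + table[name].std()
    table["group"] = table["group"].astype("category")
    return volumes, table


def roughness(cfg: PhantomConfig, n_samples: int = 2048) -> float:
    """Variance of the shell radius R over a fixed angular sample.

    A monotone summary of surface complexity: strictly increasing in
    ``corrugation_amp`` for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    # Fibonacci sphere sample (deterministic, independent of the rng draws)
    k = np.arange(n_samples, dtype=np.float64)
    z = 1.0 - 2.0 * (k + 0.5) / n_samples
    theta = np.arccos(z)
    phi = np.mod(k * np.pi * (3.0 - np.sqrt(5.0)), 2.0 * np.pi)
    B = _angular_noise(theta, phi, cfg.corrugation_freq, rng)
    R = cfg.r0 * (1.0 + cfg.corrugation_amp * B)
    return float(np.var(R))
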