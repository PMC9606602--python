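"""Continuous wavelet transform of lambda series with a complex Morlet wavelet.

Each subject's lambda series is correlated with scaled copies of the
Morlet wavelet

    psi_s(t) = s^(-1/2) pi^(-1/4) exp(i w0 t / s) exp(-(t/s)^2 / 2)

centered at every series position, giving a points-by-scales scalogram.
The stored coefficient is the real part of the complex correlation, so
positive values are "matches" with the wavelet shape and negative values
anti-matches; the complex modulus is available on request.  Boundaries
are zero-padded and coefficients within one wavelet support of either
edge are flagged as boundary-affected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from gmchaos.errors import ShapeMismatchError

logger = logging.getLogger(__name__)

#: Half-width of the truncated wavelet support in units of the scale.
SUPPORT_RADIUS = 8.0


@dataclass(frozen=True)
class WaveletConfig:
    """Scales and Morlet center frequency for the CWT.

    ``scales`` defaults to the integers 1..100; ``omega0`` = 6 is the
    standard admissible Morlet center frequency.  ``output`` selects the
    stored coefficient: the real part of the complex correlation
    ("real_part") or its modulus ("modulus").
    """

    scales: np.ndarray = field(default_factory=lambda: np.arange(1, 101, dtype=np.float64))
    omega0: float = 6.0
    output: str = "real_part"

    def __post_init__(self) -> None:
        scales = np.asarray(self.scales, dtype=np.float64)
        object.__setattr__(self, "scales", scales)
        if scales.ndim != 1 or scales.size == 0:
            raise ValueError("scales must be a non-empty 1D sequence")
        if np.any(scales <= 0) or np.any(np.diff(scales) <= 0):
            raise ValueError("scales must be strictly increasing and positive")
        if self.output not in {"real_part", "modulus"}:
            raise ValueError(f"unknown output mode: {self.output!r}")


@dataclass
class Scalogram:
    """Points-by-scales matrix of wavelet correlation coefficients.

    ``boundary_mask[p, s]`` is True where the coefficient lies within one
    truncated wavelet support of either series edge and is therefore
    affected by zero padding.
    """

    coeffs: np.ndarray  # (N, n_scales) real
    scales: np.ndarray  # (n_scales,)
    boundary_mask: np.ndarray  # (N, n_scales) bool
    subject_id: str = ""


def morlet(scale: float, grid: np.ndarray, cfg: WaveletConfig | None = None) -> np.ndarray:
    """Complex Morlet wavelet at the given scale, sampled on integer offsets.

    Truncated to zero for |t/s| > 8, where the Gaussian envelope is below
    1e-14 of its peak.
    """
    cfg = cfg or WaveletConfig()
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")
    t = np.asarray(grid, dtype=np.float64)
    u = t / scale
    psi = (
        scale**-0.5
        * np.pi**-0.25
        * np.exp(1j * cfg.omega0 * u)
        * np.exp(-0.5 * u**2)
    )
    psi[np.abs(u) > SUPPORT_RADIUS] = 0.0
    return psi


def _support_grid(scale: float) -> np.ndarray:
    half = int(np.ceil(SUPPORT_RADIUS * scale))
    return np.arange(-half, half + 1)


def cwt(series: np.ndarray, cfg: WaveletConfig | None = None) -> Scalogram:
    """CWT of a 1D series: correlation with the conjugate wavelet at each scale.

    Missing (NaN) values are imputed as 0 with a logged count; the series
    is zero-padded at the boundaries.  ``coeffs[p, s]`` is the correlation
    of the series with psi at scale ``scales[s]`` centered at point p.
    """
    cfg = cfg or WaveletConfig()
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ShapeMismatchError("series must be 1D with at least 2 points")
    n_missing = int(np.count_nonzero(~np.isfinite(x)))
    if n_missing:
        logger.info("cwt: imputed %d missing series values as 0", n_missing)
        x = np.where(np.isfinite(x), x, 0.0)
    n = x.size
    n_scales = cfg.scales.size
    coeffs = np.empty((n, n_scales), dtype=np.float64)
    boundary = np.zeros((n, n_scales), dtype=bool)
    positions = np.arange(n)
    for s_i, scale in enumerate(cfg.scales):
        grid = _support_grid(scale)
        psi = morlet(scale, grid, cfg)
        # correlation with conjugate wavelet == convolution with conj(psi(-t));
        # psi has Hermitian-symmetric real part so this is fftconvolve with
        # conj(psi) reversed
        kernel = np.conj(psi)[::-1]
        full = fftconvolve(x.astype(np.complex128), kernel, mode="same")
        if cfg.output == "modulus":
            coeffs[:, s_i] = np.abs(full)
        else:
            coeffs[:, s_i] = full.real
        half = (grid.size - 1) // 2
        boundary[:, s_i] = (positions < half) | (positions >= n - half)
    return Scalogram(coeffs=coeffs, scales=cfg.scales.copy(), boundary_mask=boundary)


def cwt_complex(series: np.ndarray, cfg: WaveletConfig | None = None) -> np.ndarray:
    """Full complex CWT coefficients, (N, n_scales); used for scale localization."""
    cfg = cfg or WaveletConfig()
    x = np.where(np.isfinite(series), np.asarray(series, dtype=np.float64), 0.0)
    out = np.empty((x.size, cfg.scales.size), dtype=np.complex128)
    for s_i, scale in enumerate(cfg.scales):
        psi = morlet(scale, _support_grid(scale), cfg)
        out[:, s_i] = fftconvolve(x.astype(np.complex128), np.conj(psi)[::-1], mode="same")
    return out


def cohort_scalograms(
    lambda_series: dict[str, np.ndarray] | list[np.ndarray],
    cfg: WaveletConfig | None = None,
) -> list[Scalogram]:
    """One scalogram per subject; all series must share the same length.

    Accepts a mapping subject_id -> series or a plain list; output order
    follows the input order.
    """
    cfg = cfg or WaveletConfig()
    if isinstance(lambda_series, dict):
        items = list(lambda_series.items())
    else:
        items = [(f"subject_{i}", s) for i, s in enumerate(lambda_series)]
    if not items:
        return []
    lengths = {np.asarray(s).size for _, s in items}
    if len(lengths) > 1:
        raise ShapeMismatchError(f"series lengths differ across subjects: {sorted(lengths)}")
    out = []
    for subject_id, series in items:
        sg = cwt(np.asarray(series, dtype=np.float64), cfg)
        sg.subject_id = subject_id
        out.append(sg)
    return out
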