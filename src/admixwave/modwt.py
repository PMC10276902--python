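"""Haar maximal-overlap discrete wavelet transform (MODWT) for one chromosome.

The MODWT places a wavelet at every position in the sequence (it is not
subsampled like the ordinary DWT), so it is shift-covariant and yields
low-noise per-scale variance estimates while still decomposing variance
independently across dyadic scales.

Conventions (Percival & Walden):

* level-1 Haar filters are h = (1/2, -1/2) and g = (1/2, 1/2); level j is
  obtained by the a-trous recursion with lag 2**(j-1).  The effective
  level-j wavelet filter has 2**j taps of magnitude 2**-j (a halved
  difference of two adjacent window means) and squared norm 2**-j.
* filtering is circular; the first min(L, 2**j - 1) coefficients of level j
  depend on wrapped values and are flagged as boundary coefficients.
* with these filters the transform conserves energy exactly:
  Var(x) = sum_j mean(W_j**2) + Var(V_J), which is the per-scale variance
  decomposition (power spectrum) plus the scaling variance left over when
  L is not a power of two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .signal_prep import GridSignal

__all__ = [
    "WaveletDecomposition",
    "ScaleSpectrum",
    "modwt_haar",
    "inverse_modwt",
    "wavelet_variance",
    "wavelet_covariance",
    "wavelet_correlation",
    "haar_filter",
]

Estimator = Literal["unbiased", "biased"]


def haar_filter(level: int) -> np.ndarray:
    """Effective level-j Haar MODWT wavelet filter (2**j taps).

    The coefficient at position t is sum_l f[l] * x[t - l], i.e. half the
    difference between the mean of the most recent 2**(j-1) values and the
    mean of the preceding 2**(j-1).
    """
    half = 2 ** (level - 1)
    f = np.empty(2 * half)
    f[:half] = 2.0**-level
    f[half:] = -(2.0**-level)
    return f


@dataclass
class WaveletDecomposition:
    """MODWT coefficients of one chromosome's grid signal.

    ``coeffs[j-1]`` holds the length-L wavelet coefficient vector at level
    j (scale 2**j grid units); ``scaling`` holds the level-J scaling
    (smooth) coefficients.
    """

    chromosome: str
    resolution: float
    coeffs: np.ndarray  # (J, L)
    scaling: np.ndarray  # (L,)
    signal_mean: float
    signal_variance: float
    map_kind: str = "genetic"

    @property
    def n_levels(self) -> int:
        return self.coeffs.shape[0]

    @property
    def length(self) -> int:
        return self.coeffs.shape[1]

    @property
    def levels(self) -> np.ndarray:
        return np.arange(1, self.n_levels + 1)

    def scale(self, level: int) -> int:
        return 2**level

    def boundary_width(self, level: int) -> int:
        return min(self.length, 2**level - 1)

    def boundary_mask(self, level: int) -> np.ndarray:
        """Boolean mask, True where the level's filter wraps the edge."""
        mask = np.zeros(self.length, dtype=bool)
        mask[: self.boundary_width(level)] = True
        return mask

    def interior(self, level: int) -> np.ndarray:
        """Non-boundary coefficients at a level."""
        return self.coeffs[level - 1, self.boundary_width(level):]


@dataclass
class ScaleSpectrum:
    """Per-scale wavelet variances plus the scaling-variance remainder."""

    chromosome: str
    resolution: float
    levels: np.ndarray
    variances: np.ndarray  # NaN where a level has no usable coefficients
    n_coeffs: np.ndarray
    scaling_variance: float
    total_variance: float
    estimator: str
    map_kind: str = "genetic"

    @property
    def scales_grid(self) -> np.ndarray:
        return 2.0**self.levels

    @property
    def scales_map(self) -> np.ndarray:
        return self.scales_grid * self.resolution


def modwt_haar(signal: GridSignal, max_level: int | None = None) -> WaveletDecomposition:
    """Circular Haar MODWT pyramid of a grid signal.

    Levels run to J = floor(log2(L)) unless capped by ``max_level`` (a
    larger request is capped with a warning).
    """
    x = np.asarray(signal.values, dtype=float)
    L = len(x)
    if L < 2:
        raise ValueError("signal too short for a wavelet transform (L < 2)")
    j_max = int(np.floor(np.log2(L)))
    if max_level is not None:
        if max_level > j_max:
            warnings.warn(
                f"max_level={max_level} exceeds floor(log2(L))={j_max}; capping",
                stacklevel=2,
            )
        elif max_level < 1:
            raise ValueError("max_level must be >= 1")
        j_max = min(max_level, j_max)
    coeffs = np.empty((j_max, L))
    v = x
    for j in range(1, j_max + 1):
        shifted = np.roll(v, 2 ** (j - 1))
        coeffs[j - 1] = (v - shifted) / 2.0
        v = (v + shifted) / 2.0
    return WaveletDecomposition(
        chromosome=signal.chromosome,
        resolution=signal.resolution,
        coeffs=coeffs,
        scaling=v,
        signal_mean=float(np.mean(x)),
        signal_variance=float(np.var(x)),
        map_kind=signal.map_kind,
    )


def inverse_modwt(decomp: WaveletDecomposition) -> np.ndarray:
    """Reconstruct the signal; exact for this filter convention, where
    V_{j-1} = W_j + V_j at every level."""
    return decomp.scaling + decomp.coeffs.sum(axis=0)


def wavelet_variance(
    decomp: WaveletDecomposition, estimator: Estimator = "unbiased"
) -> ScaleSpectrum:
    """Per-scale wavelet variances (the power spectrum of the signal).

    ``biased`` averages squared coefficients over all L positions, which
    makes the decomposition exactly energy-conserving
    (Var(x) = sum of scales + scaling variance).  ``unbiased`` drops the
    boundary coefficients whose circular filter support wraps the
    chromosome end; a level whose coefficients are all boundary is
    reported as NaN with n = 0.
    """
    _check_estimator(estimator)
    J, L = decomp.n_levels, decomp.length
    variances = np.empty(J)
    n_coeffs = np.empty(J, dtype=int)
    for j in range(1, J + 1):
        w = decomp.coeffs[j - 1]
        if estimator == "biased":
            variances[j - 1] = np.mean(w**2)
            n_coeffs[j - 1] = L
        else:
            interior = decomp.interior(j)
            n_coeffs[j - 1] = interior.size
            variances[j - 1] = np.mean(interior**2) if interior.size else np.nan
    scaling_variance = float(np.var(decomp.scaling))
    return ScaleSpectrum(
        chromosome=decomp.chromosome,
        resolution=decomp.resolution,
        levels=decomp.levels,
        variances=variances,
        n_coeffs=n_coeffs,
        scaling_variance=scaling_variance,
        total_variance=decomp.signal_variance,
        estimator=estimator,
        map_kind=decomp.map_kind,
    )


def _check_estimator(estimator: str) -> None:
    if estimator not in ("unbiased", "biased"):
        raise ValueError(f"unknown estimator {estimator!r}")


def _check_compatible(dx: WaveletDecomposition, dy: WaveletDecomposition) -> None:
    if dx.length != dy.length:
        raise ValueError("decompositions have mismatched lengths")
    if dx.n_levels != dy.n_levels:
        raise ValueError("decompositions have mismatched level counts")
    if dx.chromosome != dy.chromosome:
        raise ValueError(
            f"decompositions are from different chromosomes "
            f"({dx.chromosome!r} vs {dy.chromosome!r})"
        )


def wavelet_covariance(
    dx: WaveletDecomposition,
    dy: WaveletDecomposition,
    estimator: Estimator = "unbiased",
) -> np.ndarray:
    """Per-scale mean products of the two signals' wavelet coefficients.

    Boundary handling follows ``wavelet_variance``.  The scaling-coefficient
    covariance is not included; see :func:`scaling_covariance`.
    """
    _check_estimator(estimator)
    _check_compatible(dx, dy)
    J = dx.n_levels
    cov = np.empty(J)
    for j in range(1, J + 1):
        if estimator == "biased":
            cov[j - 1] = np.mean(dx.coeffs[j - 1] * dy.coeffs[j - 1])
        else:
            wx, wy = dx.interior(j), dy.interior(j)
            cov[j - 1] = np.mean(wx * wy) if wx.size else np.nan
    return cov


def scaling_covariance(dx: WaveletDecomposition, dy: WaveletDecomposition) -> float:
    """Covariance of the level-J scaling coefficients about their means."""
    _check_compatible(dx, dy)
    vx, vy = dx.scaling, dy.scaling
    return float(np.mean(vx * vy) - np.mean(vx) * np.mean(vy))


def wavelet_correlation(
    dx: WaveletDecomposition,
    dy: WaveletDecomposition,
    estimator: Estimator = "unbiased",
) -> np.ndarray:
    """Per-scale correlations rho_lambda = cov / sqrt(var_x * var_y).

    A scale at which either signal has zero (or undefined) wavelet variance
    is reported as NaN rather than 0: the correlation is undefined there.
    """
    cov = wavelet_covariance(dx, dy, estimator)
    var_x = wavelet_variance(dx, estimator).variances
    var_y = wavelet_variance(dy, estimator).variances
    denom = np.sqrt(var_x * var_y)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, cov / denom, np.nan)
    return rho
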