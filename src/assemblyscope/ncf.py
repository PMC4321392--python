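"""Normalized clustering factor (NCF) from the radial power spectral density.

The degree to which fluorescence intensity aggregates into clumps is scored
by a single scalar in [0, 1] built from the image's 2-D power spectral
density (PSD):

1. ``compute_psd2d`` — squared modulus of the centered 2-D DFT.
2. ``radial_psd`` — average the PSD over integer-radius annuli, giving a
   power-vs-spatial-frequency curve on the grid ``f_k = k/N`` (DC excluded,
   Nyquist 0.5 px^-1 included).
3. ``ncf`` — a PSD-weighted average of ln(frequency) using every non-DC
   Fourier sample (annulus total power = annulus count x annulus mean), then

       NCF = (ln f_max - f_bar_log) / (ln f_max - ln f_min),  clamped to [0, 1].

Anchor behaviours: spatially random (white-noise) intensity gives NCF near 0
(exactly ~1/(2 ln 300) ~ 0.088 on the finite 600-px grid), a single large
Gaussian clump gives NCF near 1, and a power-law (self-similar) spectrum
``PSD ~ f^-2`` sits near the midpoint 0.5.  The weighted mean is taken on the
log-frequency axis; weighting by total annulus power makes the statistic
exactly invariant to global intensity scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imgio import STANDARD_SHAPE, StandardizedImage, minmax_normalize

__all__ = [
    "PSD2D", "PSDCurve", "NCFResult",
    "compute_psd2d", "radial_psd", "ncf", "ncf_image", "ncf_per_channel",
]


@dataclass(frozen=True)
class PSD2D:
    """Centered 2-D power spectral density of an N x N raster."""

    psd: np.ndarray       # fftshift-centered |DFT|^2, DC at (N//2, N//2)
    dc_power: float       # the DC bin, recorded separately
    n: int                # grid side length

    @property
    def total_power(self) -> float:
        return float(self.psd.sum())


@dataclass(frozen=True)
class PSDCurve:
    """Radially sampled PSD: annulus-mean power per integer spatial frequency."""

    frequencies: np.ndarray   # f_k = k/N, k = 1..N//2, strictly increasing
    power: np.ndarray         # mean PSD over annulus k
    counts: np.ndarray        # number of Fourier pixels in annulus k

    @property
    def f_min(self) -> float:
        return float(self.frequencies[0])

    @property
    def f_max(self) -> float:
        return float(self.frequencies[-1])


@dataclass(frozen=True)
class NCFResult:
    """PSD-weighted mean log-frequency and the normalized clustering factor."""

    f_bar_log: float
    ncf: float


def compute_psd2d(image: np.ndarray, *, allow_any_shape: bool = False) -> PSD2D:
    """2-D PSD of a square raster via the discrete Fourier transform.

    Input must be the canonical 600 x 600 geometry unless ``allow_any_shape``
    is set (used for small-grid oracle comparisons).  Parseval's identity
    holds: ``psd.sum() / N**2 == (image**2).sum()``.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("compute_psd2d expects a square 2-D raster")
    if image.shape != STANDARD_SHAPE and not allow_any_shape:
        raise ValueError(
            f"expected {STANDARD_SHAPE} input; run standardize() first "
            f"(got {image.shape})"
        )
    spec = np.fft.fftshift(np.fft.fft2(image))
    psd = np.abs(spec) ** 2
    n = image.shape[0]
    return PSD2D(psd=psd, dc_power=float(psd[n // 2, n // 2]), n=n)


def radial_psd(psd2d: PSD2D) -> PSDCurve:
    """Average the 2-D PSD over annuli of (rounded) integer radius.

    Every non-DC Fourier pixel is binned by ``k = round(radius)`` (half away
    from zero); radii beyond the Nyquist ring ``k > N//2`` (the spectrum's
    corners) are discarded.  Annulus pixel counts are retained because the
    NCF weights each annulus by its *total* power.
    """
    n = psd2d.n
    c = n // 2
    idx = np.arange(n) - c
    r = np.hypot(idx[:, None], idx[None, :])
    k = np.floor(r + 0.5).astype(np.intp)       # round half away from zero
    kmax = n // 2
    keep = (k >= 1) & (k <= kmax)
    counts = np.bincount(k[keep], minlength=kmax + 1)[1:]
    sums = np.bincount(k[keep], weights=psd2d.psd[keep], minlength=kmax + 1)[1:]
    power = np.divide(sums, counts, out=np.zeros_like(sums), where=counts > 0)
    freqs = np.arange(1, kmax + 1) / n
    return PSDCurve(frequencies=freqs, power=power, counts=counts)


def ncf(curve: PSDCurve) -> NCFResult:
    """Reduce a radial PSD curve to the normalized clustering factor.

    Weights are the annulus total powers ``w_k = counts_k * power_k`` — i.e.
    every non-DC sample of the 2-D PSD contributes — and the average is taken
    on the natural-log frequency axis.  The result is normalized by the
    log-frequency span and clamped to [0, 1].
    """
    w = curve.counts * curve.power
    total = w.sum()
    if not total > 0:
        raise ValueError("degenerate spectrum: no positive power off DC")
    logf = np.log(curve.frequencies)
    f_bar_log = float((w * logf).sum() / total)
    span = np.log(curve.f_max) - np.log(curve.f_min)
    value = (np.log(curve.f_max) - f_bar_log) / span
    return NCFResult(f_bar_log=f_bar_log, ncf=float(np.clip(value, 0.0, 1.0)))


def ncf_image(image: np.ndarray, *, allow_any_shape: bool = False) -> NCFResult:
    """PSD -> radial sampling -> NCF for a single raster (no normalization)."""
    return ncf(radial_psd(compute_psd2d(image, allow_any_shape=allow_any_shape)))


def ncf_per_channel(image: StandardizedImage) -> dict[str, NCFResult]:
    """NCF of each present channel, independently.

    Channels are min-max normalized first (the statistic is scale-invariant
    anyway; normalization keeps the stored PSD magnitudes comparable).
    """
    if not image.channels:
        raise ValueError("no channels present")
    out: dict[str, NCFResult] = {}
    for role, arr in image.channels.items():
        try:
            out[role] = ncf_image(minmax_normalize(arr))
        except ValueError as exc:
            raise ValueError(f"channel {role!r}: {exc}") from exc
    return out
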