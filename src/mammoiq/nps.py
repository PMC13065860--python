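"""Noise power spectrum (NPS) estimation and directional anisotropy.

Noise images are formed by subtracting pairs of acquisitions taken under
identical conditions; fixed-pattern structure cancels and the difference
carries twice the stochastic noise variance.  The 2-D NPS of an ROI is

    NPS(fx, fy) = (1/2) * (dx * dy) / (Nx * Ny) * < |DFT2{ROI_n - mean}|^2 >

averaged over noise images, with the 1/2 compensating the variance doubling
of the subtraction.  Units: ADU^2 * mm^2; frequency axes in cycles/mm span
+-Nyquist = 1/(2*pitch) with step 1/(N*pitch).

1-D summaries: a radial profile (annular average over |f|, DC excluded) and
axial profiles along fx ("x", horizontal) and fy ("y", vertical) taken from
frequency lines adjacent to — not on — the axes, per standard detector-NPS
practice, since the on-axis lines carry any residual row/column pattern.
Anisotropy is quantified by the per-bin ratios NPS_x/NPS_r and NPS_y/NPS_r;
a two-sided Wilcoxon signed-rank test on the log-ratios across frequency
bins tests whether a direction systematically deviates from the radial
average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .imgio import ImageStack, RoiSpec, centered_roi

__all__ = [
    "NoiseImageSet",
    "Nps2D",
    "Nps1D",
    "make_noise_images",
    "compute_nps2d",
    "nps_total_variance",
    "radial_profile",
    "axis_profile",
    "anisotropy_ratios",
    "anisotropy_test",
]

#: subtraction of two same-condition images doubles the noise variance
VARIANCE_SCALE = 0.5


@dataclass
class NoiseImageSet:
    """Differences of same-condition acquisitions, m x H x W."""

    noise_images: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    variance_scale: float = VARIANCE_SCALE
    scheme: str = "circular"


@dataclass
class Nps2D:
    """2-D noise power spectrum on a centered (fftshifted) frequency grid.

    ``values[i, j]`` is the NPS at vertical frequency ``fy[i]`` and
    horizontal frequency ``fx[j]`` (cycles/mm), in ADU^2 mm^2.
    """

    values: np.ndarray
    fx: np.ndarray
    fy: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    n_noise_images: int

    @property
    def nyquist(self) -> tuple[float, float]:
        """(fy_nyquist, fx_nyquist) in cycles/mm."""
        dr, dc = self.pixel_spacing_mm
        return 1.0 / (2.0 * dr), 1.0 / (2.0 * dc)


@dataclass
class Nps1D:
    """1-D NPS profile: bin-center frequencies, values, and sample counts."""

    freq: np.ndarray
    values: np.ndarray
    direction: Literal["radial", "x", "y"]
    counts: np.ndarray


def make_noise_images(stack: ImageStack, scheme: str = "circular") -> NoiseImageSet:
    """Build subtraction noise images from repeated acquisitions.

    scheme="circular": noise image k = image k - image (k+1 mod n), giving n
    noise images from n acquisitions (consecutive pairs reuse acquisitions,
    so realizations are correlated but the mean NPS is unbiased).
    scheme="independent": disjoint pairs (0-1, 2-3, ...), n//2 images, fully
    independent — preferred for variance-sensitive estimates.
    """
    n = stack.n_images
    if n < 2:
        raise ValueError("need at least 2 acquisitions to form noise images")
    px = stack.pixels
    if scheme == "circular":
        noise = px - np.roll(px, -1, axis=0)
    elif scheme == "independent":
        m = n // 2
        noise = px[0: 2 * m: 2] - px[1: 2 * m: 2]
    else:
        raise ValueError(f"unknown pairing scheme: {scheme!r}")
    return NoiseImageSet(noise, stack.pixel_spacing_mm, scheme=scheme)


def compute_nps2d(noise: NoiseImageSet, roi: RoiSpec | None = None) -> Nps2D:
    """Mean periodogram of the (mean-subtracted) noise ROIs, scaled to NPS.

    Each noise image is cropped to ``roi`` (default: centered 128x128), its
    ROI mean subtracted, 2-D DFT taken, squared modulus scaled by
    dx*dy/(Nx*Ny); the average over noise images is halved to undo the
    subtraction's variance doubling.  No apodization window is applied:
    difference images carry no fixed-pattern gradient by construction.
    """
    imgs = np.asarray(noise.noise_images, dtype=np.float64)
    if imgs.ndim != 3 or imgs.shape[0] == 0:
        raise ValueError("empty noise image set")
    H, W = imgs.shape[1:]
    if roi is None:
        roi = centered_roi((H, W), min(128, H), min(128, W))
    roi.validate_within((H, W))
    sub = imgs[
        :,
        roi.origin_row: roi.origin_row + roi.height,
        roi.origin_col: roi.origin_col + roi.width,
    ]
    sub = sub - sub.mean(axis=(1, 2), keepdims=True)
    dr, dc = noise.pixel_spacing_mm
    ny, nx = sub.shape[1:]
    spec = np.abs(np.fft.fft2(sub, axes=(1, 2))) ** 2
    nps = spec.mean(axis=0) * (dr * dc) / (ny * nx) * noise.variance_scale
    nps = np.fft.fftshift(nps)
    fy = np.fft.fftshift(np.fft.fftfreq(ny, d=dr))
    fx = np.fft.fftshift(np.fft.fftfreq(nx, d=dc))
    return Nps2D(nps, fx, fy, noise.pixel_spacing_mm, n_noise_images=imgs.shape[0])


def nps_total_variance(nps: Nps2D) -> float:
    """Integrate the 2-D NPS over frequency: estimates the per-acquisition
    pixel noise variance (ADU^2) within the ROI (Parseval)."""
    dr, dc = nps.pixel_spacing_mm
    ny, nx = nps.values.shape
    dfy = 1.0 / (ny * dr)
    dfx = 1.0 / (nx * dc)
    return float(nps.values.sum() * dfx * dfy)


def radial_profile(nps: Nps2D, bin_width: float | None = None) -> Nps1D:
    """Annular average of the 2-D NPS over |f| = sqrt(fx^2 + fy^2).

    DC is excluded; bins past the smaller axial Nyquist are discarded (the
    corners of the frequency square sample |f| anisotropically).
    """
    FX, FY = np.meshgrid(nps.fx, nps.fy)
    fr = np.hypot(FX, FY)
    if bin_width is None:
        dr, dc = nps.pixel_spacing_mm
        ny, nx = nps.values.shape
        bin_width = max(1.0 / (ny * dr), 1.0 / (nx * dc))
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    fmax = min(nps.nyquist)
    mask = (fr > 0) & (fr <= fmax + bin_width / 2)
    idx = np.round(fr[mask] / bin_width).astype(int)
    vals = nps.values[mask]
    nbins = idx.max() + 1
    sums = np.bincount(idx, weights=vals, minlength=nbins)
    counts = np.bincount(idx, minlength=nbins)
    keep = counts > 0
    freq = np.arange(nbins)[keep] * bin_width
    inside = freq <= fmax
    return Nps1D(freq[inside], (sums[keep] / counts[keep])[inside], "radial",
                 counts[keep][inside])


def axis_profile(
    nps: Nps2D,
    direction: Literal["x", "y"],
    band_halfwidth: int = 3,
    exclude_axis: bool = True,
) -> Nps1D:
    """Average the ``band_halfwidth`` frequency lines adjacent to an axis.

    For direction "x" the profile runs along fx, averaging rows with
    ``0 < |fy| <= band_halfwidth`` frequency steps (the fy = 0 row itself is
    excluded by default).  Positive and negative frequencies are folded.
    """
    if direction == "x":
        values = nps.values
        f_along, f_across = nps.fx, nps.fy
    elif direction == "y":
        values = nps.values.T
        f_along, f_across = nps.fy, nps.fx
    else:
        raise ValueError(f"direction must be 'x' or 'y', got {direction!r}")
    n_across = len(f_across)
    zero_i = int(np.argmin(np.abs(f_across)))
    lo = 0 if not exclude_axis else 1
    offsets = [o for o in range(-band_halfwidth, band_halfwidth + 1)
               if abs(o) >= lo]
    rows = [zero_i + o for o in offsets if 0 <= zero_i + o < n_across]
    if not rows:
        raise ValueError("empty frequency band (halfwidth too small or exceeds grid)")
    if max(abs(o) for o in offsets) > n_across // 2:
        raise ValueError("band exceeds frequency grid")
    band = values[rows, :].mean(axis=0)
    # fold +-f_along
    pos = f_along > 0
    freq = f_along[pos]
    folded = np.empty_like(freq)
    counts = np.zeros(freq.shape, dtype=int)
    for i, f in enumerate(freq):
        sel = np.isclose(np.abs(f_along), f)
        folded[i] = band[sel].mean()
        counts[i] = sel.sum() * len(rows)
    order = np.argsort(freq)
    return Nps1D(freq[order], folded[order], direction, counts[order])


def anisotropy_ratios(axis: Nps1D, radial: Nps1D) -> Nps1D:
    """Per-bin ratio of an axial profile to the radial profile.

    The radial profile is linearly interpolated onto the axial frequency
    bins; bins outside the radial range are dropped.
    """
    lo, hi = radial.freq[0], radial.freq[-1]
    keep = (axis.freq >= lo) & (axis.freq <= hi)
    if not keep.any():
        raise ValueError("no overlapping frequency bins")
    f = axis.freq[keep]
    r = np.interp(f, radial.freq, radial.values)
    if (r <= 0).any():
        raise ValueError("non-positive radial NPS in a shared bin")
    return Nps1D(f, axis.values[keep] / r, axis.direction, axis.counts[keep])


def anisotropy_test(ratios: Nps1D) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of log(ratio) against 0.

    Tests whether the axial NPS systematically exceeds or falls below the
    radial average across frequency bins.  Returns (statistic, p).
    """
    x = np.log(np.asarray(ratios.values, dtype=np.float64))
    if x.size < 5:
        raise ValueError("need at least 5 frequency bins")
    if np.all(x == 0):
        raise ValueError("degenerate: all ratios exactly 1")
    res = stats.wilcoxon(x, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
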