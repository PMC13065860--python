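"""Contrast-to-noise ratio of mass inserts with a local masked background.

CNR = (mean(signal) - mean(background)) / SD(background), where the
background is the remainder of the same local ROI after the mass pixels are
masked out.  Using the surrounding pixels of the *same* ROI (rather than a
separate background region) avoids bias from spatially varying gain, and
the mask is dilated slightly beyond the nominal disk so that
edge-enhancement halos around the mass do not contaminate the background
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["MassRoi", "CnrResult", "segment_mass", "compute_cnr"]

#: default ACR-phantom tumor-mimicking mass diameters, mm
ACR_MASS_DIAMETERS_MM = (20.0, 10.0, 7.5, 5.0)

#: mask dilation factor over the nominal radius (excludes halo pixels)
MASK_SAFETY_FACTOR = 1.2


@dataclass
class MassRoi:
    """Local ROI containing one mass plus its mask (True = mass pixel)."""

    image: np.ndarray
    mass_mask: np.ndarray
    nominal_diameter_mm: float = 0.0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mass_mask = np.asarray(self.mass_mask, dtype=bool)
        if self.image.shape != self.mass_mask.shape:
            raise ValueError("mask shape must match image shape")
        if not self.mass_mask.any() or self.mass_mask.all():
            raise ValueError("mask must be neither empty nor full")


@dataclass
class CnrResult:
    pv_signal: float
    pv_background: float
    sigma_background: float
    cnr: float


class CentroidUnstableError(ValueError):
    """Raised when no mass blob is distinguishable from the noise."""


def segment_mass(
    image: np.ndarray,
    nominal_diameter_mm: float,
    spacing_mm: float,
    method: str = "geometric",
    safety_factor: float = MASK_SAFETY_FACTOR,
) -> np.ndarray:
    """Locate the mass and return a boolean mask of its (dilated) footprint.

    method="geometric" (default): smooth with a Gaussian of 1/4 the mass
    radius, find the extremum blob's intensity-weighted centroid, and mask
    a disk of the nominal diameter scaled by ``safety_factor``.  The
    extremum polarity (bright or dark mass) is auto-detected.

    method="otsu": Otsu threshold on the smoothed image; the mask is the
    connected component at the detected extremum, dilated by the same
    safety margin.  Suited to irregular objects.
    """
    image = np.asarray(image, dtype=np.float64)
    radius_px = nominal_diameter_mm / 2.0 / spacing_mm
    if 2 * radius_px >= min(image.shape):
        raise ValueError("nominal mass does not fit in the ROI")
    smoothed = ndimage.gaussian_filter(image, sigma=max(radius_px / 4.0, 0.5))
    dev = smoothed - np.median(smoothed)
    absdev = np.abs(dev)
    peak = float(absdev.max())
    noise = float(np.median(absdev)) / 0.6745  # MAD -> SD under normality
    if peak <= 4.0 * max(noise, np.finfo(float).tiny) or peak == 0.0:
        raise CentroidUnstableError(
            "no mass blob distinguishable from background noise"
        )
    if method == "otsu":
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(absdev)
        blob = absdev >= thr
    elif method == "geometric":
        blob = absdev >= 0.5 * peak
    else:
        raise ValueError(f"unknown segmentation method: {method!r}")
    # centroid of the blob containing the global extremum, weighted by |dev|
    labels, _ = ndimage.label(blob)
    peak_label = labels[np.unravel_index(np.argmax(absdev), absdev.shape)]
    core = labels == peak_label
    r0, c0 = ndimage.center_of_mass(absdev * core)
    rr, cc = np.ogrid[: image.shape[0], : image.shape[1]]
    if method == "otsu":
        grow = int(round((safety_factor - 1.0) * radius_px))
        mask = ndimage.binary_dilation(core, iterations=max(grow, 1))
    else:
        mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= (safety_factor * radius_px) ** 2
    return mask


def compute_cnr(roi: MassRoi) -> CnrResult:
    """CNR from a masked mass ROI.

    Signal mean over mask-true pixels; background mean and sample SD
    (ddof=1) over mask-false pixels of the same ROI.
    """
    sig = roi.image[roi.mass_mask]
    bkg = roi.image[~roi.mass_mask]
    if sig.size == 0 or bkg.size < 2:
        raise ValueError("both mask partitions must be non-empty")
    sigma = float(bkg.std(ddof=1))
    if sigma == 0.0:
        raise ValueError("background SD is zero; CNR undefined")
    pv_s = float(sig.mean())
    pv_b = float(bkg.mean())
    return CnrResult(pv_s, pv_b, sigma, (pv_s - pv_b) / sigma)
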