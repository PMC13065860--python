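"""Contrast-detail scoring on a CDMAM-style gold-disk grid.

The phantom is a 16 x 16 grid of cells: rows index gold-disk thickness
(contrast), columns index disk diameter.  Every cell holds a disk at its
center and an identical *eccentric* disk in one of the four cell corners;
the scoring task is to identify which corner — a four-alternative
forced-choice (4-AFC) task with a 25% guess rate.

The observer implemented here is a transparent template-matching (matched
filter) reader: it cross-correlates a disk template of the cell's diameter,
blurred by the configured system PSF, at the four candidate corner
positions after local background subtraction, and picks the argmax.  Ties
break to the lowest corner index, deterministically.

From per-cell detection fractions over repeated presentations:

* the contrast-detail (CD) curve — threshold gold thickness vs diameter at
  a detection probability of 62.5% (the midpoint between the 25% guess
  floor and 100%), via a psychometric fit in log-thickness;
* the threshold diameter per thickness row — the smallest diameter
  detected in at least 62.5% of presentations (discrete rule);
* the inverse image-quality figure

      IQFinv = 100 / sum_{i=1..16} C_i * D_{i,min}

  with C_i the row's gold thickness (um) and D_{i,min} its threshold
  diameter (mm).  Smaller detectable thickness/diameter products mean a
  larger IQFinv, i.e. better contrast-detail performance.

Absolute IQFinv values depend on the observer; values from this module are
comparable across configurations scored by the same observer, not across
different readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import ndimage, optimize

from .imgio import ImageStack

__all__ = [
    "CdmamGeometry",
    "DetectionMatrix",
    "CdThresholds",
    "disk_template",
    "score_cell",
    "build_detection_matrix",
    "threshold_thickness",
    "threshold_diameter",
    "cd_curve",
    "compute_iqf_inv",
    "GUESS_RATE",
    "DEFAULT_LEVEL",
]

GUESS_RATE = 0.25  # 4-AFC chance level
DEFAULT_LEVEL = 0.625  # midpoint of (guess rate, 1)

N_DIAMETERS = 16
N_THICKNESSES = 16


def _geometric_series(lo: float, hi: float, n: int) -> np.ndarray:
    return np.geomspace(lo, hi, n)


@dataclass
class CdmamGeometry:
    """Grid geometry: which disk lives where, in pixels.

    Rows of the grid are thickness levels (increasing downward), columns
    are diameters (increasing rightward).  ``cell_centers[i, j]`` is the
    (row, col) pixel center of cell (thickness i, diameter j);
    ``corner_offset_px`` is the magnitude of the eccentric disk's
    displacement from the cell center along both axes.  Corner indices:
    0 = top-left, 1 = top-right, 2 = bottom-left, 3 = bottom-right.
    """

    diameters_mm: np.ndarray
    thicknesses_um: np.ndarray
    cell_centers: np.ndarray  # (16, 16, 2) float, (row, col) px
    corner_offset_px: float
    cell_size_px: int
    pixel_spacing_mm: float

    CORNER_SIGNS = ((-1, -1), (-1, 1), (1, -1), (1, 1))

    def __post_init__(self) -> None:
        self.diameters_mm = np.asarray(self.diameters_mm, dtype=np.float64)
        self.thicknesses_um = np.asarray(self.thicknesses_um, dtype=np.float64)
        if len(self.diameters_mm) != N_DIAMETERS:
            raise ValueError(f"expected {N_DIAMETERS} diameters")
        if len(self.thicknesses_um) != N_THICKNESSES:
            raise ValueError(f"expected {N_THICKNESSES} thicknesses")
        if np.any(np.diff(self.diameters_mm) <= 0) or np.any(
            np.diff(self.thicknesses_um) <= 0
        ):
            raise ValueError("diameters and thicknesses must be increasing")

    @classmethod
    def regular(
        cls,
        cell_size_px: int = 64,
        pixel_spacing_mm: float = 0.05,
        diameters_mm: np.ndarray | None = None,
        thicknesses_um: np.ndarray | None = None,
        origin_px: tuple[float, float] = (0.0, 0.0),
    ) -> "CdmamGeometry":
        """Regular grid with cells tiling a (16*cell)^2 region.

        Default diameter and thickness ladders span 0.06-2.0 mm and
        0.03-2.0 um geometrically, the conventional contrast-detail
        ranges for this phantom class.
        """
        if diameters_mm is None:
            diameters_mm = _geometric_series(0.06, 2.0, N_DIAMETERS)
        if thicknesses_um is None:
            thicknesses_um = _geometric_series(0.03, 2.0, N_THICKNESSES)
        centers = np.empty((N_THICKNESSES, N_DIAMETERS, 2))
        for i in range(N_THICKNESSES):
            for j in range(N_DIAMETERS):
                centers[i, j] = (
                    origin_px[0] + (i + 0.5) * cell_size_px,
                    origin_px[1] + (j + 0.5) * cell_size_px,
                )
        max_d_px = np.max(diameters_mm) / pixel_spacing_mm
        offset = cell_size_px / 4.0
        if offset + max_d_px / 2.0 > cell_size_px / 2.0:
            raise ValueError(
                "largest disk does not fit beside the corner position; "
                "increase cell_size_px"
            )
        return cls(
            diameters_mm=np.asarray(diameters_mm),
            thicknesses_um=np.asarray(thicknesses_um),
            cell_centers=centers,
            corner_offset_px=offset,
            cell_size_px=cell_size_px,
            pixel_spacing_mm=pixel_spacing_mm,
        )

    def corner_positions(self, i: int, j: int) -> np.ndarray:
        """(4, 2) array of corner-disk center positions for cell (i, j)."""
        c = self.cell_centers[i, j]
        o = self.corner_offset_px
        return np.array([(c[0] + sr * o, c[1] + sc * o)
                         for sr, sc in self.CORNER_SIGNS])


@dataclass
class DetectionMatrix:
    """Correct-corner counts per (thickness, diameter) cell."""

    n_correct: np.ndarray  # (16, 16) int
    n_presented: np.ndarray  # (16, 16) int

    def __post_init__(self) -> None:
        self.n_correct = np.asarray(self.n_correct, dtype=int)
        self.n_presented = np.asarray(self.n_presented, dtype=int)
        if self.n_correct.shape != self.n_presented.shape:
            raise ValueError("matrix shapes differ")
        if np.any(self.n_correct < 0) or np.any(self.n_correct > self.n_presented):
            raise ValueError("need 0 <= n_correct <= n_presented")

    @property
    def fractions(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(
                self.n_presented > 0,
                self.n_correct / np.maximum(self.n_presented, 1),
                np.nan,
            )


@dataclass
class CdThresholds:
    """Detection thresholds at a given probability level.

    threshold_thickness_um[j]: CD-curve value for diameter column j (um).
    threshold_diameter_mm[i]: D_i,min for thickness row i (mm).
    Matching *_flagged arrays mark thresholds clamped at a range bound
    (nothing detected, or everything detected).
    """

    threshold_thickness_um: np.ndarray
    threshold_diameter_mm: np.ndarray
    thickness_flagged: np.ndarray
    diameter_flagged: np.ndarray
    level: float = DEFAULT_LEVEL


def template_halfwidth(diameter_mm: float, spacing_mm: float,
                       psf_sigma_mm: float, pad_px: int = 3) -> int:
    """Half-width (px) of the matched-filter window for a given disk."""
    r_px = diameter_mm / 2.0 / spacing_mm
    sigma_px = psf_sigma_mm / spacing_mm
    return int(np.ceil(r_px + 4 * sigma_px)) + pad_px


@lru_cache(maxsize=64)
def disk_template(
    diameter_mm: float,
    spacing_mm: float,
    psf_sigma_mm: float,
    pad_px: int = 3,
) -> np.ndarray:
    """Unit-amplitude disk profile blurred by a Gaussian system PSF.

    Rendered with ~pixel-area antialiasing at the rim, then blurred.  The
    same rim model generates the synthetic phantom disks, so the
    observer's template is matched to the signal it searches for.
    """
    r_px = diameter_mm / 2.0 / spacing_mm
    sigma_px = psf_sigma_mm / spacing_mm
    half = template_halfwidth(diameter_mm, spacing_mm, psf_sigma_mm, pad_px)
    ax = np.arange(-half, half + 1, dtype=np.float64)
    dist = np.hypot(ax[:, None], ax[None, :])
    profile = np.clip(r_px - dist + 0.5, 0.0, 1.0)
    if sigma_px > 0:
        profile = ndimage.gaussian_filter(profile, sigma=sigma_px,
                                          mode="constant")
    profile.setflags(write=False)
    return profile


def _corr_at(cell: np.ndarray, template: np.ndarray, center: tuple[float, float]) -> float:
    """Zero-mean template correlation at an (integer-rounded) position."""
    th, tw = template.shape
    r0 = int(round(center[0])) - th // 2
    c0 = int(round(center[1])) - tw // 2
    if r0 < 0 or c0 < 0 or r0 + th > cell.shape[0] or c0 + tw > cell.shape[1]:
        raise ValueError("template window falls outside the cell image")
    patch = cell[r0: r0 + th, c0: c0 + tw]
    t = template - template.mean()
    return float((t * (patch - patch.mean())).sum())


def score_cell(
    cell_image: np.ndarray,
    diameter_mm: float,
    spacing_mm: float,
    psf_sigma_mm: float,
    corner_centers: np.ndarray,
) -> int:
    """4-AFC decision: which of the four corner positions holds the disk.

    Correlates the matched disk template at each candidate position after
    local background (mean) subtraction; returns the argmax corner index,
    breaking exact ties toward the lowest index.
    """
    cell_image = np.asarray(cell_image, dtype=np.float64)
    template = disk_template(diameter_mm, spacing_mm, psf_sigma_mm)
    if template.shape[0] > min(cell_image.shape):
        raise ValueError("template larger than cell image")
    scores = [_corr_at(cell_image, template, tuple(c)) for c in corner_centers]
    return int(np.argmax(scores))  # argmax takes the first (lowest) maximum


def build_detection_matrix(
    stack: ImageStack,
    geometry: CdmamGeometry,
    truth: np.ndarray,
    psf_sigma_mm: float,
    jitter_px: np.ndarray | None = None,
) -> DetectionMatrix:
    """Score every cell of every image against the known corner truth.

    ``truth[k, i, j]`` is the true corner index of cell (i, j) in image k;
    ``jitter_px[k]`` is the known (row, col) translation of the whole grid
    in image k (the phantom shifts slightly between acquisitions; the grid
    is registered to these configured offsets, not re-estimated).
    """
    n = stack.n_images
    truth = np.asarray(truth)
    if truth.shape != (n, N_THICKNESSES, N_DIAMETERS):
        raise ValueError(
            f"truth shape {truth.shape} != ({n}, {N_THICKNESSES}, {N_DIAMETERS})"
        )
    if jitter_px is None:
        jitter_px = np.zeros((n, 2))
    spacing = geometry.pixel_spacing_mm
    half_cell = geometry.cell_size_px // 2
    # the correlation window of large disks can exceed the nominal cell;
    # extract each cell with whatever extra margin its template needs
    margins = [
        max(0, template_halfwidth(d, spacing, psf_sigma_mm)
            + int(np.ceil(geometry.corner_offset_px)) + 1 - half_cell)
        for d in geometry.diameters_mm
    ]
    n_correct = np.zeros((N_THICKNESSES, N_DIAMETERS), dtype=int)
    for k in range(n):
        img = stack.pixels[k]
        dy, dx = jitter_px[k]
        for i in range(N_THICKNESSES):
            for j in range(N_DIAMETERS):
                half = half_cell + margins[j]
                cr, cc = geometry.cell_centers[i, j]
                r0 = int(round(cr + dy)) - half
                c0 = int(round(cc + dx)) - half
                if r0 < 0 or c0 < 0 or r0 + 2 * half > img.shape[0] \
                        or c0 + 2 * half > img.shape[1]:
                    raise ValueError(
                        f"cell ({i},{j}) window falls outside the image; "
                        "the stack's grid padding is too small"
                    )
                cell = img[r0: r0 + 2 * half, c0: c0 + 2 * half]
                corners = geometry.corner_positions(i, j) + [dy, dx] - [r0, c0]
                choice = score_cell(
                    cell, geometry.diameters_mm[j], spacing, psf_sigma_mm,
                    corners,
                )
                if choice == truth[k, i, j]:
                    n_correct[i, j] += 1
    return DetectionMatrix(n_correct, np.full((N_THICKNESSES, N_DIAMETERS), n))


def _psychometric(log_t: np.ndarray, k: float, mu: float) -> np.ndarray:
    return GUESS_RATE + (1 - GUESS_RATE) / (1 + np.exp(-k * (log_t - mu)))


def threshold_thickness(
    fractions: np.ndarray,
    thicknesses_um: np.ndarray,
    level: float = DEFAULT_LEVEL,
) -> tuple[float, bool]:
    """Threshold gold thickness (um) at the given detection level, for one
    diameter column.

    Fits p(t) = 0.25 + 0.75 / (1 + exp(-k (ln t - mu))) by least squares;
    at the 62.5% midpoint the threshold is exactly exp(mu).  Falls back to
    monotone linear interpolation in ln t when the fit fails.  Returns
    (threshold, flagged); flagged thresholds are clamped at a range bound
    because the data never (or always) cross the level.
    """
    f = np.asarray(fractions, dtype=np.float64)
    t = np.asarray(thicknesses_um, dtype=np.float64)
    if f.shape != t.shape or f.size < 2:
        raise ValueError("fractions and thicknesses must align, size >= 2")
    if not (GUESS_RATE < level < 1):
        raise ValueError(f"level must be in ({GUESS_RATE}, 1)")
    log_t = np.log(t)
    if f.max() < level:
        return float(t[-1]), True
    if f.min() >= level:
        return float(t[0]), True
    try:
        k0 = 2.0
        mu0 = float(np.interp(level, np.clip(f, 0, 1), log_t))
        popt, _ = optimize.curve_fit(
            _psychometric, log_t, f, p0=[k0, mu0],
            bounds=([1e-3, log_t.min() - 5], [1e3, log_t.max() + 5]),
            maxfev=10000,
        )
        k, mu = popt
        # solve p = level analytically
        arg = (1 - GUESS_RATE) / (level - GUESS_RATE) - 1.0
        thr = float(np.exp(mu - np.log(arg) / k))
        if t[0] <= thr <= t[-1]:
            return thr, False
    except RuntimeError:
        pass
    # fallback: first upward crossing, linear in ln t
    above = np.nonzero(f >= level)[0]
    j = above[0]
    if j == 0:
        return float(t[0]), True
    lt = log_t[j - 1] + (level - f[j - 1]) * (log_t[j] - log_t[j - 1]) / (
        f[j] - f[j - 1]
    )
    return float(np.exp(lt)), False


def threshold_diameter(
    fractions: np.ndarray,
    diameters_mm: np.ndarray,
    level: float = DEFAULT_LEVEL,
) -> tuple[float, bool]:
    """D_min for one thickness row: the smallest diameter whose detection
    fraction reaches the level (discrete rule).

    If no diameter qualifies, the largest diameter is returned flagged as
    undetected.
    """
    f = np.asarray(fractions, dtype=np.float64)
    d = np.asarray(diameters_mm, dtype=np.float64)
    if f.size == 0 or f.shape != d.shape:
        raise ValueError("fractions and diameters must align and be non-empty")
    qualifying = np.nonzero(f >= level)[0]
    if qualifying.size == 0:
        return float(d[-1]), True
    return float(d[qualifying[0]]), False


def cd_curve(
    matrix: DetectionMatrix,
    geometry: CdmamGeometry,
    level: float = DEFAULT_LEVEL,
) -> CdThresholds:
    """CD curve and per-row threshold diameters from a detection matrix."""
    frac = matrix.fractions
    thr_t = np.empty(N_DIAMETERS)
    fl_t = np.zeros(N_DIAMETERS, dtype=bool)
    for j in range(N_DIAMETERS):
        thr_t[j], fl_t[j] = threshold_thickness(
            frac[:, j], geometry.thicknesses_um, level
        )
    thr_d = np.empty(N_THICKNESSES)
    fl_d = np.zeros(N_THICKNESSES, dtype=bool)
    for i in range(N_THICKNESSES):
        thr_d[i], fl_d[i] = threshold_diameter(
            frac[i, :], geometry.diameters_mm, level
        )
    return CdThresholds(thr_t, thr_d, fl_t, fl_d, level)


def compute_iqf_inv(
    thicknesses_um: np.ndarray,
    threshold_diameters_mm: np.ndarray,
) -> float:
    """IQFinv = 100 / sum_i C_i * D_i,min (C_i in um, D in mm; unitless by
    convention)."""
    c = np.asarray(thicknesses_um, dtype=np.float64)
    d = np.asarray(threshold_diameters_mm, dtype=np.float64)
    if c.shape != d.shape or c.size != N_THICKNESSES:
        raise ValueError(f"need {N_THICKNESSES} aligned thickness/diameter pairs")
    if np.any(c <= 0) or np.any(d <= 0):
        raise ValueError("thicknesses and diameters must be positive")
    return float(100.0 / np.sum(c * d))
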