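"""Synthetic phantom-image generators with known ground truth.

Each generator emulates the statistical structure one of the analysis
modules assumes, so the whole pipeline is testable without any acquired
data:

* flat-field stacks — spatially varying gain (a low-order polynomial field)
  times a mean level, plus white or anisotropically colored Gaussian noise
  (optionally signal-dependent, scaling with sqrt(gain));
* slanted-edge stacks — an error-function edge of known angle and PSF
  width sampled at pixel centers, so the closed-form f50 of the Gaussian
  MTF is an exact ground truth;
* mass images — a blurred disk of known contrast on a noisy background,
  with the analytic CNR (contrast / noise SD) as truth in the no-blur
  limit;
* contrast-detail stacks — the full 16 x 16 disk grid, one eccentric disk
  per cell at a random corner, per-image integer-pixel grid jitter, with
  the corner truth recorded.

Noise is additive Gaussian throughout — deliberately not a cascaded
detector model; it is sufficient to exercise every metric's contract and
the relative orderings between acquisition modes.  Colored noise is made
by convolving white noise with an anisotropic Gaussian kernel and
rescaling to the target marginal SD, so anisotropy tests isolate spectral
shape from total power.

Two presets bundle the generator parameters used for cross-metric
comparisons: ``DM`` (0.05 mm pitch, sharp PSF, white noise, flat gain)
mimics a direct conversion detector; ``SM`` (0.10 mm pitch, doubled PSF,
noise colored along x and 1.7x stronger, a 10% gain gradient) mimics the
reconstruction-induced blur, noise amplification and shading of a
synthesized 2-D view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from .cdmam import CdmamGeometry, N_DIAMETERS, N_THICKNESSES
from .imgio import ImageStack

__all__ = [
    "FlatFieldConfig",
    "EdgePhantomConfig",
    "MassPhantomConfig",
    "CdmamStackConfig",
    "gen_flat_stack",
    "gen_edge_stack",
    "gen_mass_image",
    "gen_cdmam_stack",
    "render_disk",
    "dm_preset",
    "sm_preset",
    "Preset",
]


# --------------------------------------------------------------------------
# configs

@dataclass
class FlatFieldConfig:
    shape_px: tuple[int, int] = (400, 400)
    spacing_mm: float = 0.05
    mean_adu: float = 1000.0
    gain_poly: np.ndarray | None = None  # 2-D coeff matrix for polyval2d-style gain
    noise_sd_adu: float = 10.0
    color_sigma_mm: tuple[float, float] | None = None  # (row, col) smoothing lengths
    noise_tracks_gain: bool = False  # noise SD scales with sqrt(gain)
    n_images: int = 10
    seed: int = 0
    label: str = ""


@dataclass
class EdgePhantomConfig:
    shape_px: tuple[int, int] = (256, 256)
    spacing_mm: float = 0.05
    angle_deg: float = 1.0  # tilt of the edge from the column axis
    psf_sigma_mm: float = 0.10
    edge_contrast_adu: float = 500.0
    background_adu: float = 500.0
    noise_sd_adu: float = 0.0
    n_images: int = 1
    seed: int = 0
    label: str = ""


@dataclass
class MassPhantomConfig:
    shape_px: tuple[int, int] = (300, 300)
    spacing_mm: float = 0.05
    diameter_mm: float = 5.0
    contrast_adu: float = 20.0
    blur_sigma_mm: float = 0.0
    background_adu: float = 1000.0
    noise_sd_adu: float = 10.0
    seed: int = 0


@dataclass
class CdmamStackConfig:
    geometry: CdmamGeometry
    contrast_per_um: float = 30.0  # disk amplitude per um of gold, ADU/um
    psf_sigma_mm: float = 0.08
    background_adu: float = 1000.0
    noise_sd_adu: float = 15.0
    color_sigma_mm: tuple[float, float] | None = None
    jitter_px: int = 2  # max |integer shift| of the grid per image
    n_images: int = 10
    seed: int = 0
    label: str = ""


# --------------------------------------------------------------------------
# noise helper

def _noise_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    sd: float,
    color_sigma_px: tuple[float, float] | None,
) -> np.ndarray:
    """White or colored Gaussian noise with the requested marginal SD."""
    w = rng.standard_normal(shape)
    if color_sigma_px is not None and max(color_sigma_px) > 0:
        w = ndimage.gaussian_filter(w, sigma=color_sigma_px, mode="wrap")
        w /= w.std()  # convolution shrinks the marginal SD; restore it
    return sd * w


# --------------------------------------------------------------------------
# generators

def gen_flat_stack(cfg: FlatFieldConfig) -> tuple[ImageStack, dict]:
    """Repeated flat-field acquisitions: mean * gain(x, y) + noise."""
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.shape_px
    if cfg.mean_adu <= 0:
        raise ValueError("mean_adu must be positive")
    y = np.linspace(-1, 1, rows)[:, None]
    x = np.linspace(-1, 1, cols)[None, :]
    if cfg.gain_poly is None:
        gain = np.ones((rows, cols))
    else:
        coeffs = np.asarray(cfg.gain_poly, dtype=np.float64)
        gain = np.polynomial.polynomial.polyval2d(
            np.broadcast_to(y, (rows, cols)),
            np.broadcast_to(x, (rows, cols)),
            coeffs,
        )
    if np.any(gain <= 0):
        raise ValueError("gain field must be positive everywhere")
    signal = cfg.mean_adu * gain
    color_px = None
    if cfg.color_sigma_mm is not None:
        color_px = (cfg.color_sigma_mm[0] / cfg.spacing_mm,
                    cfg.color_sigma_mm[1] / cfg.spacing_mm)
    frames = np.empty((cfg.n_images, rows, cols))
    for k in range(cfg.n_images):
        noise = _noise_field(rng, (rows, cols), cfg.noise_sd_adu, color_px)
        if cfg.noise_tracks_gain:
            noise = noise * np.sqrt(gain)
        frames[k] = signal + noise
    stack = ImageStack(frames, (cfg.spacing_mm, cfg.spacing_mm), label=cfg.label)
    truth = {"gain_map": gain, "noise_sd_adu": cfg.noise_sd_adu,
             "mean_adu": cfg.mean_adu}
    return stack, truth


def _edge_field(
    shape: tuple[int, int],
    spacing_mm: float,
    angle_deg: float,
    psf_sigma_mm: float,
    background: float,
    contrast: float,
) -> np.ndarray:
    """Continuous erf edge sampled at pixel centers.

    The edge line passes through the image center, tilted ``angle_deg``
    from the column (vertical) axis; pixel value = background +
    contrast * Phi(d / psf_sigma) with d the signed perpendicular distance
    (mm) and Phi the standard normal CDF.  Sampling the continuous model at
    pixel centers keeps the ESF exactly erf with spread psf_sigma, so the
    Gaussian-MTF closed forms hold exactly.
    """
    from scipy.special import ndtr

    rows, cols = shape
    rr = (np.arange(rows) - (rows - 1) / 2.0)[:, None]
    cc = (np.arange(cols) - (cols - 1) / 2.0)[None, :]
    t = np.tan(np.radians(angle_deg))
    # edge column at row r is  center + t*r; distance along the row axis,
    # projected perpendicular to the edge
    d_px = (cc - t * rr) * np.cos(np.radians(angle_deg))
    d_mm = d_px * spacing_mm
    return background + contrast * ndtr(d_mm / psf_sigma_mm)


def gen_edge_stack(cfg: EdgePhantomConfig) -> tuple[ImageStack, dict]:
    """Repeated slanted-edge acquisitions with analytic MTF ground truth."""
    if cfg.psf_sigma_mm <= 0:
        raise ValueError("psf_sigma_mm must be positive")
    if cfg.angle_deg == 0 and cfg.noise_sd_adu == 0:
        import warnings

        warnings.warn("axis-aligned edge carries no subpixel phase information",
                      stacklevel=2)
    rng = np.random.default_rng(cfg.seed)
    clean = _edge_field(cfg.shape_px, cfg.spacing_mm, cfg.angle_deg,
                        cfg.psf_sigma_mm, cfg.background_adu,
                        cfg.edge_contrast_adu)
    frames = np.empty((cfg.n_images,) + cfg.shape_px)
    for k in range(cfg.n_images):
        frames[k] = clean + cfg.noise_sd_adu * rng.standard_normal(cfg.shape_px)
    stack = ImageStack(frames, (cfg.spacing_mm, cfg.spacing_mm), label=cfg.label)
    sigma = cfg.psf_sigma_mm
    truth = {
        "angle_deg": cfg.angle_deg,
        "psf_sigma_mm": sigma,
        "f50": float(np.sqrt(np.log(2.0) / (2.0 * np.pi**2 * sigma**2))),
        "f10": float(np.sqrt(np.log(10.0) / (2.0 * np.pi**2 * sigma**2))),
    }
    return stack, truth


def render_disk(
    shape: tuple[int, int],
    center_px: tuple[float, float],
    diameter_mm: float,
    spacing_mm: float,
    amplitude: float,
) -> np.ndarray:
    """Disk of given amplitude with pixel-area antialiasing at the rim.

    The same rim model backs :func:`mammoiq.cdmam.disk_template`, so the
    4-AFC observer's matched filter matches the rendered signal.
    """
    rows, cols = shape
    r_px = diameter_mm / 2.0 / spacing_mm
    rr = np.arange(rows)[:, None] - center_px[0]
    cc = np.arange(cols)[None, :] - center_px[1]
    dist = np.hypot(rr, cc)
    return amplitude * np.clip(r_px - dist + 0.5, 0.0, 1.0)


def _add_disk(
    scene: np.ndarray,
    center_px: tuple[float, float],
    diameter_mm: float,
    spacing_mm: float,
    amplitude: float,
) -> None:
    """In-place local insertion of a rendered disk (window of radius + 2 px)."""
    r_px = diameter_mm / 2.0 / spacing_mm
    half = int(np.ceil(r_px)) + 2
    r0 = int(np.floor(center_px[0])) - half
    c0 = int(np.floor(center_px[1])) - half
    r1 = r0 + 2 * half + 1
    c1 = c0 + 2 * half + 1
    r0c, c0c = max(r0, 0), max(c0, 0)
    r1c, c1c = min(r1, scene.shape[0]), min(c1, scene.shape[1])
    patch = render_disk(
        (r1c - r0c, c1c - c0c),
        (center_px[0] - r0c, center_px[1] - c0c),
        diameter_mm, spacing_mm, amplitude,
    )
    scene[r0c:r1c, c0c:c1c] += patch


def gen_mass_image(cfg: MassPhantomConfig) -> tuple[np.ndarray, dict]:
    """Single mass-insert ROI: blurred disk + background + noise."""
    rows, cols = cfg.shape_px
    if cfg.diameter_mm / cfg.spacing_mm >= min(rows, cols):
        raise ValueError("disk exceeds the field")
    rng = np.random.default_rng(cfg.seed)
    center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    img = cfg.background_adu + render_disk(
        (rows, cols), center, cfg.diameter_mm, cfg.spacing_mm, cfg.contrast_adu
    )
    if cfg.blur_sigma_mm > 0:
        img = ndimage.gaussian_filter(img, sigma=cfg.blur_sigma_mm / cfg.spacing_mm)
    if cfg.noise_sd_adu > 0:
        img = img + cfg.noise_sd_adu * rng.standard_normal((rows, cols))
    expected_cnr = (cfg.contrast_adu / cfg.noise_sd_adu
                    if cfg.noise_sd_adu > 0 else np.inf)
    truth = {
        "center_px": center,
        "contrast_adu": cfg.contrast_adu,
        "expected_cnr": expected_cnr,
    }
    return img, truth


def gen_cdmam_stack(cfg: CdmamStackConfig) -> tuple[ImageStack, dict]:
    """Contrast-detail grid stack with recorded corner truth and jitter.

    Each cell gets a center disk plus an eccentric disk at a random corner;
    the disk amplitude is thickness * contrast_per_um, the whole clean
    scene is blurred by the system PSF, the grid shifts by a per-image
    integer jitter, and noise is added last (noise must not shift with the
    phantom).
    """
    geo = cfg.geometry
    rng = np.random.default_rng(cfg.seed)
    spacing = geo.pixel_spacing_mm
    cell = geo.cell_size_px
    # margin so that jittered correlation windows of boundary cells stay
    # inside the image even for the largest disks
    pad = cell // 2 + cell // 4 + cfg.jitter_px
    rows = cols = cell * N_THICKNESSES + 2 * pad
    # center disks rendered once at zero shift, then rolled per image
    scene = np.zeros((rows, cols))
    for i in range(N_THICKNESSES):
        amp = geo.thicknesses_um[i] * cfg.contrast_per_um
        for j in range(N_DIAMETERS):
            cr, cc = geo.cell_centers[i, j] + pad
            _add_disk(scene, (cr, cc), geo.diameters_mm[j], spacing, amp)
    psf_px = cfg.psf_sigma_mm / spacing
    corner_truth = rng.integers(0, 4, size=(cfg.n_images, N_THICKNESSES,
                                            N_DIAMETERS))
    jitter = rng.integers(-cfg.jitter_px, cfg.jitter_px + 1,
                          size=(cfg.n_images, 2))
    color_px = None
    if cfg.color_sigma_mm is not None:
        color_px = (cfg.color_sigma_mm[0] / spacing,
                    cfg.color_sigma_mm[1] / spacing)
    frames = np.empty((cfg.n_images, rows, cols))
    for k in range(cfg.n_images):
        corner_scene = np.zeros((rows, cols))
        for i in range(N_THICKNESSES):
            amp = geo.thicknesses_um[i] * cfg.contrast_per_um
            for j in range(N_DIAMETERS):
                cr, cc = geo.cell_centers[i, j] + pad
                sr, sc = CdmamGeometry.CORNER_SIGNS[corner_truth[k, i, j]]
                pos = (cr + sr * geo.corner_offset_px,
                       cc + sc * geo.corner_offset_px)
                _add_disk(corner_scene, pos, geo.diameters_mm[j], spacing, amp)
        clean = cfg.background_adu + ndimage.gaussian_filter(
            scene + corner_scene, sigma=psf_px
        )
        shifted = np.roll(clean, shift=tuple(jitter[k]), axis=(0, 1))
        noise = _noise_field(rng, (rows, cols), cfg.noise_sd_adu, color_px)
        frames[k] = shifted + noise
    stack = ImageStack(frames, (spacing, spacing), label=cfg.label)
    from dataclasses import replace as _replace

    geo_in_image = _replace(geo, cell_centers=geo.cell_centers + pad)
    truth = {
        "corner_truth": corner_truth,
        "jitter_px": jitter.astype(float),
        "pad_px": pad,
        "geometry": geo_in_image,
    }
    return stack, truth


# --------------------------------------------------------------------------
# presets

@dataclass(frozen=True)
class Preset:
    """Generator parameters bundled per acquisition mode."""

    name: str
    spacing_mm: float
    psf_sigma_mm: float
    noise_sd_adu: float
    color_sigma_mm: tuple[float, float] | None
    gain_peak_to_valley: float  # relative amplitude of the gain gradient
    block_px: int

    def flat_config(self, shape_px: tuple[int, int] = (400, 400),
                    n_images: int = 10, seed: int = 0) -> FlatFieldConfig:
        if self.gain_peak_to_valley > 0:
            # linear shading plus a mild bowl, ~peak-to-valley relative swing
            a = self.gain_peak_to_valley
            poly = np.array([[1.0, a / 4], [a / 4, 0.0], [a / 8, 0.0]])
        else:
            poly = None
        return FlatFieldConfig(
            shape_px=shape_px, spacing_mm=self.spacing_mm, mean_adu=1000.0,
            gain_poly=poly, noise_sd_adu=self.noise_sd_adu,
            color_sigma_mm=self.color_sigma_mm, noise_tracks_gain=False,
            n_images=n_images, seed=seed, label=self.name,
        )

    def edge_config(self, angle_deg: float = 1.0, noise_sd_adu: float | None = None,
                    n_images: int = 10, seed: int = 0) -> EdgePhantomConfig:
        side = 256 if self.spacing_mm <= 0.075 else 128
        return EdgePhantomConfig(
            shape_px=(side, side), spacing_mm=self.spacing_mm,
            angle_deg=angle_deg, psf_sigma_mm=self.psf_sigma_mm,
            edge_contrast_adu=500.0, background_adu=500.0,
            noise_sd_adu=self.noise_sd_adu if noise_sd_adu is None else noise_sd_adu,
            n_images=n_images, seed=seed, label=self.name,
        )

    def mass_config(self, diameter_mm: float, shape_px: tuple[int, int] | None = None,
                    seed: int = 0) -> MassPhantomConfig:
        roi = 300 if self.spacing_mm <= 0.075 else 150
        return MassPhantomConfig(
            shape_px=shape_px or (roi, roi), spacing_mm=self.spacing_mm,
            diameter_mm=diameter_mm, contrast_adu=20.0,
            blur_sigma_mm=self.psf_sigma_mm, background_adu=1000.0,
            noise_sd_adu=self.noise_sd_adu, seed=seed,
        )

    def cdmam_config(self, n_images: int = 10, seed: int = 0) -> CdmamStackConfig:
        cell = int(round(4.8 / self.spacing_mm))  # 4.8 mm cells
        geo = CdmamGeometry.regular(cell_size_px=cell,
                                    pixel_spacing_mm=self.spacing_mm)
        return CdmamStackConfig(
            geometry=geo, contrast_per_um=30.0, psf_sigma_mm=self.psf_sigma_mm,
            background_adu=1000.0, noise_sd_adu=self.noise_sd_adu,
            color_sigma_mm=self.color_sigma_mm, jitter_px=2,
            n_images=n_images, seed=seed, label=self.name,
        )


def dm_preset() -> Preset:
    """Direct-detector-like acquisition: fine pitch, sharp PSF, white noise."""
    return Preset(name="DM", spacing_mm=0.05, psf_sigma_mm=0.08,
                  noise_sd_adu=15.0, color_sigma_mm=None,
                  gain_peak_to_valley=0.0, block_px=100)


def sm_preset() -> Preset:
    """Synthesized-view-like acquisition: coarse pitch, reconstruction blur,
    noise colored along x and amplified, a 10% gain gradient."""
    return Preset(name="SM", spacing_mm=0.10, psf_sigma_mm=0.17,
                  noise_sd_adu=25.5, color_sigma_mm=(0.0, 0.12),
                  gain_peak_to_valley=0.10, block_px=50)
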