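"""Image-stack I/O and region extraction.

Every metric in this package operates on an :class:`ImageStack` — a set of
repeated, co-registered 2-D acquisitions of the same phantom together with
the detector pixel pitch.  This module reads stacks from DICOM, TIFF or
``.npy`` files (one file per acquisition, with an optional JSON sidecar
carrying spacing and a label) and provides the cropping/ROI plumbing used
throughout: a physical margin crop (e.g. excluding 1 cm from each phantom
edge) and rectangular ROI extraction.

Conventions
-----------
Coordinates are 0-based, row-major ``(row, col)``; ROIs are half-open
``[origin, origin + size)``.  ``pixel_spacing_mm`` is stored as
``(row_pitch, col_pitch)`` in mm/pixel; all supported detectors have square
pixels, so the ordering only matters for consistency with array indexing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "RoiSpec",
    "load_stack",
    "load_stack_dir",
    "save_stack",
    "crop_margin",
    "extract_roi",
    "centered_roi",
]

SIDECAR_NAME = "stack.json"


@dataclass
class ImageStack:
    """``n_images`` repeated 2-D acquisitions plus pixel pitch.

    Parameters
    ----------
    pixels
        Array of shape ``(n_images, rows, cols)`` of linear detector values
        (arbitrary units, "ADU").
    pixel_spacing_mm
        ``(row_pitch, col_pitch)`` in mm/pixel; both strictly positive.
    label
        Free-text tag, e.g. ``"DM"`` or ``"SM"``.
    """

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[np.newaxis]
        if self.pixels.ndim != 3:
            raise ValueError(
                f"pixels must be (n, rows, cols); got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1:
            raise ValueError("stack must contain at least one image")
        dr, dc = self.pixel_spacing_mm
        if not (dr > 0 and dc > 0):
            raise ValueError(f"pixel spacing must be positive, got ({dr}, {dc})")
        self.pixel_spacing_mm = (float(dr), float(dc))

    @property
    def n_images(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of each image."""
        return self.pixels.shape[1], self.pixels.shape[2]


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular region, half-open pixel ranges ``[origin, origin+size)``."""

    origin_row: int
    origin_col: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("ROI height and width must be positive")
        if self.origin_row < 0 or self.origin_col < 0:
            raise ValueError("ROI origin must be non-negative")

    def validate_within(self, shape: tuple[int, int]) -> None:
        rows, cols = shape
        if self.origin_row + self.height > rows or self.origin_col + self.width > cols:
            raise ValueError(
                f"ROI {self} extends past image bounds {rows}x{cols}"
            )


def centered_roi(shape: tuple[int, int], height: int, width: int) -> RoiSpec:
    """ROI of the given size centered in an image of ``shape`` (rows, cols)."""
    rows, cols = shape
    if height > rows or width > cols:
        raise ValueError("requested ROI larger than image")
    return RoiSpec((rows - height) // 2, (cols - width) // 2, height, width)


def _read_one(path: Path) -> tuple[np.ndarray, tuple[float, float] | None]:
    """Read a single 2-D grayscale image; return (array, spacing-or-None)."""
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom", ".ima"):
        import pydicom

        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array
        spacing = None
        for tag in ("PixelSpacing", "ImagerPixelSpacing"):
            val = getattr(ds, tag, None)
            if val is not None:
                spacing = (float(val[0]), float(val[1]))
                break
        return np.asarray(arr), spacing
    if suffix in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(str(path))), None
    if suffix == ".npy":
        return np.load(str(path)), None
    raise ValueError(f"unsupported image format: {path}")


def load_stack(
    paths: Sequence[str | Path],
    spacing_override: tuple[float, float] | None = None,
    label: str = "",
) -> ImageStack:
    """Stack 2-D grayscale files in path order into an :class:`ImageStack`.

    Spacing is taken from file metadata (DICOM ``PixelSpacing`` /
    ``ImagerPixelSpacing``) when present; ``spacing_override`` is used
    otherwise.  Raises if neither source provides a spacing, or if the
    images disagree in shape.
    """
    if not paths:
        raise ValueError("no input files")
    arrays = []
    meta_spacing: tuple[float, float] | None = None
    for p in paths:
        arr, spacing = _read_one(Path(p))
        if arr.ndim != 2:
            raise ValueError(f"{p}: expected a 2-D grayscale image, got shape {arr.shape}")
        if arrays and arr.shape != arrays[0].shape:
            raise ValueError(
                f"shape mismatch: {p} has {arr.shape}, expected {arrays[0].shape}"
            )
        if spacing is not None:
            if meta_spacing is not None and spacing != meta_spacing:
                raise ValueError("inconsistent pixel spacing across files")
            meta_spacing = spacing
        arrays.append(arr)
    spacing = meta_spacing if meta_spacing is not None else spacing_override
    if spacing is None:
        raise ValueError("no pixel spacing in file metadata and no override given")
    return ImageStack(np.stack(arrays), spacing, label=label)


def save_stack(stack: ImageStack, directory: str | Path) -> list[Path]:
    """Write a stack as one TIFF per image plus a JSON sidecar.

    The sidecar records pixel spacing, label, and the file order, so that
    :func:`load_stack_dir` round-trips exactly (bit-identical for integer
    pixel data; float64 TIFFs for non-integer data).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    px = stack.pixels
    if np.all(px == np.round(px)) and px.min() >= 0 and px.max() < 2**16:
        px_out = px.astype(np.uint16)
    else:
        px_out = px
    files = []
    for k in range(stack.n_images):
        f = directory / f"img_{k:03d}.tif"
        tifffile.imwrite(str(f), px_out[k])
        files.append(f)
    sidecar = {
        "pixel_spacing_mm": list(stack.pixel_spacing_mm),
        "label": stack.label,
        "files": [f.name for f in files],
    }
    (directory / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2))
    return files


def load_stack_dir(directory: str | Path) -> ImageStack:
    """Load a stack written by :func:`save_stack` (or any directory of
    images plus a ``stack.json`` sidecar)."""
    directory = Path(directory)
    sidecar_path = directory / SIDECAR_NAME
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        paths = [directory / name for name in sidecar["files"]]
        spacing = tuple(sidecar["pixel_spacing_mm"])
        return load_stack(paths, spacing_override=spacing, label=sidecar.get("label", ""))
    paths = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in (".tif", ".tiff", ".dcm", ".dicom", ".npy")
    )
    if not paths:
        raise ValueError(f"no images found in {directory}")
    return load_stack(paths)


def crop_margin(stack: ImageStack, margin_mm: float) -> ImageStack:
    """Remove a physical margin from every edge of every image.

    The margin converts to ``round(margin_mm / pitch)`` pixels per axis
    (e.g. 10 mm at 0.05 mm pitch removes 200 pixels from each edge).
    Raises if the margin consumes the whole image.
    """
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    dr, dc = stack.pixel_spacing_mm
    mr = int(round(margin_mm / dr))
    mc = int(round(margin_mm / dc))
    rows, cols = stack.shape
    if 2 * mr >= rows or 2 * mc >= cols:
        raise ValueError(
            f"margin of ({mr}, {mc}) px consumes the entire {rows}x{cols} image"
        )
    if mr == 0 and mc == 0:
        return replace(stack, pixels=stack.pixels.copy())
    return replace(
        stack,
        pixels=stack.pixels[:, mr: rows - mr, mc: cols - mc].copy(),
    )


def extract_roi(stack: ImageStack, roi: RoiSpec) -> ImageStack:
    """Sub-stack over an ROI; pixel spacing and label are preserved."""
    roi.validate_within(stack.shape)
    return replace(
        stack,
        pixels=stack.pixels[
            :,
            roi.origin_row: roi.origin_row + roi.height,
            roi.origin_col: roi.origin_col + roi.width,
        ].copy(),
    )
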