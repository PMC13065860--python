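"""Pixelwise SNR maps and the block-wise nonuniformity index (NUI).

From n repeated flat-field acquisitions, the pixelwise mean and standard
deviation maps give an SNR map (mean / SD per pixel).  Tiling the SNR map
into non-overlapping blocks and taking per-block means yields the
nonuniformity index

    NUI = (max_i m_i - min_i m_i) / ((max_i m_i + min_i m_i) / 2)

over the block means m_i — a global, scale-free measure of spatial SNR
nonuniformity.  NUI is invariant to rescaling the map, so normalizing the
SNR map to its maximum (done for display) does not change it.

Pixels where the SD is exactly zero have no defined SNR; they are flagged
invalid and excluded from block means rather than zero-filled, since
zero-filling would bias the block minimum downward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imgio import ImageStack

__all__ = [
    "SnrMap",
    "BlockGrid",
    "compute_mean_sd_maps",
    "compute_snr_map",
    "normalize_map",
    "block_means",
    "compute_nui",
    "snr_map_from_stack",
    "default_block_size",
]


@dataclass
class SnrMap:
    """Pixelwise mean, SD and SNR maps from repeated acquisitions."""

    mean_map: np.ndarray
    sd_map: np.ndarray
    snr_map: np.ndarray
    valid: np.ndarray  # bool; False where sd == 0 (SNR undefined)
    n_images: int
    normalized: bool = False


@dataclass
class BlockGrid:
    """Per-block means of a map tiled exactly by blocks of block_h x block_w."""

    block_h: int
    block_w: int
    block_means: np.ndarray  # flattened, row-major block order
    grid_rows: int
    grid_cols: int


def compute_mean_sd_maps(stack: ImageStack) -> tuple[np.ndarray, np.ndarray]:
    """Pixelwise mean and sample SD (ddof=1) across the stack.

    Requires at least two images — the SD of a single acquisition is
    undefined.
    """
    if stack.n_images < 2:
        raise ValueError("need at least 2 images for mean/SD maps")
    mean_map = stack.pixels.mean(axis=0)
    sd_map = stack.pixels.std(axis=0, ddof=1)
    return mean_map, sd_map


def compute_snr_map(mean_map: np.ndarray, sd_map: np.ndarray, n_images: int = 0) -> SnrMap:
    """Elementwise mean/SD ratio; zero-SD pixels flagged invalid."""
    mean_map = np.asarray(mean_map, dtype=np.float64)
    sd_map = np.asarray(sd_map, dtype=np.float64)
    if mean_map.shape != sd_map.shape:
        raise ValueError(
            f"shape mismatch: mean {mean_map.shape} vs sd {sd_map.shape}"
        )
    valid = sd_map > 0
    snr = np.zeros_like(mean_map)
    np.divide(mean_map, sd_map, out=snr, where=valid)
    return SnrMap(mean_map, sd_map, snr, valid, n_images=n_images)


def normalize_map(m: SnrMap) -> SnrMap:
    """Divide valid SNR values by their maximum (display convention)."""
    if not m.valid.any():
        raise ValueError("no valid pixels to normalize")
    vmax = m.snr_map[m.valid].max()
    if vmax <= 0:
        raise ValueError("maximum valid SNR is non-positive")
    out = np.where(m.valid, m.snr_map / vmax, 0.0)
    return SnrMap(m.mean_map, m.sd_map, out, m.valid, m.n_images, normalized=True)


def block_means(
    map_2d: np.ndarray,
    block_h: int,
    block_w: int,
    valid: np.ndarray | None = None,
) -> BlockGrid:
    """Mean of valid pixels per non-overlapping block, row-major order.

    The map dimensions must be exact multiples of the block size (no
    partial blocks).  A block containing no valid pixels is an error.
    """
    map_2d = np.asarray(map_2d, dtype=np.float64)
    rows, cols = map_2d.shape
    if block_h <= 0 or block_w <= 0:
        raise ValueError("block dimensions must be positive")
    if rows % block_h or cols % block_w:
        raise ValueError(
            f"map {rows}x{cols} not divisible by blocks {block_h}x{block_w}"
        )
    gr, gc = rows // block_h, cols // block_w
    blocks = map_2d.reshape(gr, block_h, gc, block_w)
    if valid is None:
        means = blocks.mean(axis=(1, 3))
    else:
        v = np.asarray(valid, dtype=bool).reshape(gr, block_h, gc, block_w)
        counts = v.sum(axis=(1, 3))
        if (counts == 0).any():
            raise ValueError("a block contains no valid pixels")
        means = np.where(v, blocks, 0.0).sum(axis=(1, 3)) / counts
    return BlockGrid(block_h, block_w, means.ravel(), gr, gc)


def compute_nui(grid: BlockGrid) -> float:
    """Nonuniformity index: (max - min) / midrange of the block means."""
    m = np.asarray(grid.block_means, dtype=np.float64)
    if m.size < 2:
        raise ValueError("need at least 2 blocks")
    if (m <= 0).any():
        raise ValueError("all block means must be positive")
    mx, mn = m.max(), m.min()
    return float((mx - mn) / ((mx + mn) / 2.0))


def default_block_size(spacing_mm: float) -> int:
    """Block edge in pixels: 100 px at 0.05 mm pitch, halved at 0.10 mm.

    Keeps the physical block size constant (5 mm) across detector pitches
    so that block statistics sample the same underlying gain-field area.
    """
    return max(1, int(round(5.0 / spacing_mm)))


def snr_map_from_stack(stack: ImageStack) -> SnrMap:
    """Convenience: mean/SD maps then SNR map in one call."""
    mean_map, sd_map = compute_mean_sd_maps(stack)
    return compute_snr_map(mean_map, sd_map, n_images=stack.n_images)
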