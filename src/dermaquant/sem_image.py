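"""Loading, banner-cropping and tiling of grayscale SEM rasters.

Tabletop SEMs stamp an instrument metadata band along the bottom edge of the
saved raster.  The analysis operates on the scan area above that band, cut
into fixed-size square tiles; partial edge tiles are discarded.  Coordinates
are 0-based ``(row, col)`` with the origin at the top-left, everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

#: Rec. 601 luma weights used when an RGB raster must be collapsed to gray.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class SEMImage:
    """A single-channel SEM raster with pixel-grid metadata.

    Parameters
    ----------
    pixels
        2-D integer array of intensities, ``0..max`` for the native bit depth.
    banner_rows
        Number of bottom rows occupied by the instrument metadata band
        (0 if the raster carries no band).
    magnification_label
        Free-text magnification tag (e.g. ``"300x"``); informational only.
    """

    pixels: np.ndarray
    banner_rows: int = 0
    magnification_label: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("SEMImage requires a non-empty 2-D pixel array")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("SEMImage intensities must be integer-typed")
        if px.min() < 0:
            raise ValueError("SEMImage intensities must be non-negative")
        if not 0 <= self.banner_rows < px.shape[0]:
            raise ValueError(
                f"banner_rows={self.banner_rows} must lie in [0, height_px)"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class TileGrid:
    """Row-major, non-overlapping ``tile_px`` × ``tile_px`` views of a scan area."""

    tiles: tuple[SEMImage, ...]
    origins: tuple[tuple[int, int], ...]
    tile_px: int
    n_rows: int
    n_cols: int
    parent_max: int = field(default=0)

    def __len__(self) -> int:
        return len(self.tiles)

    def origin_of(self, index: int) -> tuple[int, int]:
        """(row, col) offset of tile ``index`` within the parent scan area."""
        return self.origins[index]


def load_grayscale(path: str | Path) -> SEMImage:
    """Read a TIFF or PNG raster as a grayscale :class:`SEMImage`.

    Single-channel input is preserved bit-exactly (8- or 16-bit).  RGB input
    is collapsed with Rec. 601 luma weights and a warning is logged, since SEM
    data should be single-channel.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise OSError(f"could not read raster {path}: {exc}") from exc
    arr = np.asarray(raw)
    if arr.size == 0:
        raise ValueError(f"zero-sized raster: {path}")
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        logger.warning("RGB raster %s converted to grayscale via luma weights", path)
        arr = np.rint(arr[:, :, :3].astype(float) @ _LUMA_WEIGHTS).astype(raw.dtype)
    if arr.ndim != 2:
        raise ValueError(f"unsupported raster shape {raw.shape} in {path}")
    return SEMImage(pixels=arr)


def crop_scan_area(img: SEMImage) -> SEMImage:
    """Remove the bottom ``banner_rows`` metadata band from the raster."""
    if img.banner_rows == 0:
        return img
    cropped = img.pixels[: img.height_px - img.banner_rows]
    return SEMImage(
        pixels=cropped, banner_rows=0, magnification_label=img.magnification_label
    )


def tile_image(img: SEMImage, tile_px: int = 250) -> TileGrid:
    """Cut a banner-free scan area into full ``tile_px`` square tiles.

    Tiles are emitted row-major; edge remainders smaller than ``tile_px`` are
    discarded.  A 1500×2560 scan area at ``tile_px=250`` yields the reference
    6×10 = 60-tile layout.
    """
    if tile_px < 1:
        raise ValueError(f"tile_px must be >= 1, got {tile_px}")
    if img.banner_rows:
        raise ValueError("tile_image expects a banner-cropped image; crop first")
    h, w = img.height_px, img.width_px
    if tile_px > min(h, w):
        raise ValueError(
            f"tile_px={tile_px} exceeds scan area {h}x{w}; zero tiles would result"
        )
    n_rows, n_cols = h // tile_px, w // tile_px
    tiles: list[SEMImage] = []
    origins: list[tuple[int, int]] = []
    for r in range(n_rows):
        for c in range(n_cols):
            view = img.pixels[
                r * tile_px : (r + 1) * tile_px, c * tile_px : (c + 1) * tile_px
            ]
            tiles.append(
                SEMImage(pixels=view, magnification_label=img.magnification_label)
            )
            origins.append((r * tile_px, c * tile_px))
    return TileGrid(
        tiles=tuple(tiles),
        origins=tuple(origins),
        tile_px=tile_px,
        n_rows=n_rows,
        n_cols=n_cols,
        parent_max=int(img.pixels.max()),
    )
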