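"""Gap/cell segmentation of SEM tiles and the N_G / N_PC statistics.

A tile is binarized at a fraction of its maximum intensity (default 40%):
pixels strictly below the cutoff are *gaps* — the dark, deep intercellular
regions exposed by corneocyte detachment — and the rest are cell-surface
pixels.  Gap regions are then enumerated by raster-scan border following
(the Suzuki–Abe algorithm) on the 8-connected foreground, with 4-connected
background; each 8-connected gap region contributes exactly one outer
border, so

    N_G  = number of outer borders  = number of gap regions,
    N_PC = number of pixels outside every gap region.

The border follower is implemented here from first principles because it is
the analysis primitive the statistics rest on; component-labelling libraries
are used only as independent cross-checks in the test suite.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import numpy as np

from .sem_image import SEMImage, TileGrid

logger = logging.getLogger(__name__)

# 8-neighbour offsets in clockwise order starting from east (row grows down,
# so E -> SE -> S -> ... is clockwise on screen).
_CLOCKWISE = (
    (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1),
)
_DIR_INDEX = {d: i for i, d in enumerate(_CLOCKWISE)}


@dataclass(frozen=True)
class GapMask:
    """Binary gap raster plus the threshold that produced it."""

    mask: np.ndarray  # bool, True = gap pixel
    threshold_value: float
    source_max: int

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2 or m.size == 0:
            raise ValueError("GapMask requires a non-empty 2-D boolean raster")
        object.__setattr__(self, "mask", m)


@dataclass(frozen=True)
class Contour:
    """One border of a gap region: a closed 8-connected pixel sequence."""

    pixels: tuple[tuple[int, int], ...]
    kind: str  # "outer" | "hole"
    enclosed_area_px: int


@dataclass(frozen=True)
class TileStat:
    """Per-tile gap statistics: the row unit of the group comparisons."""

    n_g: int
    n_pc: int
    gap_px: int
    tile_origin: tuple[int, int]
    threshold_value: float

    def __post_init__(self) -> None:
        if self.n_g < 0 or self.n_pc < 0 or self.gap_px < 0:
            raise ValueError("counts must be non-negative")
        if (self.n_g == 0) != (self.gap_px == 0):
            raise ValueError("n_g == 0 must hold exactly when gap_px == 0")
        if self.n_g > self.gap_px:
            raise ValueError("cannot have more gap regions than gap pixels")


def binarize_gaps(
    tile: SEMImage, frac: float = 0.40, source_max: int | None = None
) -> GapMask:
    """Threshold a tile at ``frac`` of its maximum intensity.

    A pixel is a gap iff its intensity is strictly below ``frac * max``;
    a uniform tile therefore contains no gaps.  ``source_max`` overrides the
    per-tile maximum when the threshold scope is the whole parent image.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError(f"frac must lie in (0, 1), got {frac}")
    px = tile.pixels
    smax = int(px.max()) if source_max is None else int(source_max)
    threshold = frac * smax
    return GapMask(mask=px < threshold, threshold_value=threshold, source_max=smax)


def _component_areas(mask: np.ndarray) -> np.ndarray:
    """Label 8-connected foreground by iterative flood fill; return label map.

    Internal helper for per-contour areas; independent of the border follower.
    """
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=np.int32)
    current = 0
    rows, cols = np.nonzero(mask)
    for r0, c0 in zip(rows.tolist(), cols.tolist()):
        if labels[r0, c0]:
            continue
        current += 1
        stack = deque([(r0, c0)])
        labels[r0, c0] = current
        while stack:
            r, c = stack.pop()
            for dr, dc in _CLOCKWISE:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not labels[rr, cc]:
                    labels[rr, cc] = current
                    stack.append((rr, cc))
    return labels


def _hole_area(mask: np.ndarray, start: tuple[int, int]) -> int:
    """Size of the 4-connected background region containing ``start``."""
    h, w = mask.shape
    seen = {start}
    stack = deque([start])
    count = 0
    while stack:
        r, c = stack.pop()
        count += 1
        for dr, dc in ((0, 1), (1, 0), (0, -1), (-1, 0)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not mask[rr, cc] and (rr, cc) not in seen:
                seen.add((rr, cc))
                stack.append((rr, cc))
    return count


def _follow_border(
    f: np.ndarray, start: tuple[int, int], prev: tuple[int, int], nbd: int
) -> list[tuple[int, int]]:
    """Trace one border from ``start`` with initial probe pixel ``prev``.

    Implements the border-following step of the Suzuki–Abe raster-scan
    algorithm on the 8-connected foreground, marking visited pixels in ``f``
    (+nbd, or -nbd where the eastern neighbour was examined and found empty —
    the mark that prevents a border from being traced twice).
    """
    h, w = f.shape
    i, j = start

    def value(r: int, c: int) -> int:
        return f[r, c] if 0 <= r < h and 0 <= c < w else 0

    # Step 1: clockwise search around start for a non-empty neighbour.
    k0 = _DIR_INDEX[(prev[0] - i, prev[1] - j)]
    first = None
    for step in range(8):
        dr, dc = _CLOCKWISE[(k0 + step) % 8]
        if value(i + dr, j + dc) != 0:
            first = (i + dr, j + dc)
            break
    if first is None:  # isolated pixel
        f[i, j] = -nbd
        return [(i, j)]

    contour = [(i, j)]
    i2, j2 = first        # (i1, j1) in the classical formulation
    i3, j3 = i, j
    prev2 = first
    while True:
        # Counterclockwise search around (i3, j3) starting just after prev2.
        k = _DIR_INDEX[(prev2[0] - i3, prev2[1] - j3)]
        examined_east_zero = False
        nxt = None
        for step in range(1, 9):
            dr, dc = _CLOCKWISE[(k - step) % 8]
            rr, cc = i3 + dr, j3 + dc
            if value(rr, cc) != 0:
                nxt = (rr, cc)
                break
            if (dr, dc) == (0, 1):
                examined_east_zero = True
        # Marking rule.
        if examined_east_zero:
            f[i3, j3] = -nbd
        elif f[i3, j3] == 1:
            f[i3, j3] = nbd
        # Termination: back at the start moving toward the first pixel again.
        if nxt == (i, j) and (i3, j3) == (i2, j2):
            break
        prev2 = (i3, j3)
        i3, j3 = nxt
        contour.append(nxt)
    return contour


def trace_borders(mask: GapMask, compute_areas: bool = True) -> list[Contour]:
    """Enumerate outer and hole borders of the gap foreground.

    Raster-scan border following with 8-connected foreground and 4-connected
    background: every gap region yields exactly one outer border; borders of
    cell-pixel islands inside a gap are reported with ``kind="hole"``.
    Ordering is deterministic: by raster position of the border's start pixel.

    ``compute_areas=False`` skips the per-contour area flood fill (areas are
    reported as -1); the bulk tile path uses this since only counts are needed.
    """
    m = mask.mask
    h, w = m.shape
    f = m.astype(np.int32)
    # Candidate border starts, precomputed on the immutable foreground map:
    # a pixel can start an outer border only if its west neighbour is empty,
    # a hole border only if its east neighbour is empty.
    west_empty = np.ones_like(m)
    west_empty[:, 1:] = ~m[:, :-1]
    east_empty = np.ones_like(m)
    east_empty[:, :-1] = ~m[:, 1:]
    outer_cand = m & west_empty
    hole_cand = m & east_empty
    cand_rows, cand_cols = np.nonzero(outer_cand | hole_cand)

    labels = _component_areas(m) if compute_areas else None
    if labels is not None:
        areas = np.bincount(labels.ravel())

    contours: list[Contour] = []
    nbd = 1
    for i, j in zip(cand_rows.tolist(), cand_cols.tolist()):
        if outer_cand[i, j] and f[i, j] == 1:
            kind, probe = "outer", (i, j - 1)
        elif hole_cand[i, j] and f[i, j] >= 1:
            kind, probe = "hole", (i, j + 1)
        else:
            continue
        nbd += 1
        pix = _follow_border(f, (i, j), probe, nbd)
        if not compute_areas:
            area = -1
        elif kind == "outer":
            area = int(areas[labels[i, j]])
        else:
            area = _hole_area(m, (i, j + 1))
        contours.append(Contour(pixels=tuple(pix), kind=kind, enclosed_area_px=area))
    return contours


def gap_count(mask: GapMask, min_area: int = 1) -> int:
    """N_G: the number of 8-connected gap regions (outer borders).

    ``min_area`` (pixels) filters out regions smaller than the given size;
    the default of 1 applies no filter.
    """
    need_area = min_area > 1
    contours = trace_borders(mask, compute_areas=need_area)
    return sum(
        1
        for c in contours
        if c.kind == "outer" and (not need_area or c.enclosed_area_px >= min_area)
    )


def cell_pixel_count(mask: GapMask) -> int:
    """N_PC: the number of pixels outside every gap region."""
    return int((~mask.mask).sum())


def segment_tiles(
    grid: TileGrid,
    frac: float = 0.40,
    threshold_scope: str = "tile",
    min_area: int = 1,
) -> list[TileStat]:
    """Binarize and count gaps on every tile of a grid, in grid order.

    ``threshold_scope`` selects whether the 40%-of-maximum cutoff uses each
    tile's own maximum (``"tile"``, the default) or the parent image maximum
    (``"image"``).
    """
    if len(grid) == 0:
        raise ValueError("empty tile grid")
    if threshold_scope not in ("tile", "image"):
        raise ValueError(f"threshold_scope must be 'tile' or 'image', got {threshold_scope!r}")
    source_max = grid.parent_max if threshold_scope == "image" else None
    stats: list[TileStat] = []
    for tile, origin in zip(grid.tiles, grid.origins):
        mask = binarize_gaps(tile, frac=frac, source_max=source_max)
        gap_px = int(mask.mask.sum())
        stats.append(
            TileStat(
                n_g=gap_count(mask, min_area=min_area),
                n_pc=cell_pixel_count(mask),
                gap_px=gap_px,
                tile_origin=origin,
                threshold_value=mask.threshold_value,
            )
        )
    return stats


#: Overlay palette: gaps yellow, cell surfaces blue (RGB).
GAP_COLOR = (255, 255, 0)
CELL_COLOR = (0, 0, 255)


def render_overlay(mask: GapMask) -> np.ndarray:
    """Render a gap mask as an RGB raster: gaps yellow, cell pixels blue."""
    h, w = mask.mask.shape
    out = np.empty((h, w, 3), dtype=np.uint8)
    out[mask.mask] = GAP_COLOR
    out[~mask.mask] = CELL_COLOR
    return out
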