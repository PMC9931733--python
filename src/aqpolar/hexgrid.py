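"""Visium-style hexagonal lattice geometry.

Spots live on an array grid where a position ``(row, col)`` is valid iff
``row + col`` is even (odd rows are offset by one column, which packs the
spots hexagonally).  The six immediate neighbours of ``(r, c)`` are
``(r, c±2)`` and ``(r±1, c±1)``.  Pixel coordinates place adjacent spot
centres ``SPOT_PITCH_UM`` apart.
"""

from __future__ import annotations

import numpy as np

#: centre-to-centre distance between adjacent spots, in micrometres
SPOT_PITCH_UM = 100.0

#: pixel-x distance per array-column unit (columns advance by 2 between
#: same-row neighbours, so one unit is half the pitch)
COL_STEP = SPOT_PITCH_UM / 2.0
#: pixel-y distance per array-row unit (rows of a hex packing are
#: sqrt(3)/2 of the pitch apart)
ROW_STEP = SPOT_PITCH_UM * np.sqrt(3.0) / 2.0

#: the six hex-neighbour offsets in array coordinates
NEIGHBOR_OFFSETS = ((0, -2), (0, 2), (-1, -1), (-1, 1), (1, -1), (1, 1))


def valid_positions(n_rows: int, n_cols: int) -> np.ndarray:
    """All valid array positions on an ``n_rows`` x ``n_cols`` grid.

    Returns an ``(n, 2)`` int array of ``(row, col)`` pairs with
    ``row + col`` even, in row-major order.
    """
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("lattice dimensions must be positive")
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    keep = (rows + cols) % 2 == 0
    return np.column_stack([rows[keep], cols[keep]])


def neighbors(row: int, col: int) -> list[tuple[int, int]]:
    """The up-to-six hex neighbours of an array position (may be off-grid)."""
    return [(row + dr, col + dc) for dr, dc in NEIGHBOR_OFFSETS]


def pixel_coords(rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map array coordinates to pixel-space ``(pxl_row, pxl_col)`` centres."""
    return np.asarray(rows) * ROW_STEP, np.asarray(cols) * COL_STEP
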