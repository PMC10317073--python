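"""Exact integer arithmetic for the Hilbert space-filling curve.

A level-``k`` Hilbert curve visits every cell of a ``2**k x 2**k`` grid
exactly once, with consecutive curve indices always landing in
edge-adjacent cells.  These two properties are what make the curve useful
as a layout device: any contiguous run of curve indices maps to a
connected, roughly square patch of the grid, so a 1D ordering of genomes
becomes a 2D map whose "neighborhoods" stay coherent.

Coordinate convention (stated in all output metadata): ``x`` is the
column, ``y`` is the row, and the origin is the top-left corner of the
rendered image.  The base (level-1) visiting order is fixed once and for
all as ``(0,0) -> (0,1) -> (1,1) -> (1,0)`` -- a "U" opening upward in
image coordinates; higher levels derive from it by the standard quadrant
reflections.  The conversion uses iterative bitwise quadrant transforms
so that high levels (k >= 10) stay cheap.
"""

from __future__ import annotations

from typing import Iterator, List, Tuple

__all__ = [
    "MAX_LEVEL",
    "index_to_cell",
    "cell_to_index",
    "choose_level",
    "curve_path",
    "iter_curve",
]

#: Practical upper bound on the curve level; 4**30 indices already exceed
#: any reference collection by many orders of magnitude.
MAX_LEVEL = 30

Cell = Tuple[int, int]


def _check_level(k: int) -> None:
    if not isinstance(k, (int,)) or isinstance(k, bool):
        raise TypeError(f"curve level must be an integer, got {k!r}")
    if k < 1 or k > MAX_LEVEL:
        raise ValueError(f"curve level must be in 1..{MAX_LEVEL}, got {k}")


def index_to_cell(k: int, d: int) -> Cell:
    """Map curve index ``d`` to the ``(x, y)`` cell it occupies at level ``k``.

    Parameters
    ----------
    k : int
        Curve level; the grid has side ``2**k`` and ``4**k`` cells.
    d : int
        Distance along the curve, ``0 <= d < 4**k``.

    Returns
    -------
    (x, y) : tuple of int
        Column and row (origin top-left) of the ``d``-th visited cell.
    """
    _check_level(k)
    if not (0 <= d < 4**k):
        raise ValueError(f"curve index {d} out of range 0..{4**k - 1} for level {k}")
    x = y = 0
    t = d
    s = 1
    side = 1 << k
    while s < side:
        rx = 1 & (t >> 1)
        ry = 1 & (t ^ rx)
        if ry == 0:
            if rx == 1:
                x = s - 1 - x
                y = s - 1 - y
            x, y = y, x
        x += s * rx
        y += s * ry
        t >>= 2
        s <<= 1
    return x, y


def cell_to_index(k: int, cell: Cell) -> int:
    """Inverse of :func:`index_to_cell`: curve index of a grid cell."""
    _check_level(k)
    x, y = cell
    side = 1 << k
    if not (0 <= x < side and 0 <= y < side):
        raise ValueError(
            f"cell {cell!r} out of range for level {k} (side {side})"
        )
    d = 0
    s = side >> 1
    while s > 0:
        rx = 1 if (x & s) > 0 else 0
        ry = 1 if (y & s) > 0 else 0
        d += s * s * ((3 * rx) ^ ry)
        if ry == 0:
            if rx == 1:
                x = s - 1 - x
                y = s - 1 - y
            x, y = y, x
        s >>= 1
    return d


def choose_level(n_taxa: int) -> int:
    """Smallest level ``k >= 1`` whose grid holds ``n_taxa`` cells.

    The grid at level ``k`` has ``4**k`` cells, so this returns the
    minimal ``k`` with ``4**k >= n_taxa``.
    """
    if not isinstance(n_taxa, int) or isinstance(n_taxa, bool) or n_taxa < 1:
        raise ValueError(f"number of taxa must be a positive integer, got {n_taxa!r}")
    k = 1
    while 4**k < n_taxa:
        k += 1
    return k


def iter_curve(k: int) -> Iterator[Cell]:
    """Yield the cells of the level-``k`` curve in visiting order."""
    _check_level(k)
    for d in range(4**k):
        yield index_to_cell(k, d)


def curve_path(k: int) -> List[Cell]:
    """The full visiting order of the level-``k`` curve as a list of cells.

    Element ``d`` equals ``index_to_cell(k, d)``; consecutive cells are
    always at Manhattan distance 1 (the curve's continuity), which is what
    lets the path be drawn as an unbroken polyline over the map.
    """
    return list(iter_curve(k))
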