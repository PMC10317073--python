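"""Assigning taxa to Hilbert-grid cells: segment merging and neighborhoods.

A level-``k`` grid offers ``4**k`` curve segments but a collection rarely
has exactly that many genomes, so adjacent segments along the curve's
path are merged until the number of regions equals the number of
genomes: with ``n`` taxa and ``S`` available indices every taxon receives
``floor(S/n)`` or ``ceil(S/n)`` consecutive indices (balanced merging),
earlier-ordered taxa taking the extra index when there is a remainder.
Because the curve is continuous, each taxon's interval maps to a
4-connected patch of cells, and each contiguous group of the linear
order (a clade, or a condition block) maps to a connected region -- a
*microbial neighborhood*.

An optional gap policy reserves blank (unassigned) cells so that each
group after the first starts at the boundary of an aligned ``2**g x
2**g`` subsquare, leaving room for future additions without disturbing
existing positions.  With gaps on, taxa take one cell each and the slack
is absorbed by the reserved gaps; the policy is off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

from .hilbert import cell_to_index, choose_level, index_to_cell
from .taxonomy import LinearOrder

logger = logging.getLogger("hilbertmaps")

__all__ = [
    "HilbertLayout",
    "NeighborhoodSet",
    "Neighborhood",
    "build_layout",
    "cells_of",
    "taxon_at",
    "neighborhoods",
    "write_layout",
    "read_layout",
]

Cell = Tuple[int, int]
Interval = Tuple[int, int]  # inclusive curve-index interval [d_start, d_end]


@dataclass
class HilbertLayout:
    """Curve level plus the taxon -> curve-interval assignment.

    ``assignment`` maps each taxon id to its inclusive index interval
    ``(d_start, d_end)``; intervals are disjoint, ordered like the
    LinearOrder, and together with ``gaps`` cover ``0 .. 4**k - 1``.
    """

    k: int
    order: LinearOrder
    assignment: Dict[str, Interval]
    gaps: List[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index_of: Dict[str, int] = {
            t: i for i, t in enumerate(self.order.taxa)
        }

    @property
    def side(self) -> int:
        return 1 << self.k

    @property
    def n_cells(self) -> int:
        return 4**self.k

    @property
    def n_taxa(self) -> int:
        return len(self.assignment)

    def interval(self, taxon_id: str) -> Interval:
        try:
            return self.assignment[taxon_id]
        except KeyError:
            raise KeyError(f"unknown taxon {taxon_id!r} in layout") from None


def build_layout(
    order: LinearOrder,
    k: Optional[int] = None,
    reserve_gaps: bool = False,
    gap_grouping: Optional[str] = None,
) -> HilbertLayout:
    """Assign every taxon of ``order`` a contiguous curve-index interval.

    Parameters
    ----------
    order : LinearOrder
        The 1D order of taxa (taxonomic or labeled).
    k : int, optional
        Curve level; defaults to the minimal level whose grid holds all
        taxa.  Too small a level is a capacity error naming the minimal
        sufficient one.
    reserve_gaps : bool
        Pad each top-level group so the next group starts at the boundary
        of an aligned subsquare (blank-pixel reservation).  Off by
        default.
    gap_grouping : str, optional
        Which grouping of the order defines the top-level groups for the
        gap policy; defaults to the order's first grouping key.
    """
    n = len(order.taxa)
    if n == 0:
        raise ValueError("cannot lay out an empty order")
    k_min = choose_level(n)
    if k is None:
        k = k_min
    elif n > 4**k:
        raise ValueError(
            f"{n} taxa exceed the {4**k} cells of a level-{k} grid; "
            f"minimal sufficient level is {k_min}"
        )
    S = 4**k
    assignment: Dict[str, Interval] = {}
    gaps: List[Interval] = []

    if not reserve_gaps:
        base, rem = divmod(S, n)
        cursor = 0
        for i, taxon in enumerate(order.taxa):
            length = base + (1 if i < rem else 0)
            assignment[taxon] = (cursor, cursor + length - 1)
            cursor += length
    else:
        runs = _top_level_runs(order, gap_grouping)
        cursor = 0
        for label, start, end in runs:
            size = end - start
            # subsquare granularity: smallest g with 4**g >= group size
            g = choose_level(size)
            block = 4**g
            if cursor % block:
                gap_start = cursor
                cursor = (cursor // block + 1) * block
                gaps.append((gap_start, cursor - 1))
            if cursor + size > S:
                raise ValueError(
                    f"gap policy overflows the level-{k} grid at group "
                    f"{label!r}; raise the level or disable gaps"
                )
            for taxon in order.taxa[start:end]:
                assignment[taxon] = (cursor, cursor)
                cursor += 1
        if cursor < S:
            gaps.append((cursor, S - 1))

    return HilbertLayout(k=k, order=order, assignment=assignment, gaps=gaps)


def _top_level_runs(
    order: LinearOrder, grouping: Optional[str]
) -> List[Tuple[str, int, int]]:
    if not order.groups:
        return [("all", 0, len(order.taxa))]
    key = grouping if grouping is not None else next(iter(order.groups))
    return order.runs(key)


def cells_of(layout: HilbertLayout, taxon_id: str) -> List[Cell]:
    """The cells a taxon occupies, in curve order (edge-connected)."""
    d0, d1 = layout.interval(taxon_id)
    return [index_to_cell(layout.k, d) for d in range(d0, d1 + 1)]


def taxon_at(layout: HilbertLayout, cell: Cell) -> Optional[str]:
    """The taxon occupying ``cell``, or None on a reserved-gap cell."""
    d = cell_to_index(layout.k, cell)
    # binary search over the ordered intervals
    taxa = layout.order.taxa
    lo, hi = 0, len(taxa) - 1
    while lo <= hi:
        mid = (lo + hi) // 2
        d0, d1 = layout.assignment[taxa[mid]]
        if d < d0:
            hi = mid - 1
        elif d > d1:
            lo = mid + 1
        else:
            return taxa[mid]
    return None


# ---------------------------------------------------------------------------
# neighborhoods

Edge = Tuple[Cell, Cell]  # boundary segment between two cell corners


@dataclass
class Neighborhood:
    """One contiguous group's region on the map.

    ``boundary`` holds unit segments in cell-corner coordinates (the
    corner lattice is one larger than the cell grid per side), ready to
    be drawn as region outlines.  ``anchor`` is the member cell closest
    to the region's centroid, used for caption placement.
    """

    label: str
    cells: Set[Cell]
    boundary: List[Edge]
    anchor: Cell


@dataclass
class NeighborhoodSet:
    grouping: str
    neighborhoods: List[Neighborhood]

    def __iter__(self):
        return iter(self.neighborhoods)

    def __len__(self) -> int:
        return len(self.neighborhoods)

    def by_label(self, label: str) -> Neighborhood:
        for nb in self.neighborhoods:
            if nb.label == label:
                return nb
        raise KeyError(f"no neighborhood labelled {label!r}")


def neighborhoods(
    layout: HilbertLayout, grouping: str
) -> NeighborhoodSet:
    """Per-group cell sets and boundary geometry for a grouping key.

    One neighborhood per contiguous group run of the layout's order; its
    cells are the union of the member taxa's interval cells, and its
    boundary is the set of unit edges separating a member cell from a
    non-member (or off-grid) cell under the 4-neighbor test.  Each
    neighborhood's cell count is the sum of its members' interval
    lengths, so region area tracks clade size.
    """
    runs = layout.order.runs(grouping)
    out: List[Neighborhood] = []
    for label, start, end in runs:
        cells: Set[Cell] = set()
        for taxon in layout.order.taxa[start:end]:
            d0, d1 = layout.assignment[taxon]
            for d in range(d0, d1 + 1):
                cells.add(index_to_cell(layout.k, d))
        boundary = _boundary_edges(cells)
        out.append(
            Neighborhood(
                label=label,
                cells=cells,
                boundary=boundary,
                anchor=_anchor_cell(cells),
            )
        )
    return NeighborhoodSet(grouping=grouping, neighborhoods=out)


def _boundary_edges(cells: Set[Cell]) -> List[Edge]:
    """Unit segments (corner coordinates) around a cell set."""
    edges: List[Edge] = []
    for x, y in cells:
        if (x - 1, y) not in cells:
            edges.append(((x, y), (x, y + 1)))  # left wall
        if (x + 1, y) not in cells:
            edges.append(((x + 1, y), (x + 1, y + 1)))  # right wall
        if (x, y - 1) not in cells:
            edges.append(((x, y), (x + 1, y)))  # top wall
        if (x, y + 1) not in cells:
            edges.append(((x, y + 1), (x + 1, y + 1)))  # bottom wall
    return sorted(edges)


def _anchor_cell(cells: Set[Cell]) -> Cell:
    cx = sum(c[0] for c in cells) / len(cells)
    cy = sum(c[1] for c in cells) / len(cells)
    return min(cells, key=lambda c: ((c[0] - cx) ** 2 + (c[1] - cy) ** 2, c))


# ---------------------------------------------------------------------------
# layout TSV round trip — fixing the taxon order so the identical map
# geometry can be reused across samples and studies

_LAYOUT_COLUMNS = ["taxon_id", "d_start", "d_end", "x_start", "y_start", "groups"]


def write_layout(layout: HilbertLayout, path: Union[str, Path]) -> None:
    """Export the layout as TSV (one row per taxon, plus a header comment).

    Columns: taxon_id, inclusive curve-index interval, the interval's
    first cell, and the taxon's group labels as ``key=label`` pairs.
    The header comment records level, orientation and order provenance.
    """
    path = Path(path)
    group_of: Dict[str, Dict[str, str]] = {t: {} for t in layout.order.taxa}
    for key, runs in layout.order.groups.items():
        for label, start, end in runs:
            for t in layout.order.taxa[start:end]:
                group_of[t][key] = label
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# hilbertmaps layout level={layout.k} "
            f"orientation=top-left-U provenance={layout.order.provenance}\n"
        )
        fh.write("\t".join(_LAYOUT_COLUMNS) + "\n")
        for taxon in layout.order.taxa:
            d0, d1 = layout.assignment[taxon]
            x, y = index_to_cell(layout.k, d0)
            labels = ";".join(
                f"{k}={v}" for k, v in sorted(group_of[taxon].items())
            )
            fh.write(f"{taxon}\t{d0}\t{d1}\t{x}\t{y}\t{labels}\n")


def read_layout(path: Union[str, Path]) -> HilbertLayout:
    """Re-import a layout written by :func:`write_layout`."""
    path = Path(path)
    k = None
    provenance = "imported"
    taxa: List[str] = []
    assignment: Dict[str, Interval] = {}
    group_of: Dict[str, Dict[str, str]] = {}
    with open(path, encoding="utf-8") as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("level="):
                        k = int(tok[6:])
                    elif tok.startswith("provenance="):
                        provenance = tok[11:]
                continue
            if not line:
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields != _LAYOUT_COLUMNS:
                    raise ValueError(
                        f"{path} line {lineno}: unexpected layout header {fields}"
                    )
                header_seen = True
                continue
            if len(fields) != len(_LAYOUT_COLUMNS):
                raise ValueError(f"{path} line {lineno}: ragged row")
            taxon, d0, d1 = fields[0], int(fields[1]), int(fields[2])
            if taxon in assignment:
                raise ValueError(f"{path} line {lineno}: duplicate taxon {taxon!r}")
            taxa.append(taxon)
            assignment[taxon] = (d0, d1)
            group_of[taxon] = dict(
                tok.split("=", 1) for tok in fields[5].split(";") if tok
            )
    if k is None:
        raise ValueError(f"{path}: missing level in layout header comment")
    if not taxa:
        raise ValueError(f"{path}: empty layout")
    groups = _runs_from_labels(taxa, group_of)
    order = LinearOrder(taxa=taxa, groups=groups, provenance=provenance)
    covered = sum(d1 - d0 + 1 for d0, d1 in assignment.values())
    gaps: List[Interval] = []
    cursor = 0
    for taxon in taxa:
        d0, d1 = assignment[taxon]
        if d0 > cursor:
            gaps.append((cursor, d0 - 1))
        cursor = d1 + 1
    if cursor < 4**k:
        gaps.append((cursor, 4**k - 1))
    return HilbertLayout(k=k, order=order, assignment=assignment, gaps=gaps)


def _runs_from_labels(
    taxa: Sequence[str], group_of: Dict[str, Dict[str, str]]
) -> Dict[str, List[Tuple[str, int, int]]]:
    keys = sorted({k for d in group_of.values() for k in d})
    groups: Dict[str, List[Tuple[str, int, int]]] = {}
    for key in keys:
        runs: List[Tuple[str, int, int]] = []
        for i, taxon in enumerate(taxa):
            label = group_of.get(taxon, {}).get(key)
            if label is None:
                continue
            if runs and runs[-1][0] == label and runs[-1][2] == i:
                runs[-1] = (label, runs[-1][1], i + 1)
            else:
                runs.append((label, i, i + 1))
        if runs:
            groups[key] = runs
    return groups
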