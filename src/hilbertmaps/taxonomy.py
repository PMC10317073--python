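"""Taxonomic annotations and the deterministic taxonomic linear order.

A reference collection has no natural 1D order, yet the Hilbert layout
needs one.  The *taxonomic ordering* derives it from the collection's
rank lineages (e.g. genus -> species -> strain): records sharing a
lineage prefix are grouped under shared internal nodes of a taxonomy
tree, and a depth-first left-to-right traversal of that tree emits the
leaves.  Because each clade's leaves are visited consecutively, every
clade occupies one contiguous run of the order -- and therefore one
connected "microbial neighborhood" of the final map.

Trees have no intrinsic child order either, so one is declared here:
children at every node are sorted by descending leaf count (larger
clades first), ties broken lexicographically by name.  This is
deterministic, independent of input row order, and keeps the big
neighborhoods visually coherent.  A purely lexicographic rule is
available as a config option.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import pandas as pd

logger = logging.getLogger("hilbertmaps")

__all__ = [
    "TaxonRecord",
    "TaxonomyNode",
    "TaxonomyTree",
    "LinearOrder",
    "build_tree",
    "linearize",
    "read_lineage_table",
    "read_newick",
    "UNRANKED_SUFFIX",
]

#: Suffix of synthetic placeholder nodes inserted for missing ranks so that
#: clade contiguity holds even on ragged lineage tables.
UNRANKED_SUFFIX = "__unranked"


@dataclass(frozen=True)
class TaxonRecord:
    """One reference genome with its rank lineage.

    ``lineage`` holds ``(rank, name)`` pairs ordered coarse -> fine, e.g.
    ``(("genus", "Streptococcus"), ("species", "S. mitis"), ("strain", "B6"))``.
    The finest rank present defines the leaf level; 16S-style collections
    stop at species or genus and that is fine -- the leaf rank is data
    driven, never hard-coded.
    """

    taxon_id: str
    lineage: Tuple[Tuple[str, str], ...]
    display_name: str = ""

    def __post_init__(self) -> None:
        if not self.taxon_id:
            raise ValueError("taxon_id must be a non-empty string")
        if not self.lineage:
            raise ValueError(f"taxon {self.taxon_id!r} has an empty lineage")
        if not self.display_name:
            object.__setattr__(self, "display_name", self.lineage[-1][1])

    @property
    def ranks(self) -> Tuple[str, ...]:
        return tuple(r for r, _ in self.lineage)


class TaxonomyNode:
    """Internal tree node carrying (rank, name); leaves carry a record."""

    __slots__ = ("rank", "name", "children", "record", "_leaf_count")

    def __init__(self, rank: str, name: str) -> None:
        self.rank = rank
        self.name = name
        self.children: Dict[str, "TaxonomyNode"] = {}
        self.record: Optional[TaxonRecord] = None
        self._leaf_count: Optional[int] = None

    @property
    def is_leaf(self) -> bool:
        return self.record is not None

    def leaf_count(self) -> int:
        if self._leaf_count is None:
            if self.is_leaf:
                self._leaf_count = 1
            else:
                self._leaf_count = sum(c.leaf_count() for c in self.children.values())
        return self._leaf_count


@dataclass
class TaxonomyTree:
    """Rooted taxonomy tree whose leaves are exactly the input records."""

    root: TaxonomyNode
    ranks: Tuple[str, ...]

    def leaves(self) -> List[TaxonRecord]:
        out: List[TaxonRecord] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node.record)  # type: ignore[arg-type]
            else:
                stack.extend(node.children.values())
        return out

    @property
    def n_leaves(self) -> int:
        return self.root.leaf_count()


@dataclass
class LinearOrder:
    """A permutation of taxon ids with contiguous group annotations.

    ``groups`` maps each grouping key (a rank such as ``"genus"``, or
    ``"condition"`` for labeled orderings) to its ``(label, start, end)``
    runs, ``end`` exclusive.  The runs of one grouping partition the list
    and never interleave; this is the invariant that makes neighborhoods
    connected regions on the map.
    """

    taxa: List[str]
    groups: Dict[str, List[Tuple[str, int, int]]] = field(default_factory=dict)
    provenance: str = "taxonomic"

    def __len__(self) -> int:
        return len(self.taxa)

    def __iter__(self):
        return iter(self.taxa)

    def runs(self, grouping: str) -> List[Tuple[str, int, int]]:
        if grouping not in self.groups:
            raise KeyError(
                f"unknown grouping {grouping!r}; available: {sorted(self.groups)}"
            )
        return self.groups[grouping]


def build_tree(records: Iterable[TaxonRecord]) -> TaxonomyTree:
    """Assemble the taxonomy tree; identical lineage prefixes share nodes.

    Records missing an intermediate rank get a synthetic
    ``<parent>__unranked`` placeholder node so clade contiguity still
    holds.  Duplicate taxon ids are an input error.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot build a taxonomy from zero records")
    seen: Dict[str, TaxonRecord] = {}
    for rec in records:
        if rec.taxon_id in seen:
            raise ValueError(f"duplicate taxon_id {rec.taxon_id!r}")
        seen[rec.taxon_id] = rec

    # The union of ranks across records, coarse -> fine, in first-seen
    # relative order; used to align ragged lineages.
    rank_order: List[str] = []
    for rec in records:
        pos = 0
        for rank in rec.ranks:
            if rank in rank_order:
                pos = rank_order.index(rank) + 1
            else:
                rank_order.insert(pos, rank)
                pos += 1

    root = TaxonomyNode("root", "root")
    for rec in records:
        have = dict(rec.lineage)
        node = root
        # walk all ranks coarser than the record's own leaf rank
        leaf_rank = rec.lineage[-1][0]
        leaf_depth = rank_order.index(leaf_rank)
        for rank in rank_order[:leaf_depth]:
            name = have.get(rank)
            if name is None or name == "":
                name = f"{node.name}{UNRANKED_SUFFIX}"
            child = node.children.get(name)
            if child is None:
                child = TaxonomyNode(rank, name)
                node.children[name] = child
            elif child.rank != rank:
                raise ValueError(
                    f"conflicting rank for node {name!r}: {child.rank} vs {rank}"
                )
            node = child
        leaf_name = rec.lineage[-1][1]
        if leaf_name in node.children:
            raise ValueError(
                f"duplicate leaf {leaf_name!r} under {node.name!r} "
                f"(taxon_id {rec.taxon_id!r})"
            )
        leaf = TaxonomyNode(leaf_rank, leaf_name)
        leaf.record = rec
        node.children[leaf_name] = leaf
    return TaxonomyTree(root=root, ranks=tuple(rank_order))


def _sorted_children(node: TaxonomyNode, rule: str) -> List[TaxonomyNode]:
    kids = list(node.children.values())
    if rule == "size-desc":
        kids.sort(key=lambda c: (-c.leaf_count(), c.name))
    elif rule == "lexicographic":
        kids.sort(key=lambda c: c.name)
    else:
        raise ValueError(f"unknown child-order rule {rule!r}")
    return kids


def linearize(tree: TaxonomyTree, child_order: str = "size-desc") -> LinearOrder:
    """Depth-first left-to-right leaf order with deterministic child order.

    Every clade's leaves form one contiguous run of the output, and group
    annotations are emitted for every rank present in the collection.
    The result depends only on tree content, never on input row order.
    """
    taxa: List[str] = []
    # open runs per rank: rank -> (label, start)
    runs: Dict[str, List[Tuple[str, int, int]]] = {r: [] for r in tree.ranks}

    def visit(node: TaxonomyNode) -> None:
        if node.is_leaf:
            taxa.append(node.record.taxon_id)  # type: ignore[union-attr]
            return
        for child in _sorted_children(node, child_order):
            start = len(taxa)
            visit(child)
            if child.rank in runs:
                runs[child.rank].append((child.name, start, len(taxa)))

    visit(tree.root)
    # Leaves never open runs in visit(), so the finest rank would have no
    # annotation; add per-leaf singleton runs for ranks only seen at leaves.
    covered = {r for r, v in runs.items() if v}
    id_to_rec = {rec.taxon_id: rec for rec in tree.leaves()}
    for rank in tree.ranks:
        if rank in covered:
            continue
        singles = [
            (id_to_rec[tid].lineage[-1][1], i, i + 1)
            for i, tid in enumerate(taxa)
            if id_to_rec[tid].lineage[-1][0] == rank
        ]
        if singles:
            runs[rank] = singles
    runs = {r: v for r, v in runs.items() if v}
    return LinearOrder(taxa=taxa, groups=runs, provenance=f"taxonomic:{child_order}")


# ---------------------------------------------------------------------------
# readers


def read_lineage_table(path: Union[str, Path]) -> List[TaxonRecord]:
    """Read a rank-annotated lineage table (TSV or CSV).

    Expected header: ``taxon_id`` plus one column per rank, coarse ->
    fine (e.g. ``taxon_id  genus  species  strain``).  A blank cell in an
    intermediate rank produces a synthetic placeholder during tree
    construction; a blank trailing rank simply shortens the lineage (the
    leaf then sits at the finest populated rank).
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "taxon_id" not in df.columns:
        raise ValueError(f"{path}: lineage table must have a 'taxon_id' column")
    ranks = [c for c in df.columns if c != "taxon_id"]
    if not ranks:
        raise ValueError(f"{path}: lineage table has no rank columns")
    records: List[TaxonRecord] = []
    seen: set = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row_d = dict(zip(df.columns, row))
        tid = row_d["taxon_id"].strip()
        if not tid:
            raise ValueError(f"{path} line {i}: empty taxon_id")
        if tid in seen:
            raise ValueError(f"{path} line {i}: duplicate taxon_id {tid!r}")
        seen.add(tid)
        lineage = [(r, row_d[r].strip()) for r in ranks]
        # drop blank trailing ranks; blanks in the middle stay and become
        # placeholder nodes in build_tree
        while lineage and not lineage[-1][1]:
            lineage.pop()
        if not lineage:
            raise ValueError(f"{path} line {i}: taxon {tid!r} has an empty lineage")
        records.append(TaxonRecord(taxon_id=tid, lineage=tuple(lineage)))
    if not records:
        raise ValueError(f"{path}: no records")
    return records


def read_newick(
    path: Union[str, Path], ranks: Sequence[str]
) -> TaxonomyTree:
    """Read a Newick tree with named leaves plus a rank map.

    ``ranks`` names the tree's internal levels coarse -> fine, the last
    entry being the leaf rank; a leaf at depth ``d`` receives the lineage
    spelled by its named ancestors mapped onto ``ranks[:d]``.  Unnamed
    internal nodes get synthetic placeholder names.
    """
    import skbio

    if not ranks:
        raise ValueError("a non-empty rank list is required for Newick input")
    tree = skbio.TreeNode.read(str(path), format="newick")
    records: List[TaxonRecord] = []
    seen: set = set()

    def walk(node, names: List[str]) -> None:
        if node.is_tip():
            tid = node.name
            if not tid:
                raise ValueError(f"{path}: unnamed leaf in Newick tree")
            if tid in seen:
                raise ValueError(f"{path}: duplicate leaf label {tid!r}")
            seen.add(tid)
            depth = len(names)
            if depth + 1 > len(ranks):
                raise ValueError(
                    f"{path}: leaf {tid!r} at depth {depth + 1} exceeds the "
                    f"{len(ranks)} declared ranks"
                )
            lineage = [(ranks[i], names[i]) for i in range(depth)]
            lineage.append((ranks[depth] if depth < len(ranks) else ranks[-1], tid))
            records.append(TaxonRecord(taxon_id=tid, lineage=tuple(lineage)))
            return
        for child in node.children:
            label = child.name if (child.name and not child.is_tip()) else None
            if child.is_tip():
                walk(child, names)
            else:
                walk(child, names + [label or f"node{UNRANKED_SUFFIX}"])

    walk(tree, [])
    if not records:
        raise ValueError(f"{path}: Newick tree has no leaves")
    return build_tree(records)
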