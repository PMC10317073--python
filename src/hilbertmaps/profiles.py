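"""Abundance matrices, normalization and the labeled (condition) ordering.

The input is a labeled ``m x n`` sample matrix ``M`` whose entry
``M[i, j]`` is the abundance of genome ``j`` in sample ``i`` -- raw read
counts or already-relative values.  Rows are normalized to relative
abundances (each row sums to 1), and a per-matrix noise threshold tau
marks the abundance below which a taxon is treated as absent for both
anchoring and coloring.

The *labeled ordering* blocks taxa by biological condition: given a
user-declared condition sequence C_1 ... C_c, each taxon anchors to the
condition where its mean relative abundance is highest (provided that
mean reaches tau); taxa most abundant in several conditions at once go
to the earliest such condition in the user's order, and taxa below tau
everywhere form a trailing "unassigned" block.  Inside every block the
taxa keep their taxonomic order, so condition neighborhoods retain a
taxonomic fine structure.

tau: the default is the reciprocal of the median per-sample read depth
when raw counts were given (one-read resolution), else an absolute
1e-5; always user-overridable and recorded in output metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .taxonomy import LinearOrder, TaxonomyTree, linearize

logger = logging.getLogger("hilbertmaps")

__all__ = [
    "AbundanceMatrix",
    "ConditionDesign",
    "ConditionAnchors",
    "UNASSIGNED",
    "DEFAULT_TAU",
    "read_abundance",
    "normalize",
    "condition_means",
    "labeled_order",
]

#: Label of the trailing block for taxa below the noise threshold everywhere.
UNASSIGNED = "unassigned"

#: Absolute noise-threshold default when the input is already relative.
DEFAULT_TAU = 1e-5


@dataclass
class AbundanceMatrix:
    """Samples x taxa abundance values with normalization state.

    ``values`` is a pandas DataFrame indexed by sample id with taxon-id
    columns.  ``normalized`` tells whether rows are relative abundances;
    ``tau`` is the per-matrix noise threshold (set by :func:`normalize`);
    ``zero_samples`` lists all-zero rows, which stay all-zero and are
    excluded from ordering computations.
    """

    values: pd.DataFrame
    normalized: bool = False
    tau: Optional[float] = None
    zero_samples: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float, copy=False)
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.values.index[bad[0]]!r}, "
                f"taxon {self.values.columns[bad[1]]!r}"
            )
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicated sample id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicated taxon id {dup!r}")

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def taxon_ids(self) -> List[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape

    def sample(self, sample_id: str) -> pd.Series:
        if sample_id not in self.values.index:
            raise KeyError(f"unknown sample id {sample_id!r}")
        return self.values.loc[sample_id]


@dataclass
class ConditionDesign:
    """Sample -> condition labels plus the user-declared condition order."""

    condition_of: Dict[str, str]
    order: Tuple[str, ...]

    def __post_init__(self) -> None:
        self.order = tuple(self.order)
        if len(set(self.order)) != len(self.order):
            raise ValueError(f"condition order has duplicates: {self.order}")
        declared = set(self.order)
        for sid, cond in self.condition_of.items():
            if cond not in declared:
                raise ValueError(
                    f"sample {sid!r} has condition {cond!r} which is not in "
                    f"the declared order {self.order}"
                )

    def samples_of(self, condition: str) -> List[str]:
        return [s for s, c in self.condition_of.items() if c == condition]


@dataclass
class ConditionAnchors:
    """Per-taxon anchor condition and per-condition mean abundances.

    ``means`` is a conditions x taxa DataFrame of arithmetic mean relative
    abundances; ``anchor`` maps each taxon to its anchor condition (or
    :data:`UNASSIGNED`); ``score`` is the anchoring mean (>= tau when
    assigned).
    """

    means: pd.DataFrame
    anchor: Dict[str, str]
    score: Dict[str, float]
    tau: float


# ---------------------------------------------------------------------------
# I/O

_SPARSE_COLS = {"sample_id", "taxon_id"}


def read_abundance(path: Union[str, Path]) -> AbundanceMatrix:
    """Read an abundance table, wide or sparse.

    Wide format: rows = samples, header row of taxon ids, first column
    the sample id.  Sparse (BIOM-style triplet) format: exactly three
    columns headed ``sample_id``, ``taxon_id`` and a value column;
    missing pairs are zero.  Raw counts are accepted and marked
    unnormalized.  TSV by default; ``.csv`` switches to commas.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: unparseable abundance table: {exc}") from exc
    if df.shape[1] == 3 and _SPARSE_COLS.issubset(df.columns):
        value_col = next(c for c in df.columns if c not in _SPARSE_COLS)
        vals = pd.to_numeric(df[value_col], errors="raise")
        trip = df.assign(**{value_col: vals})
        dup = trip.duplicated(subset=["sample_id", "taxon_id"])
        if dup.any():
            r = trip[dup].iloc[0]
            raise ValueError(
                f"{path}: duplicate triplet for sample {r['sample_id']!r}, "
                f"taxon {r['taxon_id']!r}"
            )
        wide = trip.pivot(index="sample_id", columns="taxon_id", values=value_col)
        wide = wide.fillna(0.0)
        wide.index.name = None
        wide.columns.name = None
        return AbundanceMatrix(values=wide.astype(float))
    # wide format: first column holds sample ids
    first = df.columns[0]
    if df[first].duplicated().any():
        dup = df[first][df[first].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated sample id {dup!r}")
    wide = df.set_index(first)
    wide.index.name = None
    try:
        wide = wide.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric abundance value: {exc}") from exc
    arr = wide.to_numpy(dtype=float)
    if np.argwhere(arr < 0).size:
        i, j = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"{path}: negative value at sample {wide.index[i]!r}, "
            f"taxon {wide.columns[j]!r}"
        )
    return AbundanceMatrix(values=wide.astype(float))


# ---------------------------------------------------------------------------
# normalization


def normalize(
    matrix: AbundanceMatrix, tau: Optional[float] = None
) -> AbundanceMatrix:
    """Row-normalize to relative abundances and fix the noise threshold.

    Each row is divided by its row sum (idempotent on already-normalized
    input).  All-zero rows stay all-zero, are flagged on the result and
    excluded from ordering computations.  ``tau`` overrides the default
    threshold rule.
    """
    df = matrix.values.astype(float)
    row_sums = df.sum(axis=1)
    zero_rows = row_sums == 0
    if zero_rows.any():
        for sid in df.index[zero_rows]:
            logger.warning("sample %r has zero total abundance; excluded from ordering", sid)
    if tau is None:
        if matrix.tau is not None:
            tau = matrix.tau
        elif not matrix.normalized and _looks_like_counts(df, row_sums):
            depths = row_sums[~zero_rows]
            tau = float(1.0 / np.median(depths)) if len(depths) else DEFAULT_TAU
        else:
            tau = DEFAULT_TAU
    safe = row_sums.replace(0, 1.0)
    out = df.div(safe, axis=0)
    out[zero_rows] = 0.0
    return AbundanceMatrix(
        values=out,
        normalized=True,
        tau=float(tau),
        zero_samples=tuple(df.index[zero_rows]),
    )


def _looks_like_counts(df: pd.DataFrame, row_sums: pd.Series) -> bool:
    # raw count matrices have row sums well above 1
    return bool((row_sums > 1.5).any())


# ---------------------------------------------------------------------------
# labeled ordering


def condition_means(
    matrix: AbundanceMatrix, design: ConditionDesign
) -> ConditionAnchors:
    """Per-taxon per-condition mean relative abundance and anchors.

    For each taxon the anchor is the condition with the maximal mean,
    provided that mean reaches tau; ties across conditions resolve to the
    earliest condition in the user-declared order.  Taxa below tau in
    every condition are unassigned.
    """
    if not matrix.normalized:
        raise ValueError("matrix must be normalized before computing anchors")
    tau = matrix.tau if matrix.tau is not None else DEFAULT_TAU
    df = matrix.values
    usable = [s for s in df.index if s not in matrix.zero_samples]
    unlabeled = [s for s in usable if s not in design.condition_of]
    if unlabeled:
        raise ValueError(f"unlabeled sample(s): {unlabeled}")
    rows = {}
    for cond in design.order:
        samples = [s for s in usable if design.condition_of[s] == cond]
        if not samples:
            raise ValueError(f"condition {cond!r} has no samples")
        rows[cond] = df.loc[samples].mean(axis=0)
    means = pd.DataFrame(rows).T.loc[list(design.order)]
    arr = means.to_numpy()
    anchor: Dict[str, str] = {}
    score: Dict[str, float] = {}
    for j, tid in enumerate(means.columns):
        col = arr[:, j]
        best = int(np.argmax(col))  # argmax takes the first max: the tie rule
        if col[best] >= tau:
            anchor[tid] = design.order[best]
            score[tid] = float(col[best])
        else:
            anchor[tid] = UNASSIGNED
            score[tid] = float(col[best])
    return ConditionAnchors(means=means, anchor=anchor, score=score, tau=float(tau))


def labeled_order(
    matrix: AbundanceMatrix,
    design: ConditionDesign,
    taxonomy: TaxonomyTree,
    child_order: str = "size-desc",
) -> LinearOrder:
    """The condition-anchored linear order of the collection's taxa.

    Taxa are blocked by anchor condition following the user's condition
    order, with a trailing block for unassigned taxa; within every block
    taxa follow the taxonomic order.  Group annotations are the condition
    blocks (grouping key ``"condition"``).
    """
    anchors = condition_means(matrix, design)
    taxo = linearize(taxonomy, child_order=child_order)
    known = set(anchors.anchor)
    missing = [t for t in taxo.taxa if t not in known]
    if missing:
        raise ValueError(
            f"taxa present in the taxonomy but absent from the abundance "
            f"matrix: {missing[:5]}{'...' if len(missing) > 5 else ''}"
        )
    taxa: List[str] = []
    runs: List[Tuple[str, int, int]] = []
    for cond in list(design.order) + [UNASSIGNED]:
        start = len(taxa)
        taxa.extend(t for t in taxo.taxa if anchors.anchor[t] == cond)
        if len(taxa) > start:
            runs.append((cond, start, len(taxa)))
    return LinearOrder(
        taxa=taxa,
        groups={"condition": runs},
        provenance=f"labeled:{','.join(design.order)};tau={anchors.tau!r}",
    )
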