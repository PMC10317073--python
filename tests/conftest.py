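"""Shared fixtures: small synthetic collections built programmatically."""

import pytest

from hilbertmaps import (
    AbundanceMatrix,
    ConditionDesign,
    FixtureSpec,
    TaxonRecord,
    build_layout,
    build_tree,
    linearize,
    make_taxonomy,
    normalize,
)

import pandas as pd


@pytest.fixture
def records16():
    """2 genera x 2 species x 4 strains = 16 leaf records."""
    return make_taxonomy(FixtureSpec(n_genera=2, species_per_genus=2,
                                     strains_per_species=4))


@pytest.fixture
def tree16(records16):
    return build_tree(records16)


@pytest.fixture
def order16(tree16):
    return linearize(tree16)


@pytest.fixture
def layout16(order16):
    return build_layout(order16)


@pytest.fixture
def two_condition_matrix():
    """Hand-built 4-sample, 2-condition matrix over taxa A..D.

    Rows are already relative (sum to 1).  Hand-computed condition means:
        A: C1 = 0.30, C2 = 0.10
        B: C1 = 0.05, C2 = 0.40
        C: C1 = 0.45, C2 = 0.45   (tie -> first condition)
        D: C1 = 0.20, C2 = 0.05   (anchors to C1 unless tau > 0.20)
    """
    values = pd.DataFrame(
        {
            "A": [0.35, 0.25, 0.05, 0.15],
            "B": [0.05, 0.05, 0.40, 0.40],
            "C": [0.40, 0.50, 0.50, 0.40],
            "D": [0.20, 0.20, 0.05, 0.05],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    matrix = normalize(AbundanceMatrix(values=values), tau=0.01)
    design = ConditionDesign(
        condition_of={"s1": "C1", "s2": "C1", "s3": "C2", "s4": "C2"},
        order=("C1", "C2"),
    )
    return matrix, design


@pytest.fixture
def abcd_tree():
    """Flat taxonomy over the A..D taxa of the hand-built matrix."""
    recs = [
        TaxonRecord(taxon_id=t, lineage=(("genus", "G"), ("species", t)))
        for t in ["A", "B", "C", "D"]
    ]
    return build_tree(recs)
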