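"""Synthetic taxonomies and abundance profiles with known ground truth.

Real reference collections and cohort profiles are large downloads;
this module generates structurally equivalent inputs so the whole
pipeline is exercisable offline.  Taxonomies are balanced
genus/species/strain hierarchies with systematic names; profiles draw
per-taxon abundances from a log-normal background (mimicking the
right-skew of real microbiome abundance distributions) and boost each
condition's designated *signature taxa* by a multiplicative effect size,
so condition-anchoring can be scored against known truth.  A fixed seed
gives bit-identical output.

What this does not emulate: ecological covariance between taxa,
sequencing depth variation, or compositional artefacts -- recovery rates
measured here speak to the ordering machinery, not to any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .profiles import AbundanceMatrix, ConditionDesign, normalize
from .taxonomy import TaxonRecord

__all__ = ["FixtureSpec", "make_taxonomy", "make_profiles"]


@dataclass(frozen=True)
class FixtureSpec:
    """Shape and signal parameters for one synthetic dataset.

    ``effect_size`` is the ratio of a signature taxon's expected raw
    abundance in its own condition to the background expectation; 1.0
    means no signal.  ``dispersion`` is the sigma of the log-normal
    background.  ``n_signature`` signature taxa are drawn per condition,
    disjointly, at random under ``seed``.
    """

    n_genera: int = 2
    species_per_genus: int = 2
    strains_per_species: int = 4
    conditions: Tuple[str, ...] = ("control", "case")
    samples_per_condition: int = 3
    n_signature: int = 3
    effect_size: float = 10.0
    dispersion: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genera", "species_per_genus", "strains_per_species",
                     "samples_per_condition", "n_signature"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        if not self.conditions:
            raise ValueError("at least one condition is required")
        n = self.n_genera * self.species_per_genus * self.strains_per_species
        if self.n_signature * len(self.conditions) > n:
            raise ValueError(
                f"{self.n_signature} signature taxa x {len(self.conditions)} "
                f"conditions exceed the {n} taxa available"
            )

    @property
    def n_taxa(self) -> int:
        return self.n_genera * self.species_per_genus * self.strains_per_species


def make_taxonomy(spec: FixtureSpec) -> List[TaxonRecord]:
    """Balanced genus/species/strain records with systematic names."""
    records: List[TaxonRecord] = []
    for g in range(spec.n_genera):
        genus = f"Genus_{g + 1:04d}"
        for s in range(spec.species_per_genus):
            species = f"{genus}_sp{s + 1:02d}"
            for t in range(spec.strains_per_species):
                strain = f"{species}_st{t + 1:02d}"
                records.append(
                    TaxonRecord(
                        taxon_id=strain,
                        lineage=(
                            ("genus", genus),
                            ("species", species),
                            ("strain", strain),
                        ),
                    )
                )
    return records


def make_profiles(
    spec: FixtureSpec, taxonomy: Sequence[TaxonRecord]
) -> Tuple[AbundanceMatrix, ConditionDesign, Dict[str, str]]:
    """Log-normal profiles with per-condition signature taxa.

    Returns the row-normalized matrix, the condition design, and the
    ground-truth map signature-taxon -> condition for recovery scoring.
    Signature sets are disjoint across conditions.  The background draw
    is independent of ``effect_size`` (signatures are boosted
    multiplicatively afterwards), so on a fixed seed raising the effect
    size can only sharpen the signal -- recovery is monotone in it.
    """
    if spec.samples_per_condition < 1:
        raise ValueError("need at least one sample per condition")
    taxon_ids = [rec.taxon_id for rec in taxonomy]
    if len(set(taxon_ids)) != len(taxon_ids):
        raise ValueError("duplicate taxon ids in taxonomy")
    rng = np.random.default_rng(spec.seed)

    # disjoint signature sets, one per condition
    shuffled = list(taxon_ids)
    rng.shuffle(shuffled)
    truth: Dict[str, str] = {}
    pos = 0
    for cond in spec.conditions:
        for tid in shuffled[pos : pos + spec.n_signature]:
            truth[tid] = cond
        pos += spec.n_signature

    sample_ids: List[str] = []
    condition_of: Dict[str, str] = {}
    rows = []
    n = len(taxon_ids)
    col = {t: j for j, t in enumerate(taxon_ids)}
    for cond in spec.conditions:
        boost = np.ones(n)
        for tid, c in truth.items():
            if c == cond:
                boost[col[tid]] = spec.effect_size
        for r in range(spec.samples_per_condition):
            sid = f"{cond}_s{r + 1:02d}"
            sample_ids.append(sid)
            condition_of[sid] = cond
            background = rng.lognormal(mean=0.0, sigma=spec.dispersion, size=n)
            rows.append(background * boost)

    values = pd.DataFrame(np.array(rows), index=sample_ids, columns=taxon_ids)
    matrix = normalize(AbundanceMatrix(values=values))
    design = ConditionDesign(condition_of=condition_of, order=spec.conditions)
    return matrix, design, truth
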