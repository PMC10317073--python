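# hilbertmaps

**Microbiome maps: Hilbert-curve visualization of metagenomic abundance
profiles.**

Metagenomic profiling (mWGS or 16S) produces a samples × taxa matrix of
relative abundances over a reference collection that can hold tens of
thousands of genomes. Bar charts and line plots collapse at that scale:
dominant taxa crowd out everything else and taxonomic structure is
invisible. `hilbertmaps` renders each sample instead as a **microbiome
map** — a square image in which every genome occupies one cell (or a
small merged run of cells) of a 2^k × 2^k grid, placed along a Hilbert
space-filling curve, with the cell's intensity encoding the genome's
relative abundance. Because the Hilbert curve is continuous and
locality-preserving, any contiguous block of the underlying 1D ordering
becomes a connected 2D region — a *microbial neighborhood* — so clades
or condition-associated taxa stay visually grouped, and "hotspots" of
abundant microbes can be read off at a glance.

It is intended for microbiome researchers who already have abundance
tables (e.g. from Kraken 2-style profilers) and want scalable,
deterministic, batch-renderable images for exploration, comparison over
time or condition, and featurization in machine-learning pipelines.

## Method

1. **Hilbert curve** (`hilbert`). Exact integer index ↔ cell conversion
   at any level k by iterative bitwise quadrant transforms. The level-k
   curve visits all 4^k cells of the grid, consecutive indices always in
   edge-adjacent cells. The base orientation is fixed: origin top-left,
   level-1 order (0,0) → (0,1) → (1,1) → (1,0).
2. **Linear ordering**. Two schemes:
   - *Taxonomic* (`taxonomy`): build a taxonomy tree from rank lineages
     (genus → species → strain, or shallower for 16S), then traverse it
     depth-first with a deterministic child order (larger clades first,
     ties lexicographic). Every clade's leaves form a contiguous run.
   - *Labeled* (`profiles`): given a labeled m × n matrix M (M[i,j] =
     abundance of genome j in sample i) and a user-declared condition
     sequence C_1 … C_c, each taxon is anchored to the condition where
     its mean relative abundance is highest (if ≥ the noise threshold
     τ); ties go to the earliest condition; sub-τ taxa form a trailing
     unassigned block; within blocks, taxonomic order applies.
3. **Segment merging** (`layout`). With n taxa and 4^k curve segments,
   adjacent segments are merged so region count equals n: each taxon
   gets ⌊4^k/n⌋ or ⌈4^k/n⌉ consecutive indices (earlier taxa take the
   remainder). An optional gap policy instead reserves blank cells so
   each group starts at an aligned subsquare boundary, leaving room for
   future additions.
4. **Rendering** (`render`). Single-sample, colorless (reference-only),
   average, aggregate, differential (signed, diverging, zero-centered)
   and animation-frame maps, with neighborhood boundary outlines and
   curve-path overlay; PNG/SVG/GIF export with sidecar JSON metadata.

## Worked example

Generate a small synthetic dataset (2 genera × 2 species × 4 strains,
two conditions × 3 samples) and render one map per sample:

```sh
hilbertmaps fixtures --genera 2 --species 2 --strains 4 --samples 3 \
    --seed 7 --out demo/data
hilbertmaps render --taxonomy demo/data/taxonomy.tsv \
    --abundance demo/data/abundance.tsv \
    --boundaries --grouping genus --out demo/maps
```

The run logs its decision values and outputs:

```
INFO noise threshold tau = 1.0000000000000001e-05
INFO layout: level k=2 (16 cells for 16 taxa), gaps=off, orientation=top-left-U
INFO wrote demo/maps/control_s01.png
...
INFO wrote demo/maps/layout.tsv
```

16 taxa fit a level-2 grid exactly (4^2 = 16 cells, one per strain), so
each genus occupies one connected 8-cell neighborhood and each species
one 4-cell neighborhood. The exported `layout.tsv` pins the geometry so
other samples or studies can be rendered onto identical coordinates:

```
# hilbertmaps layout level=2 orientation=top-left-U provenance=taxonomic:size-desc
taxon_id              d_start  d_end  x_start  y_start  groups
Genus_0001_sp01_st01  0        0      0        0        genus=Genus_0001;...
Genus_0001_sp01_st02  1        1      1        0        genus=Genus_0001;...
```

The same data under the labeled ordering (via the library):

```python
from hilbertmaps import *

spec = FixtureSpec(n_genera=2, species_per_genus=2, strains_per_species=4, seed=7)
records = make_taxonomy(spec)
matrix, design, truth = make_profiles(spec, records)
order = labeled_order(matrix, design, build_tree(records))
print(order.runs("condition"))
# [('control', 0, 4), ('case', 4, 14), ('unassigned', 14, 16)]
```

Each condition block is a contiguous run (hence a connected map region);
the two taxa whose mean relative abundance stays below τ in every
condition trail in the unassigned block.

Other subcommands: `build-layout` (export a reusable layout TSV),
`diff` (signed differential map of two samples), `animate` (GIF/MP4
over a sample series with a shared global intensity scale), `curve`
(dump the raw Hilbert path as a d/x/y table).

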