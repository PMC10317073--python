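# Methods

## Model and procedure

A microbiome map is a deterministic function of three inputs: a
reference collection with rank lineages, a 1D linear order over that
collection, and per-sample relative abundance vectors. The pipeline is

    lineages ──► taxonomy tree ──► linear order ──► Hilbert layout ──► raster
    abundance matrix ──► normalize ──► (labeled order) ──► intensities

Its central assumption is that *proximity in the chosen 1D order is the
relationship worth preserving in 2D*. The Hilbert curve guarantees
exactly that: it is a bijection between curve indices 0 … 4^k − 1 and
the cells of a 2^k × 2^k grid in which consecutive indices are always
edge-adjacent, so every contiguous index interval maps to a 4-connected
region. Clades (taxonomic ordering) and condition blocks (labeled
ordering) are contiguous intervals by construction, hence connected
"microbial neighborhoods" in the image.

### Curve arithmetic

Index ↔ cell conversion is done with the standard iterative bitwise
quadrant-transform algorithm (Gray-code quadrant selection plus
reflection/transposition per level), O(k) per conversion with pure
integer arithmetic, so level-10+ grids are cheap. The recursive
definition — four copies of the level-(k−1) curve, the first
transposed, the last anti-transposed, glued in the level-1 "U" order —
is implemented independently in the test suite as a brute-force
enumerator and the two are checked cell-for-cell for k ≤ 5, alongside
bijectivity, unit-step continuity and quadrant-nesting property tests
for k ≤ 6.

Orientation is a free choice (rotating or reflecting the curve yields
an equally valid map); it is fixed once — origin top-left, level-1
visiting order (0,0) → (0,1) → (1,1) → (1,0) — and stamped into every
exported metadata file so layouts are portable across runs and tools.

### Taxonomic ordering

Trees have no intrinsic child order, and the database-specific order
used by upstream genome databases is not reproducible offline, so the
package declares its own deterministic rule: children sorted by
descending leaf count, ties broken lexicographically by name
(`size-desc`, the default; `lexicographic` is available). Descending
size keeps the large neighborhoods compact and makes the output a pure
function of tree *content* — shuffling input rows changes nothing.
Records missing an intermediate rank get a synthetic
`<parent>__unranked` placeholder node so clade contiguity survives
ragged lineage tables. The leaf rank is data-driven: strain-level
tables produce strain leaves, 16S-style tables stop at species or
genus.

### Normalization and the noise threshold τ

Rows of the abundance matrix are divided by their sums (idempotent on
already-relative input; all-zero rows are flagged, kept zero, and
excluded from ordering computations). τ is the relative abundance below
which a taxon is treated as absent, both for condition anchoring and
for coloring. Default rule: when the input looks like raw counts (row
sums ≫ 1), τ = 1 / median per-sample depth — one-read resolution; for
already-relative input, an absolute 1e−5. Always user-overridable,
always recorded in output metadata.

### Labeled ordering

Per taxon and condition, the arithmetic mean of row-normalized relative
abundances over that condition's samples (whether the original method
re-normalizes within condition is unstated; plain row-normalized means
are used and documented here — the anchoring metric is a pluggable
choice). A taxon anchors to the condition with the maximal mean if that
mean ≥ τ; exact ties resolve to the earliest condition in the
user-declared order; taxa below τ everywhere form the trailing
unassigned block. Within every block, the taxonomic order applies —
also the tie-break for equal means inside a block, never input file
order. Samples labeled with undeclared conditions are rejected rather
than silently appended.

### Segment merging and the gap policy

With n taxa and S = 4^k indices, balanced merging gives every taxon
⌊S/n⌋ or ⌈S/n⌉ consecutive indices; the ⌈⌉-share goes to the
earlier-ordered taxa (the remainder rule is otherwise arbitrary;
remainder-first is deterministic and keeps group starts aligned with
curve starts). Max − min interval length is therefore ≤ 1, so region
area faithfully tracks clade size.

The optional gap policy (off by default) reserves blank cells so that
each top-level group starts at the boundary of an aligned 2^g × 2^g
subsquare, with g the smallest value satisfying 4^g ≥ group size; by
the curve's nesting property such subsquares are exactly the index
blocks starting at multiples of 4^g. With gaps on, each taxon takes
exactly one cell and reserved gaps absorb all slack — merging exists to
match region count to taxon count, and reservation replaces that role.
Gap cells render in a neutral tone distinct from the colormap floor, so
"reserved" and "present but zero" never look alike.

### Rendering

Per-map max normalization by default: the most abundant taxon saturates
at intensity 1, abundances below the display floor τ render as the
zero class. The log10 scale (floor τ, requires τ > 0) is provided
because abundance distributions are heavily right-skewed and a linear
scale hides exactly the low-abundance taxa the method is meant to keep
visible. Average/aggregate maps reduce per-taxon across samples (mean,
sum, median, max) before scaling. Differential maps are signed, scaled
by the largest absolute difference onto [−1, 1], and drawn on a
diverging colormap centered at zero; metadata records the operand
order. Animation frames share one global maximum across the series so
brightness is comparable frame to frame. Default colormaps (viridis;
coolwarm for signed maps) are declared configuration, not a claim about
any original tool's palette. All exports are deterministic
(byte-identical on re-run) and carry sidecar JSON metadata with level,
orientation, scale, τ and order provenance.

## Synthetic data generator

`fixtures` emulates the *shape* of profiling studies, not their
biology: a balanced genus/species/strain hierarchy with systematic
names, and per-sample abundances drawn from a log-normal background
(σ = 1 by default, mimicking the right-skew of real profiles) with each
condition's disjoint signature-taxon set boosted by a multiplicative
effect size (default 10) before row normalization. Defaults follow the
small-cohort setting the renderer targets: 2 conditions × 3 samples.
The background draw does not consume the effect size, so on a fixed
seed raising the effect can only sharpen the signal — recovery of
signature taxa is monotone in effect size, which the suite asserts.

Not emulated: ecological covariance between taxa, depth variation
between samples, compositional artefacts, read-level noise. Passing
recovery tests therefore demonstrate that the ordering machinery turns
a known mean-abundance signal into the right condition blocks; they say
nothing about detecting real biological signatures.

## Problem sizes

The test and acceptance runs use collections of 16 (the worked
example), 5,127 and 44,048 leaves — the latter two matching the
documented 16S- and mWGS-scale reference collections, factorized as
1709 × 3 × 1 and 2753 × 2 × 8 (both counts have prime factors that
force unbalanced shapes; only the leaf count matters to the layout).
At 44,048 leaves the full tree build, linearization and layout complete
in well under a second.

Note one arithmetic consequence of minimal level selection: 5,127 taxa
need level 7 (4^6 = 4,096 < 5,127 ≤ 16,384), giving 5,127 intervals of
length 3 or 4; 44,048 taxa need level 8, giving 21,488 length-2 and
22,560 length-1 intervals covering all 65,536 cells.

## Degenerate inputs and numerical choices

- Row sums within 1e−9 of 1 count as normalized; normalization is
  exactly idempotent.
- All-zero samples: flagged, excluded from anchoring, rendered as
  all-zero-class maps.
- An all-zero or all-sub-τ sample renders every assigned cell in the
  zero class (no division by a zero maximum).
- Mean-tie resolution uses strict argmax-first semantics, so only exact
  float equality counts as a tie — matching the declared rule without
  an epsilon band.
- Capacity errors (n > 4^k) name the minimal sufficient level.

## Known limitations

- The child order of the original database-backed linearization cannot
  be reproduced offline; neighborhood adjacencies will differ from
  images produced against a live database snapshot, even though the
  contiguity and area properties are identical.
- The labeled ordering is recomputed from condition means, so adding
  samples can relocate taxa between blocks (inherent to any
  precomputed-anchor scheme); exporting and reusing `layout.tsv` is the
  supported way to freeze geometry across analyses.
- Only the Hilbert curve is implemented; other space-filling curves
  partition into more than four quadrants and produce harder-to-read
  images at high levels.
- SVG export writes one rectangle per cell; at level 8+ prefer PNG.
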