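# Methods

## Partition model

Set order is fixed by input order and defines bit positions: the first
set owns the least-significant bit, so element `x`'s label is
`a_x = Σ 2^(i−1)` over the sets containing it. Labels are equal iff the
elements occupy the same exclusive region, so the partition is computed
by one hash-table update per (set, element) pair followed by one scan of
the table — linear in total element count, never touching the `2^n`
combination space. The cap `n ≤ 31` keeps labels inside a signed 32-bit
integer and bounds export sizes; arbitrary-precision integers would allow
more, but the 8-set graphical / 31-set data-processing envelope is part
of the tool's contract and is enforced rather than silently extended.

Identifier comparison is byte-exact and case-sensitive; the only
normalisation is whitespace tokenisation at read time. Duplicates within
one file are deduplicated with a logged warning (sets have no
multiplicity); an empty input file yields an empty set with a warning,
not an error, since the set algebra remains well-defined. Label 0
(member of no set) cannot arise because elements only enter via set
files.

## Export dialects

* **Matrix** — binary incidence matrix (tab-delimited): header row of set
  names, one row per union element (sorted), cells 1/0. Flags rather
  than repeated element names were chosen because a binary incidence
  matrix is the standard input for network construction; the matrix
  round-trips losslessly back into the same partition.
* **Horizontal** — one intersection per line, `Name&Name: e1 e2`, in
  ascending label order.
* **Vertical** — a header row then one row per intersection
  (combination, exclusive count, elements). In exhaustive mode
  (`n ≤ 8`) every one of the `2^n − 1` combinations appears, so a
  six-set file always has 64 lines including the header. The horizontal
  and vertical dialects carry identical (combination, element-list)
  content and differ only in arrangement.

For 9–31 sets, exhaustive enumeration (`2^n` rows) is infeasible, so the
horizontal/vertical writers switch to a sparse mode: a comment line
(`# sparse mode: …`) followed by non-empty regions only. Output is
UTF-8 with Unix line endings; elements within a region are sorted
lexicographically; regions are ordered by ascending integer label in all
exports — all deterministic and therefore testable.

## Layout geometry

No canonical curve equations exist for these diagram families, so all
geometry constants are implementation choices validated by two
invariants: every one of the `2^n − 1` regions receives grid hits
(completeness), and every region's printed count sits at a point whose
membership bitmask equals the region label (anchor correctness).

Anchors come from classifying a regular grid (default 400×400 cell
centres over the 800×800 canvas) with closed-boundary membership
predicates. A region's anchor is the centroid of its grid hits; when the
centroid of a non-convex region falls outside it (serpentine bands,
half-frames), the fallback is the region's deepest sample point — the
argmax of the Euclidean distance transform over the region's mask, a
grid approximation of the pole of inaccessibility — which always passes
the membership test.

**Classic.** Circles for 1–3 sets; Venn's four-ellipse construction and
the symmetric five-ellipse family (congruent ellipses rotated in 72°
steps) with the widely used parameterisation, converted to y-down SVG
coordinates.

**Edwards.** Left and bottom half-frames, a central circle (r = 190),
and serpentine bands for sets 4–6. A band is a lobed annulus: inside iff
the polar radius lies between `r_in` and a square-wave outer boundary
alternating between `r_out` (tooth) and `r_in` (gap) over 2, 4 and 8
periods. Tooth transitions are phase-shifted by half a tooth per
frequency doubling (−π/4, −π/8, −π/16), so within every quadrant the
on/off states of the three bands run through a full 3-bit counter; with
band depths nested (80/50/25 canvas units about the circle boundary) the
radial strata then realise every membership combination — this is what
makes all 63 six-set regions non-empty. The exact cogwheel curves of the
historical construction are not parameterised anywhere; the lobed
annulus is a visually equivalent stand-in with a closed-form predicate.

**Nested.** The first four sets form the outer Classic diagram, the
remaining 1–4 sets the inner group (mirroring the published eight-sample
use of the layout; for n < 8 the inner group is simply smaller). Outer
bits occupy the low positions of the full label, inner bits the high
ones. Each outer region hosts a miniature of the inner diagram, scaled
to a disc of 0.8 × the region's clearance at its deepest point, so the
miniature provably stays inside its host; one standalone copy sits
outside all outer curves (capped at radius 150) and hosts the
inner-only combinations. The "host sets only" count (inner bits 0) is
placed at a deep grid point of the host region outside its miniature
disc. Miniature discs in distinct regions are pairwise disjoint by
construction and asserted in tests. Every anchor is re-verified against
the composite membership function (outer shapes directly; inner shapes
through the placement's inverse transform) before the layout is
returned.

The `auto` layout is Classic for up to 4 sets and Nested for 5–8, since
nested regions stay legible where five-set ellipse slivers and high-lobe
cogwheels do not; Classic (≤ 5) and Edwards (≤ 6) remain selectable.

## SVG output

Standalone SVG 1.1, UTF-8, viewBox, no external resources. One filled
element per set curve at opacity 0.4 (default palette: Paul Tol's muted
scheme, 8 colourblind-safe fills, cycled with a warning if shorter than
the set count); serpentine bands are sampled closed paths with vertices
at tooth transitions. Each region count is a text element with stable id
`region-<label>` and an embedded `<title>` tooltip naming the
combination — the scripted analog of clicking/hovering numbers in a GUI,
and the hook for post-processing exported diagrams. Zero counts are
omitted unless requested. Counts are printed without thousands
separators for locale-free downstream parsing. Rendering is
deterministic: fixed element order and fixed two-decimal coordinate
formatting give byte-identical documents for identical inputs.

## Synthetic data

The fixture generator stands in for real gene lists (the tool's inputs
are typically DE-gene lists from RNA-seq contrasts or gene sets lifted
from genome annotations). Two modes:

* **Prescribed structure** — a table mapping region labels to counts;
  region `L` of size `k` receives `k` fresh identifiers placed in
  exactly the sets of `L`, so the generated collection's partition
  equals the table by construction. This is how "every combination
  populated" inputs are made.
* **Random fill** — each of `n_elements` (default 200) identifiers joins
  each set independently with probability `density` (default 0.3),
  giving naturalistic overlap for property tests.

Both are deterministic given a seed. Identifiers are synthetic tokens
(`g<label>_<index>_<seed-suffix>`), not real gene vocabularies, and no
expression values are modelled: passing tests demonstrate the
correctness of the partition/layout/export machinery on arbitrary
identifier sets, not anything about a particular biological dataset.
Published applications of this diagram style report dataset-specific
numbers (e.g. tens of thousands of genes shared across eight RNA-seq
samples); those depend on external data and are out of scope here.

The independent correctness oracle recomputes the partition for every
non-empty subset S of sets as `⋂_{i∈S} A_i ∖ ⋃_{j∉S} A_j` using only
set intersection/complement — no bitmasks — and is compared against the
hash-table classifier on hundreds of seeded random collections
(exponential in n, hence capped at n ≤ 12, test scale).

## Problem sizes and tolerances

Tests run at the scale the guarantees are exact at: grid resolution 400
(one cell ≈ 2 canvas units; anchor symmetry assertions use a 2-cell
tolerance, area convergence under 10% between 200 and 400), random
fixtures of 40–120 elements, 200 oracle trials over 1–10 sets, and the
full 7-set (127-region) and 8-set (255-region) layouts. All headline
checks are exact integer equalities (127 regions, 64 lines, 31 sets);
nothing is estimated stochastically.

## Known limitations

* Areas are not proportional to counts (no Euler/area-proportional
  layout), and region areas are grid estimates, not analytic.
* Identifier matching is exact; no fuzzy matching or case folding.
* The nested grouping is fixed (first four sets outer); no automatic
  search for the most legible grouping.
* No raster output; SVG only.
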