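# Methods

## The anatogram model

An *anatogram* maps a quantitative per-tissue value onto a pictographic
body diagram.  The unit of display is a **view**: a base raster image in
which every tissue region is flat-filled with a unique *key colour*,
plus an XML control file assigning each key colour a tissue name, the
replicate sample IDs pooled into that tissue, an optional repository
record (GEO/ArrayExpress accession) and an optional centroid for
tooltip anchoring.  Rendering replaces exactly the pixels matching each
key colour with the colour computed for that tissue; every other pixel
passes through bit-for-bit.  This key-colour encoding was chosen over
polygon outlines because it validates trivially (does the image contain
at least one pixel of each declared colour?) and because views can then
be authored in any paint program — the only constraint is that region
fills must not be anti-aliased, which the shipped XSD documents.
Coordinates are 0-based with the origin at the top-left.

For a query the pipeline is: resolve the identifier → pick one
measurement row → summarize per tissue → map summaries to colours →
recolour, then emit the legend, the companion table, a bar chart, and
an HTML image map.

## Identifier resolution and probe-set selection

A query may be a probe-set ID, an Entrez ID, or a gene symbol, matched
in that priority order; symbols match case-insensitively, the other two
exactly.  A matched record returns *all* of its probe sets.  When a
gene has several probe sets and the user does not force one, the row
with the highest grand mean over non-missing cells is displayed, with
lexicographic tie-breaking.  This "strongest signal" default mirrors
what users expect a browser to show for a well-measured gene, and is
overridable per query.  Probe sets listed in the lookup but absent from
the active platform's matrix are dropped with a warning rather than an
error — one lookup table serves every platform in the catalog.

## Per-tissue statistics

Each tissue's value is the arithmetic mean of its non-missing replicate
samples; dispersion is the sample standard deviation (n−1 denominator),
defined as 0 for a single replicate.  Missingness is explicit: blank or
`NA` cells, and samples named in a view but absent from the matrix,
propagate as "no data" (never as 0) and render in a light grey.  A view
containing samples the current matrix lacks is therefore usable, which
lets one catalog serve subsets of a compendium.  Replicates are averaged
*after* probe-set selection.

## Colour mapping

The three modes share sentinel colours: yellow `(255,255,0)` anchors
both ramps, red `(255,0,0)` is the high endpoint, blue `(0,0,255)` the
low endpoint, light grey `(221,221,221)` marks missing data, mid grey
`(160,160,160)` marks masked (undefined-ratio) tissues.  All five are
overridable but must stay distinct.

- **Absolute.** fraction = min(mean / M, 1) with M the view's maximal
  tissue mean, or a user cap; colour = linear interpolation
  yellow→red.  M = 0 (silent gene) leaves every tissue yellow.
- **Relative.** control c = median of the non-missing *tissue means*
  (even count: mean of the two central values); value = log2(mean / c).
  Positive values interpolate yellow→red, negative yellow→blue, zero is
  exact yellow.  Saturation S defaults to the largest |log2 ratio| in
  the view ("auto"), so at least one tissue reaches a ramp endpoint; a
  numeric cap in log2 units is accepted instead.  Tissues with mean 0
  are masked; c = 0 masks the whole view's ratios.
- **Compare.** value = log2(primary mean / secondary mean) per tissue,
  coloured with the Relative rule; a tissue is masked when either
  gene's mean is zero or missing.

Ratios are log2-transformed so k-fold up and k-fold down sit
symmetrically on the two ramps.  The median is taken over tissue means
rather than individual samples — consistent with treating the tissue,
not the array, as the display unit after replicate averaging; with
balanced replication the two definitions coincide.  Channel
interpolation rounds half-up to integers, making every colour
assignment bit-exact and testable; the test suite checks the engine
against an independently written sort/median/log2/interpolate oracle.

## Array scaling

Microarray signal is made comparable across arrays by the scaling
convention of the MAS 5 pipeline: each array (column) is multiplied by
`target / trimmed_mean(column)` so its two-sided trimmed mean equals a
common target, default 100 signal units.  The trimmed mean sorts the
column, removes `floor(n · trim_fraction)` entries from each tail
(default fraction 0.02), and averages the remainder; implementations of
this step differ in tail-count rounding, and flooring per tail is the
convention here.  Scaling is idempotent, preserves within-column
ratios, keeps missing cells missing, and a non-positive trimmed mean is
a hard error naming the sample.  Probe-level processing (background
correction, mismatch handling, biweight summarization) and RNA-seq
FPKM quantification are upstream of this package: it ingests
already-summarized tables.

## Outputs

The bundle contains the recoloured PNG (always PNG, though Targa is
accepted on input), a legend strip (one 511-pixel ramp for Absolute;
a blue–yellow–red double ramp labelled −S…0…+S in log2 units for the
ratio modes, centre pixel exactly yellow), a CSV table with one row per
tissue (mean, SD, fold change, log2 value, assigned colour, record ID;
two decimals, `NA` for undefined), a horizontal bar chart with bars in
view order filled with each tissue's assigned colour, and an HTML
fragment holding the image map plus gene link-outs (BioGPS, NCBI Gene,
UniProt, EBI, GeneMANIA; URL templates configurable).  Clickable areas
are fixed-radius circles at the declared centroids — raster-to-polygon
tracing is a known limitation, and groups without a centroid are
reachable through the table.  Tooltips show "name: mean (±sd)" in
Absolute mode and "name: k-fold up/down" in the ratio modes; the exact
wording is this package's convention.  The header reports the (view,
tissue) with the globally maximal mean among same-platform views, ties
broken by catalog then view order, and repeats the view's
platform-comparability note when present.  Rendering is deterministic:
identical inputs give byte-identical CSV and pixel-identical PNGs.

## Synthetic fixtures

The fixture generator stands in for a multi-study expression
compendium.  Anatomy is geometric (non-overlapping rectangles on white,
one key colour each) because the engine is artwork-agnostic and real
anatomical artwork is not redistributable.  Expression replicates are
drawn as `max(0, Normal(mean, noise_sd))` from a per-gene, per-tissue
pattern with a seeded generator; the default demo uses 3 replicate
arrays per tissue and a 5% coefficient of variation, toy-scale values
chosen to look like MAS5-scaled signal around a target of 100.  Marker
genes follow textbook biology in shape (insulin confined to islet
cells, SIX3 in basal forebrain structures, CAMK2B neural with some
skeletal muscle, albumin hepatic, GAPDH ubiquitous) so qualitative
patterns — "exactly one region turns red" — are predictable.  The demo
catalog mirrors the compendium facts of the data it emulates: five
microarray views, an 11-entry source-accession list in the metadata,
and a 16-sample RNA-seq body-map view (the public Body Map 2.0 tissue
panel) carrying a cross-platform comparability note.

What the fixtures do not emulate: batch effects between studies,
probe-level artefacts, heavy-tailed or count-based noise, correlated
genes, and real anatomy.  Passing tests therefore demonstrate the
correctness of the mapping and rendering machinery, not robustness to
real-world normalization problems.

The truncation at zero biases recovered means upward by an amount that
is negligible when mean/sd ≥ 3 (the demo's regime); the noisy-recovery
test uses the 3·sd/√n band, which absorbs this at its sample sizes.

## Numerical and degenerate-input choices

- Interpolation fractions outside [0, 1] are errors; means above an
  Absolute-mode cap clamp to 1.
- Sample SD of a single replicate is 0, not undefined, matching common
  expression-tool convention.
- Grand-mean ties in probe-set selection break lexicographically;
  maximal-tissue ties break by catalog, then view, order.
- Zero expression in the ratio modes masks the tissue (grey) rather
  than rendering −∞ on the blue ramp.
- Trimmed-mean tail counts floor; trim_fraction must lie in [0, 0.5).
- Empty expression vectors, duplicate IDs, non-numeric cells, malformed
  or duplicate key colours are hard errors that name the offender;
  missing data is never an error.

## Problem sizes

The shipped demo runs at toy scale — 26 microarray tissues × 3
replicates plus 16 RNA-seq samples, 5 genes, images of roughly
260 × 200 px — which exercises every code path while keeping the whole
suite and the reproduction script fast on a single CPU.  The scaling
check uses 100 genes × 20 arrays, ample for a per-column statistic that
is exact by construction.
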