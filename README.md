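# anatogram

Paint gene-expression levels onto pictographic anatomy views.

Bar charts and heatmaps of a tissue compendium force the reader to map
cryptic sample names onto body parts in their head.  An *expression
anatogram* does that mapping visually: every tissue region of a body
diagram is coloured by the query gene's expression level, so "where is
this gene expressed?" is answered at a glance.  `anatogram` is a
library plus a small CLI for building such views over any expression
compendium — microarray signal or RNA-seq FPKM — given three plain-text
inputs: an expression table, a gene lookup table, and an XML view
definition over a key-coloured anatomy image.

## The model

For a gene *g* and a view with tissues *t₁…tₙ* (each the mean *eᵢ* of
its replicate samples), three interpretation modes are supported:

- **Absolute** — colour tissue *i* by *eᵢ / M* on a yellow→red ramp,
  where *M* = maxᵢ *eᵢ* (or a user cap). Yellow = no expression,
  red = view maximum.
- **Relative** — colour by log₂(*eᵢ / c*) where the control level *c*
  is the **median** of the tissue means in the view: yellow→red above
  control, yellow→blue below, exact yellow at *c*.
- **Compare** — colour by log₂(*eᵢᵖ / eᵢˢ*) for a primary and a
  secondary gene, with the Relative colour rule.

Arrays are made comparable beforehand by trimmed-mean scaling (the
scaling step of the MAS 5 convention): each array is multiplied by
*target / TM₀.₀₂(array)* so its two-sided 2% trimmed mean equals a
common target, default 100.

Tissue regions are identified by unique *key colours* painted flat into
the base image; rendering replaces exactly those pixels and nothing
else.  Outputs per query: recoloured PNG, legend, bar chart, CSV table
(mean, SD, fold change, log₂ ratio, colour per tissue), and an HTML
image map with per-tissue tooltips, GEO/ArrayExpress record links, and
gene link-outs (BioGPS, NCBI Gene, UniProt, EBI, GeneMANIA).

## Worked example

The package ships a synthetic demo compendium (five microarray views
plus a 16-sample RNA-seq body-map view; see `docs/methods.md` for what
it does and does not emulate):

```sh
anatogram fixtures --out demo
anatogram render --catalog demo/catalog.json --gene INS \
    --mode absolute --view "Skeletal Immune Digestive" --out out
```

prints

```
gene: INS (Entrez 1000, measurement INS_at)
annotation: synthetic fixture gene INS
highest expression: Islet cell cultures (2021.13) in view 'Skeletal Immune Digestive'
```

and writes `out/image.png`, `legend.png`, `chart.png`, `table.csv`,
`map.html`.  The table begins

```
tissue,sample_ids,mean,sd,fold_change,log2_value,colour_hex,record_id
Islet cell cultures,islet_cell_cultures_r1;...,2021.13,39.33,NA,NA,#FF0000,GSE1133
Pancreas,pancreas_r1;...,419.52,9.70,NA,NA,#FFCA00,GSE475
Skeletal muscle,skeletal_muscle_r1;...,4.10,0.21,NA,NA,#FFFE00,GSE2361
```

Read: the islet-cell tissue carries the view's maximal mean signal
(2021.13 ± 39.33 over three replicate arrays) and is painted full red;
whole pancreas is intermediate (orange, #FFCA00); everything else sits
at baseline and stays yellow — the classic single-tissue marker
pattern.  The same queries are available from Python (see `examples/`,
one script per capability):

```python
from anatogram import assemble, build_demo_catalog

catalog = build_demo_catalog("demo", seed=0)
bundle = assemble("INS", "absolute", "Skeletal Immune Digestive",
                  catalog, catalog.load_matrix("HG-U133A"),
                  catalog.load_lookup())
bundle.save("out")
```

Other subcommands: `anatogram normalize` (trimmed-mean array scaling),
`anatogram validate` (view QC: key colours present in the image,
samples present in the matrix).

## Bring your own data

1. Expression table: TSV/CSV, first column measurement IDs (probe sets
   or genes), header row sample IDs, blank/`NA` for missing.
2. Lookup table: TSV with `entrez_id`, `symbol`, `probeset_ids`
   (comma-joined), `annotation`.
3. View: any PNG/TGA whose regions are flat-filled with unique colours,
   plus an XML control file (schema in `docs/view-schema.xsd`) naming
   each tissue, its key colour, its samples and its repository record.
4. A JSON catalog manifest listing views, per-platform expression
   tables and the lookup.

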