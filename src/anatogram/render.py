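"""Render the anatogram bundle: image, legend, bar chart, table, image map.

Recolouring is exact: every pixel whose RGB equals a tissue group's key
colour is replaced by the colour assigned to that tissue; all other
pixels pass through untouched.  The legend is a ramp strip (single
yellow-to-red ramp in Absolute mode, blue-yellow-red double ramp in
Relative/Compare, labelled in log2 units).  The companion table lists
one row per tissue group with mean, SD, fold change and assigned colour;
the HTML image map provides mouse-over tooltips and click-through links
to the GEO/ArrayExpress record behind each tissue, plus gene-level
link-outs (BioGPS, NCBI Gene, UniProt, EBI, GeneMANIA).

Outputs are deterministic: identical inputs give byte-identical CSV and
pixel-identical PNGs.  Output images are PNG regardless of the base
image format (Targa is accepted on input only).  Numbers are shown with
two decimals; full precision is kept internally.

Clickable areas are fixed-radius circles at each group's centroid hint;
groups without a hint are reachable through the table only (polygon
tracing of raster regions is deliberately not attempted).
"""

from __future__ import annotations

import csv
import html
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from PIL import Image, ImageDraw

from .colours import ColourSpec, ModeResult, interpolate_colour
from .errors import AnatogramError, StageError
from .expression import (
    ExpressionMatrix,
    GeneLookup,
    GeneRecord,
    ViewMaximum,
    max_across_views,
    resolve_gene,
    select_measurement,
    tissue_summaries,
)
from .views import RGB, ViewCatalog, ViewDefinition, format_hex_colour
from . import colours as _colours

DEFAULT_URL_TEMPLATES: dict[str, str] = {
    "geo": "https://www.ncbi.nlm.nih.gov/geo/query/acc.cgi?acc={accession}",
    "arrayexpress": "https://www.ebi.ac.uk/biostudies/arrayexpress/studies/{accession}",
    "biogps": "http://biogps.org/#goto=genereport&id={entrez_id}",
    "ncbi_gene": "https://www.ncbi.nlm.nih.gov/gene/{entrez_id}",
    "uniprot": "https://www.uniprot.org/uniprotkb?query=gene:{symbol}+AND+organism_id:9606",
    "ebi": "https://www.ebi.ac.uk/gxa/genes/{symbol}",
    "genemania": "https://genemania.org/search/homo-sapiens/{symbol}",
}

AREA_RADIUS = 12  # px, clickable circle at each centroid hint

TABLE_COLUMNS = [
    "tissue",
    "sample_ids",
    "mean",
    "sd",
    "fold_change",
    "log2_value",
    "colour_hex",
    "record_id",
]


# ---------------------------------------------------------------------------
# image recolouring


def recolor_regions(
    base_image: Image.Image, assignments: dict[RGB, RGB]
) -> tuple[Image.Image, list[str]]:
    """Replace every pixel matching a key colour with its assigned colour.

    Returns the recoloured image (same dimensions) and warnings for key
    colours absent from the image.  Non-key pixels are bitwise
    unchanged; each key colour's pixel count is conserved into its
    assigned colour.
    """
    if len(set(assignments)) != len(assignments):
        raise AnatogramError("key colours in assignments must be distinct")
    arr = np.array(base_image.convert("RGB"))
    out = arr.copy()
    warnings_: list[str] = []
    for key, new in assignments.items():
        mask = np.all(arr == np.asarray(key, dtype=np.uint8), axis=-1)
        if not mask.any():
            warnings_.append(
                f"key colour {format_hex_colour(key)} not present in base image"
            )
            continue
        out[mask] = np.asarray(new, dtype=np.uint8)
    return Image.fromarray(out), warnings_


# ---------------------------------------------------------------------------
# legend


RAMP_STEPS = 255  # interpolation steps per half-ramp; full strip 511 px wide


def render_legend(
    mode: str,
    spec: ColourSpec = ColourSpec(),
    scale_info: Optional[dict] = None,
) -> tuple[Image.Image, list[tuple[int, str]]]:
    """Draw the colour-scale strip for a mode.

    Absolute: one ramp zero_colour -> high_colour labelled 0..M.
    Relative/Compare: double ramp low_colour <- zero_colour -> high_colour
    labelled -S..0..+S in log2 units, centre pixel exactly the zero
    colour.  Returns the strip image and the tick positions/labels
    (x offset within the ramp, label text).
    """
    scale_info = scale_info or {}
    band_h, text_h, margin = 24, 14, 10
    width = 2 * RAMP_STEPS + 1
    img = Image.new("RGB", (width + 2 * margin, band_h + text_h), (255, 255, 255))
    draw = ImageDraw.Draw(img)

    if mode == "absolute":
        m = scale_info.get("M", 1.0)
        for i in range(width):
            col = interpolate_colour(i / (width - 1), spec.zero_colour, spec.high_colour)
            draw.line(
                [(margin + i, 0), (margin + i, band_h - 1)], fill=col
            )
        ticks = [(0, "0"), (width // 2, _fmt(m / 2)), (width - 1, _fmt(m))]
    elif mode in ("relative", "compare"):
        s = scale_info.get("S", 1.0)
        for i in range(width):
            if i < RAMP_STEPS:
                frac = (RAMP_STEPS - i) / RAMP_STEPS
                col = interpolate_colour(frac, spec.zero_colour, spec.low_colour)
            elif i == RAMP_STEPS:
                col = spec.zero_colour
            else:
                frac = (i - RAMP_STEPS) / RAMP_STEPS
                col = interpolate_colour(frac, spec.zero_colour, spec.high_colour)
            draw.line([(margin + i, 0), (margin + i, band_h - 1)], fill=col)
        ticks = [
            (0, f"-{_fmt(s)}"),
            (RAMP_STEPS, "0"),
            (width - 1, f"+{_fmt(s)}"),
        ]
    else:
        raise AnatogramError(f"unknown mode {mode!r}")

    for x, label in ticks:
        anchor = "la" if x == 0 else ("ra" if x == width - 1 else "ma")
        draw.text((margin + x, band_h + 1), label, fill=(0, 0, 0), anchor=anchor)
    return img, ticks


def _fmt(x: float) -> str:
    """Two-decimal formatting; NaN/None rendered as NA."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:.2f}"


# ---------------------------------------------------------------------------
# table


def render_table(
    results: Sequence[ModeResult],
    view: ViewDefinition,
    path: Optional[Union[str, Path]] = None,
) -> tuple[list[dict], str]:
    """Build the companion table: one row per tissue group, in view order.

    Returns (rows, csv_text); also writes the CSV to ``path`` if given.
    Numbers are formatted to two decimals; undefined entries are "NA".
    """
    if not results:
        raise AnatogramError("no results to tabulate")
    rows: list[dict] = []
    by_name = {g.name: g for g in view.groups}
    for r in results:
        group = by_name.get(r.tissue_name)
        log2_value = r.value if r.fold_change is not None else None
        rows.append(
            {
                "tissue": r.tissue_name,
                "sample_ids": ";".join(group.sample_ids) if group else "",
                "mean": _fmt(r.mean),
                "sd": _fmt(r.sd) if r.sd is not None else "NA",
                "fold_change": _fmt(r.fold_change) if r.fold_change is not None else "NA",
                "log2_value": _fmt(log2_value) if log2_value is not None else "NA",
                "colour_hex": format_hex_colour(r.colour),
                "record_id": (group.record_id or "NA") if group else "NA",
            }
        )
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=TABLE_COLUMNS, lineterminator="\n")
    writer.writeheader()
    writer.writerows(rows)
    csv_text = buf.getvalue()
    if path is not None:
        Path(path).write_text(csv_text)
    return rows, csv_text


# ---------------------------------------------------------------------------
# bar chart


def render_chart(results: Sequence[ModeResult], title: str = "") -> bytes:
    """Horizontal bar chart PNG: one bar per tissue in view order, each
    bar filled with the tissue's assigned colour."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [r.tissue_name for r in results]
    means = [0.0 if math.isnan(r.mean) else r.mean for r in results]
    cols = [tuple(c / 255 for c in r.colour) for r in results]
    fig, ax = plt.subplots(figsize=(6, max(1.5, 0.35 * len(results))))
    y = np.arange(len(results))[::-1]  # view order top to bottom
    ax.barh(y, means, color=cols, edgecolor="black", linewidth=0.4)
    ax.set_yticks(y, names, fontsize=8)
    ax.set_xlabel("mean expression")
    if title:
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=100)
    plt.close(fig)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# HTML image map


def _record_url(record_id: str, templates: dict[str, str]) -> Optional[str]:
    if record_id.startswith(("http://", "https://")):
        return record_id
    if record_id.upper().startswith("GSE") or record_id.upper().startswith("GSM"):
        return templates["geo"].format(accession=record_id)
    if record_id.upper().startswith("E-"):
        return templates["arrayexpress"].format(accession=record_id)
    return None


def _tooltip(result: ModeResult, mode: str) -> str:
    if result.missing or result.masked:
        return f"{result.tissue_name}: NA"
    if mode == "absolute":
        return f"{result.tissue_name}: {_fmt(result.mean)} (±{_fmt(result.sd or 0.0)})"
    direction = "up" if result.value >= 0 else "down"
    return f"{result.tissue_name}: {_fmt(result.fold_change)}-fold {direction}"


def render_image_map(
    view: ViewDefinition,
    results: Sequence[ModeResult],
    lookup_record: Optional[GeneRecord] = None,
    mode: str = "absolute",
    url_templates: Optional[dict[str, str]] = None,
) -> str:
    """HTML fragment: an image map with one circular area per hinted
    group (tooltip + record-link) and a gene-level link-out block.

    Groups without a centroid hint get no area (table-only access);
    groups without a record_id get an area without an href.
    """
    templates = dict(DEFAULT_URL_TEMPLATES)
    if url_templates:
        templates.update(url_templates)
    by_name = {r.tissue_name: r for r in results}
    lines = [f'<map name="{html.escape(view.name)}">']
    for g in view.groups:
        if g.centroid_hint is None:
            continue
        r = by_name.get(g.name)
        tip = _tooltip(r, mode) if r else g.name
        x, y = g.centroid_hint
        href = _record_url(g.record_id, templates) if g.record_id else None
        href_attr = f' href="{html.escape(href)}"' if href else ""
        lines.append(
            f'  <area shape="circle" coords="{x},{y},{AREA_RADIUS}"'
            f' title="{html.escape(tip)}" alt="{html.escape(g.name)}"{href_attr}/>'
        )
    lines.append("</map>")
    if lookup_record is not None:
        lines.append('<ul class="gene-links">')
        for label, key, kwargs in [
            ("BioGPS", "biogps", {"entrez_id": lookup_record.entrez_id}),
            ("NCBI Gene", "ncbi_gene", {"entrez_id": lookup_record.entrez_id}),
            ("UniProt", "uniprot", {"symbol": lookup_record.symbol}),
            ("EBI", "ebi", {"symbol": lookup_record.symbol}),
            ("GeneMANIA", "genemania", {"symbol": lookup_record.symbol}),
        ]:
            url = templates[key].format(**kwargs)
            lines.append(
                f'  <li><a href="{html.escape(url)}">{html.escape(label)}</a></li>'
            )
        lines.append("</ul>")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# bundle assembly


@dataclass
class RenderBundle:
    """Everything one query produces: image, legend, chart, table, map."""

    image: Image.Image
    legend: Image.Image
    chart_png: bytes
    table_rows: list[dict]
    csv_text: str
    image_map_html: str
    header_info: dict
    warnings: list[str] = field(default_factory=list)

    def save(self, output_dir: Union[str, Path]) -> dict[str, Path]:
        """Write image.png, legend.png, chart.png, table.csv, map.html."""
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "image": out / "image.png",
            "legend": out / "legend.png",
            "chart": out / "chart.png",
            "table": out / "table.csv",
            "map": out / "map.html",
        }
        self.image.save(paths["image"], format="PNG")
        self.legend.save(paths["legend"], format="PNG")
        paths["chart"].write_bytes(self.chart_png)
        paths["table"].write_text(self.csv_text)
        paths["map"].write_text(self.image_map_html)
        return paths


@dataclass(frozen=True)
class RenderOptions:
    """Optional knobs for :func:`assemble`."""

    secondary_gene: Optional[str] = None
    probeset_override: Optional[str] = None
    secondary_probeset_override: Optional[str] = None
    cap: Optional[float] = None
    cap_log2: Union[float, str] = "auto"
    colour_spec: ColourSpec = ColourSpec()
    url_templates: Optional[dict[str, str]] = None


def assemble(
    gene_query: str,
    mode: str,
    view_name: str,
    catalog: ViewCatalog,
    matrix: ExpressionMatrix,
    lookup: GeneLookup,
    options: RenderOptions = RenderOptions(),
) -> RenderBundle:
    """Run the full query pipeline and return the output bundle.

    resolve -> select probe set -> tissue summaries -> mode colouring ->
    recolour regions -> legend -> table -> chart -> image map, with the
    header carrying the catalog-wide expression maximum and the view's
    comparability note.  Every error is tagged with the stage that
    raised it.
    """
    if mode not in ("absolute", "relative", "compare"):
        raise AnatogramError(f"unknown mode {mode!r}")
    if mode == "compare" and not options.secondary_gene:
        raise AnatogramError("compare mode requires a secondary gene")

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except AnatogramError as exc:
            raise StageError(name, exc) from exc

    view = stage("view-lookup", catalog.get_view, view_name)
    probesets, record = stage("gene-resolution", resolve_gene, gene_query, lookup)
    measurement = stage(
        "probe-set-selection",
        select_measurement,
        probesets,
        matrix,
        options.probeset_override,
    )
    summaries = stage("tissue-summaries", tissue_summaries, measurement, matrix, view)

    spec = options.colour_spec
    if mode == "absolute":
        results = stage("colouring", _colours.absolute_mode, summaries, options.cap, spec)
    elif mode == "relative":
        results = stage(
            "colouring", _colours.relative_mode, summaries, options.cap_log2, spec
        )
    else:
        sec_probesets, _ = stage(
            "gene-resolution", resolve_gene, options.secondary_gene, lookup
        )
        sec_measurement = stage(
            "probe-set-selection",
            select_measurement,
            sec_probesets,
            matrix,
            options.secondary_probeset_override,
        )
        sec_summaries = stage(
            "tissue-summaries", tissue_summaries, sec_measurement, matrix, view
        )
        results = stage(
            "colouring",
            _colours.compare_mode,
            summaries,
            sec_summaries,
            options.cap_log2,
            spec,
        )

    base = stage("base-image", view.load_base_image)
    assignments = {
        g.key_colour: r.colour for g, r in zip(view.groups, results)
    }
    image, warnings_ = stage("recolouring", recolor_regions, base, assignments)

    if mode == "absolute":
        m = options.cap if options.cap is not None else max(
            (s.mean for s in summaries if not s.missing), default=0.0
        )
        scale_info = {"M": m}
    else:
        unmasked = [r.value for r in results if not (r.masked or r.missing)]
        s_val = (
            float(options.cap_log2)
            if options.cap_log2 != "auto"
            else max((abs(v) for v in unmasked), default=0.0)
        )
        scale_info = {"S": s_val}
    legend, _ = stage("legend", render_legend, mode, spec, scale_info)
    table_rows, csv_text = stage("table", render_table, results, view)
    chart_png = stage("chart", render_chart, results, f"{record.symbol} [{mode}]")
    image_map = stage(
        "image-map", render_image_map, view, results, record, mode,
        options.url_templates,
    )

    platform_views = catalog.views_for_platform(matrix.platform_tag) or [view]
    vmax: ViewMaximum = stage(
        "view-maximum", max_across_views, measurement, matrix, platform_views
    )
    header_info = {
        "gene": record.symbol,
        "entrez_id": record.entrez_id,
        "measurement": measurement,
        "annotation": record.annotation,
        "max_view": vmax.view_name,
        "max_tissue": vmax.tissue_name,
        "max_value": vmax.mean,
        "comparability_note": view.comparability_note,
    }
    return RenderBundle(
        image=image,
        legend=legend,
        chart_png=chart_png,
        table_rows=table_rows,
        csv_text=csv_text,
        image_map_html=image_map,
        header_info=header_info,
        warnings=warnings_,
    )
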