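import csv
import io

import numpy as np
import pytest
from PIL import Image

from anatogram import (
    AnatogramError,
    ColourSpec,
    GeneRecord,
    RenderOptions,
    StageError,
    absolute_mode,
    assemble,
    interpolate_colour,
    recolor_regions,
    relative_mode,
    render_chart,
    render_image_map,
    render_legend,
    render_table,
    tissue_summaries,
)
from anatogram.render import RAMP_STEPS
from conftest import make_summaries


def count_colour(img, colour):
    arr = np.array(img.convert("RGB"))
    return int(np.all(arr == np.asarray(colour, dtype=np.uint8), axis=-1).sum())


def checkerboard(w=10, h=10, key=(200, 10, 10), n_key=30):
    """White image with exactly n_key pixels of the key colour."""
    img = Image.new("RGB", (w, h), (255, 255, 255))
    px = img.load()
    placed = 0
    for y in range(h):
        for x in range(w):
            if placed < n_key:
                px[x, y] = key
                placed += 1
    return img


class TestRecolorRegions:
    def test_pixel_count_conserved(self):
        img = checkerboard(n_key=30)
        out, warnings = recolor_regions(img, {(200, 10, 10): (0, 0, 255)})
        assert warnings == []
        assert count_colour(out, (0, 0, 255)) == 30
        assert count_colour(out, (255, 255, 255)) == 70
        assert out.size == img.size

    def test_empty_assignment_is_identity(self):
        img = checkerboard()
        out, _ = recolor_regions(img, {})
        assert np.array_equal(np.array(img), np.array(out))

    def test_swapped_assignments_swap_counts(self, drawn_view):
        _, img, view = drawn_view
        c0, c1 = view.groups[0].key_colour, view.groups[1].key_colour
        n0, n1 = count_colour(img, c0), count_colour(img, c1)
        out, _ = recolor_regions(img, {c0: c1, c1: c0})
        # regions swapped: previous c0 pixels now carry c1 and vice versa
        assert count_colour(out, c0) == n1
        assert count_colour(out, c1) == n0

    def test_non_key_pixels_bitwise_unchanged(self, drawn_view):
        _, img, view = drawn_view
        key = view.groups[0].key_colour
        before = np.array(img)
        out, _ = recolor_regions(img, {key: (9, 9, 9)})
        after = np.array(out)
        mask = np.all(before == np.asarray(key, dtype=np.uint8), axis=-1)
        assert np.array_equal(before[~mask], after[~mask])
        assert int(mask.sum()) == count_colour(out, (9, 9, 9))

    def test_absent_key_warns_without_crash(self):
        img = checkerboard()
        out, warnings = recolor_regions(img, {(1, 2, 3): (4, 5, 6)})
        assert len(warnings) == 1 and "#010203" in warnings[0]
        assert np.array_equal(np.array(img), np.array(out))


class TestRenderLegend:
    def test_absolute_ramp_endpoints_and_midpoint(self):
        img, ticks = render_legend("absolute", scale_info={"M": 80.0})
        margin = 10
        assert img.getpixel((margin, 0)) == (255, 255, 0)
        assert img.getpixel((margin + 2 * RAMP_STEPS, 0)) == (255, 0, 0)
        assert img.getpixel((margin + RAMP_STEPS, 0)) == interpolate_colour(
            0.5, (255, 255, 0), (255, 0, 0)
        )
        assert [label for _, label in ticks] == ["0", "40.00", "80.00"]

    def test_relative_double_ramp_centre_exact_yellow(self):
        img, ticks = render_legend("relative", scale_info={"S": 2.0})
        margin = 10
        assert img.getpixel((margin, 0)) == (0, 0, 255)
        assert img.getpixel((margin + RAMP_STEPS, 0)) == (255, 255, 0)
        assert img.getpixel((margin + 2 * RAMP_STEPS, 0)) == (255, 0, 0)
        assert [label for _, label in ticks] == ["-2.00", "0", "+2.00"]

    def test_unknown_mode(self):
        with pytest.raises(AnatogramError):
            render_legend("sideways")


class TestRenderTable:
    def test_row_per_group_and_round_trip(self, small_view, small_matrix):
        summaries = tissue_summaries("p1", small_matrix, small_view)
        results = absolute_mode(summaries)
        rows, csv_text = render_table(results, small_view)
        assert len(rows) == len(small_view.groups)
        parsed = list(csv.DictReader(io.StringIO(csv_text)))
        assert parsed == [
            {k: str(v) for k, v in row.items()} for row in rows
        ]
        assert parsed[0]["mean"] == "12.00"
        assert parsed[0]["record_id"] == "GSE7307"
        assert parsed[0]["sample_ids"] == "s1;s2"

    def test_masked_tissue_has_na_fold_change(self):
        results = relative_mode(make_summaries([0.0, 2.0, 8.0]))
        from anatogram import TissueGroup, ViewDefinition

        view = ViewDefinition(
            "v", "x.png", "x",
            tuple(
                TissueGroup(f"t{i}", (i, 0, 0), (f"s{i}",)) for i in range(3)
            ),
        )
        rows, _ = render_table(results, view)
        assert rows[0]["fold_change"] == "NA"
        assert rows[0]["log2_value"] == "NA"
        assert rows[2]["fold_change"] == "4.00"

    def test_writes_file(self, tmp_path, small_view, small_matrix):
        summaries = tissue_summaries("p1", small_matrix, small_view)
        results = absolute_mode(summaries)
        out = tmp_path / "table.csv"
        _, csv_text = render_table(results, small_view, out)
        assert out.read_text() == csv_text


class TestRenderImageMap:
    record = GeneRecord("3630", "INS", ("p1",), "insulin")

    def test_area_per_hinted_group_with_geo_href(self, small_view, small_matrix):
        summaries = tissue_summaries("p1", small_matrix, small_view)
        results = absolute_mode(summaries)
        frag = render_image_map(small_view, results, self.record, "absolute")
        assert frag.count("<area") == 2  # both groups hinted
        assert "GSE7307" in frag
        # absolute tooltip carries mean and sd
        assert "alpha: 12.00" in frag
        # group without record_id still gets an area, without href
        area_beta = [l for l in frag.splitlines() if 'alt="beta"' in l][0]
        assert "href" not in area_beta

    def test_relative_tooltip_fold_direction(self, small_view, small_matrix):
        summaries = tissue_summaries("p1", small_matrix, small_view)
        results = relative_mode(summaries)
        frag = render_image_map(small_view, results, self.record, "relative")
        assert "-fold up" in frag and "-fold down" in frag

    def test_gene_linkout_block(self, small_view, small_matrix):
        summaries = tissue_summaries("p1", small_matrix, small_view)
        frag = render_image_map(
            small_view, absolute_mode(summaries), self.record, "absolute"
        )
        for label in ("BioGPS", "NCBI Gene", "UniProt", "EBI", "GeneMANIA"):
            assert label in frag
        assert "ncbi.nlm.nih.gov/gene/3630" in frag

    def test_no_hinted_groups_yields_empty_valid_map(self, small_matrix):
        from anatogram import TissueGroup, ViewDefinition

        view = ViewDefinition(
            "v", "x.png", "HG-U133A",
            (TissueGroup("alpha", (1, 0, 0), ("s1",)),),
        )
        summaries = tissue_summaries("p1", small_matrix, view)
        frag = render_image_map(view, absolute_mode(summaries), None, "absolute")
        assert "<area" not in frag
        assert frag.startswith("<map") and frag.rstrip().endswith("</map>")

    def test_url_template_override(self, small_view, small_matrix):
        summaries = tissue_summaries("p1", small_matrix, small_view)
        frag = render_image_map(
            small_view,
            absolute_mode(summaries),
            self.record,
            "absolute",
            url_templates={"geo": "https://mirror.example/{accession}"},
        )
        assert "https://mirror.example/GSE7307" in frag


class TestAssemble:
    def test_full_bundle_absolute(self, demo_catalog, demo_microarray):
        _, catalog = demo_catalog
        matrix, lookup = demo_microarray
        bundle = assemble(
            "INS", "absolute", "Skeletal Immune Digestive", catalog, matrix, lookup
        )
        view = catalog.get_view("Skeletal Immune Digestive")
        base = view.load_base_image()
        assert bundle.image.size == base.size
        assert len(bundle.table_rows) == len(view.groups)
        assert bundle.header_info["max_tissue"] == "Islet cell cultures"
        assert bundle.header_info["max_view"] == "Skeletal Immune Digestive"
        assert bundle.chart_png.startswith(b"\x89PNG")

    def test_max_tissue_painted_full_red(self, demo_catalog, demo_microarray):
        _, catalog = demo_catalog
        matrix, lookup = demo_microarray
        view = catalog.get_view("Nervous")
        bundle = assemble("SIX3", "absolute", "Nervous", catalog, matrix, lookup)
        measurement = bundle.header_info["measurement"]
        summaries = tissue_summaries(measurement, matrix, view)
        best = max(
            (s for s in summaries if not s.missing), key=lambda s: s.mean
        )
        key = view.group(best.tissue_name).key_colour
        n_key = count_colour(view.load_base_image(), key)
        assert n_key > 0
        assert count_colour(bundle.image, (255, 0, 0)) >= n_key

    def test_header_names_catalog_global_max(self, demo_catalog, demo_microarray):
        _, catalog = demo_catalog
        matrix, lookup = demo_microarray
        # query from a view that does NOT contain the global maximum
        bundle = assemble("INS", "absolute", "Nervous", catalog, matrix, lookup)
        assert bundle.header_info["max_view"] == "Skeletal Immune Digestive"
        assert bundle.header_info["max_tissue"] == "Islet cell cultures"

    def test_comparability_note_in_header(self, demo_catalog):
        _, catalog = demo_catalog
        matrix = catalog.load_matrix("RNA-seq-FPKM")
        lookup = catalog.load_lookup()
        bundle = assemble(
            "CAMK2B", "absolute", "Human Body Map 2 Illumina",
            catalog, matrix, lookup,
        )
        assert "not directly comparable" in bundle.header_info["comparability_note"]
        assert bundle.header_info["max_tissue"] == "brain"

    def test_deterministic_outputs(self, demo_catalog, demo_microarray):
        _, catalog = demo_catalog
        matrix, lookup = demo_microarray
        run = lambda: assemble(
            "ALB", "relative", "Skeletal Immune Digestive", catalog, matrix, lookup
        )
        b1, b2 = run(), run()
        assert b1.csv_text == b2.csv_text
        assert np.array_equal(np.array(b1.image), np.array(b2.image))
        assert np.array_equal(np.array(b1.legend), np.array(b2.legend))
        assert b1.chart_png == b2.chart_png
        assert b1.image_map_html == b2.image_map_html

    def test_compare_same_gene_all_yellow_regions(self, demo_catalog, demo_microarray):
        _, catalog = demo_catalog
        matrix, lookup = demo_microarray
        view = catalog.get_view("Nervous")
        bundle = assemble(
            "SIX3", "compare", "Nervous", catalog, matrix, lookup,
            RenderOptions(secondary_gene="SIX3"),
        )
        base = view.load_base_image()
        n_region_px = sum(count_colour(base, g.key_colour) for g in view.groups)
        assert count_colour(bundle.image, (255, 255, 0)) == n_region_px

    def test_errors_name_their_stage(self, demo_catalog, demo_microarray):
        _, catalog = demo_catalog
        matrix, lookup = demo_microarray
        with pytest.raises(StageError, match=r"\[gene-resolution\]"):
            assemble("NOPE", "absolute", "Nervous", catalog, matrix, lookup)
        with pytest.raises(StageError, match=r"\[view-lookup\]"):
            assemble("INS", "absolute", "Atlantis", catalog, matrix, lookup)

    def test_compare_requires_secondary(self, demo_catalog, demo_microarray):
        _, catalog = demo_catalog
        matrix, lookup = demo_microarray
        with pytest.raises(AnatogramError, match="secondary"):
            assemble("INS", "compare", "Nervous", catalog, matrix, lookup)

    def test_probeset_override_respected(self, demo_catalog, demo_microarray):
        _, catalog = demo_catalog
        matrix, lookup = demo_microarray
        bundle = assemble(
            "INS", "absolute", "Skeletal Immune Digestive", catalog, matrix, lookup,
            RenderOptions(probeset_override="INS_s_at"),
        )
        assert bundle.header_info["measurement"] == "INS_s_at"


class TestRenderChart:
    def test_chart_is_png_with_one_bar_per_tissue(self):
        results = absolute_mode(make_summaries([1.0, 5.0, 10.0]))
        png = render_chart(results, "demo")
        img = Image.open(io.BytesIO(png))
        assert img.format == "PNG"
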