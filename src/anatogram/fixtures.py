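"""Synthetic anatomy, expression, and catalog generators.

Every pipeline stage is testable offline: this module draws toy anatomy
images (non-overlapping rectangles, one unique key colour each, on a
white background), simulates replicate expression values per tissue from
a per-gene mean/noise pattern, writes the matching lookup tables, and
ships a small demo catalog whose shape mirrors a real multi-study
compendium: five microarray views plus one 16-sample RNA-seq body-map
view, with the source accession list recorded in the catalog metadata.

The geometry is deliberately abstract rather than anatomical — the
rendering engine is artwork-agnostic, and real anatomical artwork is a
drop-in replacement (any flat-filled PNG/TGA plus a view XML).

Replicate values are drawn as ``max(0, Normal(mean, noise_sd))`` with a
seeded generator, so fixtures are byte-reproducible and zero-noise
patterns are recovered exactly by the summary statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .errors import AnatogramError
from .expression import ExpressionMatrix, GeneLookup, GeneRecord
from .views import (
    RGB,
    TissueGroup,
    ViewCatalog,
    ViewDefinition,
    save_catalog,
)

WHITE: RGB = (255, 255, 255)

# Printed source accessions of the compendium the demo catalog emulates.
SOURCE_ACCESSIONS = (
    "GSE1133",
    "GSE475",
    "GSE2361",
    "GSE3526",
    "GSE8961",
    "GSE4567",
    "GSE7307",
    "GSE19650",
    "E-MTAB-47",
    "E-GEOD-6257",
    "E-MEXP-2219",
)

# Illumina Body Map 2.0 tissue panel (16 samples, one per tissue).
BODYMAP_TISSUES = (
    "adipose",
    "adrenal",
    "brain",
    "breast",
    "colon",
    "heart",
    "kidney",
    "liver",
    "lung",
    "lymph node",
    "ovary",
    "prostate",
    "skeletal muscle",
    "testis",
    "thyroid",
    "white blood cells",
)

COMPARABILITY_NOTE = (
    "Expression levels in this view are RNA-seq FPKM values and are not "
    "directly comparable to microarray signal values in other views."
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic view + expression fixture.

    ``expression_pattern`` maps gene symbol -> tissue -> (mean, noise_sd);
    its tissue keys (first-seen order) define the regions drawn by
    :func:`generate_anatomy`.  With an empty pattern, ``n_regions``
    generic regions are drawn instead.
    """

    n_regions: int = 4
    image_size: tuple[int, int] = (240, 180)
    n_genes: int = 3
    replicates_per_tissue: int = 3
    expression_pattern: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=dict
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.n_genes < 1 or self.replicates_per_tissue < 1:
            raise AnatogramError("fixture counts must be >= 1")
        if self.image_size[0] < 8 or self.image_size[1] < 8:
            raise AnatogramError("image_size too small")

    def tissue_names(self) -> list[str]:
        seen: list[str] = []
        for tissues in self.expression_pattern.values():
            for t in tissues:
                if t not in seen:
                    seen.append(t)
        if seen:
            return seen
        return [f"region_{i + 1:02d}" for i in range(self.n_regions)]


def _slug(text: str) -> str:
    return "".join(c.lower() if c.isalnum() else "_" for c in text)


def key_colour_palette(n: int) -> list[RGB]:
    """n distinct key colours, none white, generated deterministically."""
    palette: list[RGB] = []
    i = 0
    while len(palette) < n:
        c: RGB = ((37 + i * 53) % 256, (89 + i * 101) % 251, (151 + i * 173) % 247)
        if c != WHITE and c not in palette:
            palette.append(c)
        i += 1
    return palette


def sample_ids_for(tissue: str, replicates: int) -> list[str]:
    return [f"{_slug(tissue)}_r{j + 1}" for j in range(replicates)]


# ---------------------------------------------------------------------------
# anatomy


def generate_anatomy(
    spec: FixtureSpec,
    directory: str | Path,
    name: str = "toy view",
    platform_tag: str = "HG-U133A",
    record_ids: Optional[Sequence[Optional[str]]] = None,
    comparability_note: Optional[str] = None,
) -> tuple[Image.Image, ViewDefinition]:
    """Draw a toy anatomy and write it plus return its view definition.

    Regions are non-overlapping axis-aligned rectangles on a grid, each
    flat-filled with a unique key colour on a white background, with the
    group centroid hint at the rectangle centre.  The PNG is written to
    ``directory`` and the view's ``base_image_path`` points at it.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tissues = spec.tissue_names()
    n = len(tissues)
    w, h = spec.image_size
    cols = math.ceil(math.sqrt(n))
    rows = math.ceil(n / cols)
    cell_w, cell_h = w // cols, h // rows
    margin_x = max(2, cell_w // 6)
    margin_y = max(2, cell_h // 6)
    if cell_w - 2 * margin_x < 1 or cell_h - 2 * margin_y < 1:
        raise AnatogramError(
            f"cannot fit {n} regions into a {w}x{h} image"
        )
    palette = key_colour_palette(n)
    img = Image.new("RGB", (w, h), WHITE)
    draw = ImageDraw.Draw(img)
    groups: list[TissueGroup] = []
    for i, tissue in enumerate(tissues):
        r, c = divmod(i, cols)
        x0 = c * cell_w + margin_x
        y0 = r * cell_h + margin_y
        x1 = (c + 1) * cell_w - margin_x - 1
        y1 = (r + 1) * cell_h - margin_y - 1
        draw.rectangle([x0, y0, x1, y1], fill=palette[i])
        groups.append(
            TissueGroup(
                name=tissue,
                key_colour=palette[i],
                sample_ids=tuple(
                    sample_ids_for(tissue, spec.replicates_per_tissue)
                ),
                record_id=record_ids[i] if record_ids else None,
                centroid_hint=((x0 + x1) // 2, (y0 + y1) // 2),
            )
        )
    image_path = directory / f"{_slug(name)}_base.png"
    img.save(image_path, format="PNG")
    view = ViewDefinition(
        name=name,
        base_image_path=str(image_path),
        platform_tag=platform_tag,
        groups=tuple(groups),
        comparability_note=comparability_note,
    )
    return img, view


def rectangle_areas(spec: FixtureSpec) -> dict[str, int]:
    """Expected pixel area per region for a spec (oracle for tests)."""
    tissues = spec.tissue_names()
    n = len(tissues)
    w, h = spec.image_size
    cols = math.ceil(math.sqrt(n))
    rows = math.ceil(n / cols)
    cell_w, cell_h = w // cols, h // rows
    margin_x = max(2, cell_w // 6)
    margin_y = max(2, cell_h // 6)
    area = (cell_w - 2 * margin_x) * (cell_h - 2 * margin_y)
    return {t: area for t in tissues}


# ---------------------------------------------------------------------------
# expression


def _draw_values(
    pattern: dict[str, dict[str, tuple[float, float]]],
    samples_by_tissue: dict[str, Sequence[str]],
    rng: np.random.Generator,
    measurement_ids_for_gene,
) -> pd.DataFrame:
    """Row per measurement id, column per sample; replicate draws are
    max(0, Normal(mean, sd)); secondary probe sets get scaled-down means."""
    columns = [s for samples in samples_by_tissue.values() for s in samples]
    rows: dict[str, list[float]] = {}
    for gene, tissue_params in pattern.items():
        for mid, scale in measurement_ids_for_gene(gene):
            vals: list[float] = []
            for tissue, samples in samples_by_tissue.items():
                mean, sd = tissue_params[tissue]
                mean *= scale
                sd *= scale
                for _ in samples:
                    v = mean if sd == 0 else max(0.0, float(rng.normal(mean, sd)))
                    vals.append(v)
            rows[mid] = vals
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns)


def generate_expression(
    spec: FixtureSpec,
    view: ViewDefinition,
    measurement_style: str = "probeset",
) -> tuple[ExpressionMatrix, GeneLookup]:
    """Simulate an expression matrix + lookup for a view.

    ``measurement_style="probeset"`` emits probe-set rows (``SYM_at``;
    the first gene additionally gets a secondary ``SYM_s_at`` probe set
    at 60% signal, exercising probe-set selection);
    ``"gene"`` emits one row per gene keyed by its symbol (RNA-seq
    style).  The pattern must cover every tissue in the view.
    """
    if not spec.expression_pattern:
        raise AnatogramError("spec has no expression_pattern")
    view_tissues = [g.name for g in view.groups]
    for gene, tissue_params in spec.expression_pattern.items():
        uncovered = set(view_tissues) - set(tissue_params)
        if uncovered:
            raise AnatogramError(
                f"pattern for gene {gene!r} does not cover tissues {sorted(uncovered)}"
            )
    samples_by_tissue = {g.name: list(g.sample_ids) for g in view.groups}
    genes = list(spec.expression_pattern)

    def mids(gene: str) -> list[tuple[str, float]]:
        if measurement_style == "gene":
            return [(gene, 1.0)]
        out = [(f"{gene}_at", 1.0)]
        if gene == genes[0]:
            out.append((f"{gene}_s_at", 0.6))
        return out

    rng = np.random.default_rng(spec.seed)
    frame = _draw_values(
        spec.expression_pattern, samples_by_tissue, rng, mids
    )
    matrix = ExpressionMatrix(frame, view.platform_tag)
    records = [
        GeneRecord(
            entrez_id=str(1000 + i),
            symbol=gene,
            probeset_ids=tuple(m for m, _ in mids(gene)),
            annotation=f"synthetic fixture gene {gene}",
        )
        for i, gene in enumerate(genes)
    ]
    return matrix, GeneLookup(records)


# ---------------------------------------------------------------------------
# demo catalog


def _microarray_patterns() -> dict[str, dict[str, dict[str, tuple[float, float]]]]:
    """Per-view expression patterns of the demo genes (signal units).

    Shapes follow well-known marker biology at toy scale: INS confined
    to islet cells (and lower in whole pancreas), SIX3 in basal
    forebrain structures, CAMK2B in neural tissue with some skeletal
    muscle, ALB in liver, GAPDH ubiquitous.
    """
    views = {
        "Skeletal Immune Digestive": [
            "Islet cell cultures", "Pancreas", "Skeletal muscle",
            "Bone marrow", "Thymus", "Colon", "Liver",
        ],
        "Nervous": [
            "Putamen", "Nucleus accumbens", "Cerebellum",
            "Frontal cortex", "Spinal cord", "Hippocampus",
        ],
        "Circulatory Respiratory": ["Heart", "Aorta", "Lung", "Trachea"],
        "Renal Urinary": ["Kidney cortex", "Kidney medulla", "Bladder", "Ureter"],
        "Endocrine Reproductive": [
            "Thyroid", "Adrenal gland", "Ovary", "Prostate", "Testis",
        ],
    }
    neural = {"Putamen", "Nucleus accumbens", "Cerebellum", "Frontal cortex",
              "Spinal cord", "Hippocampus"}
    highs: dict[str, dict[str, float]] = {
        "INS": {"Islet cell cultures": 2000.0, "Pancreas": 420.0},
        "SIX3": {"Putamen": 900.0, "Nucleus accumbens": 780.0},
        "CAMK2B": {t: 600.0 for t in neural} | {"Skeletal muscle": 150.0},
        "ALB": {"Liver": 1500.0},
        "GAPDH": {},
    }
    baselines = {"INS": 4.0, "SIX3": 6.0, "CAMK2B": 10.0, "ALB": 8.0, "GAPDH": 800.0}
    patterns: dict[str, dict[str, dict[str, tuple[float, float]]]] = {}
    for view_name, tissues in views.items():
        per_view: dict[str, dict[str, tuple[float, float]]] = {}
        for gene, base in baselines.items():
            per_view[gene] = {}
            for t in tissues:
                mean = highs[gene].get(t, base)
                per_view[gene][t] = (mean, 0.05 * mean)
        patterns[view_name] = per_view
    return patterns


def _bodymap_pattern() -> dict[str, dict[str, tuple[float, float]]]:
    highs: dict[str, dict[str, float]] = {
        "CAMK2B": {"brain": 85.0, "skeletal muscle": 25.0},
        "INS": {},
        "SIX3": {"brain": 12.0},
        "ALB": {"liver": 3000.0},
        "GAPDH": {},
    }
    baselines = {"CAMK2B": 1.0, "INS": 0.2, "SIX3": 0.3, "ALB": 0.5, "GAPDH": 300.0}
    return {
        gene: {
            t: (highs[gene].get(t, base), 0.05 * highs[gene].get(t, base))
            for t in BODYMAP_TISSUES
        }
        for gene, base in baselines.items()
    }


def build_demo_catalog(directory: str | Path, seed: int = 0) -> ViewCatalog:
    """Write the demo compendium to ``directory`` and return its catalog.

    Five toy-scale microarray views (platform HG-U133A, three replicate
    arrays per tissue) plus a 16-sample RNA-seq body-map view carrying a
    platform-comparability note; catalog metadata records the 11 source
    accessions of the compendium the fixture emulates.  All content is
    synthetic and deterministic for a given seed.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    patterns = _microarray_patterns()

    views: list[ViewDefinition] = []
    ua_frames: list[pd.DataFrame] = []
    genes = list(next(iter(patterns.values())))

    def mids(gene: str) -> list[tuple[str, float]]:
        out = [(f"{gene}_at", 1.0)]
        if gene == "INS":  # two probe sets on one gene, to exercise selection
            out.append((f"{gene}_s_at", 0.6))
        return out

    accession_cycle = list(SOURCE_ACCESSIONS)
    acc_i = 0
    for vi, (view_name, pattern) in enumerate(patterns.items()):
        tissues = list(next(iter(pattern.values())))
        spec = FixtureSpec(
            n_regions=len(tissues),
            image_size=(260, 200),
            n_genes=len(pattern),
            replicates_per_tissue=3,
            expression_pattern=pattern,
            seed=seed + vi,
        )
        record_ids = []
        for _ in tissues:
            record_ids.append(accession_cycle[acc_i % len(accession_cycle)])
            acc_i += 1
        _, view = generate_anatomy(
            spec, directory, name=view_name, platform_tag="HG-U133A",
            record_ids=record_ids,
        )
        views.append(view)
        samples_by_tissue = {g.name: list(g.sample_ids) for g in view.groups}
        ua_frames.append(_draw_values(pattern, samples_by_tissue, rng, mids))

    ua_frame = pd.concat(ua_frames, axis=1)
    ua_matrix = ExpressionMatrix(ua_frame, "HG-U133A")

    bm_pattern = _bodymap_pattern()
    bm_spec = FixtureSpec(
        n_regions=len(BODYMAP_TISSUES),
        image_size=(320, 320),
        n_genes=len(bm_pattern),
        replicates_per_tissue=1,
        expression_pattern=bm_pattern,
        seed=seed + 100,
    )
    _, bm_view = generate_anatomy(
        bm_spec, directory, name="Human Body Map 2 Illumina",
        platform_tag="RNA-seq-FPKM", comparability_note=COMPARABILITY_NOTE,
    )
    views.append(bm_view)
    bm_samples = {g.name: list(g.sample_ids) for g in bm_view.groups}
    bm_frame = _draw_values(bm_pattern, bm_samples, rng, lambda g: [(g, 1.0)])
    bm_matrix = ExpressionMatrix(bm_frame, "RNA-seq-FPKM")

    records = [
        GeneRecord(
            entrez_id=str(1000 + i),
            symbol=gene,
            probeset_ids=tuple([m for m, _ in mids(gene)] + [gene]),
            annotation=f"synthetic fixture gene {gene}",
        )
        for i, gene in enumerate(genes)
    ]
    lookup = GeneLookup(records)

    ua_path = directory / "expression_hgu133a.tsv"
    bm_path = directory / "expression_bodymap.tsv"
    lookup_path = directory / "lookup.tsv"
    ua_matrix.to_tsv(ua_path)
    bm_matrix.to_tsv(bm_path)
    lookup.to_tsv(lookup_path)

    catalog = ViewCatalog(
        views=views,
        metadata={
            "source_accessions": list(SOURCE_ACCESSIONS),
            "n_microarray_views": 5,
            "n_samples": int(ua_frame.shape[1] + bm_frame.shape[1]),
        },
        expression_paths={
            "HG-U133A": str(ua_path),
            "RNA-seq-FPKM": str(bm_path),
        },
        lookup_path=str(lookup_path),
    )
    save_catalog(catalog, directory)
    return catalog
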