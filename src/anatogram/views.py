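"""View definitions: XML control files binding tissues to image regions.

A *view* pairs a base anatomy image with an ordered set of tissue groups.
Each group lists the sample IDs pooled into that tissue, an optional
repository record ID (GEO/ArrayExpress accession) for click-through, and
a *key colour*: a unique RGB value painted into the base image that marks
every pixel belonging to the region.  The renderer recolours exactly the
pixels matching each key colour, so base images must be saved with flat
(non-anti-aliased) region fills.

Image coordinates are 0-based, origin top-left, x rightwards, y down.
Base images are accepted as PNG or uncompressed Targa (TGA); PNG is the
interchange format.

XML dialect (a clean-room schema; see ``docs/view-schema.xsd``)::

    <view name="Nervous" platform="HG-U133A" image="nervous.png"
          comparability_note="...optional...">
      <group name="Putamen" colour="#FF0000" record_id="GSE7307">
        <sample id="GSM1"/>
        <sample id="GSM2"/>
        <centroid x="40" y="25"/>
      </group>
    </view>

A *catalog* is a JSON manifest listing view XML files in display order
together with the expression table for each platform, the gene lookup
table, and compendium metadata (source accessions, view counts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from lxml import etree
from PIL import Image

from .errors import ViewError
from .expression import ExpressionMatrix, GeneLookup, load_expression_table

RGB = tuple[int, int, int]


def parse_hex_colour(text: str) -> RGB:
    """Parse ``#RRGGBB`` into an RGB triple."""
    t = text.strip()
    if len(t) != 7 or not t.startswith("#"):
        raise ViewError(f"malformed hex colour {text!r} (expected #RRGGBB)")
    try:
        return tuple(int(t[i : i + 2], 16) for i in (1, 3, 5))  # type: ignore[return-value]
    except ValueError:
        raise ViewError(f"malformed hex colour {text!r}") from None


def format_hex_colour(colour: RGB) -> str:
    """Format an RGB triple as uppercase ``#RRGGBB``."""
    return "#{:02X}{:02X}{:02X}".format(*colour)


@dataclass(frozen=True)
class TissueGroup:
    """One tissue region: name, key colour, replicate samples, record link."""

    name: str
    key_colour: RGB
    sample_ids: tuple[str, ...]
    record_id: Optional[str] = None
    centroid_hint: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not self.sample_ids:
            raise ViewError(f"group {self.name!r} has no samples")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ViewError(f"group {self.name!r} lists duplicate sample ids")


@dataclass(frozen=True)
class ViewDefinition:
    """One anatomical view: base image + ordered tissue groups."""

    name: str
    base_image_path: str
    platform_tag: str
    groups: tuple[TissueGroup, ...]
    comparability_note: Optional[str] = None

    def __post_init__(self) -> None:
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ViewError(f"view {self.name!r} has duplicate group names")
        colours = [g.key_colour for g in self.groups]
        if len(set(colours)) != len(colours):
            raise ViewError(f"view {self.name!r} has duplicate key colours")

    def group(self, name: str) -> TissueGroup:
        for g in self.groups:
            if g.name == name:
                return g
        raise ViewError(f"no group {name!r} in view {self.name!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [s for g in self.groups for s in g.sample_ids]

    def load_base_image(self) -> Image.Image:
        path = Path(self.base_image_path)
        if not path.exists():
            raise ViewError(f"base image not found: {path}")
        return Image.open(path).convert("RGB")


# ---------------------------------------------------------------------------
# XML read/write


def parse_view_xml(path: str | Path) -> ViewDefinition:
    """Parse a view control file; errors carry XML line numbers.

    A relative ``image`` attribute is resolved against the XML file's
    directory.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ViewError(f"{path.name}: malformed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "view":
        raise ViewError(f"{path.name}:{root.sourceline}: root element must be <view>")

    def need(el: etree._Element, attr: str) -> str:
        val = el.get(attr)
        if val is None:
            raise ViewError(
                f"{path.name}:{el.sourceline}: <{el.tag}> missing attribute {attr!r}"
            )
        return val

    image = need(root, "image")
    image_path = Path(image)
    if not image_path.is_absolute():
        image_path = path.parent / image_path

    groups: list[TissueGroup] = []
    seen_colours: dict[RGB, int] = {}
    for g in root.iterchildren("group"):
        try:
            colour = parse_hex_colour(need(g, "colour"))
        except ViewError as exc:
            raise ViewError(f"{path.name}:{g.sourceline}: {exc}") from None
        if colour in seen_colours:
            raise ViewError(
                f"{path.name}:{g.sourceline}: key colour "
                f"{format_hex_colour(colour)} already used at line "
                f"{seen_colours[colour]}"
            )
        seen_colours[colour] = g.sourceline
        samples = tuple(need(s, "id") for s in g.iterchildren("sample"))
        centroid = None
        for c in g.iterchildren("centroid"):
            centroid = (int(need(c, "x")), int(need(c, "y")))
        try:
            groups.append(
                TissueGroup(
                    name=need(g, "name"),
                    key_colour=colour,
                    sample_ids=samples,
                    record_id=g.get("record_id"),
                    centroid_hint=centroid,
                )
            )
        except ViewError as exc:
            raise ViewError(f"{path.name}:{g.sourceline}: {exc}") from None
    try:
        return ViewDefinition(
            name=need(root, "name"),
            base_image_path=str(image_path),
            platform_tag=need(root, "platform"),
            groups=tuple(groups),
            comparability_note=root.get("comparability_note"),
        )
    except ViewError as exc:
        raise ViewError(f"{path.name}: {exc}") from None


def write_view_xml(view: ViewDefinition, path: str | Path) -> None:
    """Serialize a view to schema-conformant XML (round-trips through
    :func:`parse_view_xml`); colours emitted as uppercase hex, groups in
    order."""
    root = etree.Element("view")
    root.set("name", view.name)
    root.set("platform", view.platform_tag)
    root.set("image", str(view.base_image_path))
    if view.comparability_note is not None:
        root.set("comparability_note", view.comparability_note)
    for g in view.groups:
        ge = etree.SubElement(root, "group")
        ge.set("name", g.name)
        ge.set("colour", format_hex_colour(g.key_colour))
        if g.record_id is not None:
            ge.set("record_id", g.record_id)
        for s in g.sample_ids:
            etree.SubElement(ge, "sample").set("id", s)
        if g.centroid_hint is not None:
            ce = etree.SubElement(ge, "centroid")
            ce.set("x", str(g.centroid_hint[0]))
            ce.set("y", str(g.centroid_hint[1]))
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Finding:
    """One validation finding; ``level`` is ``"error"`` or ``"warning"``."""

    level: str
    message: str


def validate_view(
    view: ViewDefinition, matrix: Optional[ExpressionMatrix] = None
) -> list[Finding]:
    """Structural QC of a view against its base image and, optionally, an
    expression matrix.

    Errors: unreadable base image, key colour absent from the image.
    Warnings: sample listed in the view but absent from the matrix.
    Duplicate names/colours are rejected at construction time already.
    An empty list means the view is valid.
    """
    findings: list[Finding] = []
    try:
        img = view.load_base_image()
    except (ViewError, OSError) as exc:
        findings.append(Finding("error", f"base image unreadable: {exc}"))
        img = None
    if img is not None:
        arr = np.asarray(img)
        present = {
            tuple(int(v) for v in c) for c in np.unique(arr.reshape(-1, 3), axis=0)
        }
        for g in view.groups:
            if g.key_colour not in present:
                findings.append(
                    Finding(
                        "error",
                        f"key colour {format_hex_colour(g.key_colour)} of group "
                        f"{g.name!r} absent from base image",
                    )
                )
    if matrix is not None:
        for g in view.groups:
            for s in g.sample_ids:
                if s not in matrix.values.columns:
                    findings.append(
                        Finding(
                            "warning",
                            f"sample {s!r} of group {g.name!r} absent from matrix",
                        )
                    )
    return findings


# ---------------------------------------------------------------------------
# catalog


@dataclass
class ViewCatalog:
    """Ordered collection of views plus compendium metadata and data paths.

    ``expression_paths`` maps platform tag to the expression table for
    that platform; ``lookup_path`` locates the gene lookup table.
    """

    views: list[ViewDefinition]
    metadata: dict = field(default_factory=dict)
    expression_paths: dict[str, str] = field(default_factory=dict)
    lookup_path: Optional[str] = None

    def __post_init__(self) -> None:
        names = [v.name for v in self.views]
        if len(set(names)) != len(names):
            raise ViewError("catalog has duplicate view names")

    @property
    def view_names(self) -> list[str]:
        return [v.name for v in self.views]

    def get_view(self, name: str) -> ViewDefinition:
        for v in self.views:
            if v.name == name:
                return v
        raise ViewError(
            f"no view {name!r}; available views: {', '.join(self.view_names)}"
        )

    def views_for_platform(self, platform_tag: str) -> list[ViewDefinition]:
        return [v for v in self.views if v.platform_tag == platform_tag]

    def load_matrix(self, platform_tag: str) -> ExpressionMatrix:
        if platform_tag not in self.expression_paths:
            raise ViewError(
                f"catalog has no expression table for platform {platform_tag!r}"
            )
        return load_expression_table(self.expression_paths[platform_tag], platform_tag)

    def load_lookup(self) -> GeneLookup:
        if self.lookup_path is None:
            raise ViewError("catalog has no lookup table")
        return GeneLookup.from_tsv(self.lookup_path)


def load_catalog(manifest_path: str | Path) -> ViewCatalog:
    """Load a catalog from its JSON manifest; relative paths resolve
    against the manifest's directory."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    root = manifest_path.parent

    def resolve(p: str) -> str:
        pp = Path(p)
        return str(pp if pp.is_absolute() else root / pp)

    views = [parse_view_xml(resolve(p)) for p in manifest.get("views", [])]
    return ViewCatalog(
        views=views,
        metadata=manifest.get("metadata", {}),
        expression_paths={
            plat: resolve(p) for plat, p in manifest.get("expression", {}).items()
        },
        lookup_path=(
            resolve(manifest["lookup"]) if manifest.get("lookup") else None
        ),
    )


def save_catalog(
    catalog: ViewCatalog, directory: str | Path, manifest_name: str = "catalog.json"
) -> Path:
    """Write each view's XML plus the JSON manifest into ``directory``.

    View XML files are named from a slug of the view name; expression and
    lookup paths are recorded relative to the directory when possible.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    view_files = []
    for v in catalog.views:
        slug = "".join(c.lower() if c.isalnum() else "_" for c in v.name)
        fname = f"{slug}.xml"
        write_view_xml(v, directory / fname)
        view_files.append(fname)

    def relativize(p: str) -> str:
        try:
            return str(Path(p).relative_to(directory))
        except ValueError:
            return str(p)

    manifest = {
        "views": view_files,
        "expression": {
            plat: relativize(p) for plat, p in catalog.expression_paths.items()
        },
        "lookup": relativize(catalog.lookup_path) if catalog.lookup_path else None,
        "metadata": catalog.metadata,
    }
    out = directory / manifest_name
    with open(out, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
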