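"""Expression compendium: matrices, gene lookup, and per-tissue summaries.

The compendium is a set of normalized expression matrices (microarray
signal or RNA-seq FPKM), one per platform, with rows keyed by measurement
identifier (Affymetrix probe set or gene) and columns by sample.  A gene
lookup table maps Entrez IDs, gene symbols and probe-set IDs onto each
other so a user may query by any of the three.  Per-tissue summary
statistics (mean, sample SD) over the replicate samples of a view's
tissue groups feed the colour engine and the output table.

Missing cells (blank or ``NA`` in the source table, or samples listed in
a view but absent from the matrix) propagate as "no data" — never as 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AmbiguousGeneError, DataFormatError, GeneNotFoundError

if TYPE_CHECKING:  # pragma: no cover
    from .views import ViewCatalog, ViewDefinition

_NA_STRINGS = {"", "NA", "N/A", "NaN", "nan", "null", "NULL"}


# ---------------------------------------------------------------------------
# expression matrix


class ExpressionMatrix:
    """Non-negative expression values per (measurement, sample).

    Thin wrapper around a float ``DataFrame`` (rows = measurements,
    columns = samples, ``NaN`` = missing) carrying a ``platform_tag``
    (e.g. ``"HG-U133A"`` or ``"RNA-seq-FPKM"``).  Values within one
    platform are comparable; values across platforms are not.
    """

    def __init__(self, values: pd.DataFrame, platform_tag: str):
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise DataFormatError(f"duplicate measurement id: {dup!r}")
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()][0]
            raise DataFormatError(f"duplicate sample id: {dup!r}")
        values = values.astype(float)
        arr = values.to_numpy()
        if np.isinf(arr).any():
            raise DataFormatError("expression values must be finite")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise DataFormatError(
                f"negative expression value at "
                f"({values.index[r]!r}, {values.columns[c]!r})"
            )
        values.index.name = None
        values.columns.name = None
        self.values = values
        self.platform_tag = platform_tag

    # -- basic introspection -------------------------------------------------

    @property
    def measurement_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __contains__(self, measurement_id: str) -> bool:
        return measurement_id in self.values.index

    def row(self, measurement_id: str) -> pd.Series:
        if measurement_id not in self:
            raise GeneNotFoundError(measurement_id)
        return self.values.loc[measurement_id]

    def grand_mean(self, measurement_id: str) -> float:
        """Mean over the row's non-missing cells; NaN if all missing."""
        return float(self.row(measurement_id).mean())

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="measurement_id", na_rep="NA")

    def __repr__(self) -> str:  # pragma: no cover
        n, m = self.shape
        return f"<ExpressionMatrix {n} measurements x {m} samples [{self.platform_tag}]>"


def load_expression_table(path: str | Path, platform_tag: str) -> ExpressionMatrix:
    """Load a delimited expression table into an :class:`ExpressionMatrix`.

    The table must have a header row of sample IDs and measurement IDs in
    the first column; ``.csv`` files are comma-delimited, anything else is
    read as tab-delimited.  Blank/``NA`` cells become missing values.
    Duplicate row or column IDs and non-numeric cells are hard errors that
    name the offending coordinate.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    # check the header ourselves: pandas silently mangles duplicate columns
    with open(path) as fh:
        header = [c.strip() for c in fh.readline().rstrip("\n").split(sep)][1:]
    seen: set[str] = set()
    for col in header:
        if col in seen:
            raise DataFormatError(f"duplicate sample id {col!r} in {path.name}")
        seen.add(col)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = raw.columns.astype(str).str.strip()
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise DataFormatError(f"duplicate measurement id {dup!r} in {path.name}")

    stripped = raw.apply(lambda col: col.str.strip())
    numeric = stripped.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() & ~stripped.isin(_NA_STRINGS)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataFormatError(
            f"non-numeric cell {stripped.iat[r, c]!r} at "
            f"(row {raw.index[r]!r}, column {raw.columns[c]!r}) in {path.name}"
        )
    return ExpressionMatrix(numeric, platform_tag)


# ---------------------------------------------------------------------------
# gene lookup


@dataclass(frozen=True)
class GeneRecord:
    """One gene: Entrez ID, symbol, its probe sets, and free-text annotation."""

    entrez_id: str
    symbol: str
    probeset_ids: tuple[str, ...]
    annotation: str = ""


class GeneLookup:
    """Bidirectional mapping among Entrez ID, symbol, and probe-set IDs.

    Probe-set and Entrez queries are matched exactly; symbols are matched
    case-insensitively.  Each probe set may belong to at most one record.
    """

    def __init__(self, records: Iterable[GeneRecord]):
        self.records: list[GeneRecord] = list(records)
        self._by_probeset: dict[str, GeneRecord] = {}
        self._by_entrez: dict[str, GeneRecord] = {}
        self._by_symbol: dict[str, list[GeneRecord]] = {}
        for rec in self.records:
            for ps in rec.probeset_ids:
                if ps in self._by_probeset:
                    raise DataFormatError(
                        f"probe set {ps!r} mapped by more than one record"
                    )
                self._by_probeset[ps] = rec
            self._by_entrez.setdefault(rec.entrez_id, rec)
            self._by_symbol.setdefault(rec.symbol.lower(), []).append(rec)

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneLookup":
        """Read a lookup table: columns entrez_id, symbol, probeset_ids
        (comma-joined), annotation."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = {"entrez_id", "symbol", "probeset_ids"}
        missing = required - set(df.columns)
        if missing:
            raise DataFormatError(
                f"lookup table {Path(path).name} lacks columns: {sorted(missing)}"
            )
        records = []
        for _, row in df.iterrows():
            probesets = tuple(
                p.strip() for p in row["probeset_ids"].split(",") if p.strip()
            )
            records.append(
                GeneRecord(
                    entrez_id=row["entrez_id"].strip(),
                    symbol=row["symbol"].strip(),
                    probeset_ids=probesets,
                    annotation=row.get("annotation", ""),
                )
            )
        return cls(records)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "entrez_id": r.entrez_id,
                "symbol": r.symbol,
                "probeset_ids": ",".join(r.probeset_ids),
                "annotation": r.annotation,
            }
            for r in self.records
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def resolve_gene(query: str, lookup: GeneLookup) -> tuple[list[str], GeneRecord]:
    """Resolve a user query to the probe sets of one gene record.

    Match priority: exact probe-set ID, then exact Entrez ID, then
    case-insensitive symbol.  Returns *all* probe sets of the matched
    record (so ``"p1"`` resolves to every probe set of p1's gene).
    """
    if len(lookup) == 0:
        raise GeneNotFoundError(query, "gene lookup is empty")
    q = query.strip()
    rec = lookup._by_probeset.get(q)
    if rec is None:
        rec = lookup._by_entrez.get(q)
    if rec is None:
        by_symbol = lookup._by_symbol.get(q.lower(), [])
        if len(by_symbol) > 1:
            raise AmbiguousGeneError(q, [r.entrez_id for r in by_symbol])
        if by_symbol:
            rec = by_symbol[0]
    if rec is None:
        raise GeneNotFoundError(q)
    return list(rec.probeset_ids), rec


def select_measurement(
    candidates: Sequence[str],
    matrix: ExpressionMatrix,
    override: str | None = None,
) -> str:
    """Pick the measurement row to display for a multi-probe-set gene.

    With no override, the candidate with the highest grand mean over
    non-missing cells wins; ties break lexicographically.  Candidates
    absent from the matrix are dropped with a warning; if none remain it
    is a hard error.
    """
    if not candidates:
        raise GeneNotFoundError("<empty>", "no candidate measurements")
    if override is not None:
        if override not in candidates:
            raise GeneNotFoundError(
                override, f"override {override!r} is not among candidates {list(candidates)}"
            )
        if override not in matrix:
            raise GeneNotFoundError(override, f"override {override!r} absent from matrix")
        return override
    present = []
    for c in candidates:
        if c in matrix:
            present.append(c)
        else:
            warnings.warn(f"measurement {c!r} absent from matrix; dropped", stacklevel=2)
    if not present:
        raise GeneNotFoundError(
            str(list(candidates)), f"none of {list(candidates)} present in matrix"
        )
    # highest grand mean wins; NaN grand means (all-missing rows) sort last
    def key(mid: str) -> tuple[float, str]:
        gm = matrix.grand_mean(mid)
        return (-gm if not math.isnan(gm) else math.inf, mid)

    return min(present, key=key)


# ---------------------------------------------------------------------------
# per-tissue summaries


@dataclass(frozen=True)
class TissueSummary:
    """Mean and sample SD (n-1 denominator) over one tissue group's replicates.

    ``missing`` is True iff no sample in the group carried a value; the
    statistics are then undefined (NaN) and must not be consumed.
    A single-replicate group has sd = 0.
    """

    tissue_name: str
    mean: float
    sd: float
    n: int
    missing: bool = False


def tissue_summaries(
    measurement_id: str,
    matrix: ExpressionMatrix,
    view: "ViewDefinition",
) -> list[TissueSummary]:
    """One :class:`TissueSummary` per tissue group, in view order.

    Samples listed in the view but absent from the matrix count as
    missing (not errors), so a single view catalog can serve subsets of
    the compendium.
    """
    row = matrix.row(measurement_id)
    out: list[TissueSummary] = []
    for group in view.groups:
        vals = [
            float(row[s])
            for s in group.sample_ids
            if s in row.index and not pd.isna(row[s])
        ]
        if not vals:
            out.append(
                TissueSummary(group.name, math.nan, math.nan, 0, missing=True)
            )
            continue
        arr = np.asarray(vals, dtype=float)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        out.append(TissueSummary(group.name, mean, sd, arr.size))
    return out


@dataclass(frozen=True)
class ViewMaximum:
    """Location of the highest tissue-level expression across a catalog."""

    view_name: str
    tissue_name: str
    mean: float


def max_across_views(
    measurement_id: str,
    matrix: ExpressionMatrix,
    catalog: "Sequence[ViewDefinition]",
) -> ViewMaximum:
    """The (view, tissue) with the maximal tissue mean across a catalog.

    Ties break by catalog order, then tissue order within the view.
    All views must reference the matrix's platform.
    """
    if not catalog:
        raise ValueError("catalog is empty")
    if measurement_id not in matrix:
        raise GeneNotFoundError(measurement_id)
    best: ViewMaximum | None = None
    for view in catalog:
        for summary in tissue_summaries(measurement_id, matrix, view):
            if summary.missing:
                continue
            if best is None or summary.mean > best.mean:
                best = ViewMaximum(view.name, summary.tissue_name, summary.mean)
    if best is None:
        raise GeneNotFoundError(
            measurement_id, f"no tissue carries data for {measurement_id!r}"
        )
    return best
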