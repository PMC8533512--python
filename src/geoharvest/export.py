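"""Export of the two result tables as CSV/TSV (RFC 4180 quoting).

Table 1 is the per-query hit-count table; table 2 is the full harmonized
record table with a fixed 19-column layout. Two presentation features
matter for downstream manual curation in spreadsheet software:

* records with several organisms or experiment types are split into one
  row per (organism, type) combination so single-value column filters work
  (enabled by default, can be disabled, in which case the values are joined
  with "; ");
* the concatenated protocol text can exceed the cell-size ceiling of most
  spreadsheet programs, so it is chunked into adjacent "All protocols (k)"
  overflow columns at a configurable character limit (default 32 000,
  just under the common 32 767-character cell ceiling).
"""

from __future__ import annotations

import copy
import csv
import math
from pathlib import Path

from .model import ArticleRef, DatasetRecord, LabeledBlock, Query, QueryCountRow

#: The fixed column order of export table 2.
TABLE2_COLUMNS = [
    "Accession", "Organism", "Samples", "Type", "Platform", "Title", "Year",
    "Summary", "Link", "Paper_title", "Journal", "Impact factor",
    "DOI or PubMed", "All references", "Type of molecule",
    "BioProjectlink (NCBI)", "BioProjectlink (EBI)", "SRA", "All protocols",
]

DEFAULT_CHUNK_LIMIT = 32000

MULTIVALUE_JOIN = "; "
REFERENCE_JOIN = " || "


def split_multivalue_rows(rec: DatasetRecord, enabled: bool = True) -> list[DatasetRecord]:
    """One row per (organism, experiment type) combination when enabled.

    Disabled, the record passes through unchanged (multi-value fields are
    joined at serialization). Splitting conserves information: regrouping
    the split rows by accession recovers the original organisms × types
    Cartesian product.
    """
    if not enabled:
        return [rec]
    rows = []
    for organism in rec.organisms:
        for etype in rec.types:
            row = copy.copy(rec)
            row.organisms = [organism]
            row.types = [etype]
            rows.append(row)
    return rows


def chunk_text(t: str, limit: int) -> list[str]:
    """Split text at exact character boundaries into cells of <= limit chars.

    Concatenating the cells reproduces the input byte-for-byte; the cell
    count is ceil(len(t)/limit), with one empty cell for empty text.
    """
    if limit < 1:
        raise ValueError("chunk limit must be >= 1")
    if not t:
        return [""]
    return [t[i:i + limit] for i in range(0, len(t), limit)]


def _format_reference(ref: ArticleRef) -> str:
    ident = ref.doi or ref.pmid or ""
    return f"{ref.title} | {ref.journal} | {ident}"


def protocols_text(blocks: list[LabeledBlock]) -> str:
    """Join labeled blocks with 'LABEL: ' prefixes and blank-line separators."""
    return "\n\n".join(f"{b.label}: {b.text}" for b in blocks)


def record_to_cells(rec: DatasetRecord, chunk_limit: int = DEFAULT_CHUNK_LIMIT) -> list[str]:
    """Serialize one record as the fixed 19 columns plus protocol overflow cells.

    Absent values serialize as empty strings, never as a sentinel token.
    """
    primary = rec.primary_reference
    impact = "" if primary is None or primary.impact_factor is None \
        else f"{primary.impact_factor:g}"
    doi_or_pmid = "" if primary is None else (primary.doi or primary.pmid or "")
    cells = [
        rec.accession.value,
        MULTIVALUE_JOIN.join(rec.organisms),
        str(rec.samples),
        MULTIVALUE_JOIN.join(rec.types),
        MULTIVALUE_JOIN.join(rec.platform),
        rec.title,
        str(rec.year),
        rec.summary,
        rec.link,
        "" if primary is None else primary.title,
        "" if primary is None else primary.journal,
        impact,
        doi_or_pmid,
        REFERENCE_JOIN.join(_format_reference(r) for r in rec.all_references),
        rec.molecule_type or "",
        rec.bioproject_ncbi or "",
        rec.bioproject_ebi or "",
        rec.sra or "",
    ]
    cells.extend(chunk_text(protocols_text(rec.all_protocols), chunk_limit))
    return cells


def write_table2(records: list[DatasetRecord], path: str | Path,
                 fmt: str = "csv", chunk_limit: int = DEFAULT_CHUNK_LIMIT,
                 split: bool = True) -> Path:
    """Write export table 2; header columns appear in the fixed order.

    Protocol overflow columns ("All protocols (2)", ...) appear only when
    some record needs them; shorter rows are padded so every row has the
    same field count under a strict CSV reader.
    """
    path = Path(path)
    rows = []
    for rec in records:
        for split_rec in split_multivalue_rows(rec, enabled=split):
            rows.append(record_to_cells(split_rec, chunk_limit))
    base = len(TABLE2_COLUMNS)
    width = max((len(r) for r in rows), default=base)
    header = list(TABLE2_COLUMNS) + [
        f"All protocols ({k})" for k in range(2, width - base + 2)]
    delimiter = "\t" if fmt == "tsv" else ","
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(header)
        for row in rows:
            writer.writerow(row + [""] * (width - len(row)))
    return path


def write_table1(rows: list[QueryCountRow], path: str | Path,
                 fmt: str = "csv") -> Path:
    """Write export table 1: one `query,n_datasets` row per query, in order."""
    path = Path(path)
    delimiter = "\t" if fmt == "tsv" else ","
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["query", "n_datasets"])
        for row in rows:
            writer.writerow([row.query.raw, str(row.n_datasets)])
    return path


def read_table1(path: str | Path) -> list[QueryCountRow]:
    """Read table 1 back (inverse of write_table1 up to query normalization)."""
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        next(reader, None)
        return [QueryCountRow(Query.from_raw(q), int(n)) for q, n in reader]


def read_table2(path: str | Path, fmt: str = "csv") -> list[dict[str, str]]:
    """Read table 2 rows as dicts; overflow protocol cells are re-joined
    into the "All protocols" key."""
    delimiter = "\t" if fmt == "tsv" else ","
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        header = next(reader)
        n_base = len(TABLE2_COLUMNS)
        rows = []
        for cells in reader:
            row = dict(zip(header[:n_base - 1], cells[:n_base - 1]))
            row["All protocols"] = "".join(cells[n_base - 1:])
            rows.append(row)
        return rows


def expected_protocol_columns(total_chars: int, chunk_limit: int) -> int:
    """How many protocol cells a text of the given length occupies."""
    return max(1, math.ceil(total_chars / chunk_limit))
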