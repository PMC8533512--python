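"""Block 1 of the workflow: multi-query search over GEO and ArrayExpress.

Each free-text query runs against both repositories. GEO is searched via
the E-utilities ``esearch`` endpoint restricted to series (GSE) entries;
ArrayExpress is queried so that only its native datasets come back, with
any GEO-mirror (E-GEOD) accession that slips through dropped afterwards.
Per-query hit counts feed export table 1; the union of all hits — after
collapsing E-GEOD mirrors onto their GSE originals — is the master
accession list passed to the harvesting block.

Queries are submitted verbatim: the whole point of a query *list* is that
users need not hand-build AND/OR expressions for a systematic search.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._xml import find_all, local_name, parse_xml, text_of
from .errors import FormatError, ValidationError
from .model import Accession, Query, QueryCountRow, canonical_accession
from .transport import GEO_SERIES_UID_BASE, Fetcher, FetchRequest


@dataclass
class SearchResult:
    """Hits of one query against both repositories (each internally unique)."""

    query: Query
    geo_hits: list[Accession]
    ae_hits: list[Accession]


def load_queries(text: str) -> list[Query]:
    """One query per non-blank line; duplicates (after lowercasing and
    whitespace collapsing) keep the first occurrence only."""
    queries: list[Query] = []
    seen: set[str] = set()
    for line in text.splitlines():
        if not line.strip():
            continue
        q = Query.from_raw(line)
        if q.normalized not in seen:
            seen.add(q.normalized)
            queries.append(q)
    if not queries:
        raise ValidationError("no queries: input contains only blank lines")
    return queries


def search_geo(q: Query, fetcher: Fetcher) -> list[Accession]:
    """GEO series accessions matching the query (series UIDs decoded)."""
    body, _ = fetcher.fetch(FetchRequest("geo_search", {"term": q.normalized}))
    root = parse_xml(body)
    if local_name(root) != "eSearchResult":
        raise FormatError("unparseable esearch response from geo_search")
    hits: list[Accession] = []
    seen: set[str] = set()
    for id_el in find_all(root, "Id"):
        uid = int(text_of(id_el) or 0)
        if uid <= GEO_SERIES_UID_BASE:
            continue  # not a series UID
        value = f"GSE{uid - GEO_SERIES_UID_BASE}"
        if value not in seen:
            seen.add(value)
            hits.append(Accession(value, "GEO"))
    return hits


def search_ae(q: Query, fetcher: Fetcher) -> list[Accession]:
    """Native ArrayExpress accessions matching the query.

    GEO-imported entries are excluded at query time; any E-GEOD accession
    that nonetheless appears is dropped post-hoc.
    """
    body, _ = fetcher.fetch(FetchRequest("ae_search", {"keywords": q.normalized}))
    root = parse_xml(body)
    if local_name(root) != "experiments":
        raise FormatError("unparseable experiments response from ae_search")
    hits: list[Accession] = []
    seen: set[str] = set()
    for acc_el in find_all(root, "accession"):
        value = text_of(acc_el)
        if not value or value.startswith("E-GEOD-") or value in seen:
            continue
        seen.add(value)
        hits.append(Accession(value, "AE"))
    return hits


def run_queries(queries: list[Query], fetcher: Fetcher) -> list[SearchResult]:
    """Run every query against both repositories, in order."""
    return [SearchResult(q, search_geo(q, fetcher), search_ae(q, fetcher))
            for q in queries]


def merge_and_count(
    results: list[SearchResult],
) -> tuple[list[Accession], list[QueryCountRow]]:
    """Build the globally deduplicated master list and the per-query counts.

    Per-query counts are taken after collapsing GEO/AE mirrors *within* the
    query; the master list additionally removes overlaps *across* queries,
    preserving first-seen order. Counts may therefore sum to more than the
    master list length whenever an accession matches several queries.
    """
    master: list[Accession] = []
    seen: set[str] = set()
    table1: list[QueryCountRow] = []
    for result in results:
        canon = [canonical_accession(a) for a in result.geo_hits + result.ae_hits]
        within: list[Accession] = []
        within_seen: set[str] = set()
        for a in canon:
            if a.value not in within_seen:
                within_seen.add(a.value)
                within.append(a)
        table1.append(QueryCountRow(result.query, len(within)))
        for a in within:
            if a.value not in seen:
                seen.add(a.value)
                master.append(a)
    return master, table1
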