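"""PubMed reference resolution and impact-factor ranking.

Each harvested dataset may cite one or more articles (by PubMed ID or DOI).
These are resolved to title/journal/identifiers through the PubMed summary
endpoint, assigned a journal impact factor from a static lookup table, and
the reference in the highest-impact journal is promoted to the record's
primary reference (its own export columns); all references are kept in the
"All references" block.

The bundled impact-factor table is synthetic: real JCR impact-factor data
cannot be redistributed, so users supply their own two-column TSV
(``journal<TAB>impact_factor``) for production use.
"""

from __future__ import annotations

import logging
import re
from importlib import resources
from pathlib import Path

from ._xml import find_all, parse_xml, text_of
from .errors import FetchError, FormatError, ResolutionError
from .model import ArticleRef, DatasetRecord
from .transport import Fetcher, FetchRequest

log = logging.getLogger(__name__)

_PUNCT = re.compile(r"[^a-z0-9]+")


def normalize_journal(name: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace runs."""
    return _PUNCT.sub(" ", name.lower()).strip()


def load_impact_factors(path: str | Path | None = None) -> dict[str, float]:
    """Load a journal→impact-factor TSV keyed by normalized journal name.

    A header row is auto-detected (non-numeric second field). With no path,
    the small synthetic table bundled with the package is used.
    """
    if path is None:
        source = resources.files("geoharvest.data") / "impact_factors_synthetic.tsv"
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    table: dict[str, float] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        journal, _, value = line.partition("\t")
        try:
            impact = float(value.strip())
        except ValueError:
            continue  # header or malformed row
        table[normalize_journal(journal)] = impact
    return table


def lookup_impact_factor(journal: str, if_table: dict[str, float]) -> float | None:
    """Impact factor for a journal name, or None when the table lacks it."""
    return if_table.get(normalize_journal(journal))


def fetch_article(identifier: str, fetcher: Fetcher) -> ArticleRef:
    """Resolve a PubMed ID or DOI to an ArticleRef (impact factor unset).

    Raises :class:`ResolutionError` carrying the raw identifier when PubMed
    does not know it; callers keep an unresolved stub and continue.
    """
    if not identifier:
        raise ResolutionError(identifier)
    try:
        body, _ = fetcher.fetch(FetchRequest("pubmed_summary", {"id": identifier}))
    except FetchError as exc:
        if exc.transient:
            raise
        raise ResolutionError(identifier) from exc
    root = parse_xml(body)
    docsum = next(iter(find_all(root, "DocSum")), None)
    if docsum is None:
        raise FormatError("PubMed summary response has no DocSum element")
    pmid = text_of(next(iter(find_all(docsum, "Id")), None))
    fields = {item.get("Name"): text_of(item) for item in find_all(docsum, "Item")}
    return ArticleRef(
        pmid=pmid,
        doi=fields.get("DOI"),
        title=fields.get("Title") or "",
        journal=fields.get("FullJournalName") or "",
    )


def _tie_break_key(ref: ArticleRef) -> tuple:
    has_if = ref.impact_factor is not None
    pmid_num = int(ref.pmid) if ref.pmid and ref.pmid.isdigit() else None
    return (
        not has_if,                                # refs with an IF rank first
        -(ref.impact_factor or 0.0),
        pmid_num is None,                          # numeric PMIDs before DOI-only
        pmid_num if pmid_num is not None else 0,
        ref.doi or "",
    )


def select_primary_reference(refs: list[ArticleRef]) -> ArticleRef | None:
    """The reference published in the highest-impact journal.

    References without an impact factor rank below any that have one; ties
    break by smallest numeric PMID, then lexicographically smallest DOI.
    The result is invariant under permutation of ``refs``.
    """
    if not refs:
        return None
    return min(refs, key=_tie_break_key)


def resolve_references(record: DatasetRecord, fetcher: Fetcher,
                       if_table: dict[str, float]) -> DatasetRecord:
    """Fill in all_references and primary_reference from reference_ids.

    Unresolvable identifiers degrade to raw-ID stubs (PMID-shaped IDs kept
    as PMIDs, anything else as a DOI) and never abort the harvest.
    """
    refs: list[ArticleRef] = []
    for identifier in record.reference_ids:
        try:
            ref = fetch_article(identifier, fetcher)
        except ResolutionError:
            log.warning("reference %s unresolved for %s; keeping a stub",
                        identifier, record.accession.value)
            if identifier.isdigit():
                ref = ArticleRef(pmid=identifier)
            else:
                ref = ArticleRef(doi=identifier)
        if ref.journal and ref.impact_factor is None:
            impact = lookup_impact_factor(ref.journal, if_table)
            if impact is not None:
                ref = ArticleRef(pmid=ref.pmid, doi=ref.doi, title=ref.title,
                                 journal=ref.journal, impact_factor=impact)
        refs.append(ref)
    record.all_references = refs
    record.primary_reference = select_primary_reference(refs)
    return record
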