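"""Parsing of ArrayExpress experiment and protocol XML into the unified record.

ArrayExpress serves one XML document per experiment with the basic dataset
description; the full protocol texts are not inlined — the experiment lists
protocol IDs, and each protocol is fetched separately by ID as its own XML
document. The two-step harvest (experiment, then protocols) mirrors that
service design. A missing protocol document degrades to a logged gap rather
than failing the record.
"""

from __future__ import annotations

import logging

from ._xml import find_all, first, parse_xml, text_of
from .errors import FetchError, FormatError, ValidationError
from .miniml import BIOPROJECT_EBI_URL, BIOPROJECT_NCBI_URL, SRA_URL
from .model import Accession, DatasetRecord, LabeledBlock
from .transport import Fetcher, FetchRequest

AE_RECORD_URL = "https://www.ebi.ac.uk/arrayexpress/experiments/{acc}/"

log = logging.getLogger(__name__)


class AEExperiment:
    """Dataset-level fields of one ArrayExpress experiment document."""

    def __init__(self, accession: str, title: str | None, organisms: list[str],
                 n_samples: int, types: list[str], submission_year: int | None,
                 summary: str | None, pubmed_ids: list[str], dois: list[str],
                 protocol_ids: list[str], molecule_type: str | None,
                 bioproject_id: str | None, sra_id: str | None):
        self.accession = accession
        self.title = title
        self.organisms = organisms
        self.n_samples = n_samples
        self.types = types
        self.submission_year = submission_year
        self.summary = summary
        self.pubmed_ids = pubmed_ids
        self.dois = dois
        self.protocol_ids = protocol_ids
        self.molecule_type = molecule_type
        self.bioproject_id = bioproject_id
        self.sra_id = sra_id


def _unique(values: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for v in values:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


def parse_ae_experiment(doc: bytes) -> AEExperiment:
    """Parse one experiment document; capture semantics match the GEO parser
    (verbatim fields, whitespace trimmed, document order preserved)."""
    root = parse_xml(doc)
    exp = first(root, "experiment")
    if exp is None:
        raise FormatError("ArrayExpress document has no experiment element")

    pmids, dois = [], []
    for bib in find_all(exp, "bibliography"):
        pmid = text_of(first(bib, "accession"))
        doi = text_of(first(bib, "doi"))
        if pmid:
            pmids.append(pmid)
        if doi:
            dois.append(doi)

    bioproject_id = sra_id = None
    for sec in find_all(exp, "secondaryaccession"):
        value = text_of(sec) or ""
        if value.startswith("PRJ") and bioproject_id is None:
            bioproject_id = value
        elif value[:3] in ("SRP", "ERP", "DRP") and sra_id is None:
            sra_id = value

    samples_text = text_of(first(exp, "samples"))
    release = text_of(first(exp, "releasedate"))
    return AEExperiment(
        accession=text_of(first(exp, "accession")) or "",
        title=text_of(first(exp, "name")),
        organisms=[o for o in (text_of(e) for e in find_all(exp, "organism")) if o],
        n_samples=int(samples_text) if samples_text else 0,
        types=[t for t in (text_of(e) for e in find_all(exp, "experimenttype")) if t],
        submission_year=int(release[:4]) if release else None,
        summary=text_of(first(exp, "description")),
        pubmed_ids=_unique(pmids),
        dois=_unique(dois),
        protocol_ids=_unique(
            [p for p in (text_of(first(e, "id")) for e in find_all(exp, "protocol")) if p]),
        molecule_type=text_of(first(exp, "moleculetype")),
        bioproject_id=bioproject_id,
        sra_id=sra_id,
    )


def resolve_protocols(ids: list[str], fetcher: Fetcher) -> list[LabeledBlock]:
    """Fetch each unique protocol ID and return (type label, text) blocks.

    Blocks come back in the order of ``ids``. A protocol document that
    cannot be fetched is a logged gap; only if *every* ID fails does the
    call raise an aggregate fetch error.
    """
    if not ids:
        raise ValidationError("resolve_protocols requires at least one protocol ID")
    blocks: list[LabeledBlock] = []
    failures: list[str] = []
    for pid in _unique(ids):
        try:
            body, _ = fetcher.fetch(FetchRequest("ae_protocol", {"id": pid}))
        except FetchError:
            log.warning("protocol %s could not be fetched; leaving a gap", pid)
            failures.append(pid)
            continue
        root = parse_xml(body)
        proto = first(root, "protocol")
        if proto is None:
            raise FormatError(f"protocol document {pid} has no protocol element")
        label = text_of(first(proto, "type")) or "Protocol"
        text = text_of(first(proto, "text")) or ""
        if text:
            blocks.append(LabeledBlock(label, text))
    if failures and not blocks:
        raise FetchError(f"all {len(failures)} protocol fetches failed",
                         "ae_protocol", transient=True)
    return blocks


def ae_to_unified(exp: AEExperiment,
                  protocols: list[LabeledBlock]) -> DatasetRecord:
    """Map a parsed experiment + its protocol blocks onto the unified record.

    Platform stays empty when the document names none (platform IDs are a
    GEO staple but uncommon in ArrayExpress records); references stay
    unresolved in ``reference_ids`` (PMIDs first, then DOIs).
    """
    missing = []
    if not exp.accession:
        missing.append("accession")
    if not exp.title:
        missing.append("title")
    if exp.n_samples < 1:
        missing.append("samples")
    if missing:
        raise ValidationError("experiment is missing mandatory fields: " + ", ".join(missing))
    if exp.submission_year is None:
        raise ValidationError(f"experiment {exp.accession} has no release date")

    return DatasetRecord(
        accession=Accession(exp.accession, "AE"),
        organisms=list(exp.organisms),
        samples=exp.n_samples,
        types=list(exp.types),
        platform=[],
        title=exp.title,
        year=exp.submission_year,
        summary=exp.summary or "",
        link=AE_RECORD_URL.format(acc=exp.accession),
        molecule_type=exp.molecule_type,
        bioproject_ncbi=(BIOPROJECT_NCBI_URL.format(id=exp.bioproject_id)
                         if exp.bioproject_id else None),
        bioproject_ebi=(BIOPROJECT_EBI_URL.format(id=exp.bioproject_id)
                        if exp.bioproject_id else None),
        sra=SRA_URL.format(id=exp.sra_id) if exp.sra_id else None,
        all_protocols=list(protocols),
        reference_ids=_unique(exp.pubmed_ids + exp.dois),
    ).validate()
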