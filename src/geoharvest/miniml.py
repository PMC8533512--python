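"""Parsing of GEO MINiML documents into series info and sample blocks.

MINiML is GEO's XML serialization of series/sample/platform metadata. A
series document carries the dataset-level description (title, experiment
types, summary, design, dates, relations to BioProject/SRA/SuperSeries and
the PubMed reference IDs) while each sample block carries the wet-lab
detail: source cell type, treatment/growth/extraction protocols, the
molecule assayed and free-form characteristics. Only metadata is read;
expression matrices and supplementary data are out of scope.

Per-sample fields are collapsed for presentation: a protocol shared by all
samples is reported once, per-sample protocols are all kept, in first-
appearance order with exact-duplicate removal after whitespace
normalization.
"""

from __future__ import annotations

import re

from ._xml import find_all, first, local_name, parse_xml, text_of
from .errors import FormatError, ValidationError
from .model import (
    Accession,
    DatasetRecord,
    LabeledBlock,
    SampleBlock,
    normalize_ws,
)

GEO_RECORD_URL = "https://www.ncbi.nlm.nih.gov/geo/query/acc.cgi?acc={acc}"
BIOPROJECT_NCBI_URL = "https://www.ncbi.nlm.nih.gov/bioproject/{id}"
BIOPROJECT_EBI_URL = "https://www.ebi.ac.uk/ena/browser/view/{id}"
SRA_URL = "https://www.ncbi.nlm.nih.gov/sra?term={id}"

_YEAR_RE = re.compile(r"(\d{4})")


class SeriesInfo:
    """Dataset-level fields of one MINiML series document."""

    def __init__(self, accession: str, title: str | None, organisms: list[str],
                 n_samples: int, types: list[str], platform_ids: list[str],
                 submission_year: int | None, summary: str | None,
                 overall_design: str | None, pubmed_ids: list[str],
                 relations: list[tuple[str, str]],
                 bioproject_id: str | None, sra_id: str | None):
        self.accession = accession
        self.title = title
        self.organisms = organisms
        self.n_samples = n_samples
        self.types = types
        self.platform_ids = platform_ids
        self.submission_year = submission_year
        self.summary = summary
        self.overall_design = overall_design
        self.pubmed_ids = pubmed_ids
        self.relations = relations
        self.bioproject_id = bioproject_id
        self.sra_id = sra_id


def _id_from_relation_target(target: str) -> str:
    """Relation targets are URLs; the identifier is the last path/query token."""
    tail = target.rsplit("term=", 1)[-1]
    return tail.rstrip("/").rsplit("/", 1)[-1]


def _earliest_year(series_el) -> int | None:
    years = []
    for name in ("Submission-Date", "Release-Date", "Last-Update-Date"):
        for el in find_all(series_el, name):
            text = text_of(el)
            if text:
                m = _YEAR_RE.search(text)
                if m:
                    years.append(int(m.group(1)))
    return min(years) if years else None


def _parse_sample(sample_el) -> SampleBlock:
    sid = text_of(first(sample_el, "Accession")) or sample_el.get("iid", "")
    characteristics: list[tuple[str, str]] = []
    for ch in find_all(sample_el, "Characteristics"):
        value = text_of(ch)
        if value:
            characteristics.append((ch.get("tag", ""), value))
    organisms: list[str] = []
    for org in find_all(sample_el, "Organism"):
        value = text_of(org)
        if value and value not in organisms:
            organisms.append(value)
    return SampleBlock(
        sample_id=sid,
        cell_type=text_of(first(sample_el, "Source")),
        treatment_protocol=text_of(first(sample_el, "Treatment-Protocol")),
        growth_protocol=text_of(first(sample_el, "Growth-Protocol")),
        isolation_protocol=text_of(first(sample_el, "Extract-Protocol")),
        molecule_type=text_of(first(sample_el, "Molecule")),
        characteristics=characteristics,
        organisms=organisms,
    )


def parse_miniml(doc: bytes) -> tuple[SeriesInfo, list[SampleBlock]]:
    """Parse a MINiML document into (series info, sample blocks in order).

    Fields present in the document are captured verbatim (whitespace
    trimmed); absent elements yield absent fields. Raises ``ParseError`` on
    malformed XML and ``FormatError`` when no ``Series`` element exists.
    """
    root = parse_xml(doc)
    series_el = first(root, "Series")
    if series_el is None:
        raise FormatError("MINiML document has no Series element")

    sample_els = [e for e in root.iter()
                  if isinstance(e.tag, str) and local_name(e) == "Sample"]
    samples = [_parse_sample(e) for e in sample_els]
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise FormatError("duplicate sample accession within one series")

    organisms: list[str] = []
    for s in samples:
        for org in s.organisms:
            if org not in organisms:
                organisms.append(org)

    relations = [(rel.get("type", ""), rel.get("target", ""))
                 for rel in find_all(series_el, "Relation")]
    bioproject_id = sra_id = None
    for rtype, target in relations:
        if rtype == "BioProject" and bioproject_id is None:
            bioproject_id = _id_from_relation_target(target)
        elif rtype == "SRA" and sra_id is None:
            sra_id = _id_from_relation_target(target)

    n_refs = len(find_all(series_el, "Sample-Ref"))
    info = SeriesInfo(
        accession=text_of(first(series_el, "Accession")) or series_el.get("iid", ""),
        title=text_of(first(series_el, "Title")),
        organisms=organisms,
        n_samples=n_refs or len(samples),
        types=[t for t in (text_of(e) for e in find_all(series_el, "Type")) if t],
        platform_ids=[p for p in (text_of(first(e, "Accession")) or e.get("iid")
                                  for e in find_all(root, "Platform")) if p],
        submission_year=_earliest_year(series_el),
        summary=text_of(first(series_el, "Summary")),
        overall_design=text_of(first(series_el, "Overall-Design")),
        pubmed_ids=[p for p in (text_of(e) for e in find_all(series_el, "Pubmed-ID")) if p],
        relations=relations,
        bioproject_id=bioproject_id,
        sra_id=sra_id,
    )
    return info, samples


#: (label, extractor) pairs defining the collapse order over sample fields.
_COLLAPSE_FIELDS = (
    ("Cell type", lambda s: [s.cell_type] if s.cell_type else []),
    ("Treatment protocol", lambda s: [s.treatment_protocol] if s.treatment_protocol else []),
    ("Growth protocol", lambda s: [s.growth_protocol] if s.growth_protocol else []),
    ("Isolation protocol", lambda s: [s.isolation_protocol] if s.isolation_protocol else []),
    ("Molecule type", lambda s: [s.molecule_type] if s.molecule_type else []),
    ("Characteristics", lambda s: [f"{tag}: {value}" for tag, value in s.characteristics]),
)


def collapse_sample_fields(samples: list[SampleBlock]) -> list[LabeledBlock]:
    """Collapse per-sample fields into labeled blocks with duplicates removed.

    For each field kind, values are collected across samples in order of
    first appearance and exact duplicates (after whitespace normalization)
    dropped: a field identical across all n samples contributes one block, a
    field unique per sample contributes n blocks.
    """
    if not samples:
        raise ValidationError("collapse_sample_fields requires a non-empty sample list")
    blocks: list[LabeledBlock] = []
    for label, extract in _COLLAPSE_FIELDS:
        seen: set[str] = set()
        for sample in samples:
            for value in extract(sample):
                key = normalize_ws(value)
                if key and key not in seen:
                    seen.add(key)
                    blocks.append(LabeledBlock(label, key))
    return blocks


def geo_to_unified(series: SeriesInfo,
                   collapsed: list[LabeledBlock]) -> DatasetRecord:
    """Map a parsed series + collapsed sample blocks onto the unified record.

    Literature references stay unresolved (PubMed IDs are carried in
    ``reference_ids``). Raises ``ValidationError`` listing any missing
    mandatory field (accession, title, at least one sample).
    """
    missing = []
    if not series.accession:
        missing.append("accession")
    if not series.title:
        missing.append("title")
    if series.n_samples < 1:
        missing.append("samples")
    if missing:
        raise ValidationError("series is missing mandatory fields: " + ", ".join(missing))
    if series.submission_year is None:
        raise ValidationError(f"series {series.accession} has no dated status element")

    molecule = next((b.text for b in collapsed if b.label == "Molecule type"), None)
    return DatasetRecord(
        accession=Accession(series.accession, "GEO"),
        organisms=list(series.organisms),
        samples=series.n_samples,
        types=list(series.types),
        platform=list(series.platform_ids),
        title=series.title,
        year=series.submission_year,
        summary=series.summary or "",
        link=GEO_RECORD_URL.format(acc=series.accession),
        molecule_type=molecule,
        bioproject_ncbi=(BIOPROJECT_NCBI_URL.format(id=series.bioproject_id)
                         if series.bioproject_id else None),
        bioproject_ebi=(BIOPROJECT_EBI_URL.format(id=series.bioproject_id)
                        if series.bioproject_id else None),
        sra=SRA_URL.format(id=series.sra_id) if series.sra_id else None,
        all_protocols=list(collapsed),
        reference_ids=list(series.pubmed_ids),
        relations=list(series.relations),
    ).validate()
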