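"""Unified record schema shared by the GEO and ArrayExpress parser paths.

Both repositories store the same kind of information (what was measured, on
which organism, on how many samples, under which protocols, described in
which publication) but serialize it very differently. Every parser maps its
dialect onto the types below, so downstream filtering, export and curation
see homogeneous data regardless of the source database.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ValidationError

GEO_ACCESSION_RE = re.compile(r"^GSE\d+$")
AE_ACCESSION_RE = re.compile(r"^E-[A-Z]{4}-\d+$")
_E_GEOD_RE = re.compile(r"^E-GEOD-(\d+)$")
_WS_RUN = re.compile(r"\s+")


def normalize_ws(text: str) -> str:
    """Trim and collapse internal whitespace runs to single spaces."""
    return _WS_RUN.sub(" ", text).strip()


@dataclass(frozen=True)
class Query:
    """One user search request: the raw line plus its deduplication key."""

    raw: str
    normalized: str

    @classmethod
    def from_raw(cls, raw: str) -> "Query":
        return cls(raw=raw, normalized=normalize_ws(raw).lower())

    def __post_init__(self) -> None:
        if self.raw.strip() and not self.normalized:
            raise ValidationError(f"query {self.raw!r} normalized to empty text")


@dataclass(frozen=True)
class Accession:
    """A dataset identifier together with its source repository.

    GEO series are ``GSE`` + digits; ArrayExpress accessions are
    ``E-XXXX-n`` with a four-letter pipeline code. ``E-GEOD-n`` entries are
    ArrayExpress mirrors of GEO series ``GSEn`` and are collapsed onto the
    GEO form by :func:`canonical_accession`.
    """

    value: str
    source: str  # "GEO" | "AE"

    def __post_init__(self) -> None:
        if self.source == "GEO":
            if not GEO_ACCESSION_RE.match(self.value):
                raise ValidationError(f"malformed GEO accession: {self.value!r}")
        elif self.source == "AE":
            if not AE_ACCESSION_RE.match(self.value):
                raise ValidationError(f"malformed ArrayExpress accession: {self.value!r}")
        else:
            raise ValidationError(f"unknown accession source: {self.source!r}")

    @classmethod
    def parse(cls, value: str) -> "Accession":
        """Infer the source repository from the identifier shape."""
        value = value.strip()
        if GEO_ACCESSION_RE.match(value):
            return cls(value, "GEO")
        if AE_ACCESSION_RE.match(value):
            return cls(value, "AE")
        raise ValidationError(f"malformed accession: {value!r}")


def canonical_accession(a: Accession) -> Accession:
    """Map ArrayExpress GEO-mirror accessions (E-GEOD-n) onto GSEn.

    Identity on native accessions of either repository; idempotent. This is
    the only cross-database identity rule used for deduplication.
    """
    m = _E_GEOD_RE.match(a.value)
    if m:
        return Accession(f"GSE{m.group(1)}", "GEO")
    return a


@dataclass(frozen=True)
class QueryCountRow:
    """One row of the per-query hit-count table (export table 1)."""

    query: Query
    n_datasets: int

    def __post_init__(self) -> None:
        if self.n_datasets < 0:
            raise ValidationError("n_datasets must be non-negative")


@dataclass
class SampleBlock:
    """Per-sample GEO metadata: protocols, molecule and characteristics.

    ``characteristics`` preserves source-document order of tag/value pairs.
    """

    sample_id: str
    cell_type: str | None = None
    treatment_protocol: str | None = None
    growth_protocol: str | None = None
    isolation_protocol: str | None = None
    molecule_type: str | None = None
    characteristics: list[tuple[str, str]] = field(default_factory=list)
    organisms: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class LabeledBlock:
    """One labeled text block, e.g. ('Treatment protocol', 'cells were ...')."""

    label: str
    text: str


@dataclass(frozen=True)
class ArticleRef:
    """One literature reference attached to a dataset.

    At least one of ``pmid``/``doi`` must be present. ``impact_factor`` is a
    journal-level metric used only to rank a dataset's references; it is
    absent until the impact-factor table has been consulted.
    """

    pmid: str | None = None
    doi: str | None = None
    title: str = ""
    journal: str = ""
    impact_factor: float | None = None

    def __post_init__(self) -> None:
        if not self.pmid and not self.doi:
            raise ValidationError("an ArticleRef needs a PMID or a DOI")
        if self.impact_factor is not None and self.impact_factor < 0:
            raise ValidationError("impact_factor must be non-negative")


@dataclass
class DatasetRecord:
    """The unified dataset record both parser paths map onto.

    ``reference_ids`` holds unresolved PubMed IDs / DOIs between parsing and
    literature resolution; ``relations`` keeps series relation elements (for
    SuperSeries detection). Neither is an export column.
    """

    accession: Accession
    organisms: list[str]
    samples: int
    types: list[str]
    platform: list[str]
    title: str
    year: int
    summary: str
    link: str
    primary_reference: ArticleRef | None = None
    all_references: list[ArticleRef] = field(default_factory=list)
    molecule_type: str | None = None
    bioproject_ncbi: str | None = None
    bioproject_ebi: str | None = None
    sra: str | None = None
    all_protocols: list[LabeledBlock] = field(default_factory=list)
    reference_ids: list[str] = field(default_factory=list)
    relations: list[tuple[str, str]] = field(default_factory=list)

    def validate(self) -> "DatasetRecord":
        """Check all schema invariants; raise listing every violation."""
        problems: list[str] = []
        if not self.organisms:
            problems.append("organisms is empty")
        if not self.types:
            problems.append("types is empty")
        if self.samples < 1:
            problems.append(f"samples must be >= 1 (got {self.samples})")
        if not 1000 <= self.year <= 9999:
            problems.append(f"year must be a 4-digit integer (got {self.year})")
        if not self.title:
            problems.append("title is missing")
        if self.primary_reference is not None:
            if self.primary_reference not in self.all_references:
                problems.append("primary_reference is not in all_references")
            pif = self.primary_reference.impact_factor
            present = [r.impact_factor for r in self.all_references
                       if r.impact_factor is not None]
            if present and (pif is None or pif < max(present)):
                problems.append("primary_reference does not have the maximal impact factor")
        if problems:
            raise ValidationError(
                f"invalid record {self.accession.value}: " + "; ".join(problems))
        return self
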