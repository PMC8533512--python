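"""Deterministic generator of a synthetic offline corpus with ground truth.

The generator emits the document dialects the parsers consume — GEO MINiML
series/sample documents, ArrayExpress experiment and protocol documents,
PubMed summary documents and an impact-factor TSV — plus ``index.json``, a
ground-truth sidecar recording every generated field. The sidecar is
sufficient to predict, by brute force, the exact output of every search,
merge, parse, filter and summary operation on the corpus, which makes it
the independent oracle for round-trip and end-to-end tests.

Emulated features of real repository data: multi-organism and multi-type
series, SuperSeries container records (composition sentence + relation
elements), E-GEOD mirror records in ArrayExpress that duplicate GEO series,
shared vs per-sample protocols, references by PMID or DOI (some
deliberately unresolvable), and BioProject/SRA links. The documents cover
only the elements the parsers read, not the full repository schemas.

Same seed, same parameters → byte-identical corpus.
"""

from __future__ import annotations

import json
import math
import random
from pathlib import Path

from lxml import etree

from .errors import ValidationError
from .model import normalize_ws

DEFAULT_VOCAB = [
    "polarization", "LPS", "IL-4", "macrophage", "microglia", "astrocyte",
    "inflammation", "interferon", "TNF", "monocyte", "neuroinflammation",
    "stimulation", "phenotype", "cytokine", "innate immunity", "M1", "M2",
    "bone marrow", "single cell", "transcriptome", "IFN-gamma", "IL-13",
    "hypoxia", "glia", "activation", "immune response",
]

_ORGANISMS = ["Mus musculus", "Homo sapiens", "Rattus norvegicus", "Sus scrofa"]
_GEO_TYPES = [
    "Expression profiling by high throughput sequencing",
    "Expression profiling by array",
    "Methylation profiling by array",
    "Genome binding/occupancy profiling by high throughput sequencing",
]
_AE_TYPES = ["RNA-seq of coding RNA", "transcription profiling by array"]
_MOLECULES = ["total RNA", "polyA RNA", "genomic DNA"]
_CELLS = ["bone marrow derived macrophages", "microglial cells", "astrocytes",
          "peritoneal macrophages", "blood monocytes"]
_STIMULI = ["LPS", "IL-4", "IFN-gamma", "TNF-alpha", "vehicle"]
#: journal -> impact factor; the last journal is deliberately absent from the TSV.
_JOURNALS = [
    ("Nature Communications", 11.9),
    ("Journal of Immunology", 4.7),
    ("Frontiers in Immunology", 5.1),
    ("Glia", 5.9),
    ("Cells", 4.4),
    ("Regional Proceedings of Cell Biology", None),
]

MINIML_NS = "http://www.ncbi.nlm.nih.gov/geo/info/MINiML"

GEO_RECORD_URL = "https://www.ncbi.nlm.nih.gov/geo/query/acc.cgi?acc={acc}"
BIOPROJECT_URL = "https://www.ncbi.nlm.nih.gov/bioproject/{id}"
SRA_URL = "https://www.ncbi.nlm.nih.gov/sra?term={id}"

#: label order of the per-sample field collapse, replicated here so the
#: sidecar can predict collapsed blocks without calling the parser.
_FIELD_ORDER = ("Cell type", "Treatment protocol", "Growth protocol",
                "Isolation protocol", "Molecule type", "Characteristics")


def _dedup_first(values: list[str]) -> list[str]:
    """First-appearance unique scan after whitespace normalization
    (the sidecar's own independent collapse rule)."""
    seen: set[str] = set()
    out: list[str] = []
    for v in values:
        key = normalize_ws(v)
        if key and key not in seen:
            seen.add(key)
            out.append(key)
    return out


def _predict_blocks(samples: list[dict]) -> list[list[str]]:
    """Predict the collapsed labeled blocks for a list of sample truths."""
    getters = {
        "Cell type": lambda s: [s["cell_type"]] if s.get("cell_type") else [],
        "Treatment protocol": lambda s: [s["treatment_protocol"]] if s.get("treatment_protocol") else [],
        "Growth protocol": lambda s: [s["growth_protocol"]] if s.get("growth_protocol") else [],
        "Isolation protocol": lambda s: [s["isolation_protocol"]] if s.get("isolation_protocol") else [],
        "Molecule type": lambda s: [s["molecule_type"]] if s.get("molecule_type") else [],
        "Characteristics": lambda s: [f"{t}: {v}" for t, v in s.get("characteristics", [])],
    }
    blocks: list[list[str]] = []
    for label in _FIELD_ORDER:
        values = [v for s in samples for v in getters[label](s)]
        blocks.extend([label, v] for v in _dedup_first(values))
    return blocks


def _matching_terms(vocab: list[str], title: str, summary: str) -> list[str]:
    hay = (title + " " + summary).lower()
    return sorted({t for t in vocab if t.lower() in hay}, key=str.lower)


def _sentence(rng: random.Random, vocab: list[str], n_terms: int) -> str:
    terms = rng.sample(vocab, k=min(n_terms, len(vocab)))
    filler = rng.choice([
        "Comparative profiling of treated and control cultures",
        "Time-resolved expression analysis",
        "Genome-wide characterization of stimulus response",
        "Transcriptional landscape of activated cells",
    ])
    return f"{filler} addressing {', '.join(terms)}."


def _geo_truth(rng: random.Random, index: int, superseries: bool,
               vocab: list[str], pmid_pool: list[str]) -> dict:
    accession = f"GSE{101 + index}"
    n_samples = rng.randint(1, 40)
    organisms = rng.sample(_ORGANISMS, k=min(rng.choice([1, 1, 2]), n_samples))
    types = rng.sample(_GEO_TYPES, k=rng.choice([1, 1, 2, 3]))
    cell = rng.choice(_CELLS)
    stimulus = rng.choice(_STIMULI)
    title_terms = rng.sample(vocab, k=2)
    title = f"{title_terms[0]} and {title_terms[1]} in {cell} exposed to {stimulus}"
    summary = _sentence(rng, vocab, rng.randint(1, 3))
    relations: list[list[str]] = []
    if superseries:
        summary = ("This SuperSeries is composed of the SubSeries listed below. "
                   + summary)
        for _ in range(2):
            relations.append(["SuperSeries of", f"GSE{rng.randint(200, 999)}"])
    year = rng.randint(2012, 2021)
    molecule = rng.choice(_MOLECULES)
    pmids = rng.sample(pmid_pool, k=rng.choice([0, 1, 1, 2, 3]))
    bioproject_id = f"PRJNA{600000 + index}" if rng.random() < 0.6 else None
    sra_id = f"SRP{100000 + index}" if rng.random() < 0.6 else None
    if bioproject_id:
        relations.append(["BioProject", BIOPROJECT_URL.format(id=bioproject_id)])
    if sra_id:
        relations.append(["SRA", SRA_URL.format(id=sra_id)])
    pattern = rng.choice(["shared", "unique", "mixed"])

    base_treatment = (f"Cells were stimulated with {stimulus} "
                      f"({rng.randint(1, 100)} ng/mL) for {rng.choice([2, 6, 24])} h.")
    base_growth = (f"{cell} were maintained in DMEM with 10% FBS "
                   f"at 37C and 5% CO2.")
    base_isolation = ("RNA was extracted with TRIzol and purified on "
                      "silica columns.")
    samples = []
    for j in range(n_samples):
        unique_sfx = f" Replicate-specific note for sample {j + 1}."
        if pattern == "shared":
            treatment, growth, isolation = base_treatment, base_growth, base_isolation
            characteristics = [["strain", "C57BL/6"], ["passage", "3"]]
        elif pattern == "unique":
            treatment = base_treatment + unique_sfx
            growth = base_growth + unique_sfx
            isolation = base_isolation + unique_sfx
            characteristics = [["strain", "C57BL/6"], ["time point", f"{j + 1} h"]]
        else:  # mixed: per-sample treatment, shared growth/isolation
            treatment = base_treatment + unique_sfx
            growth, isolation = base_growth, base_isolation
            characteristics = [["strain", "C57BL/6"], ["passage", "3"]]
        samples.append({
            "sample_id": f"GSM{(101 + index) * 100 + j + 1}",
            "cell_type": cell,
            "treatment_protocol": treatment,
            "growth_protocol": growth,
            "isolation_protocol": isolation,
            "molecule_type": molecule,
            "characteristics": characteristics,
            "organism": organisms[j % len(organisms)],
        })
    return {
        "accession": accession,
        "title": title,
        "summary": summary,
        "organisms": organisms,
        "n_samples": n_samples,
        "types": types,
        "platforms": [f"GPL{20000 + index * 2 + k}"
                      for k in range(rng.choice([1, 1, 2]))],
        "year": year,
        "release_year": year + rng.choice([0, 1, 2]),
        "molecule": molecule,
        "pmids": pmids,
        "bioproject_id": bioproject_id,
        "sra_id": sra_id,
        "relations": relations,
        "superseries": superseries,
        "protocol_pattern": pattern,
        "samples": samples,
        "expected_protocol_blocks": _predict_blocks(samples),
        "matching_terms": _matching_terms(vocab, title, summary),
    }


def _write_miniml(truth: dict, path: Path) -> None:
    nsmap = {None: MINIML_NS}
    root = etree.Element(f"{{{MINIML_NS}}}MINiML", nsmap=nsmap)

    def sub(parent, name, text=None, **attrs):
        el = etree.SubElement(parent, f"{{{MINIML_NS}}}{name}")
        for k, v in attrs.items():
            el.set(k, v)
        if text is not None:
            el.text = text
        return el

    for gpl in truth["platforms"]:
        plat = sub(root, "Platform", iid=gpl)
        sub(plat, "Accession", gpl, database="GEO")
    for s in truth["samples"]:
        sample = sub(root, "Sample", iid=s["sample_id"])
        sub(sample, "Accession", s["sample_id"], database="GEO")
        channel = sub(sample, "Channel", position="1")
        sub(channel, "Source", s["cell_type"])
        sub(channel, "Organism", s["organism"])
        for tag, value in s["characteristics"]:
            sub(channel, "Characteristics", value, tag=tag)
        sub(channel, "Treatment-Protocol", s["treatment_protocol"])
        sub(channel, "Growth-Protocol", s["growth_protocol"])
        sub(channel, "Molecule", s["molecule_type"])
        sub(channel, "Extract-Protocol", s["isolation_protocol"])
    series = sub(root, "Series", iid=truth["accession"])
    status = sub(series, "Status")
    sub(status, "Submission-Date", f"{truth['year']}-03-14")
    sub(status, "Release-Date", f"{truth['release_year']}-06-01")
    sub(series, "Title", truth["title"])
    sub(series, "Accession", truth["accession"], database="GEO")
    for pmid in truth["pmids"]:
        sub(series, "Pubmed-ID", pmid)
    sub(series, "Summary", truth["summary"])
    sub(series, "Overall-Design",
        f"{truth['n_samples']} samples were analyzed in total.")
    for t in truth["types"]:
        sub(series, "Type", t)
    for rtype, target in truth["relations"]:
        sub(series, "Relation", type=rtype, target=target)
    for s in truth["samples"]:
        sub(series, "Sample-Ref", ref=s["sample_id"])
    path.write_bytes(etree.tostring(root, xml_declaration=True,
                                    encoding="UTF-8", pretty_print=True))


def _ae_native_truth(rng: random.Random, index: int, vocab: list[str],
                     pmid_pool: list[str], doi_counter: list[int]) -> dict:
    accession = f"E-MTAB-{1001 + index}"
    n_samples = rng.randint(1, 40)
    title_terms = rng.sample(vocab, k=2)
    cell = rng.choice(_CELLS)
    title = f"Profiling of {cell} under {title_terms[0]} and {title_terms[1]}"
    summary = _sentence(rng, vocab, rng.randint(1, 3))
    pmids = rng.sample(pmid_pool, k=rng.choice([0, 1, 1, 2]))
    dois = []
    if rng.random() < 0.5:
        doi_counter[0] += 1
        dois.append(f"10.5000/synthetic.{doi_counter[0]}")
    labels = ["growth protocol", "treatment protocol",
              "nucleic acid extraction protocol", "sample collection protocol"]
    n_protocols = rng.randint(1, 4)
    protocol_ids = [f"P-MTAB-{1001 + index}-{k + 1}" for k in range(n_protocols)]
    protocols = [[labels[k % len(labels)],
                  f"Protocol step {k + 1}: {_sentence(rng, vocab, 1)}"]
                 for k in range(n_protocols)]
    return {
        "accession": accession,
        "mirror_of": None,
        "title": title,
        "summary": summary,
        "organisms": rng.sample(_ORGANISMS, k=rng.choice([1, 1, 2])),
        "n_samples": n_samples,
        "types": rng.sample(_AE_TYPES, k=rng.choice([1, 2])),
        "year": rng.randint(2012, 2021),
        "molecule": rng.choice(_MOLECULES) if rng.random() < 0.7 else None,
        "pmids": pmids,
        "dois": dois,
        "protocol_ids": protocol_ids,
        "protocols": protocols,
        "bioproject_id": f"PRJEB{70000 + index}" if rng.random() < 0.4 else None,
        "sra_id": f"ERP{120000 + index}" if rng.random() < 0.4 else None,
        "matching_terms": _matching_terms(vocab, title, summary),
    }


def _ae_mirror_truth(geo: dict, vocab: list[str]) -> dict:
    """E-GEOD mirror: identical ground truth to its GEO original; the
    protocol documents carry the GEO record's collapsed blocks."""
    n = geo["accession"][3:]
    return {
        "accession": f"E-GEOD-{n}",
        "mirror_of": geo["accession"],
        "title": geo["title"],
        "summary": geo["summary"],
        "organisms": geo["organisms"],
        "n_samples": geo["n_samples"],
        "types": geo["types"],
        "year": geo["year"],
        "molecule": geo["molecule"],
        "pmids": geo["pmids"],
        "dois": [],
        "protocol_ids": [f"P-GEOD-{n}-{k + 1}"
                         for k in range(len(geo["expected_protocol_blocks"]))],
        "protocols": [list(b) for b in geo["expected_protocol_blocks"]],
        "bioproject_id": geo["bioproject_id"],
        "sra_id": geo["sra_id"],
        "matching_terms": _matching_terms(vocab, geo["title"], geo["summary"]),
    }


def _write_ae_experiment(truth: dict, path: Path) -> None:
    root = etree.Element("experiments", total="1")
    exp = etree.SubElement(root, "experiment")

    def sub(tag, text=None):
        el = etree.SubElement(exp, tag)
        if text is not None:
            el.text = text
        return el

    sub("accession", truth["accession"])
    sub("name", truth["title"])
    for org in truth["organisms"]:
        sub("organism", org)
    for t in truth["types"]:
        sub("experimenttype", t)
    sub("samples", str(truth["n_samples"]))
    sub("releasedate", f"{truth['year']}-05-20")
    if truth["molecule"]:
        sub("moleculetype", truth["molecule"])
    if truth["bioproject_id"]:
        sub("secondaryaccession", truth["bioproject_id"])
    if truth["sra_id"]:
        sub("secondaryaccession", truth["sra_id"])
    for pmid in truth["pmids"]:
        bib = sub("bibliography")
        etree.SubElement(bib, "accession").text = pmid
    for doi in truth["dois"]:
        bib = sub("bibliography")
        etree.SubElement(bib, "doi").text = doi
    for pid in truth["protocol_ids"]:
        proto = sub("protocol")
        etree.SubElement(proto, "id").text = pid
    desc = sub("description")
    etree.SubElement(desc, "text").text = truth["summary"]
    path.write_bytes(etree.tostring(root, xml_declaration=True,
                                    encoding="UTF-8", pretty_print=True))


def _write_ae_protocol(pid: str, label: str, text: str, path: Path) -> None:
    root = etree.Element("protocols")
    proto = etree.SubElement(root, "protocol")
    etree.SubElement(proto, "id").text = pid
    etree.SubElement(proto, "type").text = label
    etree.SubElement(proto, "text").text = text
    path.write_bytes(etree.tostring(root, xml_declaration=True,
                                    encoding="UTF-8", pretty_print=True))


def _write_pubmed(pmid: str, meta: dict, path: Path) -> None:
    root = etree.Element("eSummaryResult")
    doc = etree.SubElement(root, "DocSum")
    etree.SubElement(doc, "Id").text = pmid
    for name, value in (("Title", meta["title"]),
                        ("FullJournalName", meta["journal"]),
                        ("DOI", meta["doi"])):
        item = etree.SubElement(doc, "Item", Name=name, Type="String")
        item.text = value
    path.write_bytes(etree.tostring(root, xml_declaration=True,
                                    encoding="UTF-8", pretty_print=True))


def generate_corpus(out_dir: str | Path, seed: int, n_geo: int = 10,
                    n_ae: int = 5, mirror_fraction: float = 0.4,
                    superseries_fraction: float = 0.2,
                    vocab: list[str] | None = None) -> dict:
    """Generate the corpus under ``out_dir`` and return the sidecar index.

    ``floor(mirror_fraction * n_ae)`` ArrayExpress documents are E-GEOD
    mirrors of GEO fixtures; ``floor(superseries_fraction * n_geo)`` GEO
    fixtures are SuperSeries containers. Same seed → byte-identical tree.
    """
    if not 0 <= mirror_fraction <= 1 or not 0 <= superseries_fraction <= 1:
        raise ValidationError("fractions must lie in [0, 1]")
    if n_geo < 0 or n_ae < 0:
        raise ValidationError("n_geo and n_ae must be non-negative")
    vocab = list(vocab) if vocab else list(DEFAULT_VOCAB)
    rng = random.Random(seed)
    out = Path(out_dir)
    for subdir in ("geo", "ae/protocols", "pubmed"):
        (out / subdir).mkdir(parents=True, exist_ok=True)

    # literature sidecars first so records can draw PMIDs from the pool
    pmid_pool = [str(9_000_000 + i) for i in range(max(3 * n_geo // 2, 8))]
    pubmed: dict[str, dict] = {}
    for i, pmid in enumerate(pmid_pool):
        journal = _JOURNALS[rng.randrange(len(_JOURNALS))][0]
        pubmed[pmid] = {
            "title": f"Findings on {rng.choice(vocab)} in dataset-linked study {i + 1}",
            "journal": journal,
            "doi": f"10.5000/linked.{pmid}",
        }
    doi_to_pmid = {meta["doi"]: pmid for pmid, meta in pubmed.items()}

    n_super = math.floor(superseries_fraction * n_geo)
    super_idx = set(rng.sample(range(n_geo), n_super)) if n_geo else set()
    geo: dict[str, dict] = {}
    for i in range(n_geo):
        truth = _geo_truth(rng, i, i in super_idx, vocab, pmid_pool)
        geo[truth["accession"]] = truth
        _write_miniml(truth, out / "geo" / f"{truth['accession']}.xml")

    n_mirror = math.floor(mirror_fraction * n_ae)
    n_mirror = min(n_mirror, n_geo)
    mirror_sources = rng.sample(sorted(geo), n_mirror) if n_mirror else []
    doi_counter = [0]
    ae: dict[str, dict] = {}
    for i in range(n_ae - n_mirror):
        truth = _ae_native_truth(rng, i, vocab, pmid_pool, doi_counter)
        ae[truth["accession"]] = truth
    for acc in mirror_sources:
        truth = _ae_mirror_truth(geo[acc], vocab)
        ae[truth["accession"]] = truth
    for truth in ae.values():
        _write_ae_experiment(truth, out / "ae" / f"{truth['accession']}.xml")
        for pid, (label, text) in zip(truth["protocol_ids"], truth["protocols"]):
            _write_ae_protocol(pid, label, text,
                               out / "ae" / "protocols" / f"{pid}.xml")

    # DOI-only AE references: half resolve through PubMed, half stay dangling
    for truth in ae.values():
        for doi in truth["dois"]:
            if rng.random() < 0.5:
                pmid = str(9_500_000 + doi_counter[0] + len(doi_to_pmid))
                pubmed[pmid] = {
                    "title": f"Companion article for {truth['accession']}",
                    "journal": rng.choice(_JOURNALS)[0],
                    "doi": doi,
                }
                doi_to_pmid[doi] = pmid

    for pmid, meta in pubmed.items():
        _write_pubmed(pmid, meta, out / "pubmed" / f"{pmid}.xml")

    impact_factors = {j: v for j, v in _JOURNALS if v is not None}
    with (out / "impact_factors.tsv").open("w", encoding="utf-8") as fh:
        fh.write("journal\timpact_factor\n")
        for journal, value in sorted(impact_factors.items()):
            fh.write(f"{journal}\t{value}\n")

    index = {
        "seed": seed,
        "params": {"n_geo": n_geo, "n_ae": n_ae,
                   "mirror_fraction": mirror_fraction,
                   "superseries_fraction": superseries_fraction},
        "vocab": vocab,
        "geo": geo,
        "ae": ae,
        "pubmed": pubmed,
        "doi_to_pmid": doi_to_pmid,
        "impact_factors": impact_factors,
    }
    (out / "index.json").write_text(json.dumps(index, indent=1, sort_keys=True))
    return index
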