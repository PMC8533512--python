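# Methods

## The problem

Gene-expression datasets are archived in two large public repositories —
NCBI's Gene Expression Omnibus (GEO, accessions `GSEn`) and EMBL-EBI's
ArrayExpress (AE, accessions `E-XXXX-n`) — whose built-in search supports
filtering only by organism, experiment type or date. A systematic secondary
study (re-analysis of transcriptomes on a topic) needs much more: many
queries run at once, per-query hit counts to tune the search, cross-repository
deduplication, and access to the experimental *protocols* (stimulus
concentration, exposure time, cell source) that decide whether a dataset is
usable. `geoharvest` implements that workflow as a two-block pipeline plus a
curation stage.

## Pipeline model

**Block 1 — search.** Each line of a query file is one verbatim query
(normalized by lowercasing and whitespace collapsing only for
deduplication; no auto-ANDing, synonym expansion or spelling correction).
GEO is searched through the E-utilities `esearch` endpoint restricted to
series entries; AE is queried for its native datasets. AE re-indexes GEO
series as `E-GEOD-n` mirror records, which would double-count datasets, so
`E-GEOD-n` is treated as canonically equal to `GSEn` — the only
cross-repository identity rule; titles or summaries are never fuzzy-matched.
Per-query counts (export table 1) are taken after mirror collapsing within
the query but before cross-query union; the master accession list is the
first-seen-order union over all queries.

**Block 2 — harvest.** GEO records are read from MINiML, GEO's XML
serialization of series/sample metadata: dataset-level fields from the
`Series` element, organisms and protocols from the per-sample `Channel`
blocks. Per-sample fields (cell type, treatment/growth/isolation protocol,
molecule, characteristics) are collapsed by a first-appearance unique scan
with exact string equality after trimming and collapsing internal
whitespace runs — a protocol shared by all samples appears once, per-sample
protocols all survive. Characteristics compare as whole `tag: value`
strings. AE experiment XML carries the same dataset-level information but
only protocol *IDs*; each protocol text is fetched separately by ID, and a
missing protocol document is a logged gap, never a record failure. Both
paths map onto one `DatasetRecord` schema so downstream code is
source-agnostic; absent values serialize as empty strings.

**Literature enrichment.** Reference identifiers (PubMed IDs from GEO,
PMIDs/DOIs from AE) resolve through the PubMed summary endpoint. Journals
map to impact factors through a static two-column TSV keyed by normalized
journal name (lowercased, punctuation stripped, whitespace collapsed). The
reference in the highest-impact journal becomes the record's primary
reference; references without a tabulated impact factor rank below any that
have one, with ties broken by smallest numeric PMID, then lexicographic
DOI (the ranking source gives no tie rule; these make the selection a pure
function of the reference set, invariant under permutation). Unresolvable
identifiers degrade to raw-ID stubs rather than aborting a harvest.

**Export.** Table 2 has a fixed 19-column layout (Accession … All
protocols). Records with several organisms or experiment types split into
one row per (organism, type) pair by default — the Cartesian product over
exactly those two fields — so single-value spreadsheet filters work; the
`--no-split` flag joins them with `"; "` instead. Protocol blocks are
serialized as `LABEL: text` separated by blank lines, then chunked at exact
character boundaries into adjacent `All protocols (k)` columns; the default
limit of 32 000 characters sits just under the 32 767-character cell
ceiling of common spreadsheet software. Chunking is lossless:
concatenating a row's protocol cells reproduces the text byte-for-byte.
Files are CSV (RFC 4180 quoting) or TSV; rows are padded so every row has
the same field count under a strict reader.

**Curation.** GEO registers combined samples under a new umbrella accession
("SuperSeries"), so those containers are filtered before secondary
analysis; detection accepts either signal present in real records — a
relation element of SuperSeries-composition type or the standard
composition sentence in the summary — because the repository guarantees no
single marker. Experiment-type filtering keeps records where *any* type
string contains *any* case-insensitive predicate (e.g. `rna-seq`,
`high throughput sequencing`). The binary markup (0/1 per feature:
cell types, stimuli, in vitro / in vivo, single-cell, …) is always authored
by a human as a CSV sidecar; the package validates it (unique accessions,
strictly binary values, all features present) and computes count/percentage
distributions (percent = 100·count/n rounded to one decimal, denominator
reported) and 2×2 cross-tabulations (e.g. in-vitro-only / in-vivo-only /
both / neither). Because a percentage can be read against the whole table
or within a parent feature, `CuratedTable.subset(feature)` makes the
denominator explicit.

## Transport and politeness

All fetches go through one rate-limited, retrying fetcher: at most
`max_per_second` requests in any sliding 1-second window (default 3, NCBI's
documented limit without an API key), sequential requests only, exponential
backoff (base 0.5 s, doubling) with up to 3 retries on HTTP 429/5xx and
timeouts; other 4xx statuses fail immediately. The clock and sleep are
injectable, so the limiter's issue times are a pure, testable function of
the request sequence. Identical requests within a run are memoized. In
offline mode the same interface is served from a fixture directory and no
socket is ever opened; the window limit is effectively unlimited there,
since the delay exists to protect the remote services.

## Synthetic corpus generator

`geoharvest fixtures` writes a deterministic corpus — MINiML documents, AE
experiment + protocol documents, PubMed summaries, an impact-factor TSV —
plus `index.json`, a ground-truth sidecar recording every generated field.
The sidecar suffices to predict, by brute force, the output of every
search, merge, parse, filter and summary operation, and the generator
computes its expected collapsed-protocol blocks with its own independent
first-appearance scan, so round-trip tests do not test the parser against
itself. Emulated: multi-organism/multi-type series, SuperSeries containers
(sentence + relation), `E-GEOD` mirrors sharing ground truth with their GEO
originals, shared/unique/mixed protocol-sharing patterns (sample counts
uniform on 1–40), PMID- and DOI-keyed references including deliberately
unresolvable ones, BioProject/SRA links, and a vocabulary of polarization-
domain terms (LPS, IL-4, macrophage, microglia, …) so term searches have
known answers. Search matching in the fixture world is case-insensitive
substring over title+summary — a documented simplification; the real
remote indexes match more fields with their own analyzers. Fixture
documents cover only the elements the parsers consume, not the full
repository schemas, and the corpus contains no real repository text — so
passing tests demonstrate the pipeline's mechanics (parsing, dedup,
collapse, ranking, export, filtering), not robustness to the full
variability of live GEO/AE records.

## Numerical and design choices

- Dataset year is the earliest year among the series' dated status
  elements (submission vs release dates are both used in the field's
  descriptions of "publication year"; earliest is the conservative
  reading). AE uses the release date.
- AE sample counts are read from the experiment document's sample-count
  element rather than by counting sample elements (AE documents
  summarize).
- GEO `esearch` UIDs for series decode as `GSE(uid − 2·10⁸)`, the
  repository's series-UID convention.
- The per-sample "cell type" is read from the MINiML `Source` element;
  `Characteristics` pairs are kept separately in document order.
- The bundled impact-factor table is synthetic (real JCR data is not
  redistributable); production runs should pass `--if-table`.
- Problem sizes in the test suite and acceptance script (50 GEO + 25 AE
  fixtures, 23 queries, 1000 chunking texts, 500 reference lists) are the
  package's chosen desk-scale study conditions: large enough that every
  code path (mirrors, SuperSeries, all three protocol patterns, missing
  impact factors, DOI-only references) occurs, small enough to run in
  seconds.

## Known limitations

- Live-service code paths (HTTP backends) are exercised only offline
  through the fixture backend; the live endpoints' response dialects may
  drift (AE in particular has been migrating to BioStudies).
- No SDRF/IDF parsing for AE and no AE sample-level attributes beyond
  protocols; no parsing of expression matrices or supplementary files.
- Cross-repository identity covers only the `E-GEOD` mirror convention;
  independently resubmitted duplicates are not detected.
- The curation markup is never inferred from text; the package summarizes
  human judgments, it does not replace them.
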