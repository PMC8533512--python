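# geoharvest

Systematic cross-repository search and metadata harvesting for
transcriptome datasets in GEO (Gene Expression Omnibus) and ArrayExpress.

Secondary analysis of public gene-expression data starts with a hefty
manual task: finding every dataset on a topic across two repositories with
different accession schemes, record formats and search capabilities, then
reading each record's experimental protocols to decide whether it is
usable. `geoharvest` automates that workflow for researchers running
systematic dataset searches (in the spirit of a systematic review):

1. **Search** — a plain-text list of queries runs against both GEO
   (E-utilities, series entries) and ArrayExpress; hits are deduplicated
   across repositories using the `E-GEOD-n ≡ GSEn` mirror rule, producing a
   per-query hit-count table (export table 1) and a master accession list.
2. **Harvest** — each accession's full metadata is collected (GEO MINiML
   series + sample blocks with per-sample protocol collapse; ArrayExpress
   experiment XML with protocols fetched separately by ID; PubMed
   reference resolution with journal impact-factor ranking) into one
   unified 19-column record table (export table 2), with multi-value rows
   split for filtering and long protocol text chunked below spreadsheet
   cell limits.
3. **Curate** — SuperSeries container records and unwanted experiment
   types are filtered out, and a human-authored binary markup (0/1 feature
   flags: cell types, stimuli, in vitro/in vivo, single-cell, …) is
   validated and summarized into count/percentage distributions.

All remote interaction honors repository politeness rules (3 requests/s,
sequential, exponential-backoff retries). A deterministic fixture generator
produces a fully offline synthetic corpus — with a ground-truth sidecar —
so the entire pipeline runs and is tested without a network connection.
See `docs/methods.md` for the model and the design decisions.

## Worked example (offline)

```sh
geoharvest fixtures --seed 1 --out corpus --n-geo 10 --n-ae 5
# wrote 10 GEO + 5 AE fixtures to corpus

printf 'polarization\nLPS\nIL-4\n' > queries.txt
geoharvest search --queries queries.txt --offline corpus \
    --out table1.csv --ids ids.txt
# 3 queries, 6 unique datasets
```

`table1.csv` now holds one row per query with the number of matching
datasets — the counts overlap (a dataset matching both "LPS" and "IL-4" is
counted for each query) while `ids.txt` is globally deduplicated:

```
query,n_datasets
polarization,1
LPS,5
IL-4,4
```

```sh
geoharvest harvest --ids ids.txt --offline corpus --out table2.csv
# harvested 6 of 6 records
```

`table2.csv` begins with the fixed column layout
(`Accession,Organism,Samples,Type,Platform,Title,Year,Summary,Link,…,All
protocols`); a record with two organisms and two experiment types occupies
four rows, one per combination (disable with `--no-split`). Finally, with
a manual `markup.csv` (`accession,macrophage,mouse` with 0/1 values):

```sh
geoharvest curate --table table2.csv --markup markup.csv \
    --superseries-filter --summary-out summary.csv
# 5 records kept; 5 with markup; summary written to summary.csv
cat summary.csv
# group,feature,count,percent,n
# all_features,macrophage,1,20.0,5
# all_features,mouse,2,40.0,5
```

One of the six harvested records was a SuperSeries container and was
dropped; of the five remaining, one is macrophage-flagged (20.0%) and two
are mouse datasets (40.0%).

For live searches omit `--offline` (network required). The bundled
impact-factor table is synthetic; pass a real `journal<TAB>impact_factor`
TSV with `--if-table` for meaningful reference ranking.

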