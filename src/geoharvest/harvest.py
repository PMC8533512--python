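"""Block 2 of the workflow: harvest full metadata for a master accession list.

GEO accessions are fetched as MINiML and collapsed into the unified record;
ArrayExpress accessions are fetched as experiment XML with their protocols
resolved separately by ID. Finally each record's literature references are
resolved through PubMed and ranked by journal impact factor.
"""

from __future__ import annotations

import logging

from . import ae, literature, miniml
from .errors import FetchError, GeoHarvestError
from .model import Accession, DatasetRecord
from .transport import Fetcher, FetchRequest

log = logging.getLogger(__name__)


def harvest_record(accession: Accession, fetcher: Fetcher) -> DatasetRecord:
    """Fetch and parse one dataset into a unified record (references unresolved)."""
    if accession.source == "GEO":
        body, _ = fetcher.fetch(
            FetchRequest("geo_miniml", {"accession": accession.value}))
        series, samples = miniml.parse_miniml(body)
        collapsed = miniml.collapse_sample_fields(samples) if samples else []
        return miniml.geo_to_unified(series, collapsed)
    body, _ = fetcher.fetch(
        FetchRequest("ae_experiment", {"accession": accession.value}))
    experiment = ae.parse_ae_experiment(body)
    protocols = (ae.resolve_protocols(experiment.protocol_ids, fetcher)
                 if experiment.protocol_ids else [])
    return ae.ae_to_unified(experiment, protocols)


def harvest(accessions: list[Accession], fetcher: Fetcher,
            if_table: dict[str, float] | None = None,
            strict: bool = False) -> list[DatasetRecord]:
    """Harvest every accession, resolve references, return records in order.

    By default a record that cannot be fetched or parsed is logged and
    skipped so one bad dataset never aborts a long run; ``strict=True``
    re-raises instead.
    """
    if if_table is None:
        if_table = literature.load_impact_factors()
    records: list[DatasetRecord] = []
    for accession in accessions:
        try:
            record = harvest_record(accession, fetcher)
        except (FetchError, GeoHarvestError):
            if strict:
                raise
            log.warning("skipping %s: harvest failed", accession.value, exc_info=True)
            continue
        literature.resolve_references(record, fetcher, if_table)
        records.append(record)
    return records
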