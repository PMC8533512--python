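"""Downstream curation of a harvested local database.

After a systematic harvest, the record table is turned into a curated local
database in three steps: (1) SuperSeries container records are removed —
GEO re-registers combined samples under a new umbrella accession, so
counting a SuperSeries alongside its SubSeries double-counts data; (2) the
records are restricted to the experiment types of interest (e.g. RNA-seq);
(3) a human-authored binary markup (0 = feature absent, 1 = present) over
features such as cell types, stimuli and in-vitro/in-vivo/single-cell
status is attached, validated, and summarized as count/percentage
distributions. The markup itself is always manual: this module validates
and summarizes, it never infers feature values from text.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .model import DatasetRecord

#: Standard sentence GEO places in a SuperSeries container's summary.
_SUPERSERIES_SENTENCE = re.compile(r"superseries\s+is\s+composed\s+of", re.IGNORECASE)


def is_superseries(summary: str, relations: list[tuple[str, str]] = ()) -> bool:
    """Detect a SuperSeries container from either signal GEO provides:
    a SuperSeries-composition relation element, or the standard composition
    sentence in the summary."""
    if any("superseries" in rtype.lower() for rtype, _ in relations):
        return True
    return bool(_SUPERSERIES_SENTENCE.search(summary))


def filter_superseries(records: list[DatasetRecord]) -> list[DatasetRecord]:
    """Drop SuperSeries container records, preserving order."""
    return [r for r in records if not is_superseries(r.summary, r.relations)]


def filter_experiment_type(records: list[DatasetRecord],
                           wanted: list[str]) -> list[DatasetRecord]:
    """Keep records where ANY type matches ANY predicate.

    Predicates are case-insensitive substrings, e.g. ``["rna-seq",
    "high throughput sequencing"]`` selects sequencing experiments.
    """
    if not wanted:
        raise ValidationError("filter_experiment_type needs at least one type predicate")
    preds = [w.lower() for w in wanted]
    return [r for r in records
            if any(p in t.lower() for t in r.types for p in preds)]


@dataclass
class MarkupSchema:
    """Ordered binary feature set for manual dataset markup."""

    features: list[str]

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValidationError("markup feature names must be unique")


@dataclass
class CuratedTable:
    """One row per accession with a 0/1 value for every schema feature."""

    schema: MarkupSchema
    data: pd.DataFrame  # index: accession; columns: schema.features; values 0/1

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate accessions in markup: {dupes}")
        missing = [f for f in self.schema.features if f not in self.data.columns]
        if missing:
            raise ValidationError(f"markup is missing feature columns: {missing}")
        values = self.data[self.schema.features]
        if not values.isin([0, 1]).all().all():
            raise ValidationError("markup values must all be 0 or 1")

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def subset(self, feature: str) -> "CuratedTable":
        """Rows flagged 1 for a feature (e.g. percentages *within* macrophage
        datasets rather than over the whole table)."""
        self._check(feature)
        return CuratedTable(self.schema, self.data[self.data[feature] == 1])

    def _check(self, feature: str) -> None:
        if feature not in self.schema.features:
            raise ValidationError(f"unknown markup feature: {feature!r}")


@dataclass
class DistributionSummary:
    """Counts and percentages for one feature group, plus the denominator."""

    rows: list[tuple[str, int, float]]
    n_rows: int = 0

    def as_dict(self) -> dict[str, tuple[int, float]]:
        return {f: (c, p) for f, c, p in self.rows}


def load_markup(path: str | Path,
                schema: MarkupSchema | None = None) -> CuratedTable:
    """Load a human-authored markup CSV (accession + one column per feature)."""
    frame = pd.read_csv(path, dtype={0: str})
    acc_col = frame.columns[0]
    frame = frame.set_index(acc_col)
    if schema is None:
        schema = MarkupSchema(list(frame.columns))
    return CuratedTable(schema, frame)


def summarize_distribution(table: CuratedTable,
                           feature_group: list[str]) -> DistributionSummary:
    """Count and percentage of rows flagged 1 for each feature in the group.

    Percentages use the whole table as denominator, rounded to one decimal;
    groups need not be mutually exclusive, so rows may contribute to several
    features. Pass ``table.subset(feature)`` to compute shares within a
    feature instead.
    """
    for f in feature_group:
        table._check(f)
    n = table.n_rows
    rows = []
    for f in feature_group:
        count = int(table.data[f].sum())
        percent = round(100.0 * count / n, 1) if n else 0.0
        rows.append((f, count, percent))
    return DistributionSummary(rows, n_rows=n)


def cross_tabulate(table: CuratedTable, feature_a: str,
                   feature_b: str) -> dict[tuple[int, int], int]:
    """2x2 contingency counts over two binary features.

    The (1,0)/(0,1)/(1,1)/(0,0) counts partition the table: a-only, b-only,
    both, neither (e.g. in-vitro-only / in-vivo-only / both / neither).
    """
    table._check(feature_a)
    table._check(feature_b)
    a = table.data[feature_a]
    b = table.data[feature_b]
    return {
        (1, 0): int(((a == 1) & (b == 0)).sum()),
        (0, 1): int(((a == 0) & (b == 1)).sum()),
        (1, 1): int(((a == 1) & (b == 1)).sum()),
        (0, 0): int(((a == 0) & (b == 0)).sum()),
    }


def write_summary(summaries: dict[str, DistributionSummary],
                  path: str | Path) -> Path:
    """Write feature-group summaries as CSV: group,feature,count,percent,n."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["group", "feature", "count", "percent", "n"])
        for group, summary in summaries.items():
            for feature, count, percent in summary.rows:
                writer.writerow([group, feature, count, percent, summary.n_rows])
    return path
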