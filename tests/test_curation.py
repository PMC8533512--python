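"""Curation stage: SuperSeries/type filtering, markup validation, summaries."""

import random

import pandas as pd
import pytest

from geoharvest.curation import (
    CuratedTable,
    MarkupSchema,
    cross_tabulate,
    filter_experiment_type,
    filter_superseries,
    is_superseries,
    load_markup,
    summarize_distribution,
)
from geoharvest.errors import ValidationError
from geoharvest.harvest import harvest_record
from geoharvest.model import Accession, DatasetRecord


def record(accession, types=("RNA-seq",), summary="plain summary",
           relations=()):
    return DatasetRecord(
        accession=Accession.parse(accession), organisms=["Mus musculus"],
        samples=2, types=list(types), platform=[], title="t", year=2020,
        summary=summary, link="https://x", relations=list(relations))


SS_SENTENCE = "This SuperSeries is composed of the SubSeries listed below."


class TestSuperseriesFilter:
    def test_detection_by_summary_sentence_and_relation(self):
        assert is_superseries(SS_SENTENCE)
        assert is_superseries("", relations=[("SuperSeries of", "GSE2")])
        assert not is_superseries("mentions SuperSeries casually")

    def test_corpus_filter_matches_sidecar_flags(self, corpus, fetcher):
        _, index = corpus
        records = [harvest_record(Accession(a, "GEO"), fetcher)
                   for a in index["geo"]]
        survivors = filter_superseries(records)
        expected = [a for a, t in index["geo"].items() if not t["superseries"]]
        assert [r.accession.value for r in survivors] == expected
        assert len(expected) < len(records), "corpus must contain SuperSeries"

    def test_no_superseries_is_identity(self):
        records = [record("GSE1"), record("GSE2")]
        assert filter_superseries(records) == records

    def test_all_superseries_gives_empty_list(self):
        records = [record("GSE1", summary=SS_SENTENCE),
                   record("GSE2", relations=[("SuperSeries of", "GSE9")])]
        assert filter_superseries(records) == []


class TestTypeFilter:
    def test_any_type_matching_any_predicate_keeps_record(self):
        rec = record("GSE1", types=["Expression profiling by array", "RNA-seq"])
        assert filter_experiment_type([rec], ["rna-seq"]) == [rec]

    def test_nothing_matching_gives_empty(self):
        assert filter_experiment_type([record("GSE1")], ["methylation"]) == []

    def test_empty_predicate_list_is_an_error(self):
        with pytest.raises(ValidationError):
            filter_experiment_type([record("GSE1")], [])

    def test_corpus_sequencing_selection_matches_sidecar(self, corpus, fetcher):
        _, index = corpus
        records = [harvest_record(Accession(a, "GEO"), fetcher)
                   for a in index["geo"]]
        kept = filter_experiment_type(records, ["high throughput sequencing"])
        expected = [a for a, t in index["geo"].items()
                    if any("high throughput sequencing" in x.lower()
                           for x in t["types"])]
        assert [r.accession.value for r in kept] == expected

    def test_filters_commute(self, corpus, fetcher):
        _, index = corpus
        records = [harvest_record(Accession(a, "GEO"), fetcher)
                   for a in index["geo"]]
        preds = ["sequencing"]
        one = filter_experiment_type(filter_superseries(records), preds)
        two = filter_superseries(filter_experiment_type(records, preds))
        assert one == two


def table(columns):
    frame = pd.DataFrame(columns, index=[f"GSE{i}" for i in
                                         range(len(next(iter(columns.values()))))])
    return CuratedTable(MarkupSchema(list(columns)), frame)


class TestMarkup:
    def test_feature_names_must_be_unique(self):
        with pytest.raises(ValidationError):
            MarkupSchema(["a", "a"])

    def test_values_must_be_binary(self):
        with pytest.raises(ValidationError):
            table({"lps": [0, 2, 1]})

    def test_duplicate_accessions_rejected(self):
        frame = pd.DataFrame({"lps": [0, 1]}, index=["GSE1", "GSE1"])
        with pytest.raises(ValidationError):
            CuratedTable(MarkupSchema(["lps"]), frame)

    def test_load_markup_csv(self, tmp_path):
        path = tmp_path / "markup.csv"
        path.write_text("accession,macrophage,lps\nGSE1,1,0\nGSE2,0,1\n")
        loaded = load_markup(path)
        assert loaded.schema.features == ["macrophage", "lps"]
        assert loaded.n_rows == 2


class TestSummaries:
    def test_count_and_percent_arithmetic(self):
        t = table({"macrophage": [1, 1, 0, 1]})
        summary = summarize_distribution(t, ["macrophage"])
        assert summary.rows == [("macrophage", 3, 75.0)]
        assert summary.n_rows == 4

    def test_all_zero_feature(self):
        t = table({"astro": [0, 0, 0]})
        assert summarize_distribution(t, ["astro"]).rows == [("astro", 0, 0.0)]

    def test_unknown_feature_is_an_error(self):
        with pytest.raises(ValidationError):
            summarize_distribution(table({"a": [1]}), ["b"])

    def test_partition_percents_sum_to_100(self):
        t = table({"a": [1, 0, 0, 1], "b": [0, 1, 1, 0]})
        rows = summarize_distribution(t, ["a", "b"]).rows
        assert sum(p for _, _, p in rows) == 100.0

    def test_row_permutation_invariance(self):
        t = table({"x": [1, 0, 1, 1, 0]})
        shuffled = CuratedTable(t.schema, t.data.sample(frac=1, random_state=3))
        assert summarize_distribution(t, ["x"]).rows == \
            summarize_distribution(shuffled, ["x"]).rows

    def test_subset_changes_the_denominator(self):
        t = table({"macrophage": [1, 1, 0, 1], "bmdm": [1, 0, 0, 1]})
        within = summarize_distribution(t.subset("macrophage"), ["bmdm"])
        assert within.n_rows == 3
        assert within.rows == [("bmdm", 2, 66.7)]


class TestCrossTab:
    def test_three_way_partition_plus_neither(self):
        t = table({"a": [1, 1, 0], "b": [0, 1, 1]})
        counts = cross_tabulate(t, "a", "b")
        assert counts == {(1, 0): 1, (1, 1): 1, (0, 1): 1, (0, 0): 0}
        assert sum(counts.values()) == t.n_rows

    def test_identical_features_have_zero_off_diagonal(self):
        t = table({"a": [1, 0, 1], "b": [1, 0, 1]})
        counts = cross_tabulate(t, "a", "b")
        assert counts[(1, 0)] == counts[(0, 1)] == 0

    def test_matches_brute_force_pair_counting(self):
        rng = random.Random(4)
        a = [rng.randint(0, 1) for _ in range(200)]
        b = [rng.randint(0, 1) for _ in range(200)]
        t = table({"a": a, "b": b})
        counts = cross_tabulate(t, "a", "b")
        brute = {}
        for x, y in zip(a, b):
            brute[(x, y)] = brute.get((x, y), 0) + 1
        for key, value in counts.items():
            assert value == brute.get(key, 0)
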