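"""GEO MINiML parsing and the per-sample field collapse."""

import pytest

from geoharvest.errors import FormatError, ParseError, ValidationError
from geoharvest.miniml import (
    collapse_sample_fields,
    geo_to_unified,
    parse_miniml,
)
from geoharvest.model import SampleBlock
from geoharvest.transport import FetchRequest

MINIMAL = b"""<MINiML xmlns="http://www.ncbi.nlm.nih.gov/geo/info/MINiML">
  <Sample iid="GSM1"><Accession>GSM1</Accession></Sample>
  <Series iid="GSE1">
    <Title>A minimal series</Title>
    <Accession>GSE1</Accession>
    <Sample-Ref ref="GSM1"/>
  </Series>
</MINiML>"""


class TestParse:
    def test_minimal_document_yields_absent_optional_fields(self):
        series, samples = parse_miniml(MINIMAL)
        assert series.accession == "GSE1"
        assert series.title == "A minimal series"
        assert series.n_samples == 1
        assert series.summary is None and series.submission_year is None
        assert series.types == [] and series.pubmed_ids == []
        assert len(samples) == 1 and samples[0].cell_type is None

    def test_truncated_xml_is_a_parse_error_with_position(self):
        with pytest.raises(ParseError) as exc:
            parse_miniml(MINIMAL[:100])
        assert exc.value.line is not None

    def test_document_without_series_is_a_format_error(self):
        with pytest.raises(FormatError):
            parse_miniml(b"<MINiML><Sample iid='GSM1'/></MINiML>")

    def test_corpus_fields_match_ground_truth(self, corpus, fetcher):
        _, index = corpus
        for acc, truth in index["geo"].items():
            body, _ = fetcher.fetch(FetchRequest("geo_miniml", {"accession": acc}))
            series, samples = parse_miniml(body)
            assert series.accession == acc
            assert series.title == truth["title"]
            assert series.organisms == truth["organisms"]
            assert series.n_samples == truth["n_samples"] == len(samples)
            assert series.types == truth["types"]
            assert series.platform_ids == truth["platforms"]
            assert series.submission_year == truth["year"]
            assert series.pubmed_ids == truth["pmids"]
            assert [s.sample_id for s in samples] == \
                [s["sample_id"] for s in truth["samples"]]


def blocks(label, texts):
    return [(label, t) for t in texts]


class TestCollapse:
    def test_shared_protocol_collapses_to_one_block(self):
        samples = [SampleBlock(f"GSM{i}", growth_protocol="DMEM, 10% FBS")
                   for i in range(10)]
        got = collapse_sample_fields(samples)
        assert [(b.label, b.text) for b in got] == blocks(
            "Growth protocol", ["DMEM, 10% FBS"])

    def test_unique_protocols_all_survive_in_sample_order(self):
        samples = [SampleBlock(f"GSM{i}", treatment_protocol=f"treatment {i}")
                   for i in range(10)]
        got = collapse_sample_fields(samples)
        assert [b.text for b in got] == [f"treatment {i}" for i in range(10)]

    def test_first_appearance_unique_scan(self):
        samples = [SampleBlock(f"GSM{i}", treatment_protocol=t)
                   for i, t in enumerate(["A", "A", "B", "A"])]
        assert [b.text for b in collapse_sample_fields(samples)] == ["A", "B"]

    def test_whitespace_variants_are_the_same_value(self):
        samples = [SampleBlock("GSM1", treatment_protocol="LPS  100 ng/mL"),
                   SampleBlock("GSM2", treatment_protocol=" LPS 100 ng/mL ")]
        assert len(collapse_sample_fields(samples)) == 1

    def test_invariant_under_duplicating_any_sample(self):
        samples = [
            SampleBlock("GSM1", cell_type="BMDM", treatment_protocol="LPS",
                        characteristics=[("strain", "C57BL/6")]),
            SampleBlock("GSM2", cell_type="BMDM", treatment_protocol="IL-4"),
        ]
        base = collapse_sample_fields(samples)
        for i in range(len(samples)):
            doubled = samples[:i + 1] + [samples[i]] + samples[i + 1:]
            assert collapse_sample_fields(doubled) == base

    def test_output_length_bounds(self, corpus, fetcher):
        _, index = corpus
        for acc in index["geo"]:
            body, _ = fetcher.fetch(FetchRequest("geo_miniml", {"accession": acc}))
            _, samples = parse_miniml(body)
            got = collapse_sample_fields(samples)
            populated_kinds = len({b.label for b in got})
            assert populated_kinds <= len(got)
            # 6 field kinds; characteristics can carry several values per sample
            per_sample_values = max(len(s.characteristics) + 5 for s in samples)
            assert len(got) <= len(samples) * per_sample_values

    def test_empty_sample_list_is_an_error(self):
        with pytest.raises(ValidationError):
            collapse_sample_fields([])


class TestUnified:
    def test_missing_mandatory_fields_are_listed(self):
        series, samples = parse_miniml(MINIMAL)
        series.title = None
        series.n_samples = 0
        with pytest.raises(ValidationError) as exc:
            geo_to_unified(series, [])
        assert "title" in str(exc.value) and "samples" in str(exc.value)

    def test_bioproject_and_sra_become_urls(self, corpus, fetcher):
        _, index = corpus
        seen_links = False
        for acc, truth in index["geo"].items():
            body, _ = fetcher.fetch(FetchRequest("geo_miniml", {"accession": acc}))
            series, samples = parse_miniml(body)
            rec = geo_to_unified(series, collapse_sample_fields(samples))
            if truth["bioproject_id"]:
                seen_links = True
                assert truth["bioproject_id"] in rec.bioproject_ncbi
                assert truth["bioproject_id"] in rec.bioproject_ebi
            else:
                assert rec.bioproject_ncbi is None
            if truth["sra_id"]:
                assert truth["sra_id"] in rec.sra
        assert seen_links, "corpus should include BioProject-linked series"

    def test_round_trip_reproduces_sidecar_record(self, corpus, fetcher):
        _, index = corpus
        for acc, truth in index["geo"].items():
            body, _ = fetcher.fetch(FetchRequest("geo_miniml", {"accession": acc}))
            series, samples = parse_miniml(body)
            rec = geo_to_unified(series, collapse_sample_fields(samples))
            assert rec.accession.value == acc
            assert rec.title == truth["title"]
            assert rec.summary == truth["summary"]
            assert rec.organisms == truth["organisms"]
            assert rec.samples == truth["n_samples"]
            assert rec.types == truth["types"]
            assert rec.year == truth["year"]
            assert rec.molecule_type == truth["molecule"]
            assert rec.reference_ids == truth["pmids"]
            assert [[b.label, b.text] for b in rec.all_protocols] == \
                truth["expected_protocol_blocks"]
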