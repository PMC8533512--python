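"""Row splitting, text chunking and bit-exact table writing."""

import csv
import math

from hypothesis import given
from hypothesis import strategies as st

from geoharvest.export import (
    TABLE2_COLUMNS,
    chunk_text,
    protocols_text,
    read_table1,
    read_table2,
    record_to_cells,
    split_multivalue_rows,
    write_table1,
    write_table2,
)
from geoharvest.model import (
    Accession,
    DatasetRecord,
    LabeledBlock,
    Query,
    QueryCountRow,
)


def record(organisms=("Mus musculus",), types=("RNA-seq",), protocols=(),
           accession="GSE1"):
    return DatasetRecord(
        accession=Accession.parse(accession), organisms=list(organisms),
        samples=4, types=list(types), platform=["GPL1"],
        title='A title with, commas and "quotes"', year=2020,
        summary="line one\nline two", link="https://example.org/x",
        all_protocols=[LabeledBlock(*p) for p in protocols])


class TestSplit:
    def test_two_organisms_one_type_gives_two_rows(self):
        rows = split_multivalue_rows(record(organisms=["mouse", "human"]))
        assert len(rows) == 2
        assert [r.organisms for r in rows] == [["mouse"], ["human"]]

    def test_disabled_flag_keeps_one_joined_row(self):
        rec = record(organisms=["mouse"], types=["RNA-seq", "ATAC-seq"])
        rows = split_multivalue_rows(rec, enabled=False)
        assert rows == [rec]
        cells = record_to_cells(rows[0])
        assert cells[3] == "RNA-seq; ATAC-seq"

    def test_cartesian_product_of_organisms_and_types(self):
        rows = split_multivalue_rows(
            record(organisms=["a", "b"], types=["x", "y", "z"]))
        assert len(rows) == 6
        assert {(r.organisms[0], r.types[0]) for r in rows} == \
            {(o, t) for o in "ab" for t in "xyz"}

    def test_regrouping_recovers_original_multisets(self):
        rec = record(organisms=["a", "b"], types=["x", "y"])
        rows = split_multivalue_rows(rec)
        assert sorted({r.organisms[0] for r in rows}) == ["a", "b"]
        assert sorted({r.types[0] for r in rows}) == ["x", "y"]
        # every (organism, type) pair appears exactly once
        pairs = [(r.organisms[0], r.types[0]) for r in rows]
        assert len(pairs) == len(set(pairs)) == 4


class TestChunk:
    @given(st.text(max_size=2000), st.integers(1, 500))
    def test_cells_bounded_and_concatenation_exact(self, text, limit):
        cells = chunk_text(text, limit)
        assert all(len(c) <= limit for c in cells)
        assert "".join(cells) == text
        assert len(cells) == max(1, math.ceil(len(text) / limit))

    def test_documented_arithmetic_example(self):
        cells = chunk_text("x" * 100001, 32000)
        assert [len(c) for c in cells] == [32000, 32000, 32000, 4001]

    def test_empty_text_is_one_empty_cell(self):
        assert chunk_text("", 32000) == [""]


class TestTable2:
    def test_header_columns_in_fixed_order(self, tmp_path):
        path = write_table2([record()], tmp_path / "t2.csv")
        with path.open(newline="") as fh:
            header = next(csv.reader(fh))
        assert header == TABLE2_COLUMNS

    def test_header_starts_with_the_fixed_prefix(self, tmp_path):
        path = write_table2([record()], tmp_path / "t2.csv")
        first_line_cols = TABLE2_COLUMNS[:9]
        assert first_line_cols == ["Accession", "Organism", "Samples", "Type",
                                   "Platform", "Title", "Year", "Summary", "Link"]

    def test_long_protocols_overflow_into_extra_columns(self, tmp_path):
        rec = record(protocols=[("Treatment protocol", "y" * 70000)])
        path = write_table2([rec], tmp_path / "t2.csv", chunk_limit=32000)
        with path.open(newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            row = next(reader)
        assert header[-3:] == ["All protocols", "All protocols (2)",
                               "All protocols (3)"]
        joined = "".join(row[len(TABLE2_COLUMNS) - 1:])
        assert joined == protocols_text(rec.all_protocols)

    def test_empty_record_list_gives_header_only_file(self, tmp_path):
        path = write_table2([], tmp_path / "t2.csv")
        assert path.read_text().count("\n") == 1

    def test_rows_reparse_with_consistent_field_counts(self, tmp_path):
        records = [
            record(protocols=[("Growth protocol", "g" * 50)]),
            record(protocols=[("Treatment protocol", "t" * 80000)],
                   accession="GSE2"),
        ]
        path = write_table2(records, tmp_path / "t2.csv", chunk_limit=32000)
        with path.open(newline="") as fh:
            widths = {len(row) for row in csv.reader(fh)}
        assert len(widths) == 1  # header and all rows padded to equal width

    def test_protocol_cells_rejoin_byte_for_byte(self, tmp_path):
        rec = record(protocols=[("Growth protocol", "a\nb" * 1000),
                                ("Characteristics", "strain: C57BL/6")])
        path = write_table2([rec], tmp_path / "t2.csv", chunk_limit=100)
        rows = read_table2(path)
        assert rows[0]["All protocols"] == protocols_text(rec.all_protocols)

    def test_tsv_dialect(self, tmp_path):
        path = write_table2([record()], tmp_path / "t2.tsv", fmt="tsv")
        header = path.read_text().splitlines()[0]
        assert header.split("\t") == TABLE2_COLUMNS


class TestTable1:
    def rows(self):
        return [QueryCountRow(Query.from_raw("LPS"), 5),
                QueryCountRow(Query.from_raw("IL-4"), 2)]

    def test_rows_written_in_order(self, tmp_path):
        path = write_table1(self.rows(), tmp_path / "t1.csv")
        lines = path.read_text().splitlines()
        assert lines[0] == "query,n_datasets"
        assert lines[1] == "LPS,5" and lines[2] == "IL-4,2"

    def test_empty_list_gives_header_only(self, tmp_path):
        path = write_table1([], tmp_path / "t1.csv")
        assert path.read_text().splitlines() == ["query,n_datasets"]

    def test_round_trip_through_reader(self, tmp_path):
        path = write_table1(self.rows(), tmp_path / "t1.csv")
        back = read_table1(path)
        assert [(r.query.raw, r.n_datasets) for r in back] == \
            [("LPS", 5), ("IL-4", 2)]
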