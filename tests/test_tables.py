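import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikequant import (
    OtuTable,
    TableError,
    aggregate_by_genus,
    filter_low_depth_samples,
    genus_of,
    read_otu_table,
    read_sample_metadata,
    write_otu_table,
    write_sample_metadata,
)
from spikequant.tables import SampleMetadata


class TestReadWrite:
    def test_round_trip_small_table(self, small_table, tmp_path):
        path = write_otu_table(small_table, tmp_path / "t.tsv")
        back = read_otu_table(path)
        assert back.equals(small_table)
        assert back.state == "raw"

    def test_round_trip_preserves_taxonomy(self, random_raw_table, tmp_path):
        path = write_otu_table(random_raw_table, tmp_path / "t.tsv")
        back = read_otu_table(path)
        assert back.equals(random_raw_table)

    def test_round_trip_normalized_reals(self, tmp_path):
        counts = pd.DataFrame(
            [[123.456789012, 1e-4], [3333.33333333, 6543.2109876]],
            index=["a", "b"],
            columns=["s1", "s2"],
        )
        table = OtuTable(counts=counts, state="total_sum_normalized")
        back = read_otu_table(
            write_otu_table(table, tmp_path / "t.tsv"), state="total_sum_normalized"
        )
        assert np.allclose(
            back.counts.to_numpy(), counts.to_numpy(), rtol=1e-9, atol=0
        )

    def test_empty_cells_parse_as_zero(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("#OTU_ID\ts1\ts2\nOTU1\t\t4\nOTU2\t2\t\n")
        table = read_otu_table(p)
        assert table.counts.loc["OTU1", "s1"] == 0
        assert table.counts.loc["OTU2", "s2"] == 0

    def test_empty_table_writes_header_only(self, tmp_path):
        table = OtuTable(counts=pd.DataFrame(columns=["s1", "s2"], dtype=int))
        text = write_otu_table(table, tmp_path / "t.tsv").read_text()
        assert text.strip() == "#OTU_ID\ts1\ts2"

    def test_raw_integers_serialized_without_decimal_point(self, small_table, tmp_path):
        text = write_otu_table(small_table, tmp_path / "t.tsv").read_text()
        assert "5\t0" in text and "." not in text.splitlines()[1]

    def test_duplicate_sample_header_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("#OTU_ID\ts1\ts1\nOTU1\t1\t2\n")
        with pytest.raises(TableError, match="s1"):
            read_otu_table(p)

    def test_duplicate_otu_id_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("#OTU_ID\ts1\nOTU1\t1\nOTU1\t2\n")
        with pytest.raises(TableError, match="OTU1"):
            read_otu_table(p)

    @pytest.mark.parametrize("bad,expect", [("x", "non-numeric"), ("-3", "negative")])
    def test_bad_cell_reports_coordinates(self, tmp_path, bad, expect):
        p = tmp_path / "t.tsv"
        p.write_text(f"#OTU_ID\ts1\ts2\nOTU1\t1\t2\nOTU2\t{bad}\t4\n")
        with pytest.raises(TableError, match=expect) as exc:
            read_otu_table(p)
        assert "OTU2" in str(exc.value) and "s1" in str(exc.value)

    @settings(max_examples=25, deadline=None)
    @given(
        data=st.lists(
            st.lists(st.integers(min_value=0, max_value=10**6), min_size=3, max_size=3),
            min_size=1,
            max_size=8,
        )
    )
    def test_round_trip_property(self, data, tmp_path_factory):
        counts = pd.DataFrame(
            data,
            index=[f"O{i}" for i in range(len(data))],
            columns=["s1", "s2", "s3"],
        )
        table = OtuTable(counts=counts, state="raw")
        path = tmp_path_factory.mktemp("rt") / "t.tsv"
        assert read_otu_table(write_otu_table(table, path)).equals(table)


class TestInvariants:
    def test_negative_counts_rejected(self):
        counts = pd.DataFrame([[1, -2]], index=["a"], columns=["s1", "s2"])
        with pytest.raises(TableError, match="negative"):
            OtuTable(counts=counts)

    def test_raw_state_requires_whole_numbers(self):
        counts = pd.DataFrame([[1.5]], index=["a"], columns=["s1"])
        with pytest.raises(TableError, match="non-integer"):
            OtuTable(counts=counts, state="raw")
        OtuTable(counts=counts, state="total_sum_normalized")  # fine when normalized


class TestDepthFilter:
    def test_boundary_sample_at_min_reads_is_kept(self):
        counts = pd.DataFrame(
            {"s1": [6203], "s2": [999], "s3": [1000]}, index=["OTU1"]
        )
        table = OtuTable(counts=counts)
        kept, dropped = filter_low_depth_samples(table, min_reads=1000)
        assert kept.sample_ids == ["s1", "s3"]
        assert dropped == ["s2"]

    def test_no_drop_when_all_deep_enough(self, random_raw_table):
        kept, dropped = filter_low_depth_samples(random_raw_table, min_reads=1)
        assert dropped == [] and kept.sample_ids == random_raw_table.sample_ids

    def test_zero_sample_table(self):
        table = OtuTable(counts=pd.DataFrame(index=["a"], dtype=int))
        kept, dropped = filter_low_depth_samples(table)
        assert kept.n_samples == 0 and dropped == []

    def test_idempotent(self, random_raw_table):
        once, _ = filter_low_depth_samples(random_raw_table, min_reads=800)
        twice, dropped2 = filter_low_depth_samples(once, min_reads=800)
        assert dropped2 == [] and twice.equals(once)


class TestGenusAggregation:
    def test_counts_add_within_genus(self):
        counts = pd.DataFrame({"s1": [3, 4]}, index=["a", "b"])
        tax = {
            "a": "Bacteria;F;B;L;Leu;Leuconostoc",
            "b": "Bacteria;F;B;L;Leu;Leuconostoc",
        }
        agg = aggregate_by_genus(OtuTable(counts=counts, taxonomy=tax))
        assert agg.counts.loc["Leuconostoc", "s1"] == 7

    def test_unique_genera_keep_table_up_to_relabelling(self):
        counts = pd.DataFrame({"s1": [3, 4]}, index=["a", "b"])
        tax = {"a": "k;p;c;o;f;GenA", "b": "k;p;c;o;f;GenB"}
        agg = aggregate_by_genus(OtuTable(counts=counts, taxonomy=tax))
        assert sorted(agg.counts["s1"]) == [3, 4]
        assert set(agg.otu_ids) == {"GenA", "GenB"}

    def test_column_sums_conserved_exactly(self, random_raw_table):
        agg = aggregate_by_genus(random_raw_table)
        assert (agg.counts.sum(axis=0) == random_raw_table.counts.sum(axis=0)).all()

    def test_unparseable_lineage_pools_as_unclassified(self):
        counts = pd.DataFrame({"s1": [3, 4]}, index=["a", "b"])
        tax = {"a": "too;short", "b": "k;p;c;o;f;   "}
        agg = aggregate_by_genus(OtuTable(counts=counts, taxonomy=tax))
        assert agg.counts.loc["unclassified", "s1"] == 7

    def test_missing_taxonomy_errors(self, small_table):
        with pytest.raises(TableError, match="taxonomy"):
            aggregate_by_genus(small_table)

    def test_rank_prefix_stripped(self):
        assert genus_of("k__B;p__F;c__B;o__L;f__X;g__Leuconostoc") == "Leuconostoc"


class TestSampleMetadata:
    def test_round_trip(self, tmp_path):
        md = {
            "s1": SampleMetadata("s1", group="spiked", spike_spores_per_sample=8.5,
                                 replicate=2, volume_ml=0.85),
            "s2": SampleMetadata("s2", group="untreated", timepoint_days=4.0),
        }
        path = write_sample_metadata(md, tmp_path / "md.tsv")
        back = read_sample_metadata(path)
        assert back == md

    def test_volume_must_be_positive(self):
        with pytest.raises(TableError, match="volume"):
            SampleMetadata("s1", volume_ml=0.0)
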