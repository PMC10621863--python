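"""Barcode-map parsing rules, exact-match counting, variant collapse."""

import gzip

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdrmave import counts_io
from hdrmave.counts_io import (
    BarcodeMap,
    BarcodeMapEntry,
    BarcodeMapError,
    collapse_to_variants,
    count_barcodes,
    parse_barcode_map,
    write_barcode_map,
)
from hdrmave.simulate import emit_fastq
from hdrmave.variants import parse_label


def _write_map(tmp_path, rows, window="1280-1576"):
    p = tmp_path / "map.tsv"
    lines = [f"# window={window}", "barcode\taa_changes\tnt_changes"]
    lines += ["\t".join(r) for r in rows]
    p.write_text("\n".join(lines) + "\n")
    return p


class TestParseBarcodeMap:
    def test_outside_window_changes_treated_as_wt(self, tmp_path):
        # in-window change kept, incidental change at residue 900 discarded
        p = _write_map(tmp_path, [["ACGT", "p.Met1400Ser;p.Ala900Thr", "c.1>2"]])
        bmap = parse_barcode_map(p)
        e = bmap.entries["ACGT"]
        assert e.variant_label == "p.Met1400Ser" and not e.excluded_multi

    def test_no_changes_maps_to_wt_cohort(self, tmp_path):
        p = _write_map(tmp_path, [["ACGT", "", ""]])
        e = parse_barcode_map(p).entries["ACGT"]
        assert e.variant_label == counts_io.WT_LABEL
        assert e.variant_class == "synonymous"

    def test_two_in_window_changes_flagged_excluded(self, tmp_path):
        p = _write_map(tmp_path, [["ACGT", "p.Met1400Ser;p.Gln1396Ala", ""]])
        e = parse_barcode_map(p).entries["ACGT"]
        assert e.excluded_multi
        assert "ACGT" not in parse_barcode_map(p).scoring_entries()

    def test_duplicate_conflicting_barcode_is_error(self, tmp_path):
        p = _write_map(
            tmp_path,
            [["ACGT", "p.Met1400Ser", ""], ["ACGT", "p.Met1400Thr", ""]],
        )
        with pytest.raises(BarcodeMapError, match="conflict"):
            parse_barcode_map(p)

    def test_malformed_label_is_parse_error(self, tmp_path):
        p = _write_map(tmp_path, [["ACGT", "Met1400Ser", ""]])
        with pytest.raises(ValueError, match="malformed"):
            parse_barcode_map(p)

    def test_window_required(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("barcode\taa_changes\nACGT\tp.Met1400Ser\n")
        with pytest.raises(BarcodeMapError, match="window"):
            parse_barcode_map(p)
        assert parse_barcode_map(p, window=(1280, 1576)).entries

    def test_mixed_barcode_lengths_rejected(self, tmp_path):
        p = _write_map(tmp_path, [["ACGT", "", ""], ["ACGTA", "", ""]])
        with pytest.raises(BarcodeMapError, match="length"):
            parse_barcode_map(p)


def test_map_write_parse_round_trip(tmp_path, small_library):
    bmap, _ = small_library
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_barcode_map(bmap, p1)
    back = parse_barcode_map(p1)
    assert back.window == bmap.window
    assert set(back.entries) == set(bmap.entries)
    for b, e in bmap.entries.items():
        assert back.entries[b].aa_changes == e.aa_changes
    write_barcode_map(back, p2)
    assert p1.read_bytes() == p2.read_bytes()


class TestCountBarcodes:
    bmap = BarcodeMap(
        entries={
            "AAAA": BarcodeMapEntry("AAAA", (parse_label("p.Met1400Ser"),)),
            "CCCC": BarcodeMapEntry("CCCC", (parse_label("p.Met1400Thr"),)),
        },
        window=(1280, 1576),
    )

    def test_all_matching(self):
        df, unmatched = count_barcodes(["AAAA"] * 10, self.bmap, 1, "control", "input")
        assert unmatched == 0
        assert int(df.set_index("barcode").loc["AAAA", "count"]) == 10

    def test_conservation_with_unknowns(self):
        reads = ["AAAA"] * 4 + ["CCCC"] * 3 + ["GGGG"] * 3
        df, unmatched = count_barcodes(reads, self.bmap, 1, "control", "gfp_pos")
        by = df.set_index("barcode")["count"]
        assert (by["AAAA"], by["CCCC"], unmatched) == (4, 3, 3)
        assert by.sum() + unmatched == len(reads)

    def test_single_substitution_is_unmatched(self):
        df, unmatched = count_barcodes(["AAAT"], self.bmap, 1, "control", "input")
        assert unmatched == 1 and df["count"].sum() == 0

    def test_empty_stream_gives_zero_slice(self):
        df, unmatched = count_barcodes([], self.bmap, 2, "siBRCA1_CDS", "gfp_neg")
        assert unmatched == 0
        assert len(df) == 2 and df["count"].sum() == 0

    def test_fastq_path_plain_and_gz(self, tmp_path):
        slice_df = pd.DataFrame({"barcode": ["AAAA", "CCCC"], "count": [5, 2]})
        fq = tmp_path / "reads.fastq"
        n = emit_fastq(slice_df, fq)
        assert n == 7
        gz = tmp_path / "reads.fastq.gz"
        gz.write_bytes(gzip.compress(fq.read_bytes()))
        for path in (fq, gz):
            df, unmatched = count_barcodes(path, self.bmap, 1, "control", "input")
            by = df.set_index("barcode")["count"]
            assert (by["AAAA"], by["CCCC"], unmatched) == (5, 2, 0)


class TestCollapse:
    def _counts(self, rows):
        return pd.DataFrame(rows, columns=["barcode", "replicate", "condition", "bin", "count"])

    bmap = BarcodeMap(
        entries={
            "AAAA": BarcodeMapEntry("AAAA", (parse_label("p.Met1400Ser"),)),
            "CCCC": BarcodeMapEntry("CCCC", (parse_label("p.Met1400Ser"),)),
            "GGGG": BarcodeMapEntry("GGGG", (parse_label("p.Met1400Ser"),)),
            "TTTT": BarcodeMapEntry("TTTT", (parse_label("p.Gln1396Ala"),)),
        },
        window=(1280, 1576),
    )

    def test_additivity(self):
        counts = self._counts(
            [["AAAA", 1, "control", "input", 5], ["CCCC", 1, "control", "input", 7]]
        )
        v, tally = collapse_to_variants(counts, self.bmap)
        assert int(v["count"].sum()) == 12
        assert v.loc[v["variant_label"] == "p.Met1400Ser", "count"].item() == 12

    def test_identity_when_one_barcode_per_variant(self):
        counts = self._counts(
            [["AAAA", 1, "control", "input", 5], ["TTTT", 1, "control", "input", 9]]
        )
        sub = BarcodeMap(
            entries={b: self.bmap.entries[b] for b in ("AAAA", "TTTT")},
            window=(1280, 1576),
        )
        v, _ = collapse_to_variants(counts, sub)
        assert sorted(v["count"]) == [5, 9]

    def test_unmapped_dropped_with_tally(self):
        counts = self._counts(
            [
                ["AAAA", 1, "control", "input", 2],
                ["CCCC", 1, "control", "input", 3],
                ["GGGG", 1, "control", "input", 4],
                ["NNNN", 1, "control", "input", 9],
            ]
        )
        v, tally = collapse_to_variants(counts, self.bmap)
        assert v.loc[v["variant_label"] == "p.Met1400Ser", "count"].item() == 9
        assert tally["unmapped_reads"] == 9

    def test_mass_conservation_on_simulated_data(self, small_library, small_sim):
        bmap, _ = small_library
        v, tally = collapse_to_variants(small_sim.counts, bmap)
        for key in ["replicate", "condition", "bin"]:
            assert set(v[key]) <= set(small_sim.counts[key])
        before = small_sim.counts.groupby(["replicate", "condition", "bin"])["count"].sum()
        after = v.groupby(["replicate", "condition", "bin"])["count"].sum()
        assert (before == after).all()
        assert tally == {"unmapped_reads": 0, "excluded_multi_reads": 0}


@settings(max_examples=25, deadline=None)
@given(
    counts=st.lists(
        st.tuples(st.sampled_from(["AAAA", "CCCC", "TTTT", "NNNN"]), st.integers(0, 50)),
        min_size=1,
        max_size=8,
        unique_by=lambda t: t[0],
    )
)
def test_collapse_conserves_mapped_mass(counts):
    df = pd.DataFrame(
        [[b, 1, "control", "input", c] for b, c in counts],
        columns=["barcode", "replicate", "condition", "bin", "count"],
    )
    v, tally = collapse_to_variants(df, TestCollapse.bmap)
    mapped = sum(c for b, c in counts if b != "NNNN")
    assert int(v["count"].sum()) == mapped
    assert tally["unmapped_reads"] == sum(c for b, c in counts if b == "NNNN")


def test_count_matrix_round_trip(tmp_path, small_sim):
    p = tmp_path / "counts.tsv"
    counts_io.write_count_matrix(small_sim.counts, p, {"seed": 7})
    back = counts_io.read_count_matrix(p)
    pd.testing.assert_frame_equal(back, small_sim.counts)
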