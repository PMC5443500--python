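from __future__ import annotations

import numpy as np
import pytest

from dloopdyn.alignment import (
    AlignedSequence,
    ReadSet,
    SampleMetadata,
    build_consensus,
    default_ref_positions,
    filter_dataset,
    read_alignment,
    read_metadata,
    write_alignment,
    write_metadata,
)
from dloopdyn.simulate import make_study_fixture

from conftest import make_seqs


def read_set(columns, extractions):
    """ReadSet from per-read strings and extraction labels."""
    reads = make_seqs(columns, ids=[f"r{i}" for i in range(len(columns))])
    return ReadSet("sampleX", reads, list(extractions))


class TestConsensus:
    def test_strict_majority_called(self):
        rs = read_set(["A", "A", "G"], ["e1", "e1", "e2"])
        assert build_consensus(rs, min_reads=3, min_extractions=2).sequence() == "A"

    def test_coverage_below_threshold_is_missing(self):
        rs = read_set(["A", "G"], ["e1", "e2"])
        assert build_consensus(rs, min_reads=3).sequence() == "?"

    def test_tie_is_missing_never_iupac(self):
        rs = read_set(["A", "A", "G", "G"], ["e1", "e2", "e3", "e3"])
        assert build_consensus(rs, min_reads=3).sequence() == "?"

    @pytest.mark.parametrize("n_a,n_g", [(a, 6 - a) for a in range(7)])
    def test_majority_rule_matches_enumeration(self, n_a, n_g):
        """Exhaustive 2-state count splits: called iff strict majority."""
        col = ["A"] * n_a + ["G"] * n_g
        if not col:
            return
        rs = read_set(col, [f"e{i}" for i in range(len(col))])
        got = build_consensus(rs, min_reads=1, min_extractions=1).sequence()
        if n_a > n_g:
            assert got == "A"
        elif n_g > n_a:
            assert got == "G"
        else:
            assert got == "?"

    def test_too_few_extractions_is_missing(self):
        rs = read_set(["A", "A", "A"], ["e1", "e1", "e1"])
        assert build_consensus(rs, min_reads=3, min_extractions=2).sequence() == "?"

    def test_consensus_idempotent_on_identical_reads(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=12))
        reads = make_seqs([seq] * 4, ids=[f"r{i}" for i in range(4)])
        rs = ReadSet("s", reads, ["e1", "e2", "e1", "e2"])
        assert build_consensus(rs).sequence() == seq

    def test_missing_reads_do_not_count_as_coverage(self):
        rs = read_set(["A", "A", "?"], ["e1", "e2", "e3"])
        assert build_consensus(rs, min_reads=3).sequence() == "?"

    def test_empty_read_set_errors(self):
        with pytest.raises(ValueError, match="empty"):
            build_consensus(ReadSet("s", [], []))

    def test_column_space_mismatch_errors(self):
        r1 = AlignedSequence("r1", list("AC"), default_ref_positions(2))
        r2 = AlignedSequence("r2", list("AC"), np.array([15492, 15494]))
        with pytest.raises(ValueError, match="column space"):
            build_consensus(ReadSet("s", [r1, r2], ["e1", "e2"]))


def toy_meta(aln, dated=()):
    return [
        SampleMetadata(s.sample_id, "SiteA", "Magdalenian", 15000.0,
                       s.sample_id in dated)
        for s in aln
    ]


class TestDatasetFilters:
    def test_dataset1_keeps_everything(self):
        aln = make_seqs(["ACGT", "AC?T", "????"[:4]])
        ds = filter_dataset(aln, toy_meta(aln), "dataset1")
        assert len(ds.members) == 3

    def test_missingness_boundary(self):
        # 45% missing excluded, exactly 40% kept
        aln = make_seqs(["?" * 9 + "A" * 11, "?" * 8 + "A" * 12, "A" * 20])
        ds = filter_dataset(aln, toy_meta(aln), "dataset2")
        assert ds.members == ["s2", "s3"]

    def test_dated_only_count(self):
        aln = make_seqs(["ACGT"] * 10, ids=[f"s{i}" for i in range(10)])
        ds = filter_dataset(aln, toy_meta(aln, dated={"s0", "s4", "s7"}), "dataset3")
        assert sorted(ds.members) == ["s0", "s4", "s7"]
        assert "Magd.+Azilian" not in ds.bins

    def test_unknown_rule_errors(self):
        aln = make_seqs(["ACGT"])
        with pytest.raises(ValueError, match="rule"):
            filter_dataset(aln, toy_meta(aln), "dataset9")

    def test_partition_complement(self):
        """dataset2 members plus the excluded samples recover dataset1."""
        aln, meta, _ = make_study_fixture(5)
        d1 = filter_dataset(aln, meta, "dataset1")
        d2 = filter_dataset(aln, meta, "dataset2")
        excluded = set(d1.members) - set(d2.members)
        assert set(d2.members) | excluded == set(d1.members)
        assert not set(d2.members) & excluded

    def test_fixture_reproduces_study_bin_sizes(self):
        aln, meta, _ = make_study_fixture(11)
        d1 = filter_dataset(aln, meta, "dataset1")
        sizes = {b: len(m) for b, m in d1.bins.items()}
        assert len(d1.members) == 97
        assert sizes == {
            "Palaeontological": 4,
            "Badegoulian": 11,
            "Magdalenian": 70,
            "Magd.+Azilian": 74,
            "Azilian": 4,
            "Neolithic": 8,
        }
        d2 = filter_dataset(aln, meta, "dataset2")
        assert len(d2.members) == 78
        d3 = filter_dataset(aln, meta, "dataset3")
        assert len(d3.members) == 36
        # combined bin is the union of its parts
        assert set(d1.bins["Magd.+Azilian"]) == set(
            d1.bins["Magdalenian"]
        ) | set(d1.bins["Azilian"])


class TestIO:
    def test_three_record_fasta(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACGT\n>b\nAC?T\n>c\nTTTT\n")
        aln = read_alignment(p)
        assert [s.sample_id for s in aln] == ["a", "b", "c"]
        assert aln[1].missing_fraction == 0.25

    def test_invalid_symbol_names_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">ok\nACGT\n>bad\nACNT\n")
        with pytest.raises(ValueError, match="bad"):
            read_alignment(p)

    def test_duplicate_id_errors(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nACGT\n>x\nACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_alignment(p)

    def test_roundtrip_identity_on_fixture(self, tmp_path):
        aln, meta, _ = make_study_fixture(3)
        fa = tmp_path / "aln.fasta"
        write_alignment(aln, fa)
        back = read_alignment(fa)
        assert len(back) == len(aln)
        for a, b in zip(aln, back):
            assert a.sample_id == b.sample_id
            assert np.array_equal(a.bases, b.bases)

    def test_metadata_roundtrip_and_ka_normalisation(self, tmp_path):
        meta = [SampleMetadata("s1", "SiteA", "Neolithic", 5500.0, True)]
        p = tmp_path / "m.tsv"
        write_metadata(meta, p)
        back = read_metadata(p)
        assert back[0] == meta[0]
        # ages below 100 are interpreted as ka
        p2 = tmp_path / "m2.csv"
        p2.write_text(
            "sample_id,site,culture,age_calBP,dated_directly,region\n"
            "s1,SiteA,Neolithic,5.5,True,SwissSwabian\n"
        )
        assert read_metadata(p2)[0].age_calBP == 5500.0

    def test_metadata_duplicate_id_errors(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text(
            "sample_id,site,culture,age_calBP,dated_directly,region\n"
            "s1,A,Neolithic,5000,True,SwissSwabian\n"
            "s1,A,Neolithic,5000,True,SwissSwabian\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_metadata(p)

    def test_alignment_metadata_mismatch_reported(self):
        aln = make_seqs(["ACGT", "AAAA"])
        with pytest.raises(ValueError, match="s2"):
            filter_dataset(aln, toy_meta(aln[:1]), "dataset1")
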