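from __future__ import annotations

import numpy as np
import pytest

from dloopdyn.alignment import AlignedSequence, default_ref_positions
from dloopdyn.haplotypes import (
    DEFAULT_HOTSPOTS,
    HaplogroupDef,
    assign_haplogroup,
    collapse_haplotypes,
    haplogroup_frequencies,
    read_haplogroup_defs,
    segregating_sites,
    shipped_haplogroup_defs,
)

from conftest import make_seqs, random_alignment


class TestCollapse:
    def test_strict_exact_matches(self):
        hts = collapse_haplotypes(make_seqs(["ACGT", "ACGT", "ACGA"]), "strict")
        assert sorted(h.count for h in hts) == [1, 2]

    def test_compatible_merges_missing(self):
        hts = collapse_haplotypes(make_seqs(["ACGT", "AC?T"]), "compatible")
        assert len(hts) == 1 and hts[0].count == 2

    def test_strict_never_matches_missing(self):
        hts = collapse_haplotypes(make_seqs(["ACGT", "AC?T"]), "strict")
        assert len(hts) == 2

    def test_partition_is_exact(self, rng):
        aln = random_alignment(rng, 20, 12, missing_prob=0.1)
        hts = collapse_haplotypes(aln, "compatible")
        members = [sid for h in hts for sid in h.members]
        assert sorted(members) == sorted(s.sample_id for s in aln)
        assert sum(h.count for h in hts) == len(aln)

    def test_matches_first_compatible_oracle(self, rng):
        """Greedy first-fit against an independent pairwise-compatibility
        re-implementation on raw strings."""
        aln = random_alignment(rng, 20, 8, missing_prob=0.15)
        seqs = [s.sequence() for s in aln]

        def compatible(a, b):
            return all(x == "?" or y == "?" or x == y for x, y in zip(a, b))

        groups: list[list[int]] = []
        patterns: list[list[str]] = []
        for i, s in enumerate(seqs):
            for g, pat in zip(groups, patterns):
                if compatible(s, pat):
                    g.append(i)
                    for c, ch in enumerate(s):
                        if pat[c] == "?" and ch != "?":
                            pat[c] = ch
                    break
            else:
                groups.append([i])
                patterns.append(list(s))
        expected = [[aln[i].sample_id for i in g] for g in groups]
        got = [h.members for h in collapse_haplotypes(aln, "compatible")]
        assert got == expected

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            collapse_haplotypes([])


class TestSegregatingSites:
    def test_single_difference(self):
        assert segregating_sites(make_seqs(["ACGT", "ACGA"]))[0] == 1

    def test_missing_excluded(self):
        assert segregating_sites(make_seqs(["AC?T", "ACGT"]))[0] == 0

    def test_random_matrix_matches_columnwise_oracle(self, rng):
        aln = random_alignment(rng, 30, 50, missing_prob=0.1)
        mat = np.stack([s.bases for s in aln])
        expected = sum(
            len(set(mat[:, c]) - {"?"}) >= 2 for c in range(mat.shape[1])
        )
        assert segregating_sites(aln)[0] == expected


def full_length_seq(ref_positions, reference, changes):
    bases = reference.copy()
    idx = {int(p): i for i, p in enumerate(ref_positions)}
    for p, b in changes.items():
        bases[idx[p]] = b
    return AlignedSequence("q", bases, ref_positions)


@pytest.fixture(scope="module")
def classifier_setup():
    ref_positions = default_ref_positions(241)
    rng = np.random.default_rng(7)
    reference = rng.choice(list("ACGT"), size=241)
    defs, hotspots = shipped_haplogroup_defs()
    idx = {int(p): i for i, p in enumerate(ref_positions)}
    for d in defs:
        for p, b in d.mandatory + d.optional:
            if reference[idx[p]] == b:
                reference[idx[p]] = {"A": "G", "G": "A", "C": "T", "T": "C"}[b]
    ref = AlignedSequence("ref", reference, ref_positions)
    return ref_positions, ref, defs, hotspots


class TestAssignHaplogroup:
    def test_x4b_without_optional_position(self, classifier_setup):
        """Derived at 15495, 15540, 15602, 15720 but ancestral at the
        optional 15718 still classifies as X4b."""
        ref_positions, ref, defs, hotspots = classifier_setup
        derived = {p: b for d in defs if d.name == "X4b" for p, b in d.mandatory + d.optional}
        derived.pop(15718)
        seq = full_length_seq(ref_positions, ref.bases, derived)
        name, diag = assign_haplogroup(seq, defs, ref, hotspots)
        assert name == "X4b"

    def test_reference_itself_unassigned(self, classifier_setup):
        ref_positions, ref, defs, hotspots = classifier_setup
        name, diag = assign_haplogroup(ref, defs, ref, hotspots)
        assert name == "unassigned"
        assert diag["reason"] == "no definition matched"

    def test_hotspot_only_variant_unassigned(self, classifier_setup):
        ref_positions, ref, defs, hotspots = classifier_setup
        seq = full_length_seq(ref_positions, ref.bases, {15585: "?"})
        idx = {int(p): i for i, p in enumerate(ref_positions)}
        b = ref.bases[idx[15585]]
        seq.bases[idx[15585]] = {"A": "G", "G": "A", "C": "T", "T": "C"}[b]
        assert assign_haplogroup(seq, defs, ref, hotspots)[0] == "unassigned"

    def test_assignment_invariant_to_hotspot_substitutions(self, classifier_setup, rng):
        ref_positions, ref, defs, hotspots = classifier_setup
        idx = {int(p): i for i, p in enumerate(ref_positions)}
        d = defs[0]
        base_seq = full_length_seq(
            ref_positions, ref.bases, {p: b for p, b in d.mandatory}
        )
        name0, _ = assign_haplogroup(base_seq, defs, ref, hotspots)
        for _ in range(20):
            seq = AlignedSequence("q", base_seq.bases.copy(), ref_positions)
            for h in DEFAULT_HOTSPOTS:
                seq.bases[idx[h]] = rng.choice(list("ACGT?"))
            assert assign_haplogroup(seq, defs, ref, hotspots)[0] == name0

    def test_missing_mandatory_is_insufficient_data(self, classifier_setup):
        ref_positions, ref, defs, hotspots = classifier_setup
        d = next(x for x in defs if x.name == "X4b")
        seq = full_length_seq(ref_positions, ref.bases, {d.mandatory[0][0]: "?"})
        name, diag = assign_haplogroup(seq, defs, ref, hotspots)
        assert name == "unassigned"
        assert diag["reason"] == "insufficient data"

    def test_defining_position_outside_span_errors(self, classifier_setup):
        ref_positions, ref, defs, hotspots = classifier_setup
        short = AlignedSequence("q", ref.bases[:10], ref_positions[:10])
        with pytest.raises(ValueError, match="outside"):
            assign_haplogroup(short, defs, ref, hotspots)

    def test_ambiguous_when_two_definitions_match(self, classifier_setup):
        ref_positions, ref, defs, hotspots = classifier_setup
        a, b = defs[1], defs[2]
        changes = {p: x for p, x in a.mandatory + b.mandatory}
        seq = full_length_seq(ref_positions, ref.bases, changes)
        name, diag = assign_haplogroup(seq, defs, ref, hotspots)
        assert name == "ambiguous"
        assert set(diag["candidates"]) == {a.name, b.name}


class TestDefsIO:
    def test_shipped_definitions_parse(self):
        defs, hotspots = shipped_haplogroup_defs()
        names = {d.name for d in defs}
        assert "X4b" in names and len(names) == 8
        assert sorted(hotspots) == [15585, 15604, 15650]
        x4b = next(d for d in defs if d.name == "X4b")
        assert (15540, "T") in x4b.mandatory
        assert 15718 in {p for p, _ in x4b.optional}

    def test_json_roundtrip(self, tmp_path):
        p = tmp_path / "defs.json"
        p.write_text(
            '{"__hotspots__": [15585], '
            '"G1": {"mandatory": [[15540, "T"]], "optional": [[15718, "A"]]}}'
        )
        defs, hotspots = read_haplogroup_defs(p)
        assert defs[0].name == "G1" and hotspots == [15585]

    def test_overlapping_mandatory_optional_rejected(self):
        with pytest.raises(ValueError):
            HaplogroupDef("bad", [(15540, "T")], [(15540, "C")])


def test_haplogroup_frequency_rows_sum_to_one():
    assignments = {"a": "A", "b": "B", "c": "A", "d": "unassigned"}
    freqs = haplogroup_frequencies(assignments, {"bin1": ["a", "b", "c", "d"]})
    assert freqs.loc["bin1"].sum() == pytest.approx(1.0)
    assert freqs.loc["bin1", "A"] == pytest.approx(2 / 3)
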