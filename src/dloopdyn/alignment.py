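"""Alignment and metadata I/O, replicate consensus, and dataset filtering.

Sequences are short mitochondrial control-region (d-loop) fragments on explicit
reference-mitogenome coordinates.  The amplified region covers two disjoint
blocks, positions 15,492-15,669 and 15,696-15,758 (1-based, inclusive), i.e. at
most 241 aligned columns.  Missing data are coded ``?``; the alphabet is
strictly ``{A, C, G, T, ?}``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

MISSING = "?"
ALPHABET = frozenset("ACGT?")

#: The two amplified reference blocks (1-based, inclusive).
REF_BLOCKS = ((15492, 15669), (15696, 15758))

#: Region of concentrated block missingness observed in partially assembled
#: ancient sequences.
MISSING_BLOCK = (15564, 15669)

CULTURES = ("Palaeontological", "Badegoulian", "Magdalenian", "Azilian", "Neolithic")
REGIONS = ("SwissSwabian", "Ural", "Asia")

#: Label of the pooled Magdalenian + Azilian bin.
COMBINED_BIN = "Magd.+Azilian"


def default_ref_positions(length: int | None = None) -> np.ndarray:
    """Reference coordinates of the full 241-column region (or a prefix)."""
    pos = np.concatenate([np.arange(a, b + 1) for a, b in REF_BLOCKS])
    return pos if length is None else pos[:length]


@dataclass
class AlignedSequence:
    """One sample's aligned d-loop sequence on reference coordinates."""

    sample_id: str
    bases: np.ndarray  # dtype '<U1', alphabet {A,C,G,T,?}
    ref_positions: np.ndarray  # 1-based, strictly increasing

    def __post_init__(self) -> None:
        self.bases = np.asarray(self.bases, dtype="<U1")
        self.ref_positions = np.asarray(self.ref_positions, dtype=np.int64)
        if self.bases.shape != self.ref_positions.shape:
            raise ValueError(
                f"{self.sample_id}: {self.bases.size} bases but "
                f"{self.ref_positions.size} reference positions"
            )
        bad = set(self.bases) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.sample_id!r}: invalid symbol(s) {sorted(bad)}; "
                f"alphabet is A,C,G,T,?"
            )
        if self.bases.size > 241:
            raise ValueError(f"{self.sample_id}: {self.bases.size} columns > 241")
        if np.any(np.diff(self.ref_positions) <= 0):
            raise ValueError(f"{self.sample_id}: ref_positions not strictly increasing")
        in_blocks = np.zeros(self.ref_positions.size, dtype=bool)
        for a, b in REF_BLOCKS:
            in_blocks |= (self.ref_positions >= a) & (self.ref_positions <= b)
        if not in_blocks.all():
            out = self.ref_positions[~in_blocks]
            raise ValueError(
                f"{self.sample_id}: positions outside amplified blocks: {out[:5]}"
            )

    def __len__(self) -> int:
        return self.bases.size

    @property
    def missing_fraction(self) -> float:
        return float(np.count_nonzero(self.bases == MISSING)) / self.bases.size

    def sequence(self) -> str:
        return "".join(self.bases)


@dataclass
class SampleMetadata:
    """Per-sample archaeological metadata row."""

    sample_id: str
    site: str
    culture: str
    age_calBP: float  # calendar years BP
    dated_directly: bool
    region: str = "SwissSwabian"

    def __post_init__(self) -> None:
        if self.culture not in CULTURES:
            raise ValueError(f"{self.sample_id}: unknown culture {self.culture!r}")
        if self.region not in REGIONS:
            raise ValueError(f"{self.sample_id}: unknown region {self.region!r}")


@dataclass
class ReadSet:
    """Aligned replicate reads (amplifications) for one sample."""

    sample_id: str
    reads: list[AlignedSequence]
    extraction_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.reads) != len(self.extraction_ids):
            raise ValueError("one extraction_id required per read")


@dataclass
class Dataset:
    """A filtered sample set partitioned into time bins.

    ``bins`` maps bin label to member sample ids.  The combined
    Magdalenian+Azilian bin, when present, is the union of the two separate
    bins and is excluded from the partition invariant.
    """

    name: str
    members: list[str]
    bins: dict[str, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# consensus

def build_consensus(
    reads: ReadSet, min_reads: int = 3, min_extractions: int = 2
) -> AlignedSequence:
    """Majority-rule consensus across replicate reads of one sample.

    A column is called iff at least ``min_reads`` reads cover it (non-missing)
    from at least ``min_extractions`` distinct extractions and one base holds a
    strict majority among covering reads; otherwise the column is ``?``.
    """
    if not reads.reads:
        raise ValueError(f"{reads.sample_id}: empty read set")
    if min_reads < 1 or min_extractions < 1:
        raise ValueError("min_reads and min_extractions must be >= 1")
    ref = reads.reads[0].ref_positions
    for r in reads.reads[1:]:
        if not np.array_equal(r.ref_positions, ref):
            raise ValueError(
                f"{reads.sample_id}: replicate reads on different column spaces"
            )
    mat = np.stack([r.bases for r in reads.reads])  # reads x columns
    ext = np.asarray(reads.extraction_ids)
    out = np.full(ref.size, MISSING, dtype="<U1")
    for c in range(ref.size):
        col = mat[:, c]
        covered = col != MISSING
        if covered.sum() < min_reads:
            continue
        if len(set(ext[covered])) < min_extractions:
            continue
        states, counts = np.unique(col[covered], return_counts=True)
        best = counts.argmax()
        # strict majority over covering reads; ties stay missing
        if counts[best] * 2 > covered.sum() and (counts == counts[best]).sum() == 1:
            out[c] = states[best]
    return AlignedSequence(reads.sample_id, out, ref)


# ---------------------------------------------------------------------------
# dataset filters

_BIN_OF_CULTURE = {c: c for c in CULTURES}


def assign_bins(
    members: Iterable[str],
    meta: dict[str, SampleMetadata],
    combined: bool = True,
) -> dict[str, list[str]]:
    """Group sample ids into culture time bins, optionally adding the pooled
    Magdalenian+Azilian bin."""
    bins: dict[str, list[str]] = {c: [] for c in CULTURES}
    for sid in members:
        bins[_BIN_OF_CULTURE[meta[sid].culture]].append(sid)
    if combined:
        bins[COMBINED_BIN] = bins["Magdalenian"] + bins["Azilian"]
    return {k: v for k, v in bins.items() if v or k in CULTURES}


def filter_dataset(
    aln: Sequence[AlignedSequence],
    meta: Sequence[SampleMetadata],
    rule: str,
    max_missing: float = 0.40,
) -> Dataset:
    """Apply one of the three dataset-selection rules.

    * ``dataset1`` — all samples;
    * ``dataset2`` — samples with more than ``max_missing`` (default 40%)
      missing nucleotides excluded;
    * ``dataset3`` — only directly radiocarbon-dated samples; the combined
      Magdalenian+Azilian bin is dropped.
    """
    meta_by_id = {m.sample_id: m for m in meta}
    missing_meta = [s.sample_id for s in aln if s.sample_id not in meta_by_id]
    if missing_meta:
        raise ValueError(f"samples without metadata: {missing_meta}")
    if rule == "dataset1":
        keep = [s.sample_id for s in aln]
    elif rule == "dataset2":
        keep = [s.sample_id for s in aln if s.missing_fraction <= max_missing]
    elif rule == "dataset3":
        keep = [s.sample_id for s in aln if meta_by_id[s.sample_id].dated_directly]
    else:
        raise ValueError(f"unknown dataset rule {rule!r}")
    bins = assign_bins(keep, meta_by_id, combined=rule != "dataset3")
    logger.info("%s: kept %d of %d samples", rule, len(keep), len(aln))
    return Dataset(rule, keep, bins)


# ---------------------------------------------------------------------------
# file I/O

def read_alignment(path: str | Path) -> list[AlignedSequence]:
    """Read a FASTA alignment ('?' permitted for missing data).

    All records must share one length; reference positions are taken as the
    first ``L`` columns of the two amplified blocks.  Duplicate ids and
    alphabet violations are reported with the offending record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    seen: set[str] = set()
    out: list[AlignedSequence] = []
    length = len(records[0].seq)
    ref = default_ref_positions(length)
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sample_id {rec.id!r}")
        seen.add(rec.id)
        if len(rec.seq) != length:
            raise ValueError(
                f"{path}: record {rec.id!r} length {len(rec.seq)} != {length}"
            )
        out.append(AlignedSequence(rec.id, list(str(rec.seq).upper()), ref))
    logger.info("read %d aligned sequences (%d columns) from %s", len(out), length, path)
    return out


def write_alignment(aln: Sequence[AlignedSequence], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(s.sequence()), id=s.sample_id, description="") for s in aln
    ]
    SeqIO.write(recs, str(path), "fasta")
    logger.info("wrote %d sequences to %s", len(recs), path)


_META_COLUMNS = ["sample_id", "site", "culture", "age_calBP", "dated_directly", "region"]


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read the sample metadata table (CSV or TSV, sniffed from the header).

    Ages given in ka are normalised to calendar years BP (values below 100 are
    interpreted as ka).
    """
    sep = "\t" if Path(path).suffix in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(_META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    rows = []
    for rec in df.to_dict("records"):
        age = float(rec["age_calBP"])
        if age < 100:  # declared in ka
            age *= 1000.0
        rows.append(
            SampleMetadata(
                sample_id=str(rec["sample_id"]),
                site=str(rec["site"]),
                culture=str(rec["culture"]),
                age_calBP=age,
                dated_directly=bool(rec["dated_directly"]),
                region=str(rec["region"]),
            )
        )
    ids = [r.sample_id for r in rows]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate sample_id(s) {dupes}")
    logger.info("read %d metadata rows from %s", len(rows), path)
    return rows


def write_metadata(meta: Sequence[SampleMetadata], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "site": m.site,
                "culture": m.culture,
                "age_calBP": m.age_calBP,
                "dated_directly": m.dated_directly,
                "region": m.region,
            }
            for m in meta
        ],
        columns=_META_COLUMNS,
    )
    sep = "\t" if Path(path).suffix in {".tsv", ".tab"} else ","
    df.to_csv(path, sep=sep, index=False)


def alignment_matrix(aln: Sequence[AlignedSequence]) -> np.ndarray:
    """Stack sequences into an (n_samples, n_columns) character matrix."""
    if not aln:
        raise ValueError("empty alignment")
    ref = aln[0].ref_positions
    for s in aln[1:]:
        if not np.array_equal(s.ref_positions, ref):
            raise ValueError("sequences on different column spaces")
    return np.stack([s.bases for s in aln])
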