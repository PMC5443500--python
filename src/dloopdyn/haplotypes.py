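"""Haplotype collapsing and haplogroup assignment with hotspot masking.

A haplotype is a distinct observed sequence variant; haplogroups are named
matrilines defined by diagnostic derived states at reference positions.
Transitions at a small set of positions recur sporadically across all
haplogroups; these hotspots are dismissed before matching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import MISSING, AlignedSequence, alignment_matrix

#: Mutational hotspot positions dismissed during haplogroup matching.
DEFAULT_HOTSPOTS = (15585, 15604, 15650)


@dataclass
class Haplotype:
    ht_id: str
    pattern: np.ndarray
    members: list[str]

    @property
    def count(self) -> int:
        return len(self.members)


@dataclass
class HaplogroupDef:
    """A named matriline: mandatory and optional defining (position, base) pairs."""

    name: str
    mandatory: list[tuple[int, str]]
    optional: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        overlap = {p for p, _ in self.mandatory} & {p for p, _ in self.optional}
        if overlap:
            raise ValueError(f"{self.name}: positions both mandatory and optional: {overlap}")

    def positions(self) -> set[int]:
        return {p for p, _ in self.mandatory} | {p for p, _ in self.optional}


def collapse_haplotypes(
    aln: Sequence[AlignedSequence], match_policy: str = "compatible"
) -> list[Haplotype]:
    """Collapse aligned sequences into haplotypes.

    ``strict``: a ``?`` never matches, so sequences join a haplotype only when
    identical including missingness.  ``compatible``: ``?`` matches any base
    and a sequence joins the first compatible existing haplotype in input
    order; observed bases fill in the haplotype pattern's gaps.
    """
    if not aln:
        raise ValueError("empty alignment")
    if match_policy not in {"strict", "compatible"}:
        raise ValueError(f"unknown match_policy {match_policy!r}")
    haplotypes: list[Haplotype] = []
    for seq in aln:
        placed = False
        for ht in haplotypes:
            if match_policy == "strict":
                ok = np.array_equal(ht.pattern, seq.bases)
            else:
                either_missing = (ht.pattern == MISSING) | (seq.bases == MISSING)
                ok = bool(np.all(either_missing | (ht.pattern == seq.bases)))
            if ok:
                ht.members.append(seq.sample_id)
                if match_policy == "compatible":
                    fill = (ht.pattern == MISSING) & (seq.bases != MISSING)
                    ht.pattern[fill] = seq.bases[fill]
                placed = True
                break
        if not placed:
            haplotypes.append(
                Haplotype(f"ht{len(haplotypes) + 1:02d}", seq.bases.copy(), [seq.sample_id])
            )
    return haplotypes


def segregating_sites(aln: Sequence[AlignedSequence]) -> tuple[int, pd.DataFrame]:
    """Count segregating columns (>= 2 distinct non-missing bases observed).

    Returns the count and a per-column polymorphism table (reference position,
    observed states, state counts, segregating flag).
    """
    if len(aln) < 2:
        raise ValueError("need >= 2 sequences")
    mat = alignment_matrix(aln)
    ref = aln[0].ref_positions
    rows = []
    for c in range(mat.shape[1]):
        col = mat[:, c]
        obs = col[col != MISSING]
        states, counts = (
            np.unique(obs, return_counts=True) if obs.size else (np.array([]), np.array([]))
        )
        rows.append(
            {
                "ref_position": int(ref[c]),
                "states": "".join(states),
                "counts": ",".join(map(str, counts)),
                "segregating": len(states) >= 2,
            }
        )
    table = pd.DataFrame(rows)
    return int(table["segregating"].sum()), table


def assign_haplogroup(
    seq: AlignedSequence,
    defs: Sequence[HaplogroupDef],
    reference: AlignedSequence,
    hotspots: Sequence[int] = DEFAULT_HOTSPOTS,
) -> tuple[str, dict]:
    """Assign a sequence to a haplogroup by its diagnostic positions.

    Hotspot columns are masked before matching.  A definition matches iff
    every mandatory (position, base) is observed (non-missing, equal to the
    derived base).  Missing data at a mandatory position makes the definition
    undecidable; if no definition is decided the result is ``unassigned`` with
    reason ``insufficient data`` when at least one was undecidable.  More than
    one match yields ``ambiguous`` with the candidate list.
    """
    pos_index = {int(p): i for i, p in enumerate(seq.ref_positions)}
    hot = set(int(h) for h in hotspots)
    for d in defs:
        for p in d.positions():
            if p in hot:
                raise ValueError(f"{d.name}: defining position {p} is a hotspot")
            if p not in pos_index:
                raise ValueError(f"{d.name}: position {p} outside alignment span")

    matches: list[str] = []
    insufficient = False
    diag: dict[str, object] = {"per_def": {}}
    for d in defs:
        states = {}
        ok = True
        undecided = False
        for p, base in d.mandatory:
            b = seq.bases[pos_index[p]]
            states[p] = b
            if b == MISSING:
                undecided = True
            elif b != base:
                ok = False
        for p, base in d.optional:
            states[p] = seq.bases[pos_index[p]]
        if ok and not undecided:
            matches.append(d.name)
        if ok and undecided:
            insufficient = True
        diag["per_def"][d.name] = {
            "observed": {p: str(b) for p, b in states.items()},
            "matched": ok and not undecided,
            "undecidable": undecided,
        }
    if len(matches) == 1:
        diag["reason"] = "unique match"
        return matches[0], diag
    if len(matches) > 1:
        diag["candidates"] = matches
        diag["reason"] = "multiple definitions match"
        return "ambiguous", diag
    diag["reason"] = "insufficient data" if insufficient else "no definition matched"
    return "unassigned", diag


def haplogroup_frequencies(
    assignments: dict[str, str], bins: dict[str, list[str]]
) -> pd.DataFrame:
    """Relative haplogroup frequencies per bin over assigned samples.

    Rows are bins, columns haplogroup names; each row sums to 1 over samples
    with a definite assignment (unassigned/ambiguous dropped).
    """
    names = sorted({a for a in assignments.values() if a not in {"unassigned", "ambiguous"}})
    rows = {}
    for label, members in bins.items():
        counts = {n: 0 for n in names}
        for sid in members:
            a = assignments.get(sid)
            if a in counts:
                counts[a] += 1
        total = sum(counts.values())
        rows[label] = (
            {n: c / total for n, c in counts.items()} if total else {n: 0.0 for n in names}
        )
    return pd.DataFrame.from_dict(rows, orient="index", columns=names)


# ---------------------------------------------------------------------------
# definition file I/O

_HOTSPOT_NAME = "__hotspots__"


def read_haplogroup_defs(
    path: str | Path,
) -> tuple[list[HaplogroupDef], list[int]]:
    """Read haplogroup definitions from TSV or JSON.

    TSV columns: name, position, base, status in {mandatory, optional};
    hotspot positions are listed under the reserved name ``__hotspots__``.
    """
    path = Path(path)
    if path.suffix == ".json":
        raw = json.loads(path.read_text())
        hotspots = [int(p) for p in raw.pop(_HOTSPOT_NAME, [])]
        defs = [
            HaplogroupDef(
                name,
                [(int(p), b) for p, b in entry.get("mandatory", [])],
                [(int(p), b) for p, b in entry.get("optional", [])],
            )
            for name, entry in raw.items()
        ]
        return defs, hotspots
    df = pd.read_csv(path, sep="\t", comment="#")
    hotspots = [int(p) for p in df.loc[df["name"] == _HOTSPOT_NAME, "position"]]
    defs = []
    for name, grp in df[df["name"] != _HOTSPOT_NAME].groupby("name", sort=False):
        mand = [(int(r.position), r.base) for r in grp.itertuples() if r.status == "mandatory"]
        opt = [(int(r.position), r.base) for r in grp.itertuples() if r.status == "optional"]
        defs.append(HaplogroupDef(str(name), mand, opt))
    return defs, hotspots


def write_haplotype_table(haplotypes: Sequence[Haplotype], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "ht_id": h.ht_id,
                "pattern": "".join(h.pattern),
                "count": h.count,
                "members": ";".join(h.members),
            }
            for h in haplotypes
        ]
    ).to_csv(path, sep="\t", index=False)


def shipped_haplogroup_defs() -> tuple[list[HaplogroupDef], list[int]]:
    """The definition table shipped with the package.

    X4b and the hotspot list follow the published account; the remaining
    haplogroup entries (A, B, C, D, H, K, X3) are synthetic placeholders for
    the user-supplied definitions of the wider nomenclature.
    """
    ref = resources.files("dloopdyn") / "data" / "haplogroups.tsv"
    with resources.as_file(ref) as p:
        return read_haplogroup_defs(p)
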