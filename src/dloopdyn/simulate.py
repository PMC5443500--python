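"""Synthetic d-loop datasets with the structure the analysis assumes.

Sequences are generated from a coalescent genealogy per bin (constant size or
stepwise expansion), with infinite-sites mutations scattered over the finite
column set under a transition:transversion bias, optional planting of
haplogroup-defining states, and block-structured missing data concentrated in
the centre of the amplified region — mirroring how partially assembled
ancient sequences fail.  True parameters (theta, tau, group memberships) are
known, so every stage of the pipeline has recovery tests without external
downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import coalescent
from .alignment import (
    MISSING,
    MISSING_BLOCK,
    AlignedSequence,
    SampleMetadata,
    default_ref_positions,
)
from .haplotypes import DEFAULT_HOTSPOTS, HaplogroupDef, shipped_haplogroup_defs

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}

#: Bin sizes of the quality-filtered dataset (<= 40% missing), used as the
#: default simulated study structure.
DEFAULT_BIN_SIZES = {
    "Palaeontological": 4,
    "Badegoulian": 11,
    "Magdalenian": 53,
    "Azilian": 4,
    "Neolithic": 6,
}

#: Calibrated age ranges (years BP) per culture bin.
AGE_RANGES = {
    "Palaeontological": (41000, 37000),
    "Badegoulian": (24000, 23000),
    "Magdalenian": (18000, 13500),
    "Azilian": (12500, 12000),
    "Neolithic": (5500, 5000),
}

SITES = {
    "Palaeontological": ["Schalberghoehle", "Bocksteinhoehle"],
    "Badegoulian": ["Kohlerhoehle"],
    "Magdalenian": ["Kesslerloch", "Kaesloch", "Schweizersbild", "Kohlerhoehle"],
    "Azilian": ["Rislisberghoehle", "Schalberghoehle"],
    "Neolithic": ["Twann-Bahnhof", "Mumpf"],
}


@dataclass
class SuddenExpansion:
    """Stepwise growth from theta0 to theta1 at mutational time tau ago."""

    tau: float
    theta0: float
    theta1: float


@dataclass
class SimulationConfig:
    seed: int
    n_per_bin: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_BIN_SIZES))
    L: int = 241
    theta: float = 5.0
    demography: str | SuddenExpansion = "constant"
    ts_tv_ratio: float = 10.0
    missing_fraction: float = 0.0  # fraction of samples carrying a missing block
    missing_block: tuple[int, int] = MISSING_BLOCK  # reference coordinates

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_bin.values()):
            raise ValueError("bin sizes must be >= 0")
        if isinstance(self.demography, SuddenExpansion):
            d = self.demography
            if d.tau < 0 or d.theta0 < 0 or d.theta1 < 0:
                raise ValueError("tau and thetas must be >= 0")


def random_reference(L: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(list("ACGT"), size=L)


def _mutate_base(ref_base: str, rng: np.random.Generator, ts_tv_ratio: float) -> str:
    p_ts = ts_tv_ratio / (ts_tv_ratio + 2.0)
    if rng.random() < p_ts:
        return TRANSITION[ref_base]
    return TRANSVERSIONS[ref_base][rng.integers(2)]


def _simulate_sequences(
    n: int,
    theta: float,
    demography: str | SuddenExpansion,
    reference: np.ndarray,
    rng: np.random.Generator,
    ts_tv_ratio: float,
    mutable_columns: np.ndarray | None = None,
) -> np.ndarray:
    """Character matrix (n x L) from one coalescent genealogy."""
    L = reference.size
    if isinstance(demography, SuddenExpansion):
        d = demography
        t_change = d.tau / d.theta1 if d.theta1 > 0 else np.inf
        ratio = d.theta0 / d.theta1 if d.theta1 > 0 else 1.0
        lengths, leafsets = coalescent.simulate_genealogy(
            n, rng, t_change=t_change, size_ratio=ratio
        )
        g = coalescent.drop_mutations(lengths, leafsets, rng, theta=d.theta1)
    elif demography == "constant":
        lengths, leafsets = coalescent.simulate_genealogy(n, rng)
        g = coalescent.drop_mutations(lengths, leafsets, rng, theta=theta)
    else:
        raise ValueError(f"unknown demography {demography!r}")
    allowed = (
        np.arange(L) if mutable_columns is None else np.asarray(mutable_columns)
    )
    if g.shape[0] > allowed.size:
        raise ValueError(
            f"L too small: {g.shape[0]} mutations but only {allowed.size} "
            f"mutable columns"
        )
    columns = rng.choice(allowed, size=g.shape[0], replace=False)
    mat = np.tile(reference, (n, 1))
    for m in range(g.shape[0]):
        derived = _mutate_base(reference[columns[m]], rng, ts_tv_ratio)
        mat[g[m], columns[m]] = derived
    return mat


def _block_columns(ref_positions: np.ndarray, block: tuple[int, int]) -> np.ndarray:
    a, b = block
    return np.flatnonzero((ref_positions >= a) & (ref_positions <= b))


def simulate_bin(
    config: SimulationConfig,
    bin_label: str | None = None,
    rng: np.random.Generator | None = None,
    reference: np.ndarray | None = None,
) -> tuple[list[AlignedSequence], list[SampleMetadata]]:
    """Simulate one time bin under the configured demography.

    The bin defaults to the first entry of ``n_per_bin``.  Missing blocks are
    applied after simulation, missing-completely-at-random at the sample
    level.  Pass a shared ``reference`` when simulating several bins of one
    study so that between-bin distances stay on the within-population scale.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    bin_label = bin_label or next(iter(config.n_per_bin))
    n = config.n_per_bin[bin_label]
    if n == 0:
        return [], []
    ref_positions = default_ref_positions(config.L)
    if reference is None:
        reference = random_reference(config.L, rng)
    if n == 1:  # no genealogy to draw; the lone lineage is the reference
        mat = reference[None, :].copy()
    else:
        mat = _simulate_sequences(
            n, config.theta, config.demography, reference, rng, config.ts_tv_ratio
        )
    if config.missing_fraction > 0:
        block = _block_columns(ref_positions, config.missing_block)
        hit = rng.random(n) < config.missing_fraction
        mat[np.ix_(hit, block)] = MISSING
    lo, hi = AGE_RANGES.get(bin_label, (10000, 9000))
    aln, meta = [], []
    sites = SITES.get(bin_label, ["SimSite"])
    for i in range(n):
        sid = f"{bin_label[:4]}{i + 1:03d}"
        aln.append(AlignedSequence(sid, mat[i], ref_positions))
        meta.append(
            SampleMetadata(
                sample_id=sid,
                site=sites[int(rng.integers(len(sites)))],
                culture=bin_label if bin_label in AGE_RANGES else "Magdalenian",
                age_calBP=float(rng.uniform(hi, lo)),
                dated_directly=bool(rng.random() < 0.5),
                region="SwissSwabian",
            )
        )
    return aln, meta


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[AlignedSequence], list[SampleMetadata]]:
    """All bins of the configured study, sharing one reference but with
    independent genealogies per bin."""
    rng = np.random.default_rng(config.seed)
    reference = random_reference(config.L, rng)
    aln: list[AlignedSequence] = []
    meta: list[SampleMetadata] = []
    for label in config.n_per_bin:
        a, m = simulate_bin(config, label, rng, reference=reference)
        aln.extend(a)
        meta.extend(m)
    return aln, meta


# ---------------------------------------------------------------------------
# the full study-structure fixture

_FIXTURE_BIN_SIZES = {
    "Palaeontological": 4,
    "Badegoulian": 11,
    "Magdalenian": 70,
    "Azilian": 4,
    "Neolithic": 8,
}

_FIXTURE_GROUPS = {
    "Palaeontological": ["A", "X3", "B", "A"],
    "Badegoulian": ["B"] * 5 + ["H"] * 3 + ["X3"] * 3,
    "Magdalenian": (
        ["A"] * 14 + ["B"] * 18 + ["D"] * 8 + ["K"] * 6 + ["H"] * 4
        + ["X3"] * 12 + ["X4b"] * 6 + ["C"] * 2
    ),
    "Azilian": ["B", "B", "K", "K"],
    "Neolithic": ["A"] * 3 + ["B"] * 2 + ["D"] * 3,
}

#: samples per bin carrying the large (>40% of columns) missing block and the
#: small sub-threshold block; 27 samples in total have missing data, of which
#: 19 fall out of the quality-filtered dataset (17 Magdalenian, 2 Neolithic).
_FIXTURE_BIG_MISSING = {"Magdalenian": 17, "Neolithic": 2}
_FIXTURE_SMALL_MISSING = {"Magdalenian": 8}

_FIXTURE_DATED = {
    "Palaeontological": 4,
    "Badegoulian": 5,
    "Magdalenian": 20,
    "Azilian": 3,
    "Neolithic": 4,
}


def make_study_fixture(
    seed: int,
) -> tuple[list[AlignedSequence], list[SampleMetadata], dict]:
    """A 97-sample multi-bin dataset mirroring the study structure.

    Bins 4/11/70/4/8 across nine-plus sites; eight planted haplogroups
    (including an X4b-bearing lineage); 27 samples carry missing blocks, 19
    of them exceeding the 40% threshold so the quality-filtered dataset has
    78 members (bins 4/11/53/4/6); directly dated flags give a 36-member
    dated-only dataset (4/5/20/3/4).  Returns (alignment, metadata, truth)
    where ``truth`` holds the reference sequence, the definitions used and
    the planted group of every sample.
    """
    rng = np.random.default_rng(seed)
    L = 241
    ref_positions = default_ref_positions(L)
    defs, hotspots = shipped_haplogroup_defs()
    def_by_name = {d.name: d for d in defs}
    pos_index = {int(p): i for i, p in enumerate(ref_positions)}

    reference = random_reference(L, rng)
    # reference must be ancestral at every defining position
    for d in defs:
        for p, base in d.mandatory + d.optional:
            if reference[pos_index[p]] == base:
                reference[pos_index[p]] = TRANSITION[base]

    reserved = {pos_index[p] for d in defs for p, _ in d.mandatory + d.optional}
    reserved |= {pos_index[h] for h in hotspots}
    mutable = np.array([c for c in range(L) if c not in reserved])

    aln: list[AlignedSequence] = []
    meta: list[SampleMetadata] = []
    truth_groups: dict[str, str] = {}
    for label, n in _FIXTURE_BIN_SIZES.items():
        mat = _simulate_sequences(
            n, 4.0, "constant", reference, rng, 10.0, mutable_columns=mutable
        )
        groups = list(_FIXTURE_GROUPS[label])
        assert len(groups) == n
        for i, gname in enumerate(groups):
            d = def_by_name[gname]
            for p, base in d.mandatory:
                mat[i, pos_index[p]] = base
            for p, base in d.optional:
                if rng.random() < 0.8:
                    mat[i, pos_index[p]] = base
        # sporadic hotspot transitions, present in all haplogroups
        for i in range(n):
            if rng.random() < 0.1:
                h = hotspots[int(rng.integers(len(hotspots)))]
                c = pos_index[h]
                mat[i, c] = TRANSITION[str(mat[i, c])]

        big = _FIXTURE_BIG_MISSING.get(label, 0)
        small = _FIXTURE_SMALL_MISSING.get(label, 0)
        hit = rng.choice(n, size=big + small, replace=False)
        big_cols = _block_columns(ref_positions, MISSING_BLOCK)
        small_cols = _block_columns(ref_positions, (15620, 15669))
        for i in hit[:big]:
            mat[i, big_cols] = MISSING
        for i in hit[big:]:
            mat[i, small_cols] = MISSING

        dated = set(rng.choice(n, size=_FIXTURE_DATED[label], replace=False))
        lo, hi = AGE_RANGES[label]
        sites = SITES[label]
        for i in range(n):
            sid = f"{label[:4]}{i + 1:03d}"
            aln.append(AlignedSequence(sid, mat[i], ref_positions))
            meta.append(
                SampleMetadata(
                    sample_id=sid,
                    site=sites[int(rng.integers(len(sites)))],
                    culture=label,
                    age_calBP=float(rng.uniform(hi, lo)),
                    dated_directly=i in dated,
                    region="SwissSwabian",
                )
            )
            truth_groups[sid] = groups[i]

    truth = {
        "reference": AlignedSequence("reference", reference, ref_positions),
        "defs": defs,
        "hotspots": hotspots,
        "groups": truth_groups,
    }
    return aln, meta, truth
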