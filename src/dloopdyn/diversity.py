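"""Nucleotide and haplotype diversity under missing data.

Two missing-data conventions are provided, because both are in routine use:

* ``pairwise`` deletion — each pair of sequences is compared over the columns
  both have data for, and the raw difference count is rescaled to the full
  alignment length by ``L / L_ij``;
* ``column_threshold`` — columns with more than a fraction ``q`` (default 5%)
  of missing entries are removed first, then pairs are compared with pairwise
  deletion over the surviving columns.

Distances are raw p-distances (no substitution-model correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alignment import MISSING, AlignedSequence, alignment_matrix


@dataclass
class DiversityResult:
    bin_label: str
    n: int
    n_haplotypes: int
    pi: float  # per-site nucleotide diversity
    pi_total: float  # mean pairwise differences (in sites)
    h: float  # haplotype diversity


def pairwise_distance_matrix(
    aln: Sequence[AlignedSequence] | np.ndarray,
    deletion: str = "pairwise",
    q: float = 0.05,
) -> tuple[np.ndarray, int]:
    """Pairwise difference matrix and the effective alignment length.

    Returns ``(D, L_eff)`` where ``D[i, j]`` is the (rescaled) number of
    differences between sequences i and j.  A pair with zero mutually
    non-missing columns is an error in ``pairwise`` mode.
    """
    mat = aln if isinstance(aln, np.ndarray) else alignment_matrix(aln)
    n, L = mat.shape
    if deletion == "column_threshold":
        keep = (mat == MISSING).mean(axis=0) <= q
        mat = mat[:, keep]
        L_eff = int(keep.sum())
        if L_eff == 0:
            raise ValueError("no columns survive the missing-data threshold")
    elif deletion == "pairwise":
        L_eff = L
    else:
        raise ValueError(f"unknown deletion mode {deletion!r}")

    present = mat != MISSING  # n x L'
    # overlap[i,j] = mutually non-missing columns; raw[i,j] = differing columns
    overlap = present.astype(np.int64) @ present.T.astype(np.int64)
    raw = np.zeros((n, n), dtype=np.int64)
    for b in "ACGT":
        is_b = (mat == b) & present
        raw += is_b.astype(np.int64) @ (present & ~is_b).T.astype(np.int64)
    D = np.zeros((n, n), dtype=float)
    iu = np.triu_indices(n, 1)
    zero = overlap[iu] == 0
    if zero.any():
        i, j = iu[0][zero][0], iu[1][zero][0]
        raise ValueError(f"sequences {i} and {j} share no non-missing columns")
    D[iu] = raw[iu] * (mat.shape[1] / overlap[iu])
    D += D.T
    return D, L_eff


def nucleotide_diversity(
    aln: Sequence[AlignedSequence] | np.ndarray,
    deletion: str = "pairwise",
    q: float = 0.05,
) -> tuple[float, float]:
    """Per-site nucleotide diversity and mean pairwise differences.

    ``pi_total`` is the mean number of (rescaled) differences over all
    C(n, 2) pairs; ``pi = pi_total / L_eff``.
    """
    D, L_eff = pairwise_distance_matrix(aln, deletion=deletion, q=q)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need >= 2 sequences")
    iu = np.triu_indices(n, 1)
    pi_total = float(D[iu].mean())
    return pi_total / L_eff, pi_total


def haplotype_diversity(counts: Sequence[int]) -> float:
    """Sample-size-corrected haplotype diversity h = n(1 - sum p_i^2)/(n-1)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("haplotype diversity undefined for n < 2")
    p = counts / n
    return float(n * (1.0 - np.sum(p**2)) / (n - 1.0))
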