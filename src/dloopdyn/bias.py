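"""Pooled-resampling test for sample-size bias between two time bins.

Before interpreting a diversity difference (or an F_ST value) between two
unevenly sized bins, the sequences of both bins are pooled and pseudo-groups
of the original sizes are repeatedly drawn from the pool with replacement.
If a bin's observed diversity falls in the tail of its own-size pseudo
distribution, the comparison is flagged as biased by sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alignment import AlignedSequence
from .diversity import pairwise_distance_matrix
from .haplotypes import collapse_haplotypes


@dataclass
class BiasTestResult:
    binA: str
    binB: str
    stat: str  # "pi" or "h"
    n_perm: int
    observedA: float
    observedB: float
    pseudo_distA: np.ndarray
    pseudo_distB: np.ndarray
    pA: float
    pB: float
    alpha: float
    skipped: bool = False
    reason: str = ""

    @property
    def biased(self) -> bool:
        return (not self.skipped) and min(self.pA, self.pB) < self.alpha


def _two_sided_p(pseudo: np.ndarray, observed: float) -> float:
    r = pseudo.size
    lo = (1 + np.sum(pseudo <= observed)) / (r + 1)
    hi = (1 + np.sum(pseudo >= observed)) / (r + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


def _group_stats(
    D: np.ndarray, classes: np.ndarray, idx: np.ndarray, L: int
) -> tuple[float, float]:
    """(pi, h) of a (multi)set of pool indices, from precomputed pieces."""
    n = idx.size
    iu = np.triu_indices(n, 1)
    pi_total = D[np.ix_(idx, idx)][iu].mean()
    _, counts = np.unique(classes[idx], return_counts=True)
    p = counts / n
    h = n * (1.0 - np.sum(p**2)) / (n - 1.0)
    return float(pi_total / L), float(h)


def bias_test(
    aln_a: Sequence[AlignedSequence],
    aln_b: Sequence[AlignedSequence],
    stat: str = "pi",
    n_perm: int = 10000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    match_policy: str = "compatible",
    replacement: bool = True,
    binA: str = "A",
    binB: str = "B",
) -> BiasTestResult:
    """Pooled-resampling sample-size-bias test for one statistic.

    Each replicate draws (with replacement by default; ``replacement=False``
    gives a classical permutation split) a pseudo-group of size n_A and one of
    size n_B from the pooled sequences and records the chosen diversity
    statistic.  Per bin, a two-sided empirical tail probability of the
    observed value within its own-size pseudo distribution is reported, with
    the +1 correction; ``biased`` is true when either p falls below alpha.

    Haplotype classes and the pairwise-deletion distance matrix are computed
    once on the pool, so resampling reduces to index arithmetic.
    """
    rng = rng if rng is not None else np.random.default_rng()
    if stat not in {"pi", "h"}:
        raise ValueError(f"unknown statistic {stat!r}")
    if n_perm < 100:
        import warnings

        warnings.warn(f"n_perm={n_perm} is low for a resampling test", stacklevel=2)
    nA, nB = len(aln_a), len(aln_b)
    if nA < 2 or nB < 2:
        raise ValueError("both bins need n >= 2")
    pool = [
        AlignedSequence(str(i), s.bases, s.ref_positions)
        for i, s in enumerate(list(aln_a) + list(aln_b))
    ]
    N = len(pool)
    haps = collapse_haplotypes(pool, match_policy=match_policy)
    if len(haps) == 1:
        return BiasTestResult(binA, binB, stat, n_perm, float("nan"), float("nan"),
                              np.array([]), np.array([]), float("nan"), float("nan"),
                              alpha, skipped=True,
                              reason="degenerate pool: single haplotype")
    by_id = {sid: k for k, h in enumerate(haps) for sid in h.members}
    classes = np.array([by_id[s.sample_id] for s in pool], dtype=int)
    D, L = pairwise_distance_matrix(pool)
    which = 0 if stat == "pi" else 1

    obsA = _group_stats(D, classes, np.arange(nA), L)[which]
    obsB = _group_stats(D, classes, np.arange(nA, N), L)[which]

    distA = np.empty(n_perm)
    distB = np.empty(n_perm)
    for r in range(n_perm):
        if replacement:
            ia = rng.integers(0, N, size=nA)
            ib = rng.integers(0, N, size=nB)
        else:
            perm = rng.permutation(N)
            ia, ib = perm[:nA], perm[nA : nA + nB]
        distA[r] = _group_stats(D, classes, ia, L)[which]
        distB[r] = _group_stats(D, classes, ib, L)[which]
    return BiasTestResult(
        binA, binB, stat, n_perm, obsA, obsB, distA, distB,
        _two_sided_p(distA, obsA), _two_sided_p(distB, obsB), alpha,
    )
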