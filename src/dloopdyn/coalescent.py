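"""Lightweight Kingman coalescent with piecewise-constant population size.

Used for neutrality-test null distributions (conditioning on the observed
number of segregating sites, which general-purpose simulators do not expose),
for the parametric bootstrap of the sudden-expansion fit, and as the genealogy
engine of the synthetic-data generator.

Units follow the mismatch-analysis convention for haploid (mitochondrial)
data: time is measured in units of N_1 generations where N_1 is the present
population size, mutations arrive at rate ``theta/2`` per lineage per unit
time (``theta = 2 N_1 u`` per locus), and a stepwise expansion that happened
``tau = 2 u T`` mutational time units ago sits at coalescent time
``tau / theta_1`` with relative ancestral size ``theta_0 / theta_1``.
"""

from __future__ import annotations

import numpy as np


def simulate_genealogy(
    n: int,
    rng: np.random.Generator,
    t_change: float = np.inf,
    size_ratio: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one coalescent genealogy.

    Population size is 1 (relative) for t < ``t_change`` and ``size_ratio``
    for t >= ``t_change`` (pastward).  Returns ``(lengths, leafsets)`` over the
    2n-2 non-root branches: branch lengths and the boolean leaf membership of
    each branch's subtended clade.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    n_nodes = 2 * n - 1
    birth = np.zeros(n_nodes)
    leafsets = np.zeros((n_nodes, n), dtype=bool)
    leafsets[np.arange(n), np.arange(n)] = True
    lengths = np.zeros(n_nodes - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    k = n
    while k > 1:
        # a zero ancestral size means instant coalescence; clamp instead
        size = 1.0 if t < t_change else max(size_ratio, 1e-9)
        rate = k * (k - 1) / 2.0 / size
        w = rng.exponential(1.0 / rate)
        if t < t_change < t + w:
            t = t_change  # re-draw in the ancestral epoch (memoryless)
            continue
        t += w
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = active[i], active[j]
        lengths[a] = t - birth[a]
        lengths[b] = t - birth[b]
        leafsets[nxt] = leafsets[a] | leafsets[b]
        birth[nxt] = t
        active[i] = nxt
        del active[j]
        nxt += 1
        k -= 1
    return lengths, leafsets[: n_nodes - 1]


def drop_mutations(
    lengths: np.ndarray,
    leafsets: np.ndarray,
    rng: np.random.Generator,
    *,
    n_mutations: int | None = None,
    theta: float | None = None,
) -> np.ndarray:
    """Place mutations on branches, uniformly by branch length.

    Either a fixed mutation count (conditioning on S) or a Poisson number with
    mean ``theta/2 * total_length``.  Each mutation hits a fresh site
    (infinite sites), so the returned (n_mutations, n_samples) boolean matrix
    has one row of derived-state carriers per mutation.
    """
    total = lengths.sum()
    if n_mutations is None:
        if theta is None:
            raise ValueError("give n_mutations or theta")
        n_mutations = rng.poisson(theta / 2.0 * total)
    if n_mutations == 0:
        return np.zeros((0, leafsets.shape[1]), dtype=bool)
    branches = rng.choice(lengths.size, size=n_mutations, p=lengths / total)
    return leafsets[branches]


def pairwise_diff_stats(genotypes: np.ndarray) -> tuple[float, int]:
    """(mean pairwise differences, segregating sites) from a mutation matrix."""
    m, n = genotypes.shape
    if m == 0:
        return 0.0, 0
    f = genotypes.sum(axis=1)
    pi_total = float((f * (n - f)).sum()) / (n * (n - 1) / 2)
    return pi_total, m


def haplotype_counts(genotypes: np.ndarray) -> np.ndarray:
    """Multiplicities of distinct haplotypes implied by a mutation matrix."""
    n = genotypes.shape[1]
    if genotypes.shape[0] == 0:
        return np.array([n])
    _, counts = np.unique(genotypes.T, axis=0, return_counts=True)
    return counts


def mismatch_counts(genotypes: np.ndarray) -> np.ndarray:
    """Histogram of pairwise difference counts over all sample pairs."""
    g = genotypes.T.astype(np.int64)  # n x m
    n = g.shape[0]
    d = g @ (1 - g).T + (1 - g) @ g.T
    iu = np.triu_indices(n, 1)
    return np.bincount(d[iu])
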