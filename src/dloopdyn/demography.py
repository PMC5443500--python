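"""Neutrality tests and sudden-expansion analysis per time bin.

Implements Tajima's D, Fu's Fs (exact Ewens-distribution computation with
log-space Stirling numbers), the mismatch distribution, and the stepwise
("sudden") expansion model fit of Rogers & Harpending with SSD and
Harpending's raggedness, each with resampling p-values from the internal
coalescent simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from . import coalescent
from .alignment import AlignedSequence
from .diversity import nucleotide_diversity, pairwise_distance_matrix
from .haplotypes import collapse_haplotypes, segregating_sites


@dataclass
class NeutralityResult:
    bin_label: str
    statistic: str  # "D" or "Fs"
    value: float  # nan when undefined
    p: float
    defined: bool
    note: str = ""


@dataclass
class MismatchDistribution:
    counts: np.ndarray  # pair counts for i = 0..d differences

    @property
    def freqs(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())


@dataclass
class ExpansionFit:
    tau: float
    theta0: float
    theta1: float
    ssd: float
    p_ssd: float
    raggedness: float
    p_rag: float
    converged: bool = True


# ---------------------------------------------------------------------------
# Tajima's D

def tajima_constants(n: int) -> dict[str, float]:
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return {
        "a1": a1,
        "a2": a2,
        "e1": c1 / a1,
        "e2": c2 / (a1**2 + a2),
    }


def tajimas_d_value(pi_total: float, S: int, n: int) -> float:
    """Tajima's D from mean pairwise differences and segregating sites."""
    if S < 1:
        return float("nan")
    c = tajima_constants(n)
    num = pi_total - S / c["a1"]
    denom = np.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))
    if denom == 0.0:
        # n=3 collapses the variance estimate; a zero numerator is still D=0
        return 0.0 if num == 0.0 else float("nan")
    return float(num / denom)


def tajimas_d(
    aln: Sequence[AlignedSequence],
    n_reps: int = 1000,
    rng: np.random.Generator | None = None,
    condition: str = "S",
    deletion: str = "pairwise",
    two_tailed: bool = False,
    bin_label: str = "",
) -> NeutralityResult:
    """Tajima's D with a coalescent-simulation p-value.

    The null distribution is simulated conditional on the observed number of
    segregating sites (``condition='S'``) or on the observed mean pairwise
    differences (``condition='theta'``).  The p-value is one-tailed toward
    negative D (the expansion signal); ``two_tailed`` reports
    Pr(|D*| >= |D_obs|) instead.
    """
    rng = rng if rng is not None else np.random.default_rng()
    n = len(aln)
    if n < 2:
        raise ValueError("need >= 2 sequences")
    S, _ = segregating_sites(aln)
    _, pi_total = nucleotide_diversity(aln, deletion=deletion)
    if S == 0:
        return NeutralityResult(bin_label, "D", float("nan"), float("nan"), False,
                                "no segregating sites")
    d_obs = tajimas_d_value(pi_total, S, n)
    sims = np.empty(n_reps)
    kept = 0
    while kept < n_reps:
        lengths, leafsets = coalescent.simulate_genealogy(n, rng)
        if condition == "S":
            g = coalescent.drop_mutations(lengths, leafsets, rng, n_mutations=S)
        elif condition == "theta":
            g = coalescent.drop_mutations(lengths, leafsets, rng, theta=pi_total)
        else:
            raise ValueError(f"unknown conditioning {condition!r}")
        pi_sim, s_sim = coalescent.pairwise_diff_stats(g)
        if s_sim == 0:
            continue
        sims[kept] = tajimas_d_value(pi_sim, s_sim, n)
        kept += 1
    if two_tailed:
        p = (1 + np.sum(np.abs(sims) >= abs(d_obs))) / (n_reps + 1)
    else:
        p = (1 + np.sum(sims <= d_obs)) / (n_reps + 1)
    return NeutralityResult(bin_label, "D", d_obs, float(p), True)


# ---------------------------------------------------------------------------
# Fu's Fs

@lru_cache(maxsize=64)
def _log_stirling_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned Stirling numbers, first kind)."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |s(0,0)| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        # |s(m,k)| = (m-1)|s(m-1,k)| + |s(m-1,k-1)|
        with np.errstate(divide="ignore"):
            grown = row + np.log(m - 1) if m > 1 else np.full(n + 1, -np.inf)
        new[1:] = np.logaddexp(grown[1:], row[:-1])
        row = new
    return row


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log Pr(K = k | theta, n) for k = 0..n under the Ewens distribution."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    k = np.arange(n + 1)
    log_rising = float(np.sum(np.log(theta + np.arange(n))))
    return _log_stirling_row(n) + k * np.log(theta) - log_rising


def fs_value(n: int, k_obs: int, theta: float) -> float:
    """Fu's Fs = ln(S'/(1-S')) with S' = Pr(K >= k_obs | theta, n)."""
    if theta <= 0:
        return float("nan")
    logp = ewens_log_pmf(n, theta)
    log_sprime = special.logsumexp(logp[k_obs:])
    if log_sprime >= 0.0:  # S' == 1: observing >= k_obs haplotypes is certain
        return float("inf")
    log_one_minus = np.log1p(-np.exp(log_sprime))
    return float(log_sprime - log_one_minus)


def fus_fs_from_stats(
    n: int,
    k_obs: int,
    theta_hat: float,
    n_reps: int = 1000,
    rng: np.random.Generator | None = None,
    bin_label: str = "",
) -> NeutralityResult:
    """Fu's Fs from sample size, haplotype count and theta-hat.

    The null is simulated conditional on n and theta-hat (constant-size
    coalescent); p = (1 + #{Fs* <= Fs_obs}) / (n_reps + 1).
    """
    rng = rng if rng is not None else np.random.default_rng()
    if theta_hat <= 0:
        return NeutralityResult(bin_label, "Fs", float("nan"), float("nan"), False,
                                "theta-hat is zero")
    fs_obs = fs_value(n, k_obs, theta_hat)
    sims = np.empty(n_reps)
    for r in range(n_reps):
        lengths, leafsets = coalescent.simulate_genealogy(n, rng)
        g = coalescent.drop_mutations(lengths, leafsets, rng, theta=theta_hat)
        pi_sim, _ = coalescent.pairwise_diff_stats(g)
        k_sim = coalescent.haplotype_counts(g).size
        sims[r] = fs_value(n, k_sim, pi_sim) if pi_sim > 0 else np.inf
    p = (1 + np.sum(sims <= fs_obs)) / (n_reps + 1)
    note = "Fs infinite (degenerate haplotype-count probability)" if np.isinf(fs_obs) else ""
    return NeutralityResult(bin_label, "Fs", fs_obs, float(p), True, note)


def fus_fs(
    aln: Sequence[AlignedSequence],
    n_reps: int = 1000,
    rng: np.random.Generator | None = None,
    match_policy: str = "compatible",
    deletion: str = "pairwise",
    bin_label: str = "",
) -> NeutralityResult:
    """Fu's Fs of a bin alignment with a coalescent-simulation p-value.

    theta is estimated by the observed mean pairwise differences; the number
    of alleles is the haplotype count under ``match_policy``.  Large negative
    Fs indicates an excess of haplotypes, the expansion signal; the customary
    significance threshold is p < 0.02.
    """
    n = len(aln)
    if n < 2:
        raise ValueError("need >= 2 sequences")
    _, theta_hat = nucleotide_diversity(aln, deletion=deletion)
    k_obs = len(collapse_haplotypes(aln, match_policy=match_policy))
    return fus_fs_from_stats(n, k_obs, theta_hat, n_reps, rng, bin_label)


# ---------------------------------------------------------------------------
# mismatch distribution and the sudden-expansion model

def mismatch(
    aln: Sequence[AlignedSequence],
    level: str = "sample",
    deletion: str = "pairwise",
) -> MismatchDistribution:
    """Histogram of pairwise sequence differences.

    ``level='sample'`` counts all C(n,2) sample pairs; ``level='haplotype'``
    counts pairs of distinct haplotypes, as in mismatch plots drawn between
    haplotypes.  Rescaled fractional distances are rounded to the nearest
    whole difference.
    """
    if level == "haplotype":
        seqs = [
            AlignedSequence(h.ht_id, h.pattern, aln[0].ref_positions)
            for h in collapse_haplotypes(aln)
        ]
    elif level == "sample":
        seqs = list(aln)
    else:
        raise ValueError(f"unknown level {level!r}")
    if len(seqs) < 2:
        return MismatchDistribution(np.array([0]))
    D, _ = pairwise_distance_matrix(seqs, deletion=deletion)
    iu = np.triu_indices(D.shape[0], 1)
    d = np.rint(D[iu]).astype(int)
    return MismatchDistribution(np.bincount(d))


def expected_mismatch(
    d_max: int, tau: float, theta0: float, theta1: float
) -> np.ndarray:
    """Expected pairwise-difference probabilities under stepwise expansion.

    Equilibrium distribution is geometric, F̂_i(θ) = θ^i / (1+θ)^{i+1}; a
    population that jumped from θ0 to θ1 at mutational time τ before sampling
    has
    F_i = F̂_i(θ1) + e^{-τ/θ1} Σ_{j<=i} Pois(j; τ) (F̂_{i-j}(θ0) - F̂_{i-j}(θ1)).
    """
    i = np.arange(d_max + 1)

    def equil(theta: float) -> np.ndarray:
        if theta <= 0:
            out = np.zeros(d_max + 1)
            out[0] = 1.0
            return out
        # theta^i / (1+theta)^(i+1), in log space to survive large i
        return np.exp(i * np.log(theta) - (i + 1) * np.log1p(theta))

    f1 = equil(theta1)
    diff = equil(theta0) - f1
    pois = stats.poisson.pmf(i, tau) if tau > 0 else np.eye(1, d_max + 1)[0]
    conv = np.array([np.sum(pois[: j + 1] * diff[j::-1]) for j in i])
    decay = np.exp(-tau / theta1) if theta1 > 0 else (1.0 if tau == 0 else 0.0)
    return f1 + decay * conv


def raggedness(freqs: np.ndarray) -> float:
    """Harpending's raggedness r = Σ_{i=1}^{d+1} (x_i - x_{i-1})², x_{d+1}=0."""
    x = np.append(np.asarray(freqs, dtype=float), 0.0)
    return float(np.sum(np.diff(x) ** 2))


def _fit_least_squares(obs_freqs: np.ndarray) -> tuple[float, float, float, float, bool]:
    d_max = obs_freqs.size - 1
    mean_d = float(np.sum(np.arange(d_max + 1) * obs_freqs))

    def ssd(params: np.ndarray) -> float:
        tau, th0, dth = params
        exp = expected_mismatch(d_max, tau, th0, th0 + dth)
        return float(np.sum((obs_freqs - exp) ** 2))

    starts = [
        (max(mean_d, 1e-3), 0.1, 50.0),
        (max(mean_d / 2, 1e-3), 1.0, 10.0),
        (1e-3, max(mean_d, 1e-3), 0.0),
    ]
    best = None
    ok = False
    for s in starts:
        res = optimize.minimize(
            ssd,
            np.asarray(s),
            method="L-BFGS-B",
            bounds=[(0.0, 4 * d_max + 10), (0.0, 1e4), (0.0, 1e5)],
        )
        if best is None or res.fun < best.fun:
            best = res
            ok = bool(res.success)
    tau, th0, dth = best.x
    return float(tau), float(th0), float(th0 + dth), float(best.fun), ok


def fit_sudden_expansion(
    mm: MismatchDistribution,
    n: int,
    n_boot: int = 100,
    rng: np.random.Generator | None = None,
) -> ExpansionFit:
    """Least-squares fit of the stepwise-expansion model to a mismatch
    distribution, with parametric-bootstrap p-values.

    SSD is the sum of squared deviations between observed and expected
    mismatch frequencies (small SSD = smooth, expansion-like).  The bootstrap
    simulates ``n_boot`` coalescent datasets under the fitted (τ, θ0, θ1),
    refits each, and reports the fraction with SSD* >= SSD (and raggedness*
    >= raggedness); high SSD/raggedness with small p rejects sudden expansion.
    """
    rng = rng if rng is not None else np.random.default_rng()
    obs = mm.freqs
    tau, th0, th1, ssd_obs, ok = _fit_least_squares(obs)
    rag_obs = raggedness(obs)

    ssd_star = np.empty(n_boot)
    rag_star = np.empty(n_boot)
    t_change = tau / th1 if th1 > 0 else np.inf
    ratio = th0 / th1 if th1 > 0 else 1.0
    for b in range(n_boot):
        lengths, leafsets = coalescent.simulate_genealogy(
            n, rng, t_change=t_change, size_ratio=ratio
        )
        g = coalescent.drop_mutations(lengths, leafsets, rng, theta=th1)
        counts = coalescent.mismatch_counts(g)
        freqs = counts / counts.sum()
        _, _, _, ssd_star[b], _ = _fit_least_squares(freqs)
        rag_star[b] = raggedness(freqs)
    p_ssd = float((1 + np.sum(ssd_star >= ssd_obs)) / (n_boot + 1))
    p_rag = float((1 + np.sum(rag_star >= rag_obs)) / (n_boot + 1))
    return ExpansionFit(tau, th0, th1, ssd_obs, p_ssd, rag_obs, p_rag, converged=ok)
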