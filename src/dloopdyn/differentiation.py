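"""Pairwise population differentiation (Phi_ST) and haplogroup-frequency PCA.

Phi_ST is the distance-based analogue of F_ST: a two-level molecular analysis
of variance on the matrix of pairwise sequence differences, with significance
by permutation of individuals between the two groups.  Negative estimates are
reported as computed (not clamped).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import AlignedSequence
from .diversity import pairwise_distance_matrix


@dataclass
class FstResult:
    fst: float
    p: float
    defined: bool = True


@dataclass
class FstMatrix:
    labels: list[str]
    fst: np.ndarray
    p: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Lower triangle Phi_ST, upper triangle permutation p."""
        out = np.full_like(self.fst, np.nan)
        n = len(self.labels)
        for i in range(n):
            for j in range(n):
                if i > j:
                    out[i, j] = self.fst[i, j]
                elif i < j:
                    out[i, j] = self.p[i, j]
                else:
                    out[i, j] = 0.0
        return pd.DataFrame(out, index=self.labels, columns=self.labels)


def _phi_st(D: np.ndarray, in_a: np.ndarray) -> float:
    """Phi_ST from squared pairwise distances and a group-A indicator.

    Variance components follow the haploid two-population decomposition:
    SSD(total) = sum_{i<j} d2_ij / N, SSD(within) computed per group with its
    own size, sigma2_within = SSD(within)/(N-2), and the among-group component
    uses the unequal-size coefficient n_c = (N - (nA^2 + nB^2)/N).
    """
    N = D.shape[0]
    a = np.flatnonzero(in_a)
    b = np.flatnonzero(~in_a)
    nA, nB = a.size, b.size
    ss_total = D.sum() / 2.0 / N
    ss_within = D[np.ix_(a, a)].sum() / 2.0 / nA + D[np.ix_(b, b)].sum() / 2.0 / nB
    ss_among = ss_total - ss_within
    sigma_w = ss_within / (N - 2)
    n_c = N - (nA**2 + nB**2) / N  # already divided by P-1 = 1
    sigma_a = (ss_among - sigma_w) / n_c
    denom = sigma_a + sigma_w
    if denom == 0.0:
        return float("nan")
    return float(sigma_a / denom)


def pairwise_fst(
    aln_a: Sequence[AlignedSequence],
    aln_b: Sequence[AlignedSequence],
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
    deletion: str = "pairwise",
) -> FstResult:
    """Phi_ST between two bins with a permutation p-value.

    Distances are pairwise differences with pairwise deletion of missing
    data, used directly as the squared distances of the variance
    decomposition.  p = (1 + #{Phi* >= Phi_obs}) / (n_perm + 1).
    """
    rng = rng if rng is not None else np.random.default_rng()
    nA, nB = len(aln_a), len(aln_b)
    if nA < 2 or nB < 2:
        raise ValueError("both bins need n >= 2")
    D, _ = pairwise_distance_matrix(list(aln_a) + list(aln_b), deletion=deletion)
    if not D.any():
        return FstResult(float("nan"), float("nan"), defined=False)
    in_a = np.zeros(nA + nB, dtype=bool)
    in_a[:nA] = True
    obs = _phi_st(D, in_a)
    if np.isnan(obs):
        return FstResult(float("nan"), float("nan"), defined=False)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(nA + nB)
        in_a_perm = np.zeros(nA + nB, dtype=bool)
        in_a_perm[perm[:nA]] = True
        star = _phi_st(D, in_a_perm)
        if not np.isnan(star) and star >= obs:
            hits += 1
    return FstResult(obs, (1 + hits) / (n_perm + 1))


def fst_matrix(
    bins: dict[str, list[AlignedSequence]],
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
    deletion: str = "pairwise",
) -> FstMatrix:
    """All pairwise Phi_ST values between the given bins."""
    rng = rng if rng is not None else np.random.default_rng()
    labels = [k for k, v in bins.items() if len(v) >= 2]
    m = len(labels)
    fst = np.zeros((m, m))
    p = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            res = pairwise_fst(bins[labels[i]], bins[labels[j]], n_perm, rng, deletion)
            fst[i, j] = fst[j, i] = res.fst
            p[i, j] = p[j, i] = res.p
    return FstMatrix(labels, fst, p)


# ---------------------------------------------------------------------------
# PCA on relative haplogroup frequencies

@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray


def haplogroup_pca(freq_table: pd.DataFrame) -> PcaResult:
    """Covariance-based PCA of a (population x haplogroup) frequency table.

    Rows are centred (not scaled); components come from the SVD of the
    centred matrix.  ``variance_explained`` sums to 1 over the retained
    components; a constant table (zero variance) is an error.
    """
    X = freq_table.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need >= 3 populations for PCA")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        raise ValueError("constant frequency table: zero variance")
    k = min(X.shape[0] - 1, X.shape[1])
    pcs = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame((U * s)[:, :k], index=freq_table.index, columns=pcs)
    loadings = pd.DataFrame(Vt[:k].T, index=freq_table.columns, columns=pcs)
    return PcaResult(scores, loadings, var[:k] / total)
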