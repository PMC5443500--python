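"""Figure helpers: bias-test density panels, mismatch histograms, PCA scatter."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .bias import BiasTestResult
from .demography import MismatchDistribution, expected_mismatch
from .differentiation import PcaResult


def plot_bias_densities(
    res_pi: BiasTestResult, res_h: BiasTestResult, path: str | Path
) -> None:
    """Two-panel pseudo-diversity densities with the observed values marked."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, res, label in ((axes[0], res_pi, "nucleotide diversity"),
                           (axes[1], res_h, "haplotype diversity")):
        if res.skipped:
            ax.set_title(f"{label}: skipped ({res.reason})")
            continue
        ax.hist(res.pseudo_distA, bins=30, density=True, alpha=0.5,
                label=f"pseudo {res.binA} (n={res.n_perm})")
        ax.hist(res.pseudo_distB, bins=30, density=True, alpha=0.5,
                label=f"pseudo {res.binB}")
        ax.axvline(res.observedA, color="C0", ls="--",
                   label=f"observed {res.binA} (p={res.pA:.3f})")
        ax.axvline(res.observedB, color="C1", ls="--",
                   label=f"observed {res.binB} (p={res.pB:.3f})")
        ax.set_title(label)
        ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_mismatch(
    mm: MismatchDistribution,
    path: str | Path,
    tau: float | None = None,
    theta0: float | None = None,
    theta1: float | None = None,
    title: str = "",
) -> None:
    """Observed mismatch histogram, optionally with the fitted expectation."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    x = np.arange(mm.counts.size)
    ax.bar(x, mm.counts, color="0.6", label="observed")
    if tau is not None:
        exp = expected_mismatch(mm.counts.size - 1, tau, theta0, theta1)
        ax.plot(x, exp * mm.n_pairs, "k--", label="sudden-expansion fit")
    ax.set_xlabel("pairwise differences")
    ax.set_ylabel("number of pairs")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_pca(pca: PcaResult, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(pca.scores["PC1"], pca.scores["PC2"])
    for label, row in pca.scores.iterrows():
        ax.annotate(str(label), (row["PC1"], row["PC2"]), fontsize=7)
    ve = pca.variance_explained
    ax.set_xlabel(f"PC1 ({ve[0]:.0%})")
    ax.set_ylabel(f"PC2 ({ve[1]:.0%})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
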