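"""End-to-end orchestration: datasets, per-bin statistics, comparisons,
networks and PCA, with reproducible seeding and a report bundle on disk.

All randomness flows from one master seed through named per-stage substreams,
so reruns with the same configuration are bit-identical.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .alignment import (
    COMBINED_BIN,
    AlignedSequence,
    SampleMetadata,
    filter_dataset,
    read_alignment,
    read_metadata,
)
from .bias import bias_test
from .demography import fit_sudden_expansion, fus_fs, mismatch, tajimas_d
from .differentiation import fst_matrix, haplogroup_pca
from .diversity import haplotype_diversity, nucleotide_diversity
from .haplotypes import (
    collapse_haplotypes,
    assign_haplogroup,
    haplogroup_frequencies,
    read_haplogroup_defs,
    shipped_haplogroup_defs,
    write_haplotype_table,
)
from .network import median_joining, temporal_networks, write_dot, write_edge_list, write_graphml

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int
    outdir: str | Path
    alignment_path: str | Path | None = None
    metadata_path: str | Path | None = None
    haplogroup_defs_path: str | Path | None = None
    dataset_rule: str = "dataset2"
    deletion: str = "pairwise"
    n_perm: int = 10000
    n_reps: int = 1000  # neutrality-test null replicates
    n_boot: int = 100  # sudden-expansion bootstrap refits
    alpha: float = 0.05
    min_bin_size: int = 4
    match_policy: str = "compatible"
    make_plots: bool = False
    bin_order: Sequence[str] = (
        "Palaeontological",
        "Badegoulian",
        "Magdalenian",
        COMBINED_BIN,
        "Azilian",
        "Neolithic",
    )

    def rng(self, stage: str) -> np.random.Generator:
        sub = zlib.crc32(stage.encode())
        return np.random.default_rng(np.random.SeedSequence([self.seed, sub]))


def _ordered_bins(bins: dict[str, list[str]], order: Sequence[str]) -> list[str]:
    out = [b for b in order if b in bins]
    out += [b for b in bins if b not in out]
    return out


def run_full_analysis(
    config: RunConfig,
    aln: Sequence[AlignedSequence] | None = None,
    meta: Sequence[SampleMetadata] | None = None,
) -> dict:
    """Run every stage and write the report bundle to ``config.outdir``.

    Inputs may be passed in memory or read from the configured paths.  A
    stage failure aborts with the stage name; artifacts written so far are
    preserved.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "load"
    try:
        if aln is None:
            aln = read_alignment(config.alignment_path)
        if meta is None:
            meta = read_metadata(config.metadata_path)
        if config.haplogroup_defs_path:
            defs, hotspots = read_haplogroup_defs(config.haplogroup_defs_path)
        else:
            defs, hotspots = shipped_haplogroup_defs()
        by_id = {s.sample_id: s for s in aln}

        stage = "datasets"
        dataset = filter_dataset(aln, meta, config.dataset_rule)
        summary_rows = []
        for rule in ("dataset1", "dataset2", "dataset3"):
            ds = filter_dataset(aln, meta, rule)
            row = {"dataset": rule, "total": len(ds.members)}
            row.update({b: len(m) for b, m in ds.bins.items()})
            summary_rows.append(row)
        pd.DataFrame(summary_rows).to_csv(outdir / "dataset_summary.tsv", sep="\t", index=False)
        results["dataset"] = dataset
        bin_labels = _ordered_bins(dataset.bins, config.bin_order)
        bin_aln = {
            b: [by_id[sid] for sid in dataset.bins[b]]
            for b in bin_labels
            if len(dataset.bins[b]) >= 2
        }

        stage = "haplotypes"
        ds_aln = [by_id[sid] for sid in dataset.members]
        haplotypes = collapse_haplotypes(ds_aln, match_policy=config.match_policy)
        write_haplotype_table(haplotypes, outdir / "haplotypes.tsv")
        results["haplotypes"] = haplotypes
        reference = None
        assignments = {}
        if defs:
            span = {int(p) for s in ds_aln[:1] for p in s.ref_positions}
            usable = [d for d in defs if all(p in span for p, _ in d.mandatory + d.optional)]
            for s in ds_aln:
                assignments[s.sample_id], _ = assign_haplogroup(s, usable, reference, hotspots)
        results["assignments"] = assignments

        stage = "diversity"
        div_rows = []
        for b, seqs in bin_aln.items():
            pi, pi_total = nucleotide_diversity(seqs, deletion=config.deletion)
            hts = collapse_haplotypes(seqs, match_policy=config.match_policy)
            h = haplotype_diversity([t.count for t in hts])
            div_rows.append(
                {
                    "bin": b,
                    "n": len(seqs),
                    "n_haplotypes": len(hts),
                    "pi": pi,
                    "pi_total": pi_total,
                    "h": h,
                    "deletion": config.deletion,
                }
            )
        diversity = pd.DataFrame(div_rows)
        diversity.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
        results["diversity"] = diversity

        stage = "neutrality"
        neut_rows = []
        for b, seqs in bin_aln.items():
            if len(seqs) < config.min_bin_size:
                continue
            rng = config.rng(f"neutrality:{b}")
            d = tajimas_d(seqs, n_reps=config.n_reps, rng=rng, bin_label=b)
            fs = fus_fs(seqs, n_reps=config.n_reps, rng=rng, bin_label=b)
            mm = mismatch(seqs, deletion=config.deletion)
            fit = fit_sudden_expansion(mm, len(seqs), n_boot=config.n_boot, rng=rng)
            if config.make_plots:
                from .plots import plot_mismatch

                plot_mismatch(
                    mm,
                    outdir / f"mismatch_{b.replace('.', '').replace('+', '_')}.png",
                    tau=fit.tau, theta0=fit.theta0, theta1=fit.theta1, title=b,
                )
            neut_rows.append(
                {
                    "bin": b,
                    "n": len(seqs),
                    "tajimas_D": d.value,
                    "p_D": d.p,
                    "fus_Fs": fs.value,
                    "p_Fs": fs.p,
                    "tau": fit.tau,
                    "theta0": fit.theta0,
                    "theta1": fit.theta1,
                    "SSD": fit.ssd,
                    "p_SSD": fit.p_ssd,
                    "raggedness": fit.raggedness,
                    "p_rag": fit.p_rag,
                }
            )
        neutrality = pd.DataFrame(neut_rows)
        neutrality.to_csv(outdir / "neutrality.tsv", sep="\t", index=False)
        results["neutrality"] = neutrality

        stage = "bias_tests"
        bias_rows = []
        comparable: dict[tuple[str, str], bool] = {}
        labels = [b for b in bin_aln if b != COMBINED_BIN]
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                flags = []
                pair_results = {}
                for statname in ("pi", "h"):
                    res = bias_test(
                        bin_aln[a],
                        bin_aln[b],
                        stat=statname,
                        n_perm=config.n_perm,
                        alpha=config.alpha,
                        rng=config.rng(f"bias:{a}|{b}|{statname}"),
                        binA=a,
                        binB=b,
                    )
                    bias_rows.append(
                        {
                            "binA": a,
                            "binB": b,
                            "stat": statname,
                            "observedA": res.observedA,
                            "observedB": res.observedB,
                            "pA": res.pA,
                            "pB": res.pB,
                            "biased": res.biased,
                            "skipped": res.skipped,
                        }
                    )
                    flags.append(res.biased)
                    pair_results[statname] = res
                comparable[(a, b)] = not any(flags)
                if config.make_plots:
                    from .plots import plot_bias_densities

                    safe = f"{a}_{b}".replace(".", "").replace("+", "_")
                    plot_bias_densities(
                        pair_results["pi"], pair_results["h"],
                        outdir / f"bias_{safe}.png",
                    )
        bias_df = pd.DataFrame(bias_rows)
        bias_df.to_csv(outdir / "bias_tests.tsv", sep="\t", index=False)
        results["bias"] = bias_df

        stage = "fst"
        fm = fst_matrix(
            {b: bin_aln[b] for b in labels},
            n_perm=config.n_perm,
            rng=config.rng("fst"),
            deletion=config.deletion,
        )
        frame = fm.to_frame()
        frame.to_csv(outdir / "fst.tsv", sep="\t")
        gating = pd.DataFrame(
            [
                {"binA": a, "binB": b, "comparable": ok}
                for (a, b), ok in comparable.items()
            ]
        )
        gating.to_csv(outdir / "fst_comparability.tsv", sep="\t", index=False)
        results["fst"] = fm
        results["comparable"] = comparable

        stage = "network"
        net = median_joining(haplotypes)
        write_graphml(net, outdir / "network.graphml")
        write_dot(net, outdir / "network.dot")
        write_edge_list(net, outdir / "network_edges.tsv")
        temporal = temporal_networks(
            net,
            {b: dataset.bins[b] for b in labels},
            haplotypes,
            bin_order=labels,
        )
        results["network"] = net
        results["temporal"] = temporal

        stage = "pca"
        freqs = haplogroup_frequencies(assignments, {b: dataset.bins[b] for b in labels})
        freqs.to_csv(outdir / "haplogroup_frequencies.tsv", sep="\t")
        nonzero = freqs.loc[freqs.sum(axis=1) > 0]
        if nonzero.shape[0] >= 3 and nonzero.to_numpy().std() > 0:
            pca = haplogroup_pca(nonzero)
            pca.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
            pca.loadings.to_csv(outdir / "pca_loadings.tsv", sep="\t")
            pd.DataFrame(
                {"component": pca.scores.columns, "variance_explained": pca.variance_explained}
            ).to_csv(outdir / "pca_variance.tsv", sep="\t", index=False)
            results["pca"] = pca
            if config.make_plots:
                from .plots import plot_pca

                plot_pca(pca, outdir / "pca.png")

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "dataset_rule": config.dataset_rule,
            "deletion": config.deletion,
            "n_perm": config.n_perm,
            "n_reps": config.n_reps,
            "n_boot": config.n_boot,
            "alpha": config.alpha,
            "n_samples": len(list(aln)),
            "bins": {b: len(m) for b, m in dataset.bins.items()},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        results["manifest"] = manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    logger.info("report bundle written to %s", outdir)
    return results
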