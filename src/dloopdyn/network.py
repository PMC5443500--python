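"""Weighted median-joining haplotype networks and temporal sub-networks.

The network is built on weighted Hamming distances between haplotype
patterns.  Sites are down-weighted in proportion to how mutable they appear
(recurrently polymorphic positions carry less phylogenetic signal), and
transversion-bearing columns weigh 10x transition columns.  Median (Steiner)
vectors are the majority consensus of connected triplets and are kept only
when they shorten the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .alignment import MISSING
from .haplotypes import Haplotype

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}

#: Default base weight before polymorphism down-weighting.
BASE_WEIGHT = 50
#: Transition : transversion weight ratio.
TS_TV_WEIGHT = 10


@dataclass
class SiteWeights:
    weights: np.ndarray  # per-column positive integers

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.int64)
        if np.any(self.weights < 1):
            raise ValueError("site weights must be >= 1")


def _is_transversion_column(states: set[str]) -> bool:
    return bool(states & PURINES) and bool(states & PYRIMIDINES)


def compute_weights(
    patterns: np.ndarray,
    base_weight: int = BASE_WEIGHT,
    ts_tv_weight: int = TS_TV_WEIGHT,
    change_counts: Sequence[int] | None = None,
) -> SiteWeights:
    """Per-column weights: ``max(1, round(base / k_c))``, x10 for transversions.

    ``k_c`` is the number of state changes at column c; by default it is
    estimated as (distinct observed bases - 1), but callers with an external
    estimate of recurrent mutation (e.g. counts on a tree) can pass
    ``change_counts`` directly.  Monomorphic columns keep the base weight.
    """
    n_cols = patterns.shape[1]
    w = np.empty(n_cols, dtype=np.int64)
    for c in range(n_cols):
        obs = set(patterns[:, c]) - {MISSING}
        if change_counts is not None:
            k = max(1, int(change_counts[c]))
        else:
            k = max(1, len(obs) - 1)
        wc = max(1, round(base_weight / k))
        if _is_transversion_column(obs):
            wc *= ts_tv_weight
        w[c] = wc
    return SiteWeights(w)


@dataclass
class HaploNetwork:
    graph: nx.Graph
    #: node id -> pattern; observed haplotype nodes carry frequency/bins,
    #: median vectors are flagged inferred.
    patterns: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total_weight(self) -> float:
        return float(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def median_nodes(self) -> list[str]:
        return [v for v, d in self.graph.nodes(data=True) if d.get("inferred")]


def _usable_columns(patterns: np.ndarray) -> np.ndarray:
    """Columns with no missing data across the haplotype set (network
    convention: any '?' removes the column from the distance)."""
    return ~(patterns == MISSING).any(axis=0)


def _wdist(a: np.ndarray, b: np.ndarray, w: np.ndarray, cols: np.ndarray) -> int:
    diff = (a != b) & cols
    return int(w[diff].sum())


def _diff_columns(a: np.ndarray, b: np.ndarray, cols: np.ndarray) -> list[int]:
    return [int(c) for c in np.flatnonzero((a != b) & cols)]


def _msn_edges(
    patterns: dict[str, np.ndarray], w: np.ndarray, cols: np.ndarray, epsilon: int = 0
) -> list[tuple[str, str, int]]:
    """Edges of the epsilon-relaxed minimum spanning network.

    A link of weight d is feasible iff its endpoints are not connected by
    links of weight < d - epsilon; at epsilon=0 this is the union of all
    minimum spanning trees.
    """
    ids = list(patterns)
    links: list[tuple[int, str, str]] = []
    for i, u in enumerate(ids):
        for v in ids[i + 1 :]:
            links.append((_wdist(patterns[u], patterns[v], w, cols), u, v))
    links.sort(key=lambda t: t[0])
    edges = []
    uf = {u: u for u in ids}

    def find(x: str) -> str:
        while uf[x] != x:
            uf[x] = uf[uf[x]]
            x = uf[x]
        return x

    distinct = sorted({d for d, _, _ in links})
    for d in distinct:
        tier = [t for t in links if d - epsilon <= t[0] <= d]
        added = []
        for dd, u, v in tier:
            if dd == d and find(u) != find(v):
                # connected only by links of weight >= d - epsilon: feasible
                edges.append((u, v, d))
                added.append((u, v))
        for u, v in added:
            uf[find(u)] = find(v)
    return edges


def _total_msn_weight(
    patterns: dict[str, np.ndarray], w: np.ndarray, cols: np.ndarray, epsilon: int
) -> int:
    return sum(d for _, _, d in _msn_edges(patterns, w, cols, epsilon))


def _majority_median(
    a: np.ndarray, b: np.ndarray, c: np.ndarray
) -> np.ndarray:
    """Per-column majority consensus of three patterns (first pattern breaks
    three-way ties, which cannot shorten the network anyway)."""
    out = a.copy()
    match_bc = b == c
    out[match_bc & (a != b)] = b[match_bc & (a != b)]
    return out


def median_joining(
    haplotypes: Sequence[Haplotype],
    site_weights: SiteWeights | None = None,
    epsilon: int = 0,
    max_rounds: int = 50,
    median_distance_cap: int | None = None,
) -> HaploNetwork:
    """Median-joining network of observed haplotypes.

    Iterates: build the epsilon-relaxed minimum spanning network; for every
    connected triplet propose the majority-consensus median vector and add it
    if it strictly reduces total network length; repeat to fixpoint; finally
    prune median vectors that are no longer needed.  The epsilon=0 network
    contains a minimum spanning network over its node set by construction.
    """
    if len(haplotypes) < 2:
        raise ValueError("need >= 2 haplotypes")
    patterns: dict[str, np.ndarray] = {h.ht_id: np.asarray(h.pattern) for h in haplotypes}
    observed = set(patterns)
    mat = np.stack(list(patterns.values()))
    cols = _usable_columns(mat)
    w = (site_weights or compute_weights(mat)).weights
    if w.size != mat.shape[1]:
        raise ValueError("site weights do not match pattern length")

    n_median = 0
    for round_no in range(max_rounds):
        edges = _msn_edges(patterns, w, cols, epsilon)
        current = sum(d for _, _, d in edges)
        g = nx.Graph((u, v) for u, v, _ in edges)
        candidates: list[np.ndarray] = []
        for u, v, _ in edges:
            for x in set(g.neighbors(u)) | set(g.neighbors(v)):
                if x in (u, v):
                    continue
                trip = (patterns[u], patterns[v], patterns[x])
                if median_distance_cap is not None:
                    span = max(
                        _wdist(a, b, w, cols)
                        for a in trip
                        for b in trip
                        if a is not b
                    )
                    if span > median_distance_cap:
                        continue
                m = _majority_median(*trip)
                if any(np.array_equal(m, p) for p in patterns.values()):
                    continue
                candidates.append(m)
        improved = False
        for m in candidates:
            if any(np.array_equal(m, p) for p in patterns.values()):
                continue
            trial = dict(patterns)
            trial[f"mv{n_median + 1:02d}"] = m
            if _total_msn_weight(trial, w, cols, epsilon) < current:
                n_median += 1
                patterns[f"mv{n_median:02d}"] = m
                current = _total_msn_weight(patterns, w, cols, epsilon)
                improved = True
        if not improved:
            break
    else:
        raise RuntimeError(
            f"median-joining did not converge in {max_rounds} rounds; "
            f"{len(patterns)} nodes so far"
        )

    # prune obsolete median vectors: drop inferred nodes of degree <= 2 whose
    # removal does not lengthen the network
    while True:
        edges = _msn_edges(patterns, w, cols, epsilon)
        total = sum(d for _, _, d in edges)
        deg: dict[str, int] = {u: 0 for u in patterns}
        for u, v, _ in edges:
            deg[u] += 1
            deg[v] += 1
        removable = [
            u for u in patterns if u not in observed and deg[u] <= 2
        ]
        removed = False
        for u in removable:
            trial = {k: v for k, v in patterns.items() if k != u}
            if _total_msn_weight(trial, w, cols, epsilon) <= total:
                patterns = trial
                removed = True
                break
        if not removed:
            break

    freq = {h.ht_id: h.count for h in haplotypes}
    members = {h.ht_id: h.members for h in haplotypes}
    g = nx.Graph()
    for node, pat in patterns.items():
        g.add_node(
            node,
            inferred=node not in observed,
            frequency=freq.get(node, 0),
            members=";".join(members.get(node, [])),
        )
    for u, v, d in _msn_edges(patterns, w, cols, epsilon):
        g.add_edge(
            u, v,
            weight=d,
            mutated_columns=_diff_columns(patterns[u], patterns[v], cols),
            n_mutations=len(_diff_columns(patterns[u], patterns[v], cols)),
        )
    return HaploNetwork(g, patterns)


def temporal_networks(
    net: HaploNetwork,
    bin_members: dict[str, list[str]],
    haplotypes: Sequence[Haplotype],
    bin_order: Sequence[str] | None = None,
) -> dict[str, nx.Graph]:
    """Per-bin views of the full network.

    Each bin keeps the full topology; haplotypes not observed in that bin
    become empty placeholder nodes (frequency 0, ``present=False``).  Nodes
    shared between consecutive bins are flagged ``continuous_with_next``.
    """
    ht_of_sample = {sid: h.ht_id for h in haplotypes for sid in h.members}
    order = list(bin_order) if bin_order is not None else list(bin_members)
    for b in order:
        if b not in bin_members:
            raise ValueError(f"unknown bin label {b!r}")
    present: dict[str, set[str]] = {}
    for b in order:
        present[b] = {ht_of_sample[sid] for sid in bin_members[b] if sid in ht_of_sample}
    out: dict[str, nx.Graph] = {}
    for i, b in enumerate(order):
        sub = net.graph.copy()
        counts: dict[str, int] = {}
        for sid in bin_members[b]:
            ht = ht_of_sample.get(sid)
            if ht is not None:
                counts[ht] = counts.get(ht, 0) + 1
        nxt = present[order[i + 1]] if i + 1 < len(order) else set()
        for node in sub.nodes:
            sub.nodes[node]["present"] = node in present[b]
            sub.nodes[node]["frequency"] = counts.get(node, 0)
            sub.nodes[node]["continuous_with_next"] = node in present[b] and node in nxt
        out[b] = sub
    return out


# ---------------------------------------------------------------------------
# writers

def write_graphml(net: HaploNetwork, path: str | Path) -> None:
    g = net.graph.copy()
    for _, _, d in g.edges(data=True):
        d["mutated_columns"] = ",".join(map(str, d["mutated_columns"]))
    nx.write_graphml(g, str(path))


def write_dot(net: HaploNetwork, path: str | Path) -> None:
    lines = ["graph haplonetwork {"]
    for v, d in net.graph.nodes(data=True):
        shape = "point" if d.get("inferred") else "circle"
        lines.append(
            f'  "{v}" [shape={shape}, label="{v} ({d.get("frequency", 0)})"];'
        )
    for u, v, d in net.graph.edges(data=True):
        lines.append(f'  "{u}" -- "{v}" [label="{d["n_mutations"]}"];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_edge_list(net: HaploNetwork, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "node_a": u,
                "node_b": v,
                "weight": d["weight"],
                "n_mutations": d["n_mutations"],
                "mutated_columns": ",".join(map(str, d["mutated_columns"])),
            }
            for u, v, d in net.graph.edges(data=True)
        ]
    ).to_csv(path, sep="\t", index=False)
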