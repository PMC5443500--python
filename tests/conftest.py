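from __future__ import annotations

import numpy as np
import pytest

from dloopdyn.alignment import AlignedSequence, default_ref_positions


def make_seqs(strings, ids=None):
    """AlignedSequence list from equal-length strings over {A,C,G,T,?}."""
    L = len(strings[0])
    ref = default_ref_positions(L)
    ids = ids or [f"s{i + 1}" for i in range(len(strings))]
    return [AlignedSequence(i, list(s), ref) for i, s in zip(ids, strings)]


def random_alignment(rng, n, L, missing_prob=0.0):
    """Random alignment drawn column-wise from 2-3 states, with optional
    scattered missingness (every pair keeps overlap)."""
    bases = np.array(list("ACGT"))
    mat = np.empty((n, L), dtype="<U1")
    for c in range(L):
        states = rng.choice(bases, size=rng.integers(1, 4), replace=False)
        mat[:, c] = rng.choice(states, size=n)
    if missing_prob:
        mask = rng.random((n, L)) < missing_prob
        # never blank a full row
        full = mask.all(axis=1)
        mask[full, 0] = False
        mat[mask] = "?"
    ref = default_ref_positions(L)
    return [AlignedSequence(f"s{i + 1}", mat[i], ref) for i in range(n)]


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
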