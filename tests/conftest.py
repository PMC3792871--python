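"""Shared fixtures and independent oracles.

The oracles here (exhaustive Fitch labeling, a plain triple-loop affine
Smith-Waterman) deliberately share no code with the package so they can
arbitrate its answers.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from markermine.seqcore import IUPAC_SETS, MultipleAlignment, Sequence

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# exhaustive Fitch oracle


def fitch_oracle(tree, alignment) -> int:
    """Minimum state changes by brute force over all internal labelings.

    Tips with ambiguity codes may take any member state (cost handled by
    treating the tip as a free choice within its set); '-'/'?' may take
    any state.
    """
    tips = tree.tips()
    internals = [n for n in tree.postorder() if not n.is_tip]
    edges = []
    for n in tree.postorder():
        if n.parent is not None:
            edges.append((n.parent, n))
    total = 0
    for j in range(alignment.ncols):
        tip_sets = {}
        for t in tips:
            c = alignment.row(t.label).residues[j]
            tip_sets[id(t)] = (
                set(BASES) if c in "-?" else set(IUPAC_SETS[c])
            )
        best = None
        for labeling in itertools.product(BASES, repeat=len(internals)):
            state = {id(n): labeling[k] for k, n in enumerate(internals)}
            cost = 0
            for (p, c) in edges:
                sp = state[id(p)]
                if c.is_tip:
                    if sp not in tip_sets[id(c)]:
                        cost += 1
                else:
                    if sp != state[id(c)]:
                        cost += 1
            if best is None or cost < best:
                best = cost
        total += best
    return total


# ---------------------------------------------------------------------------
# Smith-Waterman oracle (affine; gap of length L costs open + L*extend)


def sw_oracle(q: str, s: str, match=1.0, mismatch=-2.0, gap_open=5.0,
              gap_extend=2.0) -> float:
    m, n = len(q), len(s)
    NEG = float("-inf")
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    first = gap_open + gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            sub = match if q[i - 1] == s[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


# ---------------------------------------------------------------------------
# random instance helpers


def random_tree(labels, rng):
    """Random binary tree topology over the given tip labels."""
    from markermine.trees import Node, PhyloTree

    nodes = [Node(lab) for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node()
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = Node()
    for n in nodes:
        root.add(n)
    return PhyloTree(root)


def random_alignment(labels, ncols, rng, alphabet="ACGT", p_other=0.0,
                     others="RYSWKMN-?"):
    rows = []
    for lab in labels:
        chars = []
        for _ in range(ncols):
            if p_other and rng.random() < p_other:
                chars.append(others[rng.integers(len(others))])
            else:
                chars.append(alphabet[rng.integers(len(alphabet))])
        rows.append(Sequence(lab, "".join(chars)))
    return MultipleAlignment(rows=rows)


def mutate(seq: str, n_sub: int, rng) -> str:
    out = list(seq)
    pos = rng.choice(len(seq), size=min(n_sub, len(seq)), replace=False)
    for p in pos:
        out[p] = BASES[(_BASE_IDX[out[p]] + 1 + rng.integers(3)) % 4]
    return "".join(out)


def random_dna(n: int, rng) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_sim():
    """A small end-to-end synthetic dataset shared by pipeline tests."""
    from markermine.simdata import SimConfig, make_pools

    cfg = SimConfig(n_taxa=6, n_families=2, dropout=0.0, seed=13)
    pools, truth = make_pools(cfg)
    return cfg, pools, truth
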