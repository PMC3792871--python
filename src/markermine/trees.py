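"""Phylogeny engine.

Newick I/O (parsing via dendropy), neighbor joining (via scikit-bio),
Fitch parsimony with a stepwise-addition + NNI heuristic search,
Felsenstein-pruning likelihood under JC/K80/HKY/GTR with optional +I and
discrete-gamma (+G, 4 equal-probability categories, category means) rate
variation, round-robin branch-length optimization, nonparametric
bootstrap, and sequence simulation.

Trees are unrooted in semantics; the in-memory representation is an
arbitrarily rooted node structure.  Under the reversible models used here
the likelihood does not depend on the rooting.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from .seqcore import BITS, MultipleAlignment, Sequence

__all__ = [
    "PhyloTree",
    "Node",
    "SubstModel",
    "BootstrapResult",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "nj_tree",
    "fitch_score",
    "mp_search",
    "prune_loglik",
    "loglik_patterns",
    "optimize_branch_lengths",
    "bootstrap",
    "simulate_evolution",
    "discrete_gamma_rates",
    "smallest_spanning_clade",
    "minimal_spanning_sides",
]


class NewickParseError(ValueError):
    pass


class Node:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children


class PhyloTree:
    """A phylogenetic tree with tip labels and optional branch lengths."""

    def __init__(self, root: Node):
        self.root = root

    def postorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        out.reverse()
        return out

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def copy(self) -> "PhyloTree":
        def rec(n: Node) -> Node:
            m = Node(n.label, n.length)
            for c in n.children:
                m.add(rec(c))
            return m

        return PhyloTree(rec(self.root))

    def newick(self) -> str:
        return write_newick(self)

    def bipartitions(self) -> dict[frozenset, Node]:
        """Nontrivial bipartitions, each keyed by its canonical side (the
        side not containing the lexicographically smallest tip)."""
        all_tips = frozenset(self.tip_labels())
        ref = min(all_tips)
        out: dict[frozenset, Node] = {}
        clades = _clades(self)
        for node, clade in clades.items():
            if node is self.root:
                continue
            side = frozenset(clade)
            if ref in side:
                side = all_tips - side
            if 2 <= len(side) <= len(all_tips) - 2:
                out[side] = node
        return out


def _clades(tree: PhyloTree) -> dict[Node, set[str]]:
    clades: dict[Node, set[str]] = {}
    for n in tree.postorder():
        if n.is_tip:
            clades[n] = {n.label}
        else:
            s: set[str] = set()
            for c in n.children:
                s |= clades[c]
            clades[n] = s
    return clades


def minimal_spanning_sides(tree: PhyloTree, labels: set) -> list:
    """All minimum-size edge sides of the unrooted tree containing every
    label.  Several sides can tie (symmetric trees); callers that need a
    conservative answer should inspect all of them."""
    all_tips = set(tree.tip_labels())
    missing = set(labels) - all_tips
    if missing:
        raise KeyError(f"labels not in tree: {sorted(missing)}")
    sides: set[frozenset] = set()
    best = len(all_tips)
    for node, clade in _clades(tree).items():
        if node is tree.root:
            continue
        for side in (frozenset(clade), frozenset(all_tips - clade)):
            if labels <= side and len(side) <= best:
                if len(side) < best:
                    best = len(side)
                    sides = set()
                sides.add(side)
    if not sides:
        sides = {frozenset(all_tips)}
    return sorted((set(s) for s in sides), key=lambda s: sorted(s))


def smallest_spanning_clade(tree: PhyloTree, labels: set[str]) -> set[str]:
    """One smallest side containing every label (ties broken
    deterministically by sorted tip labels); rooting-independent."""
    return minimal_spanning_sides(tree, labels)[0]


# ---------------------------------------------------------------------------
# newick I/O


def parse_newick(text: str) -> PhyloTree:
    """Parse a newick string (delegates to dendropy for the grammar)."""
    import dendropy

    try:
        dt = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as e:  # dendropy raises schema-specific errors
        raise NewickParseError(f"newick parse error: {e}") from e

    def conv(dn) -> Node:
        label = dn.taxon.label if dn.taxon is not None else (dn.label or None)
        n = Node(label=label, length=dn.edge.length)
        for c in dn.child_nodes():
            n.add(conv(c))
        return n

    return PhyloTree(conv(dt.seed_node))


def write_newick(tree: PhyloTree) -> str:
    def fmt(n: Node) -> str:
        if n.is_tip:
            s = n.label or ""
        else:
            s = "(" + ",".join(fmt(c) for c in n.children) + ")"
            if n.label:
                s += n.label
        if n.length is not None:
            s += f":{n.length:.6f}"
        return s

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: np.ndarray, labels: list[str]) -> PhyloTree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Additive matrices are recovered exactly.  Three taxa are resolved with
    the closed-form three-point formulas; larger matrices go through
    scikit-bio's NJ implementation.
    """
    dm = np.asarray(dm, dtype=float)
    n = dm.shape[0]
    if dm.shape != (n, n) or len(labels) != n:
        raise ValueError("distance matrix / label size mismatch")
    if not np.allclose(dm, dm.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(dm) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(dm < 0):
        raise ValueError("distances must be non-negative")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if n == 3:
        a, b, c = labels
        root = Node()
        root.add(Node(a, (dm[0, 1] + dm[0, 2] - dm[1, 2]) / 2))
        root.add(Node(b, (dm[0, 1] + dm[1, 2] - dm[0, 2]) / 2))
        root.add(Node(c, (dm[0, 2] + dm[1, 2] - dm[0, 1]) / 2))
        return PhyloTree(root)

    from skbio import DistanceMatrix
    from skbio.tree import nj as _skbio_nj

    t = _skbio_nj(DistanceMatrix(dm, ids=labels))
    buf = io.StringIO()
    t.write(buf)
    return parse_newick(buf.getvalue())


# ---------------------------------------------------------------------------
# parsimony


def _tip_masks(alignment: MultipleAlignment) -> dict[str, np.ndarray]:
    lut = np.zeros(128, dtype=np.uint8)
    for ch, bits in BITS.items():
        lut[ord(ch)] = bits
    return {
        r.id: lut[np.frombuffer(r.residues.encode(), dtype=np.uint8)]
        for r in alignment.rows
    }


def _check_labels(tree_labels: list[str], aln_ids: list[str]) -> None:
    extra = set(tree_labels) - set(aln_ids)
    miss = set(aln_ids) - set(tree_labels)
    if extra or miss:
        raise ValueError(
            f"tip/row label mismatch; tree-only={sorted(extra)}, "
            f"alignment-only={sorted(miss)}"
        )


def fitch_score(tree: PhyloTree, alignment: MultipleAlignment) -> int:
    """Minimum number of state changes (Fitch), summed over columns.

    Ambiguity codes enter as state sets; ``-`` and ``?`` as fully missing.
    Multifurcating nodes are folded sequentially, which is exact for the
    degree-3 node of an unrooted binary tree (it amounts to a rooting).
    """
    _check_labels(tree.tip_labels(), [r.id for r in alignment.rows])
    masks = _tip_masks(alignment)
    ncols = alignment.ncols
    changes = np.zeros(ncols, dtype=np.int64)
    node_mask: dict[int, np.ndarray] = {}
    for n in tree.postorder():
        if n.is_tip:
            node_mask[id(n)] = masks[n.label]
        else:
            acc = None
            for c in n.children:
                m = node_mask.pop(id(c))
                if acc is None:
                    acc = m
                else:
                    inter = acc & m
                    zero = inter == 0
                    changes += zero
                    acc = np.where(zero, acc | m, inter)
            node_mask[id(n)] = acc
    return int(changes.sum())


# -- unrooted adjacency representation used by the heuristic search ---------


class _UTree:
    def __init__(self):
        self.adj: dict[int, list[int]] = {}
        self.label: dict[int, str] = {}
        self._next = 0

    def new_node(self, label: str | None = None) -> int:
        i = self._next
        self._next += 1
        self.adj[i] = []
        if label is not None:
            self.label[i] = label
        return i

    def connect(self, a: int, b: int) -> None:
        self.adj[a].append(b)
        self.adj[b].append(a)

    def disconnect(self, a: int, b: int) -> None:
        self.adj[a].remove(b)
        self.adj[b].remove(a)

    def edges(self) -> list[tuple[int, int]]:
        return sorted(
            (min(a, b), max(a, b))
            for a in self.adj
            for b in self.adj[a]
            if a < b
        )

    def to_tree(self) -> PhyloTree:
        # root at an internal node (any node of degree >= 2)
        root_id = next(
            (i for i in sorted(self.adj) if len(self.adj[i]) >= 2),
            min(self.adj),
        )
        root = Node(self.label.get(root_id))
        stack = [(root_id, None, root)]
        while stack:
            i, parent_id, node = stack.pop()
            for j in self.adj[i]:
                if j == parent_id:
                    continue
                child = Node(self.label.get(j))
                node.add(child)
                stack.append((j, i, child))
        return PhyloTree(root)


def _fitch_utree(ut: _UTree, masks: dict[str, np.ndarray], ncols: int) -> int:
    root_id = next(i for i in sorted(ut.adj) if len(ut.adj[i]) >= 2)
    changes = np.zeros(ncols, dtype=np.int64)
    # iterative postorder over the adjacency structure
    out: dict[int, np.ndarray] = {}
    stack: list[tuple[int, int | None, bool]] = [(root_id, None, False)]
    while stack:
        i, parent, done = stack.pop()
        kids = [j for j in ut.adj[i] if j != parent]
        if not kids:
            out[i] = masks[ut.label[i]]
            continue
        if not done:
            stack.append((i, parent, True))
            for j in kids:
                stack.append((j, i, False))
        else:
            acc = None
            for j in kids:
                m = out.pop(j)
                if acc is None:
                    acc = m
                else:
                    inter = acc & m
                    zero = inter == 0
                    changes += zero
                    acc = np.where(zero, acc | m, inter)
            out[i] = acc
    return int(changes.sum())


def _compress(alignment: MultipleAlignment) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Unique-column (pattern) compression of tip masks, with counts."""
    masks = _tip_masks(alignment)
    ids = [r.id for r in alignment.rows]
    mat = np.stack([masks[i] for i in ids])  # rows x cols
    pats, counts = np.unique(mat, axis=1, return_counts=True)
    return {i: pats[k] for k, i in enumerate(ids)}, counts


def mp_search(
    alignment: MultipleAlignment,
    n_starts: int = 1,
    seed: int = 0,
    ratchet: int = 0,
) -> tuple[PhyloTree, int]:
    """Maximum-parsimony heuristic search.

    Random stepwise addition, then NNI hill-climbing interleaved with
    subtree pruning-regrafting sweeps; optionally ``ratchet`` iterations
    of the parsimony ratchet (upweight a random quarter of the patterns,
    re-climb, climb again under original weights) to escape coordinated
    local optima, which fragment-rich alignments produce readily.
    Returns (best tree, Fitch score); deterministic for a given seed.
    """
    ids = [r.id for r in alignment.rows]
    if len(ids) < 4:
        raise ValueError("mp_search needs at least 4 tips")
    masks, counts = _compress(alignment)
    rng = np.random.default_rng(seed)
    ncols = len(counts)

    def score(ut: _UTree) -> int:
        return _weighted_fitch(ut, masks, counts)

    def climb(ut: _UTree, cur: int, weights: np.ndarray) -> int:
        def sc(u: _UTree) -> int:
            return _weighted_fitch(u, masks, weights)

        cur = _nni_hillclimb(ut, sc, cur)
        while True:
            cur, moved = _spr_pass(ut, sc, masks, weights, cur)
            if not moved:
                break
            cur = _nni_hillclimb(ut, sc, cur)
        return cur

    best_ut: _UTree | None = None
    best_score = np.inf
    for _ in range(max(1, n_starts)):
        order = list(ids)
        rng.shuffle(order)
        ut = _UTree()
        center = ut.new_node()
        for lab in order[:3]:
            ut.connect(center, ut.new_node(lab))
        for lab in order[3:]:
            best_edge, best_s = None, np.inf
            for (a, b) in ut.edges():
                ut.disconnect(a, b)
                w = ut.new_node()
                t = ut.new_node(lab)
                ut.connect(a, w)
                ut.connect(w, b)
                ut.connect(w, t)
                s = score(ut)
                if s < best_s:
                    best_s, best_edge = s, (a, b)
                # revert
                ut.disconnect(a, w)
                ut.disconnect(w, b)
                ut.disconnect(w, t)
                del ut.adj[w], ut.adj[t]
                del ut.label[t]
                ut.connect(a, b)
            a, b = best_edge
            ut.disconnect(a, b)
            w = ut.new_node()
            t = ut.new_node(lab)
            ut.connect(a, w)
            ut.connect(w, b)
            ut.connect(w, t)
        cur = climb(ut, score(ut), counts)
        for _ in range(ratchet):
            boost = rng.random(ncols) < 0.25
            perturbed = counts + counts * boost * 3
            climb(ut, _weighted_fitch(ut, masks, perturbed), perturbed)
            cur = climb(ut, score(ut), counts)
        if cur < best_score:
            best_score, best_ut = cur, ut
    return best_ut.to_tree(), int(best_score)


def _weighted_fitch(ut: _UTree, masks, counts) -> int:
    root_id = next(i for i in sorted(ut.adj) if len(ut.adj[i]) >= 2)
    changes = np.zeros(len(counts), dtype=np.int64)
    out: dict[int, np.ndarray] = {}
    stack: list[tuple[int, int | None, bool]] = [(root_id, None, False)]
    while stack:
        i, parent, done = stack.pop()
        kids = [j for j in ut.adj[i] if j != parent]
        if not kids:
            out[i] = masks[ut.label[i]]
            continue
        if not done:
            stack.append((i, parent, True))
            stack.extend((j, i, False) for j in kids)
        else:
            acc = None
            for j in kids:
                m = out.pop(j)
                if acc is None:
                    acc = m
                else:
                    inter = acc & m
                    zero = inter == 0
                    changes += zero
                    acc = np.where(zero, acc | m, inter)
            out[i] = acc
    return int((changes * counts).sum())


def _fitch_fold(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    inter = a & b
    return np.where(inter != 0, inter, a | b)


def _subtree_set(ut: _UTree, masks, root: int, avoid: int) -> np.ndarray:
    """Fitch state-set array of the subtree at ``root`` looking away from
    ``avoid``."""
    out: dict[int, np.ndarray] = {}
    stack = [(root, avoid, False)]
    while stack:
        i, parent, done = stack.pop()
        kids = [j for j in ut.adj[i] if j != parent]
        if not kids:
            out[i] = masks[ut.label[i]]
            continue
        if not done:
            stack.append((i, parent, True))
            stack.extend((j, i, False) for j in kids)
        else:
            acc = None
            for j in kids:
                m = out.pop(j)
                acc = m if acc is None else _fitch_fold(acc, m)
            out[i] = acc
    return out[root]


def _spr_pass(ut: _UTree, score_fn, masks, counts, cur: int) -> tuple:
    """One sweep of subtree pruning-regrafting.

    For every directed edge, the subtree is pruned and candidate
    reinsertion edges are ranked by a vectorized up/down Fitch bound
    (0 extra steps where the subtree set intersects the states around the
    edge); only the best few are scored exactly, and a move is kept only
    when the exact score improves."""
    moved = False
    again = True
    while again:
        again = False
        for (pu, v) in [e for a, b in _all_edges(ut) for e in ((a, b), (b, a))]:
            if pu not in ut.adj or v not in ut.adj[pu]:
                continue  # topology changed under us
            if len(ut.adj[pu]) == 1:
                continue  # remaining side would be a lone tip
            # detach subtree at v; splice pu (degree 3 -> 2)
            ut.disconnect(pu, v)
            nbrs = list(ut.adj[pu])
            spliced = None
            if len(nbrs) == 2:
                ut.disconnect(pu, nbrs[0])
                ut.disconnect(pu, nbrs[1])
                del ut.adj[pu]
                ut.connect(nbrs[0], nbrs[1])
                spliced = (pu, nbrs[0], nbrs[1])
            rest_edges = _all_edges(ut, component_of=nbrs[0] if spliced
                                    else pu)
            if not rest_edges:
                _undo_detach(ut, pu, v, spliced)
                continue
            sub = _subtree_set(ut, masks, v, avoid=None)
            ranked = _rank_insertions(ut, masks, counts, sub, rest_edges)
            best_edge, best_s = None, cur
            for (a, b) in ranked[:4]:
                w = ut.new_node()
                ut.disconnect(a, b)
                ut.connect(a, w)
                ut.connect(w, b)
                ut.connect(w, v)
                s = score_fn(ut)
                if s < best_s:
                    best_s, best_edge = s, (a, b)
                ut.disconnect(a, w)
                ut.disconnect(w, b)
                ut.disconnect(w, v)
                del ut.adj[w]
                ut.connect(a, b)
            if best_edge is None:
                _undo_detach(ut, pu, v, spliced)
            else:
                a, b = best_edge
                w = ut.new_node()
                ut.disconnect(a, b)
                ut.connect(a, w)
                ut.connect(w, b)
                ut.connect(w, v)
                cur = best_s
                moved = True
                again = True
    return cur, moved


def _undo_detach(ut: _UTree, pu: int, v: int, spliced) -> None:
    if spliced is not None:
        p, x, y = spliced
        ut.disconnect(x, y)
        ut.adj[p] = []
        ut.connect(p, x)
        ut.connect(p, y)
    ut.connect(pu, v)


def _all_edges(ut: _UTree, component_of: int | None = None) -> list:
    if component_of is None:
        return ut.edges()
    seen = {component_of}
    stack = [component_of]
    while stack:
        i = stack.pop()
        for j in ut.adj[i]:
            if j not in seen:
                seen.add(j)
                stack.append(j)
    return sorted(
        (min(a, b), max(a, b))
        for a in seen
        for b in ut.adj[a]
        if a < b and b in seen
    )


def _rank_insertions(ut: _UTree, masks, counts, sub: np.ndarray,
                     edges: list) -> list:
    """Order candidate insertion edges by a Fitch lower-bound on the extra
    steps of attaching a subtree with state sets ``sub``."""
    root = edges[0][0]
    up: dict[int, np.ndarray] = {}
    parent: dict[int, int | None] = {root: None}
    order: list[int] = []
    stack = [(root, None, False)]
    while stack:
        i, par, done = stack.pop()
        kids = [j for j in ut.adj[i] if j != par]
        if not done:
            parent[i] = par
            order.append(i)
            if kids:
                stack.append((i, par, True))
                stack.extend((j, i, False) for j in kids)
            else:
                up[i] = masks[ut.label[i]]
        else:
            acc = None
            for j in kids:
                acc = up[j] if acc is None else _fitch_fold(acc, up[j])
            up[i] = acc
    down: dict[int, np.ndarray] = {}
    for i in order:  # preorder
        kids = [j for j in ut.adj[i] if j != parent[i]]
        for c in kids:
            acc = down.get(i)
            for s in kids:
                if s is c:
                    continue
                acc = up[s] if acc is None else _fitch_fold(acc, up[s])
            down[c] = acc if acc is not None else up[c]
    scored = []
    for (a, b) in edges:
        c = b if parent.get(b) == a else a
        dn = down.get(c)
        edge_set = up[c] if dn is None else _fitch_fold(up[c], dn)
        extra = int(((sub & edge_set) == 0).dot(counts))
        scored.append((extra, (a, b)))
    scored.sort(key=lambda t: (t[0], t[1]))
    return [e for _, e in scored]


def _nni_hillclimb(ut: _UTree, score_fn, cur: int) -> int:
    improved = True
    while improved:
        improved = False
        internal_edges = [
            (u, v)
            for (u, v) in ut.edges()
            if len(ut.adj[u]) >= 3 and len(ut.adj[v]) >= 3
        ]
        best_move, best_s = None, cur
        for (u, v) in internal_edges:
            u_nb = [x for x in ut.adj[u] if x != v]
            v_nb = [x for x in ut.adj[v] if x != u]
            b = u_nb[1]
            for c in v_nb:
                ut.disconnect(u, b)
                ut.disconnect(v, c)
                ut.connect(u, c)
                ut.connect(v, b)
                s = score_fn(ut)
                if s < best_s:
                    best_s, best_move = s, (u, v, b, c)
                ut.disconnect(u, c)
                ut.disconnect(v, b)
                ut.connect(u, b)
                ut.connect(v, c)
        if best_move is not None:
            u, v, b, c = best_move
            ut.disconnect(u, b)
            ut.disconnect(v, c)
            ut.connect(u, c)
            ut.connect(v, b)
            cur = best_s
            improved = True
    return cur


# ---------------------------------------------------------------------------
# substitution models


@dataclass
class SubstModel:
    """Time-reversible nucleotide model (JC/K80/HKY/GTR), optionally with a
    proportion of invariant sites (+I) and 4-category discrete-gamma rate
    variation (+G).

    ``rates`` are the six exchangeabilities in order AC, AG, AT, CG, CT, GT
    (GT is the reference and conventionally 1).  ``freqs`` are stationary
    base frequencies in order A, C, G, T.  Gamma categories are
    equal-probability with category-mean rates normalized to average 1 over
    the variable classes; no additional rescaling by 1 − p_inv is applied.
    """

    family: str = "GTR"
    rates: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    plus_I: bool = False
    plus_G: bool = False
    p_inv: float = 0.0
    alpha: float = 1.0
    ncat: int = 4
    _decomp: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.family not in ("JC", "K80", "HKY", "GTR"):
            raise ValueError(f"unknown model family {self.family!r}")
        if len(self.rates) != 6 or any(r <= 0 for r in self.rates):
            raise ValueError("need 6 positive exchangeabilities")
        if len(self.freqs) != 4 or not math.isclose(sum(self.freqs), 1.0,
                                                    abs_tol=1e-6):
            raise ValueError("frequencies must sum to 1")
        if not (0 <= self.p_inv < 1):
            raise ValueError("p_inv must be in [0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    # -- constructors -------------------------------------------------------

    @classmethod
    def jc(cls, **kw) -> "SubstModel":
        return cls(family="JC", **kw)

    @classmethod
    def k80(cls, kappa: float = 2.0, **kw) -> "SubstModel":
        return cls(family="K80",
                   rates=(1.0, kappa, 1.0, 1.0, kappa, 1.0), **kw)

    @classmethod
    def hky(cls, kappa: float = 2.0,
            freqs: tuple = (0.25, 0.25, 0.25, 0.25), **kw) -> "SubstModel":
        return cls(family="HKY", rates=(1.0, kappa, 1.0, 1.0, kappa, 1.0),
                   freqs=tuple(freqs), **kw)

    @classmethod
    def gtr(cls, rates: tuple, freqs: tuple, **kw) -> "SubstModel":
        return cls(family="GTR", rates=tuple(rates), freqs=tuple(freqs), **kw)

    @property
    def label(self) -> str:
        s = self.family
        if self.plus_I:
            s += "+I"
        if self.plus_G:
            s += "+G"
        return s

    # -- matrices -----------------------------------------------------------

    def q_matrix(self) -> np.ndarray:
        """Rate matrix scaled to one expected substitution per unit time."""
        ac, ag, at, cg, ct, gt = self.rates
        S = np.array(
            [
                [0, ac, ag, at],
                [ac, 0, cg, ct],
                [ag, cg, 0, gt],
                [at, ct, gt, 0],
            ],
            dtype=float,
        )
        pi = np.asarray(self.freqs, dtype=float)
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        beta = -1.0 / (pi * np.diag(Q)).sum()
        return Q * beta

    def decomposition(self):
        if self._decomp is None:
            pi = np.asarray(self.freqs, dtype=float)
            Q = self.q_matrix()
            rpi = np.sqrt(pi)
            # A = D^{1/2} Q D^{-1/2} is symmetric for reversible Q
            A = (Q * rpi[:, None]) / rpi[None, :]
            A = (A + A.T) / 2
            lam, U = np.linalg.eigh(A)
            # exp(Qt) = D^{-1/2} U exp(lam t) U^T D^{1/2}
            right = U / rpi[:, None]
            left = U.T * rpi[None, :]
            object.__setattr__(self, "_decomp", (right, lam, left))
        return self._decomp

    def transition_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("negative branch length")
        right, lam, left = self.decomposition()
        P = (right * np.exp(lam * t)[None, :]) @ left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def category_rates(self) -> np.ndarray:
        if self.plus_G:
            return discrete_gamma_rates(self.alpha, self.ncat)
        return np.array([1.0])


def discrete_gamma_rates(alpha: float, ncat: int = 4) -> np.ndarray:
    """Category-mean rates of the equal-probability discrete gamma
    (mean-1 gamma with shape ``alpha``)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    probs = np.arange(1, ncat) / ncat
    bounds = np.concatenate(
        [[0.0], _gamma_dist.ppf(probs, alpha, scale=1.0 / alpha), [np.inf]]
    )
    upper = gammainc(alpha + 1, alpha * bounds[1:])
    lower = gammainc(alpha + 1, alpha * bounds[:-1])
    rates = ncat * (upper - lower)
    return rates / rates.mean()


# ---------------------------------------------------------------------------
# likelihood


def _tip_partials(mask_col: np.ndarray) -> np.ndarray:
    """patterns -> (4, npatterns) 0/1 partials from bitmasks."""
    bits = np.array([1, 2, 4, 8], dtype=np.uint8)
    return (mask_col[None, :] & bits[:, None] > 0).astype(float)


def prune_loglik(
    tree: PhyloTree,
    alignment: MultipleAlignment,
    model: SubstModel,
    rate_scale: float = 1.0,
) -> float:
    """Felsenstein-pruning log-likelihood of the alignment on the tree.

    Gaps/missing are marginalized; ambiguity codes contribute the union of
    their compatible states.  ``rate_scale`` multiplies every branch length
    (used for per-subset rate multipliers in partitioned models).
    """
    _check_labels(tree.tip_labels(), [r.id for r in alignment.rows])
    masks, counts = _compress(alignment)
    return loglik_patterns(tree, masks, counts, model, rate_scale)


def loglik_patterns(
    tree: PhyloTree,
    masks: dict,
    counts: np.ndarray,
    model: SubstModel,
    rate_scale: float = 1.0,
) -> float:
    """Pruning log-likelihood over pre-compressed site patterns (the core
    of :func:`prune_loglik`, reusable across repeated model fits)."""
    for n in tree.postorder():
        if n is tree.root:
            continue
        if n.length is None:
            raise ValueError("all branches need lengths for likelihood")
        if n.length < 0:
            raise ValueError("negative branch length")
    npat = len(counts)
    pi = np.asarray(model.freqs, dtype=float)
    cat_rates = model.category_rates()

    sitelik = np.zeros(npat)
    for r in cat_rates:
        partial: dict[int, np.ndarray] = {}
        for n in tree.postorder():
            if n.is_tip:
                p = _tip_partials(masks[n.label])
            else:
                p = np.ones((4, npat))
                for c in n.children:
                    P = model.transition_matrix(c.length * r * rate_scale)
                    p = p * (P @ partial.pop(id(c)))
            partial[id(n)] = p
        sitelik += pi @ partial[id(tree.root)]
    sitelik /= len(cat_rates)

    if model.plus_I and model.p_inv > 0:
        common = None
        for lab in masks:
            common = masks[lab] if common is None else common & masks[lab]
        inv = _tip_partials(common)  # (4, npat) indicator of shared states
        l_inv = pi @ inv
        sitelik = model.p_inv * l_inv + (1 - model.p_inv) * sitelik

    return float(np.dot(counts, np.log(np.clip(sitelik, 1e-300, None))))


def optimize_branch_lengths(
    tree: PhyloTree,
    alignment: MultipleAlignment,
    model: SubstModel,
    tol: float = 1e-4,
    max_iter: int = 50,
    max_branch: float = 20.0,
) -> tuple[PhyloTree, float]:
    """Round-robin single-branch optimization (bounded 1-D search) until
    the log-likelihood improves by less than ``tol``.  The lnL trace is
    monotone non-decreasing."""
    t = tree.copy()
    branches = [n for n in t.postorder() if n is not t.root]
    for n in branches:
        if n.length is None:
            n.length = 0.1
    cur = prune_loglik(t, alignment, model)
    for _ in range(max_iter):
        start = cur
        for n in branches:
            old = n.length

            def neg(x: float) -> float:
                n.length = x
                return -prune_loglik(t, alignment, model)

            res = minimize_scalar(
                neg, bounds=(0.0, max_branch), method="bounded",
                options={"xatol": 1e-9},
            )
            if -res.fun > cur:
                n.length = float(res.x)
                cur = -res.fun
            else:
                n.length = old
        if cur - start < tol:
            break
    return t, cur


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapResult:
    """Bipartition support percentages from column-resampled replicates."""

    support: dict
    n_reps: int

    def __post_init__(self):
        for v in self.support.values():
            if not (0 <= v <= 100):
                raise ValueError("support must be a percentage")


def bootstrap(
    alignment: MultipleAlignment,
    n_reps: int,
    infer_fn,
    seed: int = 0,
) -> BootstrapResult:
    """Nonparametric bootstrap: resample columns with replacement, infer a
    tree per replicate with ``infer_fn``, tally bipartition frequencies."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    chars = np.array([list(r.residues) for r in alignment.rows])
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, alignment.ncols, size=alignment.ncols)
        rep = MultipleAlignment(
            rows=[
                Sequence(r.id, "".join(chars[i, cols]), accession=r.accession)
                for i, r in enumerate(alignment.rows)
            ]
        )
        t = infer_fn(rep)
        for bp in t.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    return BootstrapResult(
        support={bp: 100.0 * c / n_reps for bp, c in counts.items()},
        n_reps=n_reps,
    )


# ---------------------------------------------------------------------------
# simulation


def simulate_evolution(
    tree: PhyloTree,
    model: SubstModel,
    length: int,
    seed: int = 0,
) -> MultipleAlignment:
    """Simulate an ungapped alignment on the tree: root states drawn from
    the stationary frequencies, then substitutions along each branch under
    the model (per-site gamma/invariant rates if configured)."""
    rng = np.random.default_rng(seed)
    pi = np.asarray(model.freqs, dtype=float)
    site_rate = np.ones(length)
    if model.plus_G:
        cr = model.category_rates()
        site_rate = cr[rng.integers(0, len(cr), size=length)]
    if model.plus_I and model.p_inv > 0:
        site_rate[rng.random(length) < model.p_inv] = 0.0

    states: dict[int, np.ndarray] = {
        id(tree.root): rng.choice(4, size=length, p=pi)
    }
    order = list(reversed(tree.postorder()))  # preorder
    for n in order:
        if n is tree.root:
            continue
        if n.length is None:
            raise ValueError("simulation needs branch lengths")
        parent_states = states[id(n.parent)]
        child = parent_states.copy()
        for r in np.unique(site_rate):
            sel = site_rate == r
            if r == 0 or n.length * r == 0:
                continue
            P = model.transition_matrix(n.length * r)
            sub = parent_states[sel]
            u = rng.random(sub.shape[0])
            cum = np.cumsum(P, axis=1)
            child[sel] = (u[:, None] > cum[sub]).sum(axis=1)
        states[id(n)] = child

    letters = np.array(list("ACGT"))
    rows = [
        Sequence(n.label, "".join(letters[states[id(n)]]))
        for n in tree.postorder()
        if n.is_tip
    ]
    return MultipleAlignment(rows=rows)
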