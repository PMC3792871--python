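"""Synthetic transcriptome-assembly pools with known ground truth.

Emulates the data regime the mining pipeline faces: per-accession pools
of short, fragmentary, possibly strand-flipped contigs derived from
single- or multi-copy gene families on a species tree, with taxon
dropout, optional assembler redundancy (two contig sets with shifted
breakpoints), and intron-bearing genomic counterparts with canonical
splice signals (GTAAG donor / TTCAG acceptor consensus).  Every contig
is a verbatim substring of a true transcript, and a truth ledger maps it
back, so each pipeline stage can be scored exactly.

Defaults model a conserved single-copy coding locus sampled across a
plant order: moderate sequence divergence (mean root-to-tip 0.1
substitutions/site in exons, introns evolving 2.5x faster), ~600 nt
transcripts broken into ~3 overlapping fragments, and 10% per-accession
dropout.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field

import numpy as np

from .search import AssemblyPool
from .seqcore import Sequence, revcomp_str
from .trees import Node, PhyloTree, SubstModel, parse_newick, simulate_evolution

__all__ = [
    "IntronConfig",
    "FragmentConfig",
    "SimConfig",
    "FamilyTruth",
    "SyntheticTruth",
    "sim_species_tree",
    "sim_gene_family",
    "sim_locus",
    "fragmentize",
    "make_pools",
]

_DONOR = "GTAAG"
_ACCEPTOR = "TTCAG"


@dataclass
class IntronConfig:
    n_introns: int = 2
    min_len: int = 70
    max_len: int = 150
    rate_multiplier: float = 2.5

    def __post_init__(self):
        if self.min_len < len(_DONOR) + len(_ACCEPTOR) + 10:
            raise ValueError("introns too short for splice signals")
        if self.rate_multiplier <= 0:
            raise ValueError("rate multiplier must be positive")


@dataclass
class FragmentConfig:
    n_fragments: int = 3
    overlap_mean: float = 35.0
    overlap_sd: float = 10.0
    min_len: int = 60

    def __post_init__(self):
        if self.n_fragments < 1:
            raise ValueError("need at least one fragment")


@dataclass
class SimConfig:
    """End-to-end generator configuration (defaults = study conditions)."""

    n_taxa: int = 15
    tree_height: float = 0.1  # mean root-to-tip, substitutions/site (exons)
    birth_rate: float = 1.0
    n_families: int = 20
    dup_rate: float = 0.0  # duplications per unit branch length
    loss_prob: float = 0.3  # per-tip loss probability of duplicated copies
    transcript_length: int = 600
    model: SubstModel = field(
        default_factory=lambda: SubstModel.hky(
            kappa=2.5, freqs=(0.3, 0.2, 0.2, 0.3)
        )
    )
    introns: IntronConfig = field(default_factory=IntronConfig)
    fragments: FragmentConfig = field(default_factory=FragmentConfig)
    dropout: float = 0.1  # per accession x family
    assembler_redundancy: bool = False
    seed: int = 0

    def __post_init__(self):
        for p in (self.dup_rate, self.loss_prob, self.dropout):
            if p < 0:
                raise ValueError("rates/probabilities must be >= 0")
        for p in (self.loss_prob, self.dropout):
            if p > 1:
                raise ValueError("probabilities must be <= 1")


# ---------------------------------------------------------------------------
# species tree


def sim_species_tree(
    n_taxa: int, seed: int = 0, height: float = 0.1, birth_rate: float = 1.0
) -> PhyloTree:
    """Yule species tree rescaled so the mean root-to-tip path equals
    ``height`` (expected substitutions per site)."""
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    from dendropy.simulate import treesim

    rnd = random.Random(int(seed))
    dt = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=rnd,
    )
    # the simulator stops at the n-th speciation instant, leaving the
    # youngest cherry with zero-length tips; let the process run the
    # Exp(n*lambda) waiting time to the next (uncounted) event
    extra = rnd.expovariate(n_taxa * birth_rate)
    for k, leaf in enumerate(sorted(dt.leaf_node_iter(),
                                    key=lambda x: x.taxon.label)):
        leaf.taxon.label = f"sp{k + 1:02d}"
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    tree = parse_newick(dt.as_string(schema="newick").strip())
    depths = []
    for tip in tree.tips():
        d, n = 0.0, tip
        while n.parent is not None:
            d += n.length or 0.0
            n = n.parent
        depths.append(d)
    scale = height / (sum(depths) / len(depths))
    for n in tree.postorder():
        if n.length is not None:
            n.length *= scale
    return tree


# ---------------------------------------------------------------------------
# gene families


def sim_gene_family(
    species_tree: PhyloTree,
    dup_rate: float = 0.0,
    loss_prob: float = 0.0,
    seed: int = 0,
    force_root_duplication: bool = False,
) -> PhyloTree:
    """Gene tree on the species tree: duplications arise along branches as
    a Poisson process (each creating an independently evolving copy),
    and each duplicated copy is lost in any given descendant species with
    probability ``loss_prob``.  Tips are labeled ``species|copy``.
    With ``dup_rate=0`` and no forced duplication the gene tree is
    congruent with the species tree (tips ``species|c0``)."""
    rng = np.random.default_rng(int(seed))
    copy_counter = [0]

    def new_copy() -> str:
        copy_counter[0] += 1
        return f"c{copy_counter[0]}"

    def descend(sp_node: Node, branch_len: float, copy_id: str,
                lossy: bool) -> Node | None:
        """Gene lineage entering the branch above ``sp_node``."""
        n_dups = rng.poisson(dup_rate * branch_len) if dup_rate > 0 else 0
        times = np.sort(rng.uniform(0, branch_len, size=n_dups))
        top = Node(length=None)
        cur = top
        used = 0.0
        for t in times:
            mid = Node(length=None)
            mid.length = float(t - used)
            used = float(t)
            dup_child = descend(sp_node, branch_len - t, new_copy(), True)
            cur.add(mid)
            if dup_child is not None:
                mid.add(dup_child)
            cur = mid
        tail = _at_species_node(sp_node, copy_id, lossy)
        if tail is not None:
            tail.length = (tail.length or 0.0) + float(branch_len - used)
            cur.add(tail)
        # unwind: drop empty scaffolding, suppress unary nodes
        return _simplify(top)

    def _at_species_node(sp_node: Node, copy_id: str, lossy: bool):
        if sp_node.is_tip:
            if lossy and loss_prob > 0 and rng.random() < loss_prob:
                return None
            return Node(label=f"{sp_node.label}|{copy_id}", length=0.0)
        inner = Node(length=0.0)
        for c in sp_node.children:
            child = descend(c, c.length or 0.0, copy_id, lossy)
            if child is not None:
                inner.add(child)
        if not inner.children:
            return None
        return inner

    def _simplify(n: Node) -> Node | None:
        if n.is_tip:
            return n if n.label is not None else None
        kids = [k for k in (_simplify(c) for c in list(n.children))
                if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].length = (kids[0].length or 0.0) + (n.length or 0.0)
            kids[0].parent = None
            return kids[0]
        n.children = []
        for k in kids:
            n.add(k)
        return n

    roots = []
    start = _at_species_node(species_tree.root, "c0", False)
    if start is not None:
        roots.append(start)
    if force_root_duplication:
        extra = _at_species_node(species_tree.root, new_copy(), True)
        if extra is not None:
            roots.append(extra)
    if not roots:
        raise RuntimeError("gene family went extinct; use another seed")
    if len(roots) == 1:
        root = roots[0]
        root.length = None
        return PhyloTree(root)
    root = Node()
    for r in roots:
        r.length = r.length or 0.0
        root.add(r)
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# loci


def sim_locus(
    gene_tree: PhyloTree,
    model: SubstModel,
    length: int,
    intron_cfg: IntronConfig | None = None,
    seed: int = 0,
) -> dict:
    """Evolve one locus on a gene tree.

    Returns a dict with ``transcripts`` (tip -> coding sequence),
    ``genomics`` (tip -> genomic copy with introns inserted at fixed
    homologous points, evolved at an elevated rate, flanked by canonical
    splice signals), ``intron_points`` (cDNA insertion points), and
    ``intron_spans`` (tip -> list of genomic (start, end))."""
    cfg = intron_cfg or IntronConfig()
    rng = np.random.default_rng(int(seed))
    sub_seeds = rng.integers(0, 2**31 - 1, size=cfg.n_introns + 1)
    exon_aln = simulate_evolution(gene_tree, model, length,
                                  seed=int(sub_seeds[0]))
    transcripts = {r.id: r.residues for r in exon_aln.rows}

    points: list[int] = []
    if cfg.n_introns:
        lo, hi = 60, length - 60
        while len(points) < cfg.n_introns:
            p = int(rng.integers(lo, hi))
            if all(abs(p - q) >= 80 for q in points):
                points.append(p)
        points.sort()

    intron_seqs: list[dict] = []
    fast = _scaled_tree(gene_tree, cfg.rate_multiplier)
    for i in range(cfg.n_introns):
        ilen = int(rng.integers(cfg.min_len, cfg.max_len + 1))
        interior = ilen - len(_DONOR) - len(_ACCEPTOR)
        aln = simulate_evolution(fast, model, interior,
                                 seed=int(sub_seeds[i + 1]))
        intron_seqs.append(
            {r.id: _DONOR + r.residues + _ACCEPTOR for r in aln.rows}
        )

    genomics: dict[str, str] = {}
    spans: dict[str, list] = {}
    for tip, cds in transcripts.items():
        parts = []
        tip_spans = []
        prev = 0
        offset = 0
        for p, iseq in zip(points, intron_seqs):
            parts.append(cds[prev:p])
            offset += p - prev
            intron = iseq[tip]
            tip_spans.append((offset, offset + len(intron)))
            parts.append(intron)
            offset += len(intron)
            prev = p
        parts.append(cds[prev:])
        genomics[tip] = "".join(parts)
        spans[tip] = tip_spans
    return {
        "transcripts": transcripts,
        "genomics": genomics,
        "intron_points": points,
        "intron_spans": spans,
    }


def _scaled_tree(tree: PhyloTree, factor: float) -> PhyloTree:
    t = tree.copy()
    for n in t.postorder():
        if n.length is not None:
            n.length *= factor
    return t


# ---------------------------------------------------------------------------
# fragmentation


def fragmentize(
    transcript: str,
    cfg: FragmentConfig | None = None,
    seed: int = 0,
) -> list:
    """Break a transcript into overlapping (or slightly gapped) coverage
    intervals.  Every emitted interval is a verbatim substring span;
    consecutive fragments overlap by ~N(overlap_mean, overlap_sd) nt
    (truncated, occasionally negative = a coverage gap)."""
    cfg = cfg or FragmentConfig()
    rng = np.random.default_rng(int(seed))
    L = len(transcript)
    n = cfg.n_fragments
    if n == 1 or L <= cfg.min_len * n:
        return [(0, L)]
    base = np.linspace(0, L, n + 1).astype(int)
    jitter = rng.integers(-L // (6 * n), L // (6 * n) + 1, size=n - 1)
    cuts = [0] + [int(np.clip(base[i + 1] + jitter[i],
                              cfg.min_len * (i + 1),
                              L - cfg.min_len * (n - i - 1)))
                  for i in range(n - 1)] + [L]
    half = cfg.overlap_mean / 2.0
    sd = cfg.overlap_sd / 2.0
    out = []
    for i in range(n):
        left = 0.0 if i == 0 else float(
            np.clip(rng.normal(half, sd), -5.0, 3 * half)
        )
        right = 0.0 if i == n - 1 else float(
            np.clip(rng.normal(half, sd), -5.0, 3 * half)
        )
        a = max(0, int(round(cuts[i] - left)))
        b = min(L, int(round(cuts[i + 1] + right)))
        if b - a >= cfg.min_len:
            out.append((a, b))
    return out


# ---------------------------------------------------------------------------
# end-to-end pools


@dataclass
class FamilyTruth:
    name: str
    gene_tree: PhyloTree
    transcripts: dict
    genomics: dict
    intron_points: list
    intron_spans: dict
    fragments: dict  # contig id -> (tip, start, end, strand)
    dropped: list
    single_copy: bool


@dataclass
class SyntheticTruth:
    species_tree: PhyloTree
    families: dict
    config: SimConfig

    def contig_origin(self, contig_id: str) -> tuple:
        for fam in self.families.values():
            if contig_id in fam.fragments:
                return fam.name, fam.fragments[contig_id]
        raise KeyError(contig_id)

    def to_json(self) -> str:
        doc = {
            "species_tree": self.species_tree.newick(),
            "families": {
                name: {
                    "gene_tree": f.gene_tree.newick(),
                    "transcripts": f.transcripts,
                    "intron_points": list(f.intron_points),
                    "intron_spans": {k: list(map(list, v))
                                     for k, v in f.intron_spans.items()},
                    "fragments": {k: list(v)
                                  for k, v in f.fragments.items()},
                    "dropped": list(f.dropped),
                    "single_copy": f.single_copy,
                }
                for name, f in self.families.items()
            },
        }
        return json.dumps(doc, indent=1)


def make_pools(
    config: SimConfig | None = None,
    force_root_duplication_in: str | None = None,
) -> tuple:
    """Generate the full synthetic dataset.

    Returns (pools, truth): one AssemblyPool per accession holding the
    fragmentary contigs of every family that accession retains, and the
    SyntheticTruth ledger.  ``force_root_duplication_in`` names one
    family to receive a duplication at the root of the species tree.
    """
    cfg = config or SimConfig()
    master = np.random.default_rng(int(cfg.seed))
    sp_tree = sim_species_tree(
        cfg.n_taxa, seed=int(master.integers(2**31 - 1)),
        height=cfg.tree_height, birth_rate=cfg.birth_rate,
    )
    accessions = sorted(sp_tree.tip_labels())
    pools: dict[str, list] = {a: [] for a in accessions}
    families: dict[str, FamilyTruth] = {}
    for fidx in range(cfg.n_families):
        fname = f"fam{fidx + 1:03d}"
        forced = fname == force_root_duplication_in
        gtree = sim_gene_family(
            sp_tree,
            dup_rate=cfg.dup_rate,
            loss_prob=cfg.loss_prob,
            seed=int(master.integers(2**31 - 1)),
            force_root_duplication=forced,
        )
        locus = sim_locus(
            gtree, cfg.model, cfg.transcript_length, cfg.introns,
            seed=int(master.integers(2**31 - 1)),
        )
        dropped = [
            a for a in accessions if master.random() < cfg.dropout
        ]
        fragments: dict[str, tuple] = {}
        for tip, cds in locus["transcripts"].items():
            species = tip.split("|")[0]
            if species in dropped:
                continue
            sets = [("A", int(master.integers(2**31 - 1)))]
            if cfg.assembler_redundancy:
                sets.append(("B", int(master.integers(2**31 - 1))))
            for tag, fseed in sets:
                for k, (a, b) in enumerate(
                    fragmentize(cds, cfg.fragments, seed=fseed)
                ):
                    strand = "+" if master.random() < 0.5 else "-"
                    seg = cds[a:b]
                    if strand == "-":
                        seg = revcomp_str(seg)
                    cid = f"{species}_{fname}_{tip.split('|')[1]}_{tag}{k}"
                    fragments[cid] = (tip, a, b, strand)
                    pools[species].append(
                        Sequence(cid, seg, accession=species)
                    )
        families[fname] = FamilyTruth(
            name=fname,
            gene_tree=gtree,
            transcripts=locus["transcripts"],
            genomics=locus["genomics"],
            intron_points=locus["intron_points"],
            intron_spans=locus["intron_spans"],
            fragments=fragments,
            dropped=dropped,
            single_copy=not forced and cfg.dup_rate == 0,
        )
    pool_objs = {
        a: AssemblyPool(accession=a, contigs=pools[a]) for a in accessions
    }
    return pool_objs, SyntheticTruth(
        species_tree=sp_tree, families=families, config=cfg
    )
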