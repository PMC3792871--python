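"""Iterative tree-guided fragment merging, paralog handling, concatenation.

Fragmentary transcriptome contigs of one accession that (a) sit close
together in the current parsimony tree and (b) have no base conflicts are
combined into a single sequence; the tree is then re-inferred from the
longer sequences and the procedure repeats until nothing more merges.
When the tree cannot say which 5' fragment belongs with which 3' one, the
pairing is made arbitrarily in input order and the products are flagged
as potential chimeras.  Accessions that retain multiple sequences in
separate parts of the tree are flagged as candidate gene duplications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqcore import (
    CODE_OF_SET,
    GAP,
    IUPAC_SETS,
    MISSING,
    MultipleAlignment,
    Sequence,
    iupac_compatible,
)
from .trees import PhyloTree, minimal_spanning_sides, smallest_spanning_clade

__all__ = [
    "FragmentSet",
    "MergeLog",
    "MergeRecord",
    "DuplicationReport",
    "ConflictError",
    "conflicts",
    "candidate_groups",
    "merge_group",
    "iterate_merge",
    "flag_duplications",
    "extract_copy_alignment",
    "concat_loci",
]


class ConflictError(ValueError):
    pass


@dataclass
class FragmentSet:
    """An alignment of sequence fragments plus their accession labels.

    One accession may own several rows (fragments and/or paralogs).
    Coverage is derived from the residues: '-' and '?' columns are not
    covered.
    """

    alignment: MultipleAlignment

    @property
    def rows(self) -> list[Sequence]:
        return self.alignment.rows

    def accession_of(self, row_id: str) -> str:
        return self.alignment.row(row_id).accession

    def accessions(self) -> list[str]:
        seen: list[str] = []
        for r in self.rows:
            if r.accession not in seen:
                seen.append(r.accession)
        return seen

    def rows_of(self, accession: str) -> list[str]:
        return [r.id for r in self.rows if r.accession == accession]

    def coverage(self, row_id: str) -> list[tuple]:
        """Maximal covered (non-gap, non-missing) column intervals."""
        res = self.alignment.row(row_id).residues
        out: list[tuple] = []
        start = None
        for j, c in enumerate(res):
            if c not in (GAP, MISSING):
                if start is None:
                    start = j
            elif start is not None:
                out.append((start, j))
                start = None
        if start is not None:
            out.append((start, len(res)))
        return out


@dataclass(frozen=True)
class MergeRecord:
    round: int
    merged_rows: tuple
    product_id: str
    conflict_count: int
    arbitrary: bool


@dataclass
class MergeLog:
    records: list = field(default_factory=list)
    chimera_flags: dict = field(default_factory=dict)  # row id -> bool

    def add(self, rec: MergeRecord) -> None:
        self.records.append(rec)
        if rec.arbitrary:
            self.chimera_flags[rec.product_id] = True

    def tsv(self) -> str:
        lines = ["round\tmerged_rows\tproduct\tconflicts\tarbitrary\tchimera"]
        for r in self.records:
            lines.append(
                f"{r.round}\t{','.join(r.merged_rows)}\t{r.product_id}"
                f"\t{r.conflict_count}\t{'yes' if r.arbitrary else 'no'}"
                f"\t{'yes' if self.chimera_flags.get(r.product_id) else 'no'}"
            )
        return "\n".join(lines) + "\n"


def conflicts(alignment: MultipleAlignment, row_a: str, row_b: str) -> int:
    """Number of columns where both rows are present (non-gap, non-missing)
    and their IUPAC base sets do not intersect."""
    if row_a == row_b:
        raise ValueError("rows must be distinct")
    a = alignment.row(row_a).residues
    b = alignment.row(row_b).residues
    n = 0
    for x, y in zip(a, b):
        if x in (GAP, MISSING) or y in (GAP, MISSING):
            continue
        if not iupac_compatible(x, y):
            n += 1
    return n


def _contained_foreign(
    tree: PhyloTree, fragset: FragmentSet, clade: set, accession: str
) -> int:
    """Number of foreign accessions with >= 2 rows whose *every* row lies
    inside the clade.

    A lone foreign fragment drifting into a clade carries no placement
    information (rows with little overlapping data move at zero parsimony
    cost), and a completed single-row accession between near-identical
    neighbors does not indicate paralogy either.  What marks a clade as
    spanning real copy structure is a wholly contained foreign accession
    whose own rows are still separated — the same duplication signature
    repeated in another taxon."""
    n = 0
    for other in fragset.accessions():
        if other == accession:
            continue
        rows = set(fragset.rows_of(other))
        if len(rows) >= 2 and rows <= clade:
            n += 1
    return n


def _worst_contained_foreign(
    tree: PhyloTree, fragset: FragmentSet, labels: set, accession: str
) -> int:
    """Maximum contained-foreign count over all tied minimal spanning
    sides — several sides can tie in symmetric trees, and paralogy
    protection must see the worst of them."""
    return max(
        _contained_foreign(tree, fragset, side, accession)
        for side in minimal_spanning_sides(tree, labels)
    )


def _eligible(
    tree: PhyloTree,
    fragset: FragmentSet,
    a: str,
    b: str,
    max_foreign: int,
    accession: str,
    tolerance: int = 0,
) -> bool:
    if _worst_contained_foreign(tree, fragset, {a, b}, accession) > max_foreign:
        return False
    return conflicts(fragset.alignment, a, b) <= tolerance


def candidate_groups(
    tree: PhyloTree,
    fragset: FragmentSet,
    accession: str,
    max_foreign: int = 0,
    tolerance: int = 0,
) -> tuple:
    """Partition an accession's rows into mergeable groups.

    Two rows are pairwise eligible when their smallest spanning clade in
    the (unrooted) tree wholly contains at most ``max_foreign`` other
    accessions (see :func:`_contained_foreign`) and they have no more
    than ``tolerance`` conflicts.  Rows are assigned greedily in input
    order to the first group whose every member they are eligible with,
    which keeps groups maximal and the procedure deterministic.

    Returns (groups, arbitrary_group_ids): group indices whose members
    have eligibility edges into a *different* group are pairing-ambiguous
    (the Fig-5 situation) and their merges must be flagged as potential
    chimeras.
    """
    if max_foreign < 0:
        raise ValueError("max_foreign must be >= 0")
    rows = fragset.rows_of(accession)
    elig: dict[tuple, bool] = {}
    for i, a in enumerate(rows):
        for b in rows[i + 1 :]:
            elig[(a, b)] = elig[(b, a)] = _eligible(
                tree, fragset, a, b, max_foreign, accession, tolerance
            )
    groups: list[list[str]] = []
    for r in rows:
        placed = False
        for g in groups:
            if all(elig[(r, m)] for m in g):
                g.append(r)
                placed = True
                break
        if not placed:
            groups.append([r])
    member_of = {r: gi for gi, g in enumerate(groups) for r in g}
    arbitrary: set[int] = set()
    for (a, b), ok in elig.items():
        if ok and member_of[a] != member_of[b]:
            arbitrary.add(member_of[a])
            arbitrary.add(member_of[b])
    return [tuple(g) for g in groups], arbitrary


def merge_group(fragset: FragmentSet, row_ids: tuple) -> Sequence:
    """Columnwise consensus of conflict-free fragments of one accession.

    Covered columns take the IUPAC intersection of the covering rows
    (rendered as the minimal code); columns nobody covers become '-' only
    where every row has '-', else '?'.  Any conflict refuses the merge,
    naming the columns.
    """
    rows = [fragset.alignment.row(r) for r in row_ids]
    accs = {r.accession for r in rows}
    if len(accs) != 1:
        raise ValueError(f"rows span multiple accessions: {sorted(accs)}")
    ncols = fragset.alignment.ncols
    out = []
    bad_cols = []
    for j in range(ncols):
        present = [r.residues[j] for r in rows
                   if r.residues[j] not in (GAP, MISSING)]
        if present:
            inter = IUPAC_SETS[present[0]]
            for c in present[1:]:
                inter = inter & IUPAC_SETS[c]
            if not inter:
                bad_cols.append(j)
                out.append(MISSING)
            else:
                out.append(CODE_OF_SET[frozenset(inter)])
        elif all(r.residues[j] == GAP for r in rows):
            out.append(GAP)
        else:
            out.append(MISSING)
    if bad_cols:
        raise ConflictError(
            f"rows {row_ids} conflict at columns {bad_cols}"
        )
    return Sequence(
        "+".join(row_ids), "".join(out), accession=rows[0].accession
    )


def _overlap_columns(fragset: FragmentSet, a: str, b: str) -> int:
    ra = fragset.alignment.row(a).residues
    rb = fragset.alignment.row(b).residues
    return sum(
        1
        for x, y in zip(ra, rb)
        if x not in (GAP, MISSING) and y not in (GAP, MISSING)
    )


def iterate_merge(
    fragset: FragmentSet,
    tree_fn,
    max_rounds: int = 20,
    max_foreign: int = 0,
    tolerance: int = 0,
    min_link: int = 20,
) -> tuple:
    """The "infer-tree, group-sequences" loop (to a fixpoint).

    Each round infers a tree from the current fragments (``tree_fn`` maps
    a FragmentSet to a PhyloTree, typically an MP search with a fixed
    seed), forms candidate groups per accession, and merges every group of
    size >= 2.  Ambiguous pairings are made arbitrarily in input order and
    flagged as chimeras.

    When a tree round produces no merge but same-accession rows remain
    that share a compatible overlap of at least ``min_link`` columns,
    those rows are merged on that direct sequence evidence alone — close
    neighbors can deadlock the clade criterion even though the identical
    overlap leaves no real doubt.  Rows whose overlap conflicts (true
    paralogs) are never merged this way, and non-overlapping rows are
    left to the tree.  Terminates when nothing merges or after
    ``max_rounds``.  Returns (fragset, MergeLog).
    """
    log = MergeLog()
    current = fragset
    for rnd in range(1, max_rounds + 1):
        multi = [a for a in current.accessions()
                 if len(current.rows_of(a)) >= 2]
        if not multi:
            break
        if len(current.rows) >= 4:
            tree = tree_fn(current)
        else:
            tree = None
        merged_any = False
        new_rows: list[Sequence] = []
        consumed: set[str] = set()
        for acc in current.accessions():
            rows = current.rows_of(acc)
            if len(rows) < 2:
                continue
            if tree is not None:
                groups, arbitrary = candidate_groups(
                    tree, current, acc, max_foreign, tolerance
                )
            else:
                # too few rows for a tree: group on conflicts alone
                groups, arbitrary = _conflict_only_groups(
                    current, rows, tolerance
                )
            for gi, g in enumerate(groups):
                if len(g) < 2:
                    continue
                product = merge_group(current, g)
                arb = gi in arbitrary or any(
                    log.chimera_flags.get(r, False) for r in g
                )
                log.add(MergeRecord(rnd, g, product.id, 0, arb))
                if arb:
                    log.chimera_flags[product.id] = True
                new_rows.append(product)
                consumed.update(g)
                merged_any = True
        if not merged_any:
            # overlap-evidence fallback for deadlocked neighbors
            for acc in current.accessions():
                rows = current.rows_of(acc)
                if len(rows) < 2:
                    continue
                groups, _ = _overlap_groups(current, rows, tolerance,
                                            min_link)
                for g in groups:
                    if len(g) < 2:
                        continue
                    product = merge_group(current, g)
                    arb = any(log.chimera_flags.get(r, False) for r in g)
                    log.add(MergeRecord(rnd, g, product.id, 0, arb))
                    if arb:
                        log.chimera_flags[product.id] = True
                    new_rows.append(product)
                    consumed.update(g)
                    merged_any = True
        if not merged_any and tree is not None:
            # circular deadlocks: X blocked only by split Y, Y only by
            # split X (etc.), all pairs conflict-free.  The paralogy
            # evidence is mutual and dissolves; merge the single
            # best-overlapping group and re-infer the tree.
            pick = _circular_deadlock_group(current, tree, tolerance)
            if pick is not None:
                g = pick
                product = merge_group(current, g)
                arb = any(log.chimera_flags.get(r, False) for r in g)
                log.add(MergeRecord(rnd, g, product.id, 0, arb))
                if arb:
                    log.chimera_flags[product.id] = True
                new_rows.append(product)
                consumed.update(g)
                merged_any = True
        if not merged_any:
            break
        kept = [r for r in current.rows if r.id not in consumed]
        current = FragmentSet(
            MultipleAlignment(
                rows=kept + new_rows,
                colmeta=list(current.alignment.colmeta),
                charsets=dict(current.alignment.charsets),
            )
        )
    return current, log


def _circular_deadlock_group(fragset: FragmentSet, tree: PhyloTree,
                             tolerance: int):
    """Find the best conflict-free group whose tree blocking is circular.

    An accession's candidate group (formed on conflicts alone) may be
    blocked because a split foreign accession lies wholly inside its
    spanning sides.  When every such blocker is itself a conflict-free
    candidate blocked (among others) by the first accession, no
    independent evidence of paralogy exists: true duplicate copies
    overlap and conflict, which breaks the cycle by removing the blocker
    from the "trying to merge" set.  Returns the group with the largest
    internal compatible overlap, or None.
    """
    candidates: dict[str, tuple] = {}
    blockers: dict[str, set] = {}
    for acc in fragset.accessions():
        rows = fragset.rows_of(acc)
        if len(rows) < 2:
            continue
        groups, _ = _conflict_only_groups(fragset, rows, tolerance)
        big = [g for g in groups if len(g) >= 2]
        if not big:
            continue  # internally conflicting (paralog-like): not trying
        g = max(
            big,
            key=lambda g: sum(
                _overlap_columns(fragset, a, b)
                for i, a in enumerate(g)
                for b in g[i + 1 :]
            ),
        )
        candidates[acc] = g
        blocked_by: set[str] = set()
        for side in minimal_spanning_sides(tree, set(g)):
            for other in fragset.accessions():
                if other == acc:
                    continue
                orows = set(fragset.rows_of(other))
                if len(orows) >= 2 and orows <= side:
                    blocked_by.add(other)
        blockers[acc] = blocked_by
    circular = []
    for acc, g in candidates.items():
        b = blockers[acc]
        if not b:
            continue  # tree round would have merged it; leave alone
        if all(y in candidates and acc in blockers[y] for y in b):
            overlap = sum(
                _overlap_columns(fragset, a, c)
                for i, a in enumerate(g)
                for c in g[i + 1 :]
            )
            circular.append((-overlap, acc, g))
    if not circular:
        return None
    circular.sort()
    return circular[0][2]


def _overlap_groups(fragset: FragmentSet, rows: list, tolerance: int,
                    min_link: int):
    elig = {}
    for i, a in enumerate(rows):
        for b in rows[i + 1 :]:
            ok = (
                _overlap_columns(fragset, a, b) >= min_link
                and conflicts(fragset.alignment, a, b) <= tolerance
            )
            elig[(a, b)] = elig[(b, a)] = ok
    groups: list[list[str]] = []
    for r in rows:
        for g in groups:
            if all(elig[(r, m)] for m in g):
                g.append(r)
                break
        else:
            groups.append([r])
    return [tuple(g) for g in groups], set()


def _conflict_only_groups(fragset: FragmentSet, rows: list, tolerance: int):
    elig = {
        (a, b): conflicts(fragset.alignment, a, b) <= tolerance
        for i, a in enumerate(rows)
        for b in rows[i + 1 :]
    }
    elig.update({(b, a): v for (a, b), v in list(elig.items())})
    groups: list[list[str]] = []
    for r in rows:
        for g in groups:
            if all(elig[(r, m)] for m in g):
                g.append(r)
                break
        else:
            groups.append([r])
    member_of = {r: gi for gi, g in enumerate(groups) for r in g}
    arbitrary = {
        gi
        for (a, b), ok in elig.items()
        if ok and member_of[a] != member_of[b]
        for gi in (member_of[a], member_of[b])
    }
    return [tuple(g) for g in groups], arbitrary


@dataclass
class DuplicationReport:
    """Per-accession evidence for retained paralogs after merging."""

    entries: dict  # accession -> dict(tip_count, clade_size, foreign, flag)

    def flagged(self) -> list:
        return sorted(a for a, e in self.entries.items() if e["duplicated"])

    def tsv(self) -> str:
        lines = ["accession\ttip_count\tclade_size\tforeign_tips\tduplicated"]
        for a in sorted(self.entries):
            e = self.entries[a]
            lines.append(
                f"{a}\t{e['tip_count']}\t{e['clade_size']}\t{e['foreign']}"
                f"\t{'yes' if e['duplicated'] else 'no'}"
            )
        return "\n".join(lines) + "\n"


def flag_duplications(tree: PhyloTree, fragset: FragmentSet) -> DuplicationReport:
    """Flag accessions whose surviving rows spread beyond a private clade:
    >= 2 rows whose smallest spanning clade wholly contains at least one
    foreign accession.  Clade sizes are reported so the duplication depth
    can be judged by a human."""
    entries: dict[str, dict] = {}
    for acc in fragset.accessions():
        rows = fragset.rows_of(acc)
        if len(rows) < 2:
            entries[acc] = {
                "tip_count": len(rows), "clade_size": len(rows),
                "foreign": 0, "duplicated": False,
            }
            continue
        clade = smallest_spanning_clade(tree, set(rows))
        foreign = _worst_contained_foreign(tree, fragset, set(rows), acc)
        entries[acc] = {
            "tip_count": len(rows),
            "clade_size": len(clade),
            "foreign": foreign,
            "duplicated": foreign >= 1,
        }
    return DuplicationReport(entries)


def extract_copy_alignment(
    fragset: FragmentSet, tip_subset: list
) -> tuple:
    """Sub-alignment of the chosen rows with all-gap/missing columns
    dropped.  Returns (alignment, provenance) where provenance[j] is the
    parent column index of output column j."""
    if not tip_subset:
        raise ValueError("tip_subset must be nonempty")
    sub = fragset.alignment.take_rows(list(tip_subset))
    keep = [
        j for j in range(sub.ncols)
        if any(r.residues[j] not in (GAP, MISSING) for r in sub.rows)
    ]
    rows = [
        Sequence(r.id, "".join(r.residues[j] for j in keep),
                 accession=r.accession)
        for r in sub.rows
    ]
    colmeta = [sub.colmeta[j] for j in keep]
    return MultipleAlignment(rows=rows, colmeta=colmeta), keep


def select_copy(tree: PhyloTree, fragset: FragmentSet) -> list:
    """Pick the paralog copy with the greatest average ungapped length.

    Copies are taken as the two sides of the deepest bipartition that
    separates duplicate rows of flagged accessions; with no duplication
    every row is returned.  Within an accession, the longest row wins.
    """
    report = flag_duplications(tree, fragset)
    if not report.flagged():
        return _longest_per_accession(fragset, [r.id for r in fragset.rows])
    # score each bipartition side by average row length, prefer the side
    # that covers the most accessions, then the longest average
    best_side, best_key = None, None
    all_tips = set(r.id for r in fragset.rows)
    for side in _all_sides(tree, all_tips):
        accs = {fragset.accession_of(t) for t in side}
        lens = [len(fragset.alignment.row(t).ungapped()) for t in side]
        key = (len(accs), sum(lens) / len(lens))
        if best_key is None or key > best_key:
            best_key, best_side = key, side
    return _longest_per_accession(fragset, sorted(best_side))


def _all_sides(tree: PhyloTree, all_tips: set):
    from .trees import _clades

    seen = set()
    for node, clade in _clades(tree).items():
        for side in (frozenset(clade), frozenset(all_tips - clade)):
            if 0 < len(side) < len(all_tips) and side not in seen:
                seen.add(side)
                yield side


def _longest_per_accession(fragset: FragmentSet, ids: list) -> list:
    best: dict[str, str] = {}
    for rid in ids:
        acc = fragset.accession_of(rid)
        if acc not in best or (
            len(fragset.alignment.row(rid).ungapped())
            > len(fragset.alignment.row(best[acc]).ungapped())
        ):
            best[acc] = rid
    return [best[a] for a in sorted(best)]


def concat_loci(
    per_locus: dict,
    accession_universe: list,
) -> MultipleAlignment:
    """Concatenate per-locus alignments into a supermatrix.

    ``per_locus`` maps locus name -> MultipleAlignment whose rows are one
    per accession (row accession labels identify them).  Accessions absent
    from a locus get '?' filler; charsets record each locus range and
    colmeta carries the codon labels through.
    """
    parts: dict[str, list] = {a: [] for a in accession_universe}
    colmeta: list[str] = []
    charsets: dict[str, tuple] = {}
    offset = 0
    for name, aln in per_locus.items():
        by_acc: dict[str, Sequence] = {}
        for r in aln.rows:
            acc = r.accession or r.id
            if acc in by_acc:
                raise ValueError(
                    f"locus {name!r}: duplicate accession {acc!r}"
                )
            by_acc[acc] = r
        unknown = set(by_acc) - set(accession_universe)
        if unknown:
            raise ValueError(f"locus {name!r}: unknown accessions {unknown}")
        n = aln.ncols
        for a in accession_universe:
            parts[a].append(
                by_acc[a].residues if a in by_acc else MISSING * n
            )
        colmeta.extend(aln.colmeta)
        charsets[name] = (offset, offset + n)
        offset += n
    rows = [
        Sequence(a, "".join(parts[a]), accession=a)
        for a in accession_universe
    ]
    return MultipleAlignment(rows=rows, colmeta=colmeta, charsets=charsets)


def sets_block(aln: MultipleAlignment) -> str:
    """NEXUS-style sets block plus a plain partition text for the charsets
    (1-based inclusive; codon positions as start-end\\3 lines)."""
    lines = ["begin sets;"]
    for name, (a, b) in aln.charsets.items():
        lines.append(f"  charset {name} = {a + 1}-{b};")
    lines.append("end;")
    return "\n".join(lines) + "\n"
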