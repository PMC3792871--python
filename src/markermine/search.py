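"""Homolog harvesting against transcriptome contig pools.

A seeded local search plays the role an external BLAST would: exact-word
seeding on both strands followed by an exact affine-gap Smith-Waterman
restricted to subject/strand pairs that carry a seed.  Raw alignment
scores (match +1, mismatch -2, gap open -5, gap extend -2; a gap of
length L costs open + L*extend) replace E-values: no database-size model
is needed at this scale.  On top of that sit reciprocal ("nested")
search rounds, master-assembly overlap merging of two assembler variants
per accession, and the coverage-vs-redundancy quality score used to rank
candidate loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqcore import (
    CODE_OF_SET,
    IUPAC_SETS,
    MultipleAlignment,
    Sequence,
    revcomp_str,
)

__all__ = [
    "AssemblyPool",
    "HitSegment",
    "CandidateScore",
    "Scoring",
    "merge_assemblies",
    "seeded_search",
    "harvest",
    "score_candidate",
    "rank_candidates",
    "hits_to_alignment",
    "hits_table",
]


@dataclass
class AssemblyPool:
    """Per-accession contig pool, optionally tagged by source assembler."""

    accession: str
    contigs: list[Sequence] = field(default_factory=list)
    source: dict = field(default_factory=dict)  # contig id -> assembler tag

    def __post_init__(self):
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"pool {self.accession}: duplicate contig ids")
        for c in self.contigs:
            if not c.accession:
                c.accession = self.accession

    def get(self, contig_id: str) -> Sequence:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(contig_id)


@dataclass(frozen=True)
class HitSegment:
    """A local-alignment hit of a query against a pool contig.

    ``subject_interval`` and ``query_interval`` are 0-based half-open;
    subject coordinates are always on the forward strand of the contig.
    """

    query_id: str
    subject_id: str
    subject_interval: tuple
    query_interval: tuple
    strand: str
    score: float
    identity: float

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not (0 <= self.identity <= 1):
            raise ValueError("identity must be in [0, 1]")


@dataclass(frozen=True)
class Scoring:
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = 5.0   # positive penalties; gap of length L costs
    gap_extend: float = 2.0  # gap_open + L * gap_extend


# ---------------------------------------------------------------------------
# master-assembly merging


def _iupac_sets(s: str):
    return [IUPAC_SETS.get(c) for c in s]


def _best_ungapped_overlap(a: str, b: str, min_overlap: int,
                           min_identity: float):
    """Best compatible ungapped overlap of b against a over all offsets
    (including containment).  Returns (score_key, merged_string) or None.
    Every overlap position must be IUPAC-compatible; the exact-match
    fraction must reach ``min_identity``."""
    la, lb = len(a), len(b)
    sa, sb = _iupac_sets(a), _iupac_sets(b)
    best = None
    for off in range(-(lb - min_overlap), la - min_overlap + 1):
        lo_a, hi_a = max(0, off), min(la, off + lb)
        L = hi_a - lo_a
        if L < min_overlap:
            continue
        exact = 0
        merged_mid = []
        ok = True
        for i in range(lo_a, hi_a):
            x, y = sa[i], sb[i - off]
            inter = x & y
            if not inter:
                ok = False
                break
            if a[i] == b[i - off]:
                exact += 1
            merged_mid.append(CODE_OF_SET[inter])
        if not ok or exact / L < min_identity:
            continue
        key = (L, exact)
        if best is None or key > best[0]:
            left = a[:lo_a] if off >= 0 else b[: -off]
            right = a[hi_a:] if off + lb <= la else b[la - off :]
            best = (key, left + "".join(merged_mid) + right)
    return best


def merge_assemblies(
    poolA: AssemblyPool,
    poolB: AssemblyPool,
    min_overlap: int = 30,
    min_identity: float = 0.98,
) -> AssemblyPool:
    """Greedy overlap-consensus merge of two assemblies of one accession
    into a "master" assembly.

    Contig pairs whose best ungapped overlap (either order, either strand)
    is at least ``min_overlap`` long, fully IUPAC-compatible, and at least
    ``min_identity`` exact-identical are merged; compatible ambiguity is
    resolved to the intersection code.  Repeats until no merge applies;
    unmerged contigs pass through.
    """
    if poolA.accession != poolB.accession:
        raise ValueError(
            f"accession mismatch: {poolA.accession!r} vs {poolB.accession!r}"
        )
    if min_overlap < 20:
        raise ValueError("min_overlap must be >= 20")
    if not (0.9 <= min_identity <= 1.0):
        raise ValueError("min_identity must be in [0.9, 1]")

    work: list[Sequence] = [
        Sequence(c.id, c.residues, accession=c.accession)
        for c in poolA.contigs
    ]
    taken = {c.id for c in work}
    for c in poolB.contigs:
        # the two assemblers may reuse contig names; disambiguate
        cid = c.id if c.id not in taken else f"{c.id}#B"
        taken.add(cid)
        work.append(Sequence(cid, c.residues, accession=c.accession))
    source = dict(poolA.source)
    source.update(poolB.source)

    changed = True
    while changed:
        changed = False
        n = len(work)
        best = None  # (key, i, j, merged_residues)
        for i in range(n):
            for j in range(i + 1, n):
                for b_res in (work[j].residues, revcomp_str(work[j].residues)):
                    r = _best_ungapped_overlap(
                        work[i].residues, b_res, min_overlap, min_identity
                    )
                    if r and (best is None or r[0] > best[0]):
                        best = (r[0], i, j, r[1])
        if best is not None:
            _, i, j, merged = best
            new = Sequence(
                f"{work[i].id}|{work[j].id}", merged,
                accession=poolA.accession,
            )
            work = [c for k, c in enumerate(work) if k not in (i, j)]
            work.append(new)
            source[new.id] = "merged"
            changed = True
    return AssemblyPool(accession=poolA.accession, contigs=work, source=source)


# ---------------------------------------------------------------------------
# seeded local search


def _words(s: str, w: int):
    out: dict[str, list[int]] = {}
    for i in range(len(s) - w + 1):
        word = s[i : i + w]
        if set(word) <= set("ACGT"):
            out.setdefault(word, []).append(i)
    return out


def _sw_align(q: str, s: str, sc: Scoring):
    """Exact local affine-gap alignment (row-vectorized Smith-Waterman).

    Returns (score, qstart, qend, sstart, send, matches, aligned_cols) of
    the best-scoring local path, or None if the best score is 0.
    """
    m, n = len(q), len(s)
    qa = np.frombuffer(q.encode(), dtype=np.uint8)
    sa = np.frombuffer(s.encode(), dtype=np.uint8)
    go, ge = sc.gap_open, sc.gap_extend
    first_gap = go + ge

    H = np.zeros((m + 1, n + 1), dtype=np.float64)
    E = np.full((m + 1, n + 1), -np.inf)  # gap in subject (left moves)
    F = np.full((m + 1, n + 1), -np.inf)  # gap in query (up moves)
    jidx = np.arange(1, n + 1, dtype=np.float64)
    for i in range(1, m + 1):
        sub = np.where(sa == qa[i - 1], sc.match, sc.mismatch)
        diag = H[i - 1, :-1] + sub
        F[i, 1:] = np.maximum(H[i - 1, 1:] - first_gap, F[i - 1, 1:] - ge)
        h0 = np.maximum(0.0, np.maximum(diag, F[i, 1:]))
        # E via prefix max: gap-from-gap along a row never beats a fresh
        # open from the dominating cell, so E can be formed from h0 alone.
        a = h0 + ge * jidx
        pref = np.maximum.accumulate(a)
        E[i, 2:] = pref[:-1] - ge * jidx[1:] - first_gap + ge
        # (E[i, j] = max_{j'<j} h0[j'] - go - ge*(j-j'))
        H[i, 1:] = np.maximum(h0, E[i, 1:])

    best = np.unravel_index(np.argmax(H), H.shape)
    score = float(H[best])
    if score <= 0:
        return None
    i, j = best
    qend, send = i, j
    matches = 0
    cols = 0
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            diag = H[i - 1, j - 1] + (
                sc.match if q[i - 1] == s[j - 1] else sc.mismatch
            )
            if np.isclose(H[i, j], diag):
                matches += q[i - 1] == s[j - 1]
                cols += 1
                i -= 1
                j -= 1
            elif np.isclose(H[i, j], E[i, j]):
                state = "E"
            else:
                state = "F"
        elif state == "E":
            cols += 1
            j -= 1
            if np.isclose(E[i, j + 1], H[i, j] - first_gap):
                state = "H"
        else:
            cols += 1
            i -= 1
            if np.isclose(F[i + 1, j], H[i, j] - first_gap):
                state = "H"
    return score, i, qend, j, send, matches, cols


def seeded_search(
    query: Sequence,
    pool: AssemblyPool,
    word_size: int = 11,
    min_score: float = 40.0,
    scoring: Scoring = Scoring(),
) -> list[HitSegment]:
    """Seeded local search of one query against a contig pool.

    Exact ``word_size``-mers seed candidate subject/strand pairs; each
    seeded pair is aligned exactly under the affine scheme, and hits with
    score >= ``min_score`` are reported (best local path per
    subject/strand, which subsumes the overlap-merge de-duplication rule).
    """
    if word_size < 7:
        raise ValueError("word_size must be >= 7 in nucleotide mode")
    qwords = _words(query.residues, word_size)
    hits: list[HitSegment] = []
    for contig in pool.contigs:
        L = len(contig.residues)
        for strand in "+-":
            subj = (
                contig.residues if strand == "+"
                else revcomp_str(contig.residues)
            )
            swords = _words(subj, word_size)
            if not (qwords.keys() & swords.keys()):
                continue
            res = _sw_align(query.residues, subj, scoring)
            if res is None:
                continue
            score, qs, qe, ss, se, matches, cols = res
            if score < min_score:
                continue
            s_iv = (ss, se) if strand == "+" else (L - se, L - ss)
            hits.append(
                HitSegment(
                    query_id=query.id,
                    subject_id=contig.id,
                    subject_interval=s_iv,
                    query_interval=(qs, qe),
                    strand=strand,
                    score=score,
                    identity=matches / cols if cols else 0.0,
                )
            )
    hits.sort(key=lambda h: (-h.score, h.subject_id))
    return hits


def _dedupe(hits: list[HitSegment]) -> list[HitSegment]:
    """Merge overlapping hits on the same subject/strand, keeping the
    best-scoring segment."""
    out: list[HitSegment] = []
    for h in sorted(hits, key=lambda h: (h.subject_id, h.strand, -h.score)):
        merged = False
        for k, o in enumerate(out):
            if (
                o.subject_id == h.subject_id
                and o.strand == h.strand
                and h.subject_interval[0] < o.subject_interval[1]
                and o.subject_interval[0] < h.subject_interval[1]
            ):
                merged = True  # o has the better (or equal) score
                break
        if not merged:
            out.append(h)
    return out


def harvest(
    queries: list[Sequence],
    pools: list[AssemblyPool],
    rounds: int = 2,
    word_size: int = 11,
    min_score: float = 40.0,
    scoring: Scoring = Scoring(),
) -> dict:
    """Nested ("reciprocal") search: hits of round r become the queries of
    round r+1, accumulating per original query.  The hit set is monotone
    non-decreasing in ``rounds``."""
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    by_id = {p.accession: p for p in pools}
    if len(by_id) != len(pools):
        raise ValueError("duplicate pool accessions")

    def run(qs: list[Sequence]) -> list[HitSegment]:
        found = []
        for q in qs:
            for p in pools:
                found.extend(
                    seeded_search(q, p, word_size=word_size,
                                  min_score=min_score, scoring=scoring)
                )
        return found

    pool_of = {c.id: p for p in pools for c in p.contigs}
    result: dict[str, list[HitSegment]] = {}
    for query in queries:
        acc: list[HitSegment] = run([query])
        queried: set[str] = set()
        for _ in range(rounds - 1):
            # hit contigs become the next round's queries, whole
            frontier_ids = sorted(
                {h.subject_id for h in acc} - queried
            )
            if not frontier_ids:
                break
            queried.update(frontier_ids)
            next_queries = [
                pool_of[cid].get(cid) for cid in frontier_ids
            ]
            seen = {(h.subject_id, h.subject_interval) for h in acc}
            acc.extend(
                h for h in run(next_queries)
                if (h.subject_id, h.subject_interval) not in seen
            )
        # re-attribute every hit to the original query; de-duplication by
        # (subject, interval) happened during accumulation
        result[query.id] = [
            HitSegment(query.id, h.subject_id, h.subject_interval,
                       h.query_interval, h.strand, h.score, h.identity)
            for h in acc
        ]
    return result


# ---------------------------------------------------------------------------
# candidate-alignment quality scoring


@dataclass(frozen=True)
class CandidateScore:
    """Coverage-vs-redundancy score of a candidate locus alignment.

    Rewards broad representation across transcriptomes (T_h / T) and
    penalizes excess hits per represented transcriptome, the signature of
    paralogy and/or short contigs:
    score = T_h/T - lambda * (H / max(T_h, 1) - 1).
    """

    taxa_total: int
    taxa_hit: int
    total_hits: int
    score: float
    name: str = ""

    def __post_init__(self):
        if not (0 <= self.taxa_hit <= self.taxa_total):
            raise ValueError("need 0 <= taxa_hit <= taxa_total")
        if self.total_hits < self.taxa_hit:
            raise ValueError("total_hits must be >= taxa_hit")


def score_candidate(
    taxa_total: int,
    taxa_hit: int,
    total_hits: int,
    lam: float = 0.5,
    name: str = "",
) -> CandidateScore:
    if taxa_total == 0:
        raise ValueError("taxa_total must be positive")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    score = taxa_hit / taxa_total - lam * (
        total_hits / max(taxa_hit, 1) - 1.0
    )
    if taxa_hit == 0:
        score = 0.0
    return CandidateScore(taxa_total, taxa_hit, total_hits, score, name)


def rank_candidates(candidates: list[CandidateScore]) -> list[CandidateScore]:
    """Descending by score; ties broken by taxa_hit (more first), then name."""
    return sorted(
        candidates, key=lambda c: (-c.score, -c.taxa_hit, c.name)
    )


# ---------------------------------------------------------------------------
# hit stacking and reporting


def hits_to_alignment(
    query: Sequence,
    hits: list[HitSegment],
    pools: list[AssemblyPool],
    include_query: bool = False,
) -> MultipleAlignment:
    """Stack hit segments into a query-coordinate alignment.

    Each hit's subject segment (oriented to the query strand) is placed at
    its query interval, padded with '?' elsewhere — an ungapped projection
    suited to contigs without indels relative to the query frame.
    """
    pool_of = {c.id: p for p in pools for c in p.contigs}
    ncols = len(query.residues)
    rows: list[Sequence] = []
    if include_query:
        rows.append(Sequence(query.id, query.residues,
                             accession=query.accession))
    hits = _dedupe(hits)  # one row per subject/strand (best scoring)
    for h in hits:
        contig = pool_of[h.subject_id].get(h.subject_id)
        a, b = h.subject_interval
        seg = contig.residues[a:b]
        if h.strand == "-":
            seg = revcomp_str(seg)
        qs, qe = h.query_interval
        seg = seg[: qe - qs]
        row = "?" * qs + seg + "?" * (ncols - qs - len(seg))
        rows.append(
            Sequence(h.subject_id, row[:ncols],
                     accession=pool_of[h.subject_id].accession)
        )
    return MultipleAlignment(rows=rows)


def hits_table(hits: list[HitSegment]) -> str:
    """Tabular hit report (TSV, 1-based inclusive coordinates)."""
    lines = ["query\tsubject\tstrand\tstart\tend\tscore\tidentity"]
    for h in hits:
        a, b = h.subject_interval
        lines.append(
            f"{h.query_id}\t{h.subject_id}\t{h.strand}\t{a + 1}\t{b}"
            f"\t{h.score:g}\t{h.identity:.3f}"
        )
    return "\n".join(lines) + "\n"
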