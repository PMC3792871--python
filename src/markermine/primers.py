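"""Degenerate primer design on conserved alignment windows.

Covers the primer-design workflow: per-column conservation profiling,
minimal-IUPAC consensus primers, nearest-neighbor melting temperatures
(SantaLucia & Hicks 2004 unified parameters, entropic monovalent-salt
correction), hairpin and primer-dimer screens, exon-intron boundary
mapping from a genomic/cDNA reference pair (high gap-opening penalty,
boundaries refined to GT...AG splice signatures), and enumeration of
primer pairs whose amplicons bracket at least one intron.

Degenerate bases are handled by full enumeration of expansions (capped),
so per-expansion Tm extremes — the quantity that makes degenerate PCR
fail — are exact rather than averaged.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .seqcore import (
    CODE_OF_SET,
    GAP,
    IUPAC_SETS,
    MISSING,
    MultipleAlignment,
    revcomp_str,
)

__all__ = [
    "ThermoReport",
    "PrimerPair",
    "Intron",
    "IntronMap",
    "PrimerConstraints",
    "DesignResult",
    "conservation_profile",
    "consensus_primer",
    "degeneracy",
    "expansions",
    "tm_nn",
    "hairpin_screen",
    "dimer_screen",
    "map_introns",
    "project_introns",
    "design_pairs",
    "encode_pcr_program",
    "parse_pcr_program",
]

# SantaLucia & Hicks (2004) unified NN parameters: dH kcal/mol, dS cal/(mol K).
# Dinucleotides not listed equal their reverse complement.
_NN = {
    "AA": (-7.6, -21.3),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
for _d in list(_NN):
    _NN.setdefault(revcomp_str(_d), _NN[_d])
_INIT = (0.2, -5.7)
_INIT_AT = (2.2, 6.9)  # per A/T terminus; G/C termini contribute nothing
_SYM = (0.0, -1.4)
_R_GAS = 1.987  # cal/(mol K)

_COMP_SET = {
    code: frozenset({"A": "T", "C": "G", "G": "C", "T": "A"}[b] for b in s)
    for code, s in IUPAC_SETS.items()
}


# ---------------------------------------------------------------------------
# conservation and consensus


def conservation_profile(alignment: MultipleAlignment) -> np.ndarray:
    """Per-column conservation in [0, 1].

    A column scores the largest fraction of its present rows compatible
    with any single IUPAC code of set size <= 2; any gap in the column
    forces 0 (indel-prone sites make no primer).  '?' rows are ignored.
    """
    if alignment.nrows < 2:
        raise ValueError("need at least 2 rows")
    bases = "ACGT"
    candidates = [frozenset(b) for b in bases] + [
        frozenset(p) for p in itertools.combinations(bases, 2)
    ]
    out = np.zeros(alignment.ncols)
    for j in range(alignment.ncols):
        col = alignment.column(j)
        if GAP in col:
            continue
        present = [IUPAC_SETS[c] for c in col if c != MISSING]
        if not present:
            continue
        out[j] = max(
            sum(1 for s in present if s & cand) for cand in candidates
        ) / len(present)
    return out


def consensus_primer(alignment: MultipleAlignment, window: tuple) -> str:
    """Columnwise minimal IUPAC cover of the observed bases in a window.

    Rows entirely '?' across the window are ignored; a gap anywhere in the
    window refuses the design.
    """
    a, b = window
    if not (0 <= a < b <= alignment.ncols):
        raise ValueError("window out of bounds")
    rows = [
        r.residues[a:b]
        for r in alignment.rows
        if set(r.residues[a:b]) != {MISSING}
    ]
    out = []
    for j in range(b - a):
        union: frozenset = frozenset()
        for row in rows:
            c = row[j]
            if c == MISSING:
                continue
            if c == GAP:
                raise ValueError(
                    f"window contains an alignment gap at column {a + j}"
                )
            union = union | IUPAC_SETS[c]
        if not union:
            raise ValueError(f"no coverage at column {a + j}")
        out.append(CODE_OF_SET[union])
    return "".join(out)


def degeneracy(primer: str) -> int:
    """Number of distinct unambiguous sequences a degenerate primer encodes
    (product of per-site IUPAC set sizes)."""
    n = 1
    for c in primer.upper():
        if c in (GAP, MISSING):
            raise ValueError("primers cannot contain gaps")
        n *= len(IUPAC_SETS[c])
    return n


def expansions(primer: str, cap: int = 1024) -> list:
    """All unambiguous expansions of a degenerate primer (error above cap)."""
    d = degeneracy(primer)
    if d > cap:
        raise ValueError(
            f"degeneracy {d} exceeds cap {cap}; choose a narrower window"
        )
    pools = [sorted(IUPAC_SETS[c]) for c in primer.upper()]
    return ["".join(p) for p in itertools.product(*pools)]


# ---------------------------------------------------------------------------
# thermodynamics


def _tm_single(seq: str, na_mM: float, primer_nM: float) -> float:
    dh, ds = _INIT
    selfcomp = seq == revcomp_str(seq)
    for i in (0, -1):
        if seq[i] in "AT":
            dh += _INIT_AT[0]
            ds += _INIT_AT[1]
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    if selfcomp:
        dh += _SYM[0]
        ds += _SYM[1]
        k = primer_nM * 1e-9
    else:
        k = primer_nM * 1e-9 / 4.0
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM * 1e-3)
    return 1000.0 * dh / (ds + _R_GAS * math.log(k)) - 273.15


@dataclass(frozen=True)
class TmSummary:
    mean: float
    min: float
    max: float
    n_expansions: int


def tm_nn(primer: str, na_mM: float = 50.0, primer_nM: float = 500.0,
          cap: int = 1024) -> TmSummary:
    """Nearest-neighbor Tm (degrees C) of a possibly degenerate primer.

    Each expansion is evaluated against its exact complement; the summary
    reports mean/min/max over expansions.  Monovalent salt enters through
    the SantaLucia (1998) entropic correction; the duplex concentration
    term uses CT/4 (CT = ``primer_nM``) for non-self-complementary
    primers.
    """
    tms = [_tm_single(e, na_mM, primer_nM) for e in expansions(primer, cap)]
    return TmSummary(
        mean=float(np.mean(tms)), min=float(np.min(tms)),
        max=float(np.max(tms)), n_expansions=len(tms),
    )


def hairpin_screen(primer: str, min_stem: int = 4, min_loop: int = 3) -> tuple:
    """(flagged, best_stem_length): does any expansion fold back on itself
    with an antiparallel self-complementary stem >= min_stem and a loop of
    at least min_loop unpaired bases?

    Stem positions are distinct, so degenerate bases can be screened by
    pairwise set compatibility without enumerating expansions.
    """
    seq = primer.upper()
    n = len(seq)
    best = 0
    for i in range(n):
        for j in range(i + 2 * min_stem + min_loop - 1, n):
            # stem pairs (i + k) with (j - k), k = 0..L-1
            L = 0
            while (
                i + L < j - L - min_loop
                and bool(_COMP_SET[seq[i + L]] & IUPAC_SETS[seq[j - L]])
            ):
                L += 1
            best = max(best, L)
    return best >= min_stem, best


def dimer_screen(seq_a: str, seq_b: str, anchored_3prime: bool = False) -> float:
    """Best antiparallel complementarity score over all offsets.

    +1 per Watson-Crick-compatible pair (degenerate bases pair when any
    expansion does), plus a +1 bonus per contiguous complementary run of
    length >= 4.  The anchored variant only considers offsets where the 3'
    terminal base of ``seq_a`` is paired.  Self-dimer =
    ``dimer_screen(x, x)``.
    """
    a = seq_a.upper()
    b_rev = seq_b.upper()[::-1]  # antiparallel: read b 3'->5'
    la, lb = len(a), len(b_rev)
    best = 0.0
    for off in range(-(lb - 1), la):
        lo = max(0, off)
        hi = min(la, off + lb)
        if hi <= lo:
            continue
        paired = [
            bool(_COMP_SET[a[i]] & IUPAC_SETS[b_rev[i - off]])
            for i in range(lo, hi)
        ]
        if anchored_3prime and not (lo <= la - 1 < hi and paired[-1]):
            continue
        score = float(sum(paired))
        run = 0
        for p in paired + [False]:
            if p:
                run += 1
            else:
                if run >= 4:
                    score += 1
                run = 0
        best = max(best, score)
    return best


@dataclass(frozen=True)
class ThermoReport:
    """Thermodynamic screens for one primer."""

    degeneracy: int
    tm: TmSummary
    hairpin: bool
    hairpin_stem: int
    self_dimer: float
    self_dimer_3p: float

    def __post_init__(self):
        if self.degeneracy < 1:
            raise ValueError("degeneracy must be >= 1")
        if not (self.tm.min <= self.tm.mean <= self.tm.max):
            raise ValueError("Tm summary out of order")


def thermo_report(primer: str, na_mM: float = 50.0,
                  primer_nM: float = 500.0) -> ThermoReport:
    flag, stem = hairpin_screen(primer)
    return ThermoReport(
        degeneracy=degeneracy(primer),
        tm=tm_nn(primer, na_mM, primer_nM),
        hairpin=flag,
        hairpin_stem=stem,
        self_dimer=dimer_screen(primer, primer),
        self_dimer_3p=dimer_screen(primer, primer, anchored_3prime=True),
    )


# ---------------------------------------------------------------------------
# intron mapping


@dataclass(frozen=True)
class Intron:
    genomic_start: int
    genomic_end: int
    cdna_pos: int  # insertion point on the cDNA (0-based, before this base)
    donor: str
    acceptor: str

    @property
    def canonical(self) -> bool:
        return self.donor == "GT" and self.acceptor == "AG"

    @property
    def length(self) -> int:
        return self.genomic_end - self.genomic_start


@dataclass
class IntronMap:
    introns: list = field(default_factory=list)

    def __post_init__(self):
        spans = [(i.genomic_start, i.genomic_end) for i in self.introns]
        if spans != sorted(spans):
            raise ValueError("introns must be ordered")
        for (a, b), (c, d) in zip(spans, spans[1:]):
            if c < b:
                raise ValueError("intron spans must be disjoint")

    def __len__(self) -> int:
        return len(self.introns)

    def __iter__(self):
        return iter(self.introns)

    def gff3(self, seqid: str = "genomic") -> str:
        lines = ["##gff-version 3"]
        for k, i in enumerate(self.introns, 1):
            attr = (
                f"ID=intron{k};donor={i.donor};acceptor={i.acceptor};"
                f"canonical={'true' if i.canonical else 'false'}"
            )
            lines.append(
                f"{seqid}\tmarkermine\tintron\t{i.genomic_start + 1}"
                f"\t{i.genomic_end}\t.\t+\t.\t{attr}"
            )
        return "\n".join(lines) + "\n"


def map_introns(
    genomic: str,
    cdna: str,
    gap_open: float = 40.0,
    gap_extend: float = 0.5,
    min_intron: int = 20,
    shift_window: int = 6,
) -> IntronMap:
    """Locate introns by globally aligning a cDNA to its genomic copy.

    Uses a high gap-opening penalty so introns come out as single long
    cDNA-side gaps; runs >= ``min_intron`` are intron candidates.
    Boundaries are then shifted within +/- ``shift_window`` wherever the
    shift preserves the spliced exon sequence and lands on a GT donor and
    AG acceptor (smallest shift wins).
    """
    from Bio import Align

    genomic = genomic.upper().replace("U", "T")
    cdna = cdna.upper().replace("U", "T")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(genomic, cdna)[0]
    t_blocks, q_blocks = aln.aligned

    matched = sum(
        1
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks)
        for k in range(te - ts)
        if genomic[ts + k] == cdna[qs + k]
    )
    if len(cdna) == 0 or matched / len(cdna) < 0.5:
        raise ValueError(
            "genomic and cDNA references are too divergent to map introns"
        )

    introns = []
    for (ts, te), (ts2, _), (qe, _) in zip(
        t_blocks[:-1], t_blocks[1:], [(q[1], None) for q in q_blocks[:-1]]
    ):
        gap_len = ts2 - te
        if gap_len < min_intron:
            continue
        s, e, p = te, ts2, qe
        chosen = None
        for mag in range(shift_window + 1):
            for d in ([0] if mag == 0 else [mag, -mag]):
                s2, e2 = s + d, e + d
                if s2 < 0 or e2 > len(genomic):
                    continue
                if d > 0 and genomic[s:s2] != genomic[e:e2]:
                    continue
                if d < 0 and genomic[s2:s] != genomic[e2:e]:
                    continue
                if (
                    genomic[s2 : s2 + 2] == "GT"
                    and genomic[e2 - 2 : e2] == "AG"
                ):
                    chosen = (s2, e2, p + d)
                    break
            if chosen:
                break
        if chosen is None:
            chosen = (s, e, p)
        s2, e2, p2 = chosen
        introns.append(
            Intron(
                genomic_start=s2,
                genomic_end=e2,
                cdna_pos=p2,
                donor=genomic[s2 : s2 + 2],
                acceptor=genomic[e2 - 2 : e2],
            )
        )
    return IntronMap(introns=introns)


def project_introns(intron_map: IntronMap, cdna_row: str) -> list:
    """Alignment column of each intron insertion point.

    ``cdna_row`` is the aligned cDNA (or consensus) row; insertion points
    inside alignment gaps land on the nearest following non-gap column.
    """
    positions = [
        j for j, c in enumerate(cdna_row) if c not in (GAP, MISSING)
    ]
    cols = []
    for i in intron_map:
        p = i.cdna_pos
        if p >= len(positions):
            cols.append(len(cdna_row))
        else:
            cols.append(positions[p])
    return cols


# ---------------------------------------------------------------------------
# pair design


@dataclass
class PrimerConstraints:
    """Screening thresholds for primer pair enumeration (defaults are
    conventional PCR practice; all configurable)."""

    min_len: int = 18
    max_len: int = 32
    max_degeneracy: int = 96
    tm_min: float = 50.0
    tm_max: float = 68.0
    max_pair_tm_diff: float = 5.0
    product_min: int = 150
    product_max: int = 1200
    max_self_dimer: float = 16.0
    max_3p_dimer: float = 8.0
    max_hetero_dimer: float = 16.0
    min_conservation: float = 0.9
    max_candidates_per_side: int = 60
    na_mM: float = 50.0
    primer_nM: float = 500.0


@dataclass(frozen=True)
class PrimerPair:
    """A degenerate primer pair; both primers are written 5'->3', the
    reverse primer on the opposite strand."""

    name: str
    forward: str
    reverse: str
    fwd_window: tuple
    rev_window: tuple
    product_range: tuple
    anneal_c: int
    thermo_fwd: ThermoReport
    thermo_rev: ThermoReport
    hetero_dimer: float
    conservation: float

    def __post_init__(self):
        if not (self.fwd_window[1] <= self.rev_window[0]):
            raise ValueError("forward window must lie upstream of reverse")
        for p in (self.forward, self.reverse):
            if not (18 <= len(p) <= 32):
                raise ValueError("primer length must be 18-32")

    def pcr_program(self, elongation_s: int = 60, cycles: int = 35) -> str:
        return encode_pcr_program(self.anneal_c, elongation_s, cycles)


@dataclass
class DesignResult:
    pairs: list
    rejections: Counter


def _window_candidates(alignment, profile, cols_ok, cons: PrimerConstraints,
                       lo: int, hi: int, rejections: Counter):
    """Screened candidate windows within columns [lo, hi)."""
    out = []
    raw = []
    for start in range(lo, hi):
        for L in range(cons.min_len, cons.max_len + 1):
            end = start + L
            if end > hi:
                break
            if not cols_ok[start:end].all():
                rejections["conservation"] += 1
                continue
            try:
                seq = consensus_primer(alignment, (start, end))
            except ValueError:
                rejections["gapped_window"] += 1
                continue
            deg = degeneracy(seq)
            if deg > cons.max_degeneracy:
                rejections["degeneracy"] += 1
                continue
            raw.append((deg, -float(profile[start:end].sum()), start, end,
                        seq))
    # screen cheapest-to-amplify (least degenerate) windows first; the
    # final pair ranking restores conservation-first order
    raw.sort()
    for deg, neg_cons, start, end, seq in raw:
        cons_sum = -neg_cons
        rep = thermo_report(seq, cons.na_mM, cons.primer_nM)
        if not (cons.tm_min <= rep.tm.mean <= cons.tm_max):
            rejections["tm_range"] += 1
            continue
        if rep.hairpin:
            rejections["hairpin"] += 1
            continue
        if rep.self_dimer > cons.max_self_dimer:
            rejections["self_dimer"] += 1
            continue
        if rep.self_dimer_3p > cons.max_3p_dimer:
            rejections["self_dimer_3p"] += 1
            continue
        out.append((cons_sum, start, end, seq, rep))
        if len(out) >= cons.max_candidates_per_side:
            break
    return out


def design_pairs(
    alignment: MultipleAlignment,
    intron_columns: list,
    constraints: PrimerConstraints | None = None,
    name_prefix: str = "pair",
) -> DesignResult:
    """Enumerate primer pairs in conserved exonic windows bracketing at
    least one intron insertion point.

    Pairs passing every screen are ranked by (conservation sum,
    -degeneracy, -dimer score) lexicographically.  When nothing passes,
    the result carries per-constraint rejection counts.
    """
    cons = constraints or PrimerConstraints()
    if not intron_columns:
        raise ValueError("need at least one intron column to bracket")
    rejections: Counter = Counter()
    profile = conservation_profile(alignment)
    cols_ok = profile >= cons.min_conservation

    first_intron = min(intron_columns)
    last_intron = max(intron_columns)
    fwd = _window_candidates(
        alignment, profile, cols_ok, cons, 0, last_intron, rejections
    )
    rev = _window_candidates(
        alignment, profile, cols_ok, cons, first_intron + 1,
        alignment.ncols, rejections,
    )

    # per-row present-base counts for product size estimation
    present = np.array(
        [
            [c not in (GAP, MISSING) for c in r.residues]
            for r in alignment.rows
        ],
        dtype=np.int32,
    )
    cum = np.cumsum(present, axis=1)

    pairs = []
    for cf, fs, fe, fseq, frep in fwd:
        for cr, rs, re_, rseq_plus, rrep_plus in rev:
            if fe > rs:
                continue
            if not any(fe <= c <= rs for c in intron_columns):
                rejections["no_intron_bracketed"] += 1
                continue
            spans = cum[:, re_ - 1] - (cum[:, fs - 1] if fs else 0)
            covered = spans[spans > 0]
            if covered.size == 0:
                rejections["no_covered_rows"] += 1
                continue
            pmin, pmax = int(covered.min()), int(covered.max())
            if pmin < cons.product_min or pmax > cons.product_max:
                rejections["product_size"] += 1
                continue
            rseq = revcomp_str(rseq_plus)
            rrep = thermo_report(rseq, cons.na_mM, cons.primer_nM)
            if abs(frep.tm.mean - rrep.tm.mean) > cons.max_pair_tm_diff:
                rejections["pair_tm_diff"] += 1
                continue
            hd = dimer_screen(fseq, rseq)
            if hd > cons.max_hetero_dimer:
                rejections["hetero_dimer"] += 1
                continue
            anneal = int(round(min(frep.tm.mean, rrep.tm.mean) - 3))
            pairs.append(
                PrimerPair(
                    name="",
                    forward=fseq,
                    reverse=rseq,
                    fwd_window=(fs, fe),
                    rev_window=(rs, re_),
                    product_range=(pmin, pmax),
                    anneal_c=anneal,
                    thermo_fwd=frep,
                    thermo_rev=rrep,
                    hetero_dimer=hd,
                    conservation=cf + cr,
                )
            )
    pairs.sort(
        key=lambda p: (
            -p.conservation,
            p.thermo_fwd.degeneracy * p.thermo_rev.degeneracy,
            p.hetero_dimer,
            p.fwd_window,
        )
    )
    named = [
        PrimerPair(
            name=f"{name_prefix}{k + 1}",
            forward=p.forward, reverse=p.reverse,
            fwd_window=p.fwd_window, rev_window=p.rev_window,
            product_range=p.product_range, anneal_c=p.anneal_c,
            thermo_fwd=p.thermo_fwd, thermo_rev=p.thermo_rev,
            hetero_dimer=p.hetero_dimer, conservation=p.conservation,
        )
        for k, p in enumerate(pairs)
    ]
    return DesignResult(pairs=named, rejections=rejections)


def primer_table(pairs: list, elongation_s: int = 60,
                 cycles: int = 35) -> str:
    """TSV primer report (name, sequences, PCR program code)."""
    lines = ["name\tforward\treverse\tproduct_min\tproduct_max\tprogram"]
    for p in pairs:
        lines.append(
            f"{p.name}\t{p.forward}\t{p.reverse}\t{p.product_range[0]}"
            f"\t{p.product_range[1]}\t{p.pcr_program(elongation_s, cycles)}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# PCR program encoding (two digits annealing temperature, three digits
# elongation seconds, then cycle count)


def encode_pcr_program(anneal_c: int, elongation_s: int, cycles: int) -> str:
    if not (10 <= anneal_c <= 99):
        raise ValueError("annealing temperature must have two digits")
    if not (0 <= elongation_s <= 999):
        raise ValueError("elongation time must have at most three digits")
    return f"{anneal_c:02d}{elongation_s:03d}{cycles:d}"


def parse_pcr_program(code: str) -> tuple:
    """(annealing C, elongation s, cycles) from a program code like
    6512035 = 65 C annealing, 120 s elongation, 35 cycles."""
    if not code.isdigit() or len(code) < 6:
        raise ValueError(f"bad PCR program code {code!r}")
    return int(code[:2]), int(code[2:5]), int(code[5:])
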