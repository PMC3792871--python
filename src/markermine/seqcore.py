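"""Sequence and alignment data model: IUPAC algebra, FASTA I/O, ORF detection.

DNA residues are drawn from {A,C,G,T}, the eleven IUPAC ambiguity codes,
``-`` (alignment gap) and ``?`` (unsequenced/missing).  ``-`` and ``?`` are
distinct: a gap is an inferred indel, a question mark is absence of data;
both count as "missing" for summary statistics.  All coordinates in the
library are 0-based half-open; only human-readable reports convert to
1-based inclusive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "IUPAC_SETS",
    "CODE_OF_SET",
    "ALPHABET",
    "Sequence",
    "MultipleAlignment",
    "ORF",
    "FastaParseError",
    "NoORFError",
    "read_fasta",
    "write_fasta",
    "find_orfs",
    "longest_orf",
    "iupac_compatible",
    "revcomp",
    "revcomp_str",
]

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
CODE_OF_SET: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

GAP = "-"
MISSING = "?"
ALPHABET = frozenset(IUPAC_SETS) | {GAP, MISSING}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
    GAP: GAP, MISSING: MISSING,
}

# Bitmask encoding (A=1, C=2, G=4, T=8); gap/missing encode as the full set.
BITS: dict[str, int] = {
    code: sum({"A": 1, "C": 2, "G": 4, "T": 8}[b] for b in s)
    for code, s in IUPAC_SETS.items()
}
BITS[GAP] = 15
BITS[MISSING] = 15

_STOPS = {"TAA", "TAG", "TGA"}


class FastaParseError(ValueError):
    """Malformed FASTA input; message names the offending line."""


class NoORFError(ValueError):
    """Raised when an ORF is requested from a sequence containing none."""


def _normalize(residues: str) -> str:
    return residues.upper().replace("U", "T")


@dataclass
class Sequence:
    """A DNA sequence with an identifier and an organism/sample label."""

    id: str
    residues: str
    accession: str = ""

    def __post_init__(self) -> None:
        self.residues = _normalize(self.residues)
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: residues must be nonempty")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: illegal residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        """Residues with gaps and missing characters removed."""
        return self.residues.replace(GAP, "").replace(MISSING, "")


@dataclass
class MultipleAlignment:
    """Equal-length rows with optional codon labels and named column ranges.

    ``colmeta`` holds one label per column from {'1','2','3','N'}
    (codon positions or noncoding).  ``charsets`` maps locus names to
    0-based half-open column ranges and must be disjoint.
    """

    rows: list[Sequence]
    colmeta: list[str] | None = None
    charsets: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment needs at least one row")
        n = len(self.rows[0].residues)
        for r in self.rows:
            if len(r.residues) != n:
                raise ValueError(
                    f"row {r.id!r} has length {len(r.residues)}, expected {n}"
                )
        ids = [r.id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("row ids must be unique within an alignment")
        if self.colmeta is None:
            self.colmeta = ["N"] * n
        if len(self.colmeta) != n:
            raise ValueError("colmeta length must equal ncols")
        taken: set[int] = set()
        for name, (a, b) in self.charsets.items():
            if not (0 <= a <= b <= n):
                raise ValueError(f"charset {name!r} out of bounds")
            cols = set(range(a, b))
            if cols & taken:
                raise ValueError(f"charset {name!r} overlaps another charset")
            taken |= cols

    @property
    def ncols(self) -> int:
        return len(self.rows[0].residues)

    @property
    def nrows(self) -> int:
        return len(self.rows)

    def row(self, id_: str) -> Sequence:
        for r in self.rows:
            if r.id == id_:
                return r
        raise KeyError(id_)

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.rows)

    def take_rows(self, ids: list[str]) -> "MultipleAlignment":
        keep = [self.row(i) for i in ids]
        return MultipleAlignment(
            rows=keep, colmeta=list(self.colmeta), charsets=dict(self.charsets)
        )


@dataclass(frozen=True)
class ORF:
    """An open reading frame located on the forward strand of its source.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    input sequence; ``end`` includes the stop codon when one is present.
    ``open_ended`` marks ORFs that run off the sequence end without a stop
    (expected for fragmentary transcriptome contigs).
    """

    frame: int
    start: int
    end: int
    aa_length: int
    open_ended: bool = False


_HEADER_RE = re.compile(r"^>(\S+)(?:\s+(.*))?$")


def read_fasta(path: str | Path, accession: str | None = None) -> list[Sequence]:
    """Read a (possibly wrapped) multi-record FASTA file.

    Lowercase residues are uppercased and U is mapped to T.  Malformed
    headers or illegal residues raise :class:`FastaParseError` naming the
    line number.
    """
    records: list[Sequence] = []
    cur_id: str | None = None
    chunks: list[str] = []

    def _flush(lineno: int) -> None:
        if cur_id is None:
            return
        residues = "".join(chunks)
        if not residues:
            raise FastaParseError(f"line {lineno}: record {cur_id!r} has no residues")
        try:
            records.append(
                Sequence(cur_id, residues, accession=accession or "")
            )
        except ValueError as e:
            raise FastaParseError(f"near line {lineno}: {e}") from e

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                m = _HEADER_RE.match(line)
                if not m:
                    raise FastaParseError(f"line {lineno}: malformed header {line!r}")
                _flush(lineno)
                cur_id = m.group(1)
                chunks = []
            else:
                if cur_id is None:
                    raise FastaParseError(
                        f"line {lineno}: sequence data before any header"
                    )
                bad = set(_normalize(line)) - ALPHABET
                if bad:
                    raise FastaParseError(
                        f"line {lineno}: illegal characters {sorted(bad)}"
                    )
                chunks.append(line)
        _flush(lineno if cur_id is not None else 0)
    return records


def write_fasta(seqs: list[Sequence], path: str | Path, width: int = 80) -> None:
    """Write sequences as FASTA, wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def iupac_compatible(a: str, b: str) -> bool:
    """True iff the base sets of two residues intersect (R vs A, not R vs C)."""
    if a in (GAP, MISSING) or b in (GAP, MISSING):
        raise ValueError("gap/missing characters have no base set")
    try:
        return bool(IUPAC_SETS[a] & IUPAC_SETS[b])
    except KeyError as e:
        raise ValueError(f"not a DNA residue: {e}") from e


def revcomp_str(residues: str) -> str:
    residues = _normalize(residues)
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(residues))
    except KeyError as e:
        raise ValueError(f"not a DNA residue: {e}") from e


def revcomp(seq: Sequence) -> Sequence:
    """Reverse complement with IUPAC-aware base mapping; gaps preserved."""
    return Sequence(seq.id, revcomp_str(seq.residues), accession=seq.accession)


def _scan_frame(residues: str, offset: int, min_aa: int) -> list[tuple[int, int, int, bool]]:
    """Return (start, end, aa_length, open_ended) for maximal ORFs in one
    forward frame. Ambiguous codons translate as X: they are never a start
    and never a stop."""
    out = []
    start: int | None = None
    naa = 0
    i = offset
    L = len(residues)
    while i + 3 <= L:
        codon = residues[i : i + 3]
        if start is None:
            if codon == "ATG":
                start = i
                naa = 1
        else:
            if codon in _STOPS:
                if naa >= min_aa:
                    out.append((start, i + 3, naa, False))
                start = None
            else:
                naa += 1
        i += 3
    if start is not None and naa >= min_aa:
        out.append((start, i, naa, True))
    return out


def find_orfs(seq: Sequence | str, min_aa: int = 50) -> list[ORF]:
    """All maximal ATG-initiated ORFs in all six frames.

    ORFs may run off the 3' end without a stop codon (flagged
    ``open_ended``), reflecting partial transcriptome contigs.  Coordinates
    are always reported on the forward strand.  Results are sorted by
    ``aa_length`` descending, then start, then positive frame first.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    residues = seq.residues if isinstance(seq, Sequence) else _normalize(seq)
    L = len(residues)
    orfs: list[ORF] = []
    for off in range(3):
        for s, e, naa, open_ended in _scan_frame(residues, off, min_aa):
            orfs.append(ORF(frame=off + 1, start=s, end=e, aa_length=naa,
                            open_ended=open_ended))
    rc = revcomp_str(residues)
    for off in range(3):
        for s, e, naa, open_ended in _scan_frame(rc, off, min_aa):
            orfs.append(ORF(frame=-(off + 1), start=L - e, end=L - s,
                            aa_length=naa, open_ended=open_ended))
    orfs.sort(key=lambda o: (-o.aa_length, o.start, 0 if o.frame > 0 else 1))
    return orfs


def longest_orf(seq: Sequence | str) -> ORF:
    """The single longest ORF; ties break to smallest start, then positive
    frame. Raises :class:`NoORFError` if no ORF exists."""
    orfs = find_orfs(seq, min_aa=1)
    if not orfs:
        raise NoORFError("no ORF found in any frame")
    return orfs[0]


def orf_report(seqs: list[Sequence], min_aa: int = 50) -> str:
    """TSV table of ORFs (1-based inclusive coordinates for human eyes)."""
    lines = ["seq_id\tframe\tstart\tend\taa_length\topen_ended"]
    for s in seqs:
        for o in find_orfs(s, min_aa=min_aa):
            lines.append(
                f"{s.id}\t{o.frame}\t{o.start + 1}\t{o.end}\t{o.aa_length}"
                f"\t{'yes' if o.open_ended else 'no'}"
            )
    return "\n".join(lines) + "\n"
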