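"""Sequence-characterization statistics for marker regions.

Implements the difference-counting convention used for close species
pairs (every indel run counts as one "difference" regardless of length),
plus alignment-level summaries: percent variable sites and percent
missing characters (gaps or question marks).
"""

from __future__ import annotations

import pandas as pd

from .seqcore import GAP, IUPAC_SETS, MISSING, MultipleAlignment, Sequence

__all__ = [
    "pair_differences",
    "percent_variable",
    "percent_missing",
    "region_length",
    "variability_report",
]


def pair_differences(row_a: str, row_b: str) -> int:
    """Base differences between two aligned rows.

    Substitutions count per column where both residues are present and
    IUPAC-incompatible; each maximal run of columns where exactly one row
    is gapped counts once (one indel event, any length).  Columns with
    '?' in either row are skipped, so leading/trailing unsequenced
    overhangs never count.
    """
    if len(row_a) != len(row_b):
        raise ValueError(
            f"aligned rows must have equal length ({len(row_a)} vs {len(row_b)})"
        )
    diffs = 0
    in_gap_run = False
    for x, y in zip(row_a.upper(), row_b.upper()):
        if x == MISSING or y == MISSING:
            in_gap_run = False
            continue
        if (x == GAP) != (y == GAP):
            if not in_gap_run:
                diffs += 1
                in_gap_run = True
            continue
        in_gap_run = False
        if x == GAP and y == GAP:
            continue
        if not (IUPAC_SETS[x] & IUPAC_SETS[y]):
            diffs += 1
    return diffs


def percent_variable(alignment: MultipleAlignment) -> float:
    """Percentage of columns holding at least two mutually IUPAC-
    incompatible present residues."""
    if alignment.nrows < 2:
        raise ValueError("need at least 2 rows")
    variable = 0
    for j in range(alignment.ncols):
        sets = [
            IUPAC_SETS[c]
            for c in alignment.column(j)
            if c not in (GAP, MISSING)
        ]
        if any(
            not (sets[i] & sets[k])
            for i in range(len(sets))
            for k in range(i + 1, len(sets))
        ):
            variable += 1
    return 100.0 * variable / alignment.ncols


def percent_missing(alignment: MultipleAlignment) -> float:
    """Percentage of characters that are gaps or question marks."""
    total = alignment.nrows * alignment.ncols
    missing = sum(
        r.residues.count(GAP) + r.residues.count(MISSING)
        for r in alignment.rows
    )
    return 100.0 * missing / total


def region_length(row: Sequence | str) -> int:
    """Ungapped, sequenced length of one row (amplified-region length)."""
    res = row.residues if isinstance(row, Sequence) else row.upper()
    return len(res) - res.count(GAP) - res.count(MISSING)


def variability_report(
    alignment: MultipleAlignment,
    species_pairs: list,
) -> pd.DataFrame:
    """Region-by-species-pair difference table.

    Regions come from the alignment's charsets (the whole alignment if
    none are defined); ``species_pairs`` is a list of (row_id, row_id).
    """
    regions = alignment.charsets or {"all": (0, alignment.ncols)}
    rows = []
    for name, (a, b) in regions.items():
        rec: dict = {"region": name, "aligned_length": b - a}
        for (x, y) in species_pairs:
            ra = alignment.row(x).residues[a:b]
            rb = alignment.row(y).residues[a:b]
            rec[f"diff_{x}_vs_{y}"] = pair_differences(ra, rb)
            rec[f"len_{x}"] = region_length(ra)
            rec[f"len_{y}"] = region_length(rb)
        rows.append(rec)
    return pd.DataFrame(rows)
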