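"""Partitioning-scheme and substitution-model selection.

Data blocks (codon positions, loci, noncoding sites) are grouped into
subsets; each subset carries its own substitution model and rate
multiplier while branch lengths are shared across the whole alignment.
Schemes are compared by information criteria:

    AIC = -2 lnL + 2k        BIC = -2 lnL + k ln(n)

with n the total number of alignment sites.  The free-parameter
convention counts 2N-3 shared branch lengths for N taxa, S-1 subset rate
multipliers for S subsets, and per-subset model parameters (JC 0, K80 1,
HKY 4, GTR 8; +I and +G one each; base frequencies count as free).
Scheme search is exhaustive over all set partitions for few blocks, or a
greedy pairwise-merge heuristic for many.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .seqcore import MultipleAlignment, Sequence
from .trees import (
    PhyloTree,
    SubstModel,
    _compress,
    loglik_patterns,
    optimize_branch_lengths,
)

__all__ = [
    "DataBlock",
    "PartitionScheme",
    "ModelScore",
    "MODEL_BASE_PARAMS",
    "model_param_count",
    "parse_model_label",
    "count_free_params",
    "aic",
    "bic",
    "best_model_for_subset",
    "score_scheme",
    "exhaustive_schemes",
    "greedy_scheme_search",
    "read_partition_text",
    "write_partition_text",
    "blocks_from_charsets",
    "DEFAULT_CANDIDATES",
]

MODEL_BASE_PARAMS = {"JC": 0, "K80": 1, "HKY": 4, "GTR": 8}

DEFAULT_CANDIDATES = [
    f"{fam}{suffix}"
    for fam in ("JC", "K80", "HKY", "GTR")
    for suffix in ("", "+I", "+G", "+I+G")
]


@dataclass(frozen=True)
class DataBlock:
    """A named set of alignment columns (codon position, locus, ...)."""

    name: str
    columns: tuple
    kind: str = "locus"

    def __post_init__(self):
        if self.kind not in ("pos1", "pos2", "pos3", "noncoding", "locus"):
            raise ValueError(f"unknown block kind {self.kind!r}")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError(f"block {self.name!r}: duplicate columns")

    def __len__(self) -> int:
        return len(self.columns)


@dataclass(frozen=True)
class PartitionScheme:
    """Disjoint subsets of data blocks covering all blocks."""

    subsets: tuple  # tuple of tuples of DataBlock

    def __post_init__(self):
        names = [b.name for s in self.subsets for b in s]
        if len(set(names)) != len(names):
            raise ValueError("blocks must appear in exactly one subset")
        if not self.subsets:
            raise ValueError("need at least one subset")
        cols: set[int] = set()
        for s in self.subsets:
            for b in s:
                if cols & set(b.columns):
                    raise ValueError("subset columns overlap")
                cols |= set(b.columns)

    @property
    def n_subsets(self) -> int:
        return len(self.subsets)

    def subset_columns(self, i: int) -> tuple:
        cols: list[int] = []
        for b in self.subsets[i]:
            cols.extend(b.columns)
        return tuple(sorted(cols))


@dataclass(frozen=True)
class ModelScore:
    lnL: float
    k: int
    n: int
    aic: float
    bic: float

    def __post_init__(self):
        if not math.isclose(self.aic, -2 * self.lnL + 2 * self.k,
                            rel_tol=1e-9, abs_tol=1e-6):
            raise ValueError("AIC inconsistent with lnL and k")
        if not math.isclose(self.bic, -2 * self.lnL + self.k * math.log(self.n),
                            rel_tol=1e-9, abs_tol=1e-6):
            raise ValueError("BIC inconsistent with lnL, k and n")

    @classmethod
    def from_fit(cls, lnL: float, k: int, n: int) -> "ModelScore":
        return cls(lnL=lnL, k=k, n=n, aic=aic(lnL, k), bic=bic(lnL, k, n))


def aic(lnL: float, k: int) -> float:
    return -2.0 * lnL + 2.0 * k


def bic(lnL: float, k: int, n: int) -> float:
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * lnL + k * math.log(n)


def parse_model_label(label: str) -> tuple:
    """'GTR+I+G' -> ('GTR', True, True)."""
    parts = label.upper().split("+")
    family = parts[0]
    if family not in MODEL_BASE_PARAMS:
        raise ValueError(f"unknown model family {family!r}")
    flags = set(parts[1:])
    if flags - {"I", "G"}:
        raise ValueError(f"unknown model flags in {label!r}")
    return family, "I" in flags, "G" in flags


def model_param_count(model) -> int:
    """Free parameters of a substitution model (frequencies counted as
    free: 3 for HKY/GTR)."""
    if isinstance(model, SubstModel):
        family, plus_i, plus_g = model.family, model.plus_I, model.plus_G
    else:
        family, plus_i, plus_g = parse_model_label(model)
    return MODEL_BASE_PARAMS[family] + int(plus_i) + int(plus_g)


def count_free_params(scheme, subset_models: list, n_taxa: int) -> int:
    """Total free parameters: 2N-3 shared branch lengths, S-1 subset rate
    multipliers, and per-subset model parameters."""
    if isinstance(scheme, PartitionScheme):
        s = scheme.n_subsets
    else:
        s = int(scheme)
    if len(subset_models) != s:
        raise ValueError(
            f"{s} subsets but {len(subset_models)} models supplied"
        )
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    return (2 * n_taxa - 3) + (s - 1) + sum(
        model_param_count(m) for m in subset_models
    )


# ---------------------------------------------------------------------------
# subset model fitting


def _subset_alignment(alignment: MultipleAlignment, columns: tuple):
    return MultipleAlignment(
        rows=[
            Sequence(r.id, "".join(r.residues[j] for j in columns),
                     accession=r.accession)
            for r in alignment.rows
        ]
    )


def _empirical_freqs(aln: MultipleAlignment) -> tuple:
    counts = {b: 0 for b in "ACGT"}
    for r in aln.rows:
        for b in "ACGT":
            counts[b] += r.residues.count(b)
    tot = sum(counts.values())
    if tot == 0:
        return (0.25, 0.25, 0.25, 0.25)
    # small pseudocount keeps frequencies off the boundary
    return tuple((counts[b] + 1.0) / (tot + 4.0) for b in "ACGT")


def _build_model(family: str, plus_i: bool, plus_g: bool,
                 theta: np.ndarray, freqs: tuple) -> tuple:
    """(SubstModel, rate_scale) from the transformed parameter vector.

    Layout of theta: [log scale, family params..., log alpha?, logit p_inv?]
    """
    k = 0
    scale = math.exp(theta[k]); k += 1
    if family == "JC":
        rates = (1.0,) * 6
        fr = (0.25, 0.25, 0.25, 0.25)
    elif family == "K80":
        kappa = math.exp(theta[k]); k += 1
        rates = (1.0, kappa, 1.0, 1.0, kappa, 1.0)
        fr = (0.25, 0.25, 0.25, 0.25)
    elif family == "HKY":
        kappa = math.exp(theta[k]); k += 1
        rates = (1.0, kappa, 1.0, 1.0, kappa, 1.0)
        fr = freqs
    else:  # GTR
        rs = [math.exp(t) for t in theta[k : k + 5]]; k += 5
        rates = (*rs, 1.0)
        fr = freqs
    alpha = 1.0
    p_inv = 0.0
    if plus_g:
        alpha = math.exp(theta[k]); k += 1
    if plus_i:
        p_inv = 0.95 / (1.0 + math.exp(-theta[k])); k += 1
    model = SubstModel(
        family=family, rates=rates, freqs=fr,
        plus_I=plus_i, plus_G=plus_g, p_inv=p_inv, alpha=alpha,
    )
    return model, scale


def _n_theta(family: str, plus_i: bool, plus_g: bool) -> int:
    n = 1 + {"JC": 0, "K80": 1, "HKY": 1, "GTR": 5}[family]
    return n + int(plus_g) + int(plus_i)


def fit_subset_model(
    columns: tuple,
    alignment: MultipleAlignment,
    tree: PhyloTree,
    label: str,
) -> dict:
    """ML fit of one substitution model (plus a subset rate multiplier) to
    a column subset, holding tree and branch lengths fixed.

    Returns {'model', 'scale', 'lnL', 'label'}.
    """
    family, plus_i, plus_g = parse_model_label(label)
    sub = _subset_alignment(alignment, columns)
    masks, counts = _compress(sub)
    freqs = _empirical_freqs(sub)

    def neg(theta: np.ndarray) -> float:
        model, scale = _build_model(family, plus_i, plus_g, theta, freqs)
        try:
            return -loglik_patterns(tree, masks, counts, model, scale)
        except (ValueError, FloatingPointError):
            return 1e12

    x0 = np.zeros(_n_theta(family, plus_i, plus_g))
    if plus_g:
        # log alpha start at 0 (alpha = 1)
        pass
    if plus_i:
        x0[-1] = -2.0  # p_inv ~ 0.1
    res = minimize(neg, x0, method="L-BFGS-B",
                   options={"maxiter": 200, "ftol": 1e-9})
    model, scale = _build_model(family, plus_i, plus_g, res.x, freqs)
    return {"model": model, "scale": scale, "lnL": -res.fun, "label": label}


def best_model_for_subset(
    columns: tuple,
    alignment: MultipleAlignment,
    tree: PhyloTree,
    candidates: list | None = None,
) -> dict:
    """Fit each candidate model to the subset (shared tree) and return the
    minimum-AIC fit; ties break toward fewer parameters."""
    cands = candidates or DEFAULT_CANDIDATES
    if not cands:
        raise ValueError("candidate list must be nonempty")
    fits = []
    for label in cands:
        fit = fit_subset_model(columns, alignment, tree, label)
        k = model_param_count(label)
        fits.append((aic(fit["lnL"], k), k, label, fit))
    fits.sort(key=lambda t: (t[0], t[1], t[2]))
    return fits[0][3]


def score_scheme(
    scheme: PartitionScheme,
    alignment: MultipleAlignment,
    tree: PhyloTree,
    subset_models: list | None = None,
    candidates: list | None = None,
) -> tuple:
    """Score a partitioning scheme on a fixed tree.

    Branch lengths are shared; each subset gets its own substitution
    model (given as labels, else chosen per subset by AIC) and rate
    multiplier, optimized by ML.  Returns (ModelScore, fits) where fits
    is a list of per-subset fit dicts with multipliers normalized to a
    site-weighted mean of 1.
    """
    if subset_models is not None and len(subset_models) != scheme.n_subsets:
        raise ValueError("one model per subset required")
    fits = []
    for i in range(scheme.n_subsets):
        cols = scheme.subset_columns(i)
        if not cols:
            raise ValueError(f"subset {i} is empty")
        if subset_models is None:
            fit = best_model_for_subset(cols, alignment, tree, candidates)
        else:
            fit = fit_subset_model(cols, alignment, tree, subset_models[i])
        fit = dict(fit)
        fit["columns"] = cols
        fits.append(fit)
    lens = np.array([len(f["columns"]) for f in fits], dtype=float)
    scales = np.array([f["scale"] for f in fits])
    mean_rate = float((lens * scales).sum() / lens.sum())
    for f in fits:
        f["multiplier"] = f["scale"] / mean_rate
    lnl = sum(f["lnL"] for f in fits)
    k = count_free_params(scheme, [f["model"] for f in fits],
                          n_taxa=len(tree.tip_labels()))
    return ModelScore.from_fit(lnl, k, alignment.ncols), fits


# ---------------------------------------------------------------------------
# scheme search


def _set_partitions(items: list):
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[head] + part[i]] + part[i + 1 :]
        yield [[head]] + part


def exhaustive_schemes(blocks: list):
    """Every set partition of the blocks exactly once (Bell-number many).
    Guarded at 8 blocks; beyond that use the greedy search."""
    if len(blocks) > 8:
        raise ValueError(
            f"{len(blocks)} blocks is too many for exhaustive enumeration; "
            "use greedy_scheme_search"
        )
    if not blocks:
        raise ValueError("need at least one block")
    for part in _set_partitions(list(blocks)):
        yield PartitionScheme(subsets=tuple(tuple(s) for s in part))


def _prepare_tree(tree: PhyloTree, alignment: MultipleAlignment):
    has_lengths = all(
        n.length is not None for n in tree.postorder() if n is not tree.root
    )
    if has_lengths:
        return tree
    base = SubstModel.gtr(
        rates=(1.0,) * 6, freqs=_empirical_freqs(alignment),
        plus_G=True, alpha=1.0,
    )
    fitted, _ = optimize_branch_lengths(tree, alignment, base, tol=1e-3)
    return fitted


def greedy_scheme_search(
    blocks: list,
    alignment: MultipleAlignment,
    tree: PhyloTree,
    criterion: str = "BIC",
    candidates: list | None = None,
) -> tuple:
    """Greedy pairwise-merge scheme search.

    Starts fully split (one subset per block, best AIC model each), then
    repeatedly applies the subset merge that most improves the criterion;
    stops when no merge improves.  Deterministic.  Returns
    (PartitionScheme, fits, ModelScore).
    """
    if criterion not in ("AIC", "BIC"):
        raise ValueError("criterion must be 'AIC' or 'BIC'")
    tree = _prepare_tree(tree, alignment)
    n_taxa = len(tree.tip_labels())
    n_sites = alignment.ncols
    cache: dict[frozenset, dict] = {}

    def fit_group(group: tuple) -> dict:
        key = frozenset(b.name for b in group)
        if key not in cache:
            cols = tuple(sorted(c for b in group for c in b.columns))
            cache[key] = best_model_for_subset(cols, alignment, tree,
                                               candidates)
        return cache[key]

    def value(groups: list) -> float:
        lnl = sum(fit_group(g)["lnL"] for g in groups)
        k = count_free_params(
            len(groups), [fit_group(g)["model"] for g in groups], n_taxa
        )
        return aic(lnl, k) if criterion == "AIC" else bic(lnl, k, n_sites)

    groups = [tuple([b]) for b in blocks]
    cur = value(groups)
    while len(groups) > 1:
        best_pair, best_val = None, cur
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                trial = (
                    [g for k_, g in enumerate(groups) if k_ not in (i, j)]
                    + [tuple(groups[i] + groups[j])]
                )
                v = value(trial)
                if v < best_val - 1e-9:
                    best_val, best_pair = v, (i, j)
        if best_pair is None:
            break
        i, j = best_pair
        merged = tuple(groups[i] + groups[j])
        groups = [g for k_, g in enumerate(groups) if k_ not in (i, j)]
        groups.append(merged)
        cur = best_val
    scheme = PartitionScheme(subsets=tuple(groups))
    models = [fit_group(g)["label"] for g in groups]
    score, fits = score_scheme(scheme, alignment, tree, subset_models=models)
    return scheme, fits, score


def exhaustive_scheme_search(
    blocks: list,
    alignment: MultipleAlignment,
    tree: PhyloTree,
    criterion: str = "BIC",
    candidates: list | None = None,
) -> tuple:
    """Best scheme over all set partitions (small block counts only)."""
    tree = _prepare_tree(tree, alignment)
    n_taxa = len(tree.tip_labels())
    n_sites = alignment.ncols
    cache: dict[frozenset, dict] = {}

    def fit_group(group: tuple) -> dict:
        key = frozenset(b.name for b in group)
        if key not in cache:
            cols = tuple(sorted(c for b in group for c in b.columns))
            cache[key] = best_model_for_subset(cols, alignment, tree,
                                               candidates)
        return cache[key]

    best = None
    for scheme in exhaustive_schemes(blocks):
        lnl = sum(fit_group(g)["lnL"] for g in scheme.subsets)
        k = count_free_params(
            scheme, [fit_group(g)["model"] for g in scheme.subsets], n_taxa
        )
        v = aic(lnl, k) if criterion == "AIC" else bic(lnl, k, n_sites)
        if best is None or v < best[0]:
            best = (v, scheme)
    _, scheme = best
    models = [fit_group(g)["label"] for g in scheme.subsets]
    score, fits = score_scheme(scheme, alignment, tree, subset_models=models)
    return scheme, fits, score


# ---------------------------------------------------------------------------
# partition text I/O ("pos1 = 1-9007\3" dialect, 1-based inclusive)


_RANGE_RE = re.compile(r"^(\d+)-(\d+)(?:\\(\d+))?$")


def read_partition_text(text: str, kind_default: str = "locus") -> list:
    """Parse data-block definitions like ``pos1 = 1-9007\\3;``.

    Each line is ``name = range[, range...]`` with ranges 1-based
    inclusive, optionally stepped with ``\\step``.  Returns DataBlocks.
    """
    blocks = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip().rstrip(";")
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'name = ranges'")
        name, ranges = (p.strip() for p in line.split("=", 1))
        cols: list[int] = []
        for part in ranges.split(","):
            m = _RANGE_RE.match(part.strip())
            if not m:
                raise ValueError(f"line {lineno}: bad range {part.strip()!r}")
            a, b, step = int(m.group(1)), int(m.group(2)), m.group(3)
            step = int(step) if step else 1
            if a < 1 or b < a:
                raise ValueError(f"line {lineno}: bad range bounds")
            cols.extend(range(a - 1, b, step))
        kind = kind_default
        low = name.lower()
        for k in ("pos1", "pos2", "pos3", "noncoding"):
            if k in low:
                kind = k
        blocks.append(DataBlock(name=name, columns=tuple(cols), kind=kind))
    return blocks


def write_partition_text(blocks: list) -> str:
    """Serialize blocks back to the plain partition dialect (detects
    uniform-step column sets and writes the ``\\step`` shorthand)."""
    lines = []
    for b in blocks:
        cols = sorted(b.columns)
        steps = {j - i for i, j in zip(cols, cols[1:])}
        if len(cols) == 1:
            rng = f"{cols[0] + 1}-{cols[0] + 1}"
        elif len(steps) == 1:
            step = steps.pop()
            end = cols[-1] + 1
            rng = (
                f"{cols[0] + 1}-{end}" if step == 1
                else f"{cols[0] + 1}-{end}\\{step}"
            )
        else:
            rng = ", ".join(f"{c + 1}-{c + 1}" for c in cols)
        lines.append(f"{b.name} = {rng};")
    return "\n".join(lines) + "\n"


def blocks_from_charsets(
    alignment: MultipleAlignment, by_codon: bool = False
) -> list:
    """DataBlocks from an alignment's charsets: one per locus, or one per
    codon position pooled across loci plus one noncoding block."""
    if not alignment.charsets:
        raise ValueError("alignment has no charsets")
    if not by_codon:
        return [
            DataBlock(name=name, columns=tuple(range(a, b)), kind="locus")
            for name, (a, b) in alignment.charsets.items()
        ]
    pools: dict[str, list] = {"pos1": [], "pos2": [], "pos3": [],
                              "noncoding": []}
    for j, lab in enumerate(alignment.colmeta):
        key = {"1": "pos1", "2": "pos2", "3": "pos3"}.get(lab, "noncoding")
        pools[key].append(j)
    return [
        DataBlock(name=k, columns=tuple(v), kind=k if k != "noncoding"
                  else "noncoding")
        for k, v in pools.items()
        if v
    ]
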