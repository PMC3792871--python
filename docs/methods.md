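# Methods

`markermine` develops single-copy nuclear phylogenetic markers from
fragmentary per-species transcriptome assemblies.  This note documents
the models and procedures it implements, the parameters that matter, the
synthetic data regime used to validate the pipeline, and the design
choices made where the problem was genuinely open.

## Homolog harvesting (`search`)

Queries (coding sequences or their longest ORFs, module `seqcore`) are
searched against per-accession contig pools with a seeded local aligner:
exact word seeds (default word size 11) on both strands nominate
subject/strand pairs, and every nominated pair is then aligned with an
exact affine-gap Smith–Waterman (match +1, mismatch −2, gap open −5,
gap extend −2; a gap of length L costs `open + L·extend`).  The DP is
row-vectorized; the within-row gap dependency is resolved by a
prefix-max scan, which is exact because a gap opened from a gap-derived
cell never beats opening from the dominating cell directly.  Raw score
thresholds (default 40) replace E-values: at desk scale there is no
database-size model worth fitting.  "Nested" searching re-queries each
hit contig in full against all pools, so homologs reachable only through
an intermediate taxon are recovered; the hit set is monotone in the
number of rounds.

Two assembler variants of one accession can be merged into a master
assembly by greedy ungapped overlap consensus: an overlap qualifies when
it is at least `min_overlap` (default 30) columns, every position is
IUPAC-compatible, and the exact-match fraction reaches `min_identity`
(default 0.98); compatible ambiguity resolves to the set intersection.

Candidate loci are ranked by `score = T_h/T − λ·(H/max(T_h,1) − 1)`
(T taxa total, T_h taxa hit, H total hits, λ default 0.5): broad taxon
coverage is rewarded; many hits per taxon — the signature of paralogy or
very short contigs — is penalized.  The functional form is this
package's concretization; only the two monotonicity directions are
externally constrained.

## Phylogenetic engines (`trees`)

*Parsimony.*  Fitch scoring treats IUPAC codes as state sets and
gaps/missing as the full set, vectorized over unique column patterns.
The heuristic search uses random stepwise addition, NNI hill-climbing,
and subtree pruning–regrafting (SPR) sweeps in which candidate
reinsertion edges are ranked by an up/down-pass Fitch edge-set bound and
only the best few are re-scored exactly; an optional parsimony ratchet
(upweight a random quarter of the patterns ×4, re-climb, restore)
escapes coordinated local optima.  SPR and the ratchet are essential
here, not a luxury: alignments of fragments covering disjoint column
spans drive stepwise addition toward *region-clustered* trees, and NNI
provably cannot cross from those to the better taxon-clustered optima
(we verified by brute force that such local optima admit no improving
NNI or single-SPR move even when a better tree exists).

*Likelihood.*  Felsenstein pruning under JC/K80/HKY/GTR with optional
+I and +G.  Discrete gamma uses 4 equal-probability categories with
category means (not medians) normalized to average 1 over the variable
classes; with +I no additional rescaling by 1 − p_inv is applied, so
branch lengths are in expected substitutions per *variable* site when
p_inv > 0.  Transition matrices come from the symmetrized
eigendecomposition of the reversible rate matrix, scaled to one expected
substitution per unit time.  Ambiguity codes contribute the union of
their compatible states; gaps and `?` are marginalized.  Branch lengths
are optimized by round-robin bounded 1-D search until the log-likelihood
improves by less than 1e-4, with a monotone lnL trace.  The nonparametric
bootstrap resamples columns with replacement and tallies bipartition
frequencies.  The sequence simulator draws root states from the
stationary frequencies and mutates along branches; it produces no
indels, which is what makes exact truth-checking of the merge protocol
possible.

Neighbor joining is delegated to scikit-bio (three taxa use the
closed-form three-point formulas); newick parsing is delegated to
dendropy.

## Fragment merging and paralog handling (`merge`)

The iterative protocol alternates tree inference (maximum parsimony with
a fixed seed) with grouping: rows of one accession merge when they are
conflict-free (no column where both are present with disjoint IUPAC
sets) and *closely related* in the current tree.  Closeness is
concretized as follows: a pair is vetoed only when one of its
minimum-size spanning sides (all ties inspected, worst case taken)
wholly contains a foreign accession that itself still has ≥ 2 rows.
The rationale: a lone fragment drifting into a clade carries no
placement information (rows with little overlapping data move at zero
parsimony cost), and a completed single-row neighbor between
near-identical tips is not paralogy evidence either; what marks real
copy structure is the *same split repeated in another taxon*.

Two stall-breaking mechanisms run only when a tree round merges
nothing.  First, rows sharing a compatible overlap of ≥ `min_link`
(default 20) columns merge on that direct sequence evidence.  Second,
circular deadlocks dissolve: when accession X is blocked only by split
accession Y and Y only by X (all pairs internally conflict-free), the
paralogy evidence is mutual-only; the group with the largest internal
overlap merges and the tree is re-inferred.  True duplications survive
both mechanisms because overlapping paralogous copies conflict, which
removes them from the "trying to merge" set and breaks the cycle.

When an accession's rows admit more than one conflict-free pairing that
the tree cannot separate (two 5' and two 3' fragments, mutually
conflicting within each end), pairing is resolved in input order and
every product is flagged as a potential chimera; the flag propagates
through later merges.  Duplication flagging reuses the same machinery:
an accession is reported duplicated when ≥ 2 of its surviving rows span
a clade wholly containing a split foreign accession, with clade sizes
reported so a human can judge the duplication depth.

Copy extraction drops all-gap columns and keeps a provenance map to
parent coordinates; supermatrix concatenation inserts `?` blocks for
absent accession×locus cells and carries charsets and codon labels
through.

*Known limitation.*  A duplication whose copies share no overlapping
columns (and hence no conflicts anywhere) is undetectable in principle;
any merger of such rows may be chimeric.  This is the same disclosure
the underlying protocol makes for its arbitrary merges.

## Primer design (`primers`)

Conservation per column is the largest fraction of present rows
compatible with any IUPAC code of set size ≤ 2; a gap anywhere forces 0.
Consensus primers take the columnwise minimal IUPAC cover of observed
bases.  Melting temperatures use the SantaLucia & Hicks (2004) unified
nearest-neighbor parameters with the SantaLucia (1998) entropic
monovalent-salt correction and a CT/4 duplex term (defaults 50 mM Na+,
500 nM primer); degenerate primers are handled by full enumeration of
expansions (cap 1024) so per-expansion Tm extremes — the quantity that
makes degenerate PCR fail — are exact rather than averaged.  Hairpins
are screened by antiparallel stem search (stem ≥ 4, loop ≥ 3; degenerate
bases by pairwise set compatibility, which is exact because stem
positions are distinct); dimers score +1 per Watson–Crick-compatible
pair over all antiparallel offsets with a +1 bonus per run ≥ 4, with a
3'-anchored variant.

Exon–intron boundaries come from globally aligning a cDNA to its
genomic counterpart with a high gap-opening penalty (40; match +1,
mismatch −1, gap extend −0.5, via Biopython's PairwiseAligner) so each
intron emerges as one long cDNA-side gap (≥ 20 nt).  Boundaries are then
shifted within ±6 nt wherever the shift preserves the spliced exon
sequence and lands on a GT donor and AG acceptor, smallest shift first.
Pair enumeration screens conserved exonic windows (length 18–32,
degeneracy ≤ 96, Tm 50–68 °C, pair ΔTm ≤ 5, product 150–1200 nt by
per-row present-base counts, hairpin/dimer thresholds) on both sides of
at least one intron insertion point; candidates are screened in order of
increasing degeneracy (cheapest to amplify first) and final pairs are
ranked by conservation sum, then total degeneracy, then dimer score.
PCR programs are encoded in the compact seven-digit form
(two-digit annealing °C, three-digit elongation seconds, cycle count).

## Variability metrics (`metrics`)

Pairwise differences count one per column with incompatible present
residues plus one per maximal run where exactly one row is gapped — an
indel of any length is a single difference.  Columns with `?` in either
row are skipped, so unsequenced overhangs never count.  Percent-variable
uses pairwise IUPAC incompatibility within columns; percent-missing
counts gaps and question marks together.

## Partitioned model selection (`partition`)

AIC = −2lnL + 2k and BIC = −2lnL + k·ln(n) with n the total alignment
length.  Free parameters follow the convention that uniquely reproduces
the published counts (37 unpartitioned, 68 by-position, 15 taxa): JC 0,
K80 1, HKY 4, GTR 8 (frequencies counted as free), +I and +G one each;
2N−3 branch lengths shared across subsets; S−1 subset rate multipliers.
Branch lengths are estimated once on the full alignment (GTR+G); each
subset then gets its own substitution model (chosen per subset by AIC
from a JC/K80/HKY/GTR × {+I, +G} ladder, ties to fewer parameters) and
rate multiplier, optimized by L-BFGS-B over log/logit-transformed
parameters with empirical base frequencies as point estimates.
Multipliers are reported normalized to a site-weighted mean of 1; since
branch lengths stay fixed during subset fits, the mean-1 constraint is
applied as a post-hoc normalization rather than inside the optimizer.
Scheme search is exhaustive over all set partitions up to 8 blocks
(Bell-number enumeration) and greedy pairwise merging beyond, with fits
cached per block subset.

## Synthetic data (`simdata`) — what it emulates and what it does not

The generator produces the data regime the pipeline faces: a Yule
species tree (the simulator's stop-at-n-th-speciation artifact of
zero-length terminal branches is corrected by adding the Exp(nλ)
waiting time to the next event), gene families with Poisson duplications
and per-tip copy loss, transcripts evolved under HKY (κ = 2.5, mildly
AT-rich frequencies) with a mean root-to-tip divergence of 0.1
substitutions/site — representative of the conserved single-copy coding
loci this mining strategy targets — introns inserted at fixed homologous
points with GTAAG/TTCAG consensus splice signals and interiors evolving
2.5× faster, transcripts broken into ~3 fragments with ~N(35, 10)-nt
overlaps (occasionally negative, leaving coverage gaps), 10% per
accession×family dropout, optional second contig sets with shifted
breakpoints, and random strand flips.  Every contig is a verbatim
substring of a true transcript and the truth ledger maps it back, so
merging can be scored to the residue.

What the generator does *not* emulate — and therefore what passing
tests do not demonstrate about real data: sequencing and assembly
errors, chimeric misassemblies, alignment-error indels (simulated
evolution is substitution-only, so hit stacking is ungapped and exact),
expression-dependent coverage, allelic variation, and intron length
variation among taxa within one intron.  Real transcriptome work will
see merge conflicts at sequencing-error rates (the `tolerance` knob
exists for exactly this) and alignment uncertainty the synthetic tests
never exercise.

## Problem sizes used by the default test run and acceptance script

Pipeline closure runs 15 taxa × 20 families (tests) or 10 families
(acceptance script) with 600-nt transcripts; oracle equivalence uses 200
random parsimony instances (≤ 6 tips), 100 seeded-aligner instances
(≤ 200 nt), and 4-block scheme searches with 400-site blocks; parameter
recovery uses 10^5-site simulations.  These sizes are the package's
validation choices: large enough that consistent estimators sit inside
their stated tolerances, small enough to run routinely.
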