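# Methods

This note documents the models and procedures the package implements, the
choices made where the design was open, and what the synthetic data do and
do not establish.

## Structural alignment

The aligner is a compact double-dynamic-programming variant of the classic
SSAP idea, not a reimplementation of any production code path.

*Views.* For residue *i* with both sequence neighbours present, a local
orthonormal frame is built from the CA atoms: e₁ ∝ (CA(i+1) − CA(i)) −
(CA(i−1) − CA(i)) (the local chain direction), e₃ ∝ the normal of the
neighbour plane, e₂ = e₃ × e₁. The view set of residue *i* is the matrix
of vectors from its CB (CA when no CB is present, including glycine) to
every residue's CA, expressed in this frame. Views are exactly invariant
under rigid motion; near-colinear neighbour triples (‖u × v‖ below 1e-8 of
the norm product) raise a degeneracy error naming the residue. The two
chain termini have no frame; they carry zero rows/columns in the summary
matrix but remain alignable.

*Two DP levels.* For each framed residue pair (i, j) a global
Needleman–Wunsch aligns the two view sets with cell score S/(d + d₀)
(S = 500, d₀ = 10 Å, d the Euclidean distance between view vectors) and
linear gap penalty 50 per residue, charged at the ends as well. The
optimal lower score, clamped at 0, becomes cell (i, j) of the summary
matrix; a second global NW (same gap penalty, default 50) over the summary
matrix gives the raw score and the aligned pairs. Scores are normalised by
the geometric mean of the two self-alignments and clamped to [0, 100]; the
self-normalisation uses the identical code path so score(a, a) is exactly
100 in floating point. Overlap is 100·|pairs|/max(n_a, n_b) — the longer
structure in the denominator is the stricter of the plausible readings and
penalises partial matches.

Numerical notes: the lower level is vectorised across all (i, j) pairs by
batched anti-diagonal sweeps, chunked to bound memory at ~4M cells; the
upper-level traceback prefers match over vertical over horizontal moves on
exact float ties, so aligned pairs are deterministic. The upper DP is
verified against exhaustive enumeration of all monotone matchings for
structures of ≤ 8 residues (the equivalence score = Σ cells − gap·(n_a +
n_b − 2m) holds for linear end-charged gaps).

## Profile comparison

A profile is a list of per-column emission distributions over the 20 amino
acids plus a background (uniform by default; the HMMER3 reader uses the
standard amino-acid background). Column emissions from an alignment follow
(count + pc·bg)/(n_ungapped + pc) over ungapped rows; columns that are
gaps in more than half the rows are treated as insert columns and dropped.
This formula is deliberately depth-sensitive: duplicating all rows shrinks
the pseudocount weight, so profiles are only idempotent under duplication
in the pc → 0 limit.

Profile pairs are scored by Gotoh local alignment (affine gaps, open 3
bits, extend 0.3 bits) over s(i, j) = log₂ Σₐ pᵢ(a)qⱼ(a)/bg(a). This dot-
product log-odds replaces full HMM co-emission but keeps the bit scale: a
conserved identical column contributes log₂ 20 ≈ 4.32 bits, background-
like columns contribute 0, and the 10-bit network-edge threshold retains
its qualitative meaning. The two backgrounds are averaged before scoring
so the score is symmetric in its arguments. The `.hmm` reader keeps match
emissions only — insert states and transitions are a documented loss.

## Superfamily assignment

*Features.* One pair of domains yields (ssap_score/100, ssap_overlap/100,
min(prc_bits/50, 1)), each in [0, 1].

*Classifier.* A linear soft-margin classifier minimising squared hinge
loss with L2 penalty (λ = 1e-3) by L-BFGS-B, with weights constrained
non-negative so the decision value is monotone in every similarity — a
contract a curator can reason about. The decision threshold is the
smallest value maximising F1 on the training decision values. A freshly
trained classifier lives on its own score scale; the published decision
cut-off 3.47 is kept as the default in `Thresholds` for data on the
production scale, and the pipeline substitutes the calibrated threshold
when it trains its own model (the CLI reports which is in use).

*Benchmark.* Easy positives are removed greedily: while any pair has
identity ≥ 35% (the S35 sequence-family level; the exact production
cut-off is not published) or structural score > 80, the domain in the most
violating pairs is dropped (ties to the lexicographically smaller ID).
Positives are same-superfamily pairs of the reduced list; negatives are
stratified 8/15, 4/15, 2/15, 1/15 over same-topology, same-architecture,
same-class and different-class pairs, rounded to nearest with a
largest-remainder correction, sampled without replacement and shuffled.

*Protocol.* Three ordered steps with inclusive thresholds ("reaches the
threshold", "at least 70%"): best SVM hit with decision ≥ cut-off and
overlap ≥ 70% whose superfamily is not under an excluded node prefix →
assign to that superfamily; else highest structural score ≥ 70 with
overlap ≥ 60% → new superfamily inside the match's 3-level fold code; else
manual review, always carrying the best SVM and best structural hit as
evidence. Ties break toward higher overlap, then lexicographic match ID.
The exclusion list is an empty-by-default sequence of code prefixes.

## Architecture resolution

Strict non-overlap, no trimming: residues are 1-based inclusive and a
single shared residue is a conflict, which keeps the optimum well defined.
Single-segment inputs use weighted interval scheduling; the tie-break
objective (max score, then fewer hits, then lexicographically earliest
sorted match IDs) composes correctly through the DP because score and
count are additive and sorted-multiset order is preserved under adding a
common element. Discontiguous inputs go to branch and bound over the
conflict graph ordered by descending score with a suffix-sum bound; a
`max_hits` cap (default 30) guards the exponential worst case. The oracle
enumerates all 2ⁿ subsets via bitmask recursion. Tests use integer scores
so float ties are exact.

## FunFam analyses

*Conservation.* score = (1 − H/ln 20)(1 − gap_fraction) per column, H the
Shannon entropy of ungapped residue frequencies; an all-gap column scores
0. This entropy-with-gap-penalty form reproduces the published endpoint
semantics (1 = completely conserved, 0 = completely unconserved) without
claiming to be any particular production scorer.

*DOPs.* Scores are rounded to 3 decimals (the precision is a parameter);
with u distinct values over L columns, DOPs = 100(u − 1)/(L − 1), 0 for
L ≤ 1. This is the simplest statistic satisfying the documented endpoints:
0 when every column scores the same, 100 when no two share a score.
Families freeze at DOPs ≥ 70 (boundary inclusive).

*Version mapping.* overlap = 100·|shared residues|/max(len_old, len_new);
keep iff ≥ 70%. The longer-region denominator is again the stricter
reading.

*Inclusion thresholds.* The family cut-off is the minimum over members of
the member's single-sequence profile scored against the family profile; a
candidate is admitted only strictly above it ("surpassed"). This is a
simplified stand-in for the published per-family procedure, which is
defined in work this package does not reimplement.

*Naming.* (1) Greedy redundancy reduction, longest sequence first, joining
a representative at ≥ 95% global identity (edit-distance identity,
100·(1 − d/max len)); (2) term normalisation: lowercase, punctuation
stripped, numerals, stopwords and synonym-mapped terms removed (the
synonym map ships empty; the stopword list is editable); (3) term score =
number of retained descriptions containing the term; (4) description
score = sum of term scores; (5) divided by 1 + |n_terms − mean_terms| —
the simplest monotone penalty favouring typical-length descriptions. Ties
go to the lexicographically smaller description; clusters with no
informative terms are named "uncharacterized". Descriptions left with no
terms are excluded from the mean-length computation (they can never win:
their score is 0).

*Networks.* Undirected, no self-loops; an edge requires bits strictly
above the threshold (default 10), node size is the member count.

## Synthetic data: what it emulates and what it does not

Toy structures are ideal helices (rise 1.5 Å, 100° twist, radius 2.3 Å),
zigzag strands (3.3 Å rise), two-helix bundles and six-residue β-meanders,
plus isotropic Gaussian coordinate noise. The hierarchy generator derives
each topology template from the ideal geometry of its fold kind with a
topology-specific random deformation (σ = 3.5 Å), each superfamily
template from its topology template (σ = 2.5 Å), and each member from its
superfamily template (σ = 0.8 Å) with up to 2 residues trimmed per
terminus; member sequences mutate 85% of template positions. These
defaults were fixed once, at design time, to place superfamily members in
the remote-homolog regime a purged benchmark implies — measured structural
scores within a superfamily fall in ≈ 42–71 (below the easy-positive cut
of 80), same-topology/different-superfamily pairs in ≈ 20–50, and pairwise
sequence identity stays below 35%. Default shape: 2 classes × 2
architectures × 2 topologies × 2 superfamilies × 3 domains = 48 domains —
small enough that the full held-out recovery experiment (≈ 1000 structural
alignments) completes in about two minutes on one core.

Passing tests on these fixtures show that the algorithms honour their
contracts (metric properties, protocol totality, optimality, endpoint
semantics) and that the pipeline separates hierarchy levels whose
similarity structure it controls. They do not show performance on real
protein structures: real domains have indels in the middle of folds,
non-ideal geometry, composition bias, and genuinely ambiguous boundary
cases, none of which the generators model.

Alignments with prescribed conservation are built per column from integer
residue compositions (one dominant residue, the remainder spread over k
types) chosen by exhaustive search to minimise the distance to the target;
the generator raises if a target cannot be met within ±0.05 at the given
depth. Row order is shuffled (conservation is order-invariant) and residue
identities rotate across columns.

## Degenerate inputs and tie-breaking (summary)

Parsers reject and report rather than coerce (position-naming errors for
IDs, segments, regions). Empty alignments score 0 with overlap 0; an
empty candidate list yields manual review with empty evidence; an empty
hit list yields an empty architecture of score 0; a single-column DOPs is
0 by convention. All randomised procedures take explicit integer seeds and
are bit-reproducible.

## Known limitations

The aligner and profile scorer are specified variants, not the historical
tools; absolute score values are comparable only within this package even
though the scales (0–100 structural, bits) match. The SVM feature set is
the three similarities above — production systems use more. Re-clustering
of non-frozen families and tree-based family partitioning are out of
scope: the freeze partition only labels which families would be
re-clustered. mmCIF input, trimming/overlap-tolerance in architecture
resolution, and E-value calibration are not implemented.
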