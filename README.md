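# cathkit

A desk-scale Python toolkit for the computational machinery behind
CATH-style protein domain classification. It is aimed at structural
bioinformaticians who want the *algorithms* of a domain classification
pipeline — structure-versus-structure scoring, profile-versus-profile
scoring, automated superfamily assignment, domain architecture resolution
and functional-family analysis — as an importable, testable library rather
than a database-scale production system.

Everything runs on synthetic, seeded inputs generated by the package
itself; no downloads are required.

## What it implements

**Structural alignment (`cathkit.ssap`).** A documented SSAP-style double
dynamic programming aligner. Each residue *i* gets a *view*: the vectors
from its CB (CA when absent) to every CA, expressed in a local frame built
from CA(i−1), CA(i), CA(i+1), so views are invariant under rigid motion.
The lower DP level aligns view sets for every residue pair (i, j) with cell
score S/(d + d₀) (defaults S = 500, d₀ = 10 Å); the upper level aligns the
resulting summary matrix. The final score is normalised to

    score(a, b) = 100 · raw(a, b) / √(raw(a, a) · raw(b, b))

so self-alignments score exactly 100 and the score is symmetric. The
overlap is the percentage of the longer structure's residues aligned.

**Profile comparison (`cathkit.prc`).** Profiles are per-column emission
distributions over the 20 amino acids (built from alignments with
pseudocounts, or read from HMMER3 `.hmm` files). Two profiles are compared
by Smith–Waterman with affine gaps over the column log-odds
s(i, j) = log₂ Σₐ pᵢ(a)qⱼ(a)/bg(a), giving a symmetric, non-negative score
in bits.

**Superfamily assignment (`cathkit.homology`, `cathkit.pipeline`).** A
linear soft-margin classifier with non-negative weights combines
(ssap/100, overlap/100, bits/50) into one decision value, trained on a
balanced benchmark of homologous and non-homologous pairs in which "easy"
positives (identity ≥ 35% or structural score > 80) are removed and
negatives are stratified 8:4:2:1 over topology-, architecture-,
class-level matches and different-class pairs —
`stratify_negatives(10788)` = (5754, 2877, 1438, 719). Queries then pass a
three-step protocol: SVM ≥ 3.47 with overlap ≥ 70% assigns an existing
superfamily; else structural score ≥ 70 with overlap ≥ 60% creates a new
superfamily in the matched fold; else the domain goes to manual review.

**Architecture resolution (`cathkit.resolve`).** The maximum-score subset
of scored domain hits with no residue claimed twice: weighted interval
scheduling for single-segment hits, exact branch and bound for
discontiguous ones, plus an exhaustive oracle for verification.

**FunFam analysis (`cathkit.funfam`).** Entropy-based column conservation
(0–1), the diversity-of-positions score DOPs = 100·(u−1)/(L−1) over rounded
conservation values (0–100), freezing at DOPs ≥ 70, inter-version domain
mapping (removed when boundary overlap < 70%), per-family inclusion
thresholds, cluster naming from member descriptions, and similarity
networks with edges strictly above 10 bits.

**Synthetic fixtures (`cathkit.fixtures`).** Seeded generators for toy
structures (helix, strand, helix bundle, β-meander), a full four-level
classification hierarchy whose members are remote homologues, alignments
with prescribed per-column conservation, and description sets with
controlled sequence redundancy.

## Worked example

```bash
python examples/06_homology_benchmark.py
```

builds the default 2×2×2×2 hierarchy (16 superfamilies × 3 domains), holds
one domain per superfamily out, trains the classifier on a stratified
benchmark over the rest and reassigns the held-out domains:

```
held-out queries : 16
correctly assigned: 16
accuracy          : 1.000
classifier weights: [11.603  0.     0.64 ] (ssap, overlap, bits)
decision threshold: 0.228
outcomes          : {'assign_existing': 16}
```

All 16 held-out domains return to their true superfamily through step 1 of
the protocol. The weights show the structural score dominating the
decision, with a small profile contribution — on remote homologues the
profile signal is weak by construction. The other examples
(`examples/01…05`) each demonstrate one capability and print a short
interpretation; a thin CLI (`cathkit ssap|prcsim|assign|benchmark|resolve|
conserve|name|network|fixtures`) wraps the same functions for shell use.

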