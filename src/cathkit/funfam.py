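"""Functional-family (FunFam) analyses.

A FunFam is a sub-cluster of a superfamily whose members are predicted to
share function.  This module covers the per-family computations:

* per-column conservation of the family alignment, on a 0 (completely
  unconserved) to 1 (completely conserved) scale;
* the diversity-of-positions (DOPs) score, 0 (every column has the same
  conservation score) to 100 (no two columns share one);
* freezing: families with DOPs >= 70 are informative enough to keep their
  identifier and membership stable across releases;
* mapping domains between classification versions by boundary overlap
  (< 70% overlap means the domain is removed from its old family);
* per-family inclusion thresholds for admitting new member sequences;
* naming a family from its members' free-text descriptions;
* similarity networks whose edges are profile-profile scores above a bit
  threshold.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .prc import AA_INDEX, compare_profiles, sequence_profile
from .types import MSA, DomainRegion, ProfileModel, Thresholds


# ---------------------------------------------------------------------------
# conservation and DOPs
# ---------------------------------------------------------------------------


@dataclass
class ConservationProfile:
    scores: list[float]
    dops: float


def column_conservation(msa: MSA) -> list[float]:
    """Entropy-based conservation of each alignment column.

    ``score = (1 - H / ln 20) * (1 - gap_fraction)`` where H is the Shannon
    entropy of the ungapped residue frequencies.  A single-residue gap-free
    column scores exactly 1; a gap-free column with all 20 residues equally
    frequent scores 0; an all-gap column scores 0.
    """
    scores = []
    for j in range(msa.n_columns):
        col = msa.column(j)
        residues = [c for c in col if c in AA_INDEX]
        if not residues:
            scores.append(0.0)
            continue
        gap_fraction = 1.0 - len(residues) / len(col)
        counts = np.bincount([AA_INDEX[c] for c in residues], minlength=20)
        freqs = counts[counts > 0] / len(residues)
        entropy = float(-(freqs * np.log(freqs)).sum())
        scores.append((1.0 - entropy / np.log(20.0)) * (1.0 - gap_fraction))
    return scores


def dops_score(scores: Sequence[float], precision: int = 3) -> float:
    """Diversity of positions: how varied the column conservation scores are.

    Scores are rounded to ``precision`` decimals; with ``u`` distinct values
    over ``L`` columns, ``DOPs = 100 * (u - 1) / (L - 1)`` (0 for a single
    column).  Endpoints: 0 when every column scores the same, 100 when no
    two columns share a score.
    """
    if len(scores) == 0:
        raise ValueError("empty conservation score list")
    if any(not 0.0 <= s <= 1.0 for s in scores):
        raise ValueError("conservation scores must lie in [0, 1]")
    rounded = [round(float(s), precision) for s in scores]
    n_cols = len(rounded)
    if n_cols <= 1:
        return 0.0
    return 100.0 * (len(set(rounded)) - 1) / (n_cols - 1)


def conservation_profile(msa: MSA, precision: int = 3) -> ConservationProfile:
    scores = column_conservation(msa)
    return ConservationProfile(scores, dops_score(scores, precision))


# ---------------------------------------------------------------------------
# records and freezing
# ---------------------------------------------------------------------------


@dataclass
class FunFamRecord:
    """One functional family: members, alignment and derived annotations."""

    funfam_id: str  # e.g. "3.40.50.620/FF/89168"
    members: list[str]
    msa: Optional[MSA] = None
    conservation: Optional[ConservationProfile] = None
    frozen: bool = False
    name: str = ""
    inclusion_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"FunFam {self.funfam_id} has no members")


def select_frozen(
    funfams: Iterable[FunFamRecord], thresholds: Thresholds = Thresholds()
) -> tuple[list[FunFamRecord], list[FunFamRecord]]:
    """Partition families into (frozen, updatable) by DOPs >= the freeze cut-off.

    Frozen families keep their identifiers across releases; the rest are
    candidates for re-clustering.  The ``frozen`` flag is set on each record.
    """
    frozen, updatable = [], []
    for ff in funfams:
        if ff.conservation is None:
            raise ValueError(f"FunFam {ff.funfam_id} has no conservation profile")
        ff.frozen = ff.conservation.dops >= thresholds.dops_frozen_min
        (frozen if ff.frozen else updatable).append(ff)
    return frozen, updatable


# ---------------------------------------------------------------------------
# version mapping
# ---------------------------------------------------------------------------


def map_version_overlap(
    old_region: DomainRegion,
    new_region: DomainRegion,
    thresholds: Thresholds = Thresholds(),
) -> tuple[float, bool]:
    """Boundary overlap between two versions of a domain, and whether to keep it.

    ``overlap = 100 * |shared residues| / max(length(old), length(new))``;
    the domain stays in its family iff the overlap is at least the version
    mapping cut-off (default 70%).
    """
    shared = len(old_region.residue_set() & new_region.residue_set())
    overlap = 100.0 * shared / max(old_region.total_length, new_region.total_length)
    return overlap, overlap >= thresholds.version_map_overlap_min_pct


# ---------------------------------------------------------------------------
# inclusion thresholds
# ---------------------------------------------------------------------------


def inclusion_threshold(
    family_profile: ProfileModel, member_sequences: Mapping[str, str], pseudocount: float = 1.0
) -> float:
    """Per-family admission cut-off in bits.

    The threshold is the weakest member's score: the minimum, over members,
    of the member's single-sequence profile compared against the family
    profile.  A candidate is admitted iff its score is strictly above it.
    """
    if not member_sequences:
        raise ValueError("family has no member sequences")
    scores = [
        compare_profiles(sequence_profile(seq, pseudocount), family_profile).score
        for seq in member_sequences.values()
    ]
    return min(scores)


def admits(
    family_profile: ProfileModel, threshold: float, candidate_seq: str, pseudocount: float = 1.0
) -> bool:
    score = compare_profiles(sequence_profile(candidate_seq, pseudocount), family_profile).score
    return score > threshold


# ---------------------------------------------------------------------------
# naming
# ---------------------------------------------------------------------------

DEFAULT_STOPWORDS = frozenset(
    {"protein", "putative", "uncharacterized", "uncharacterised", "probable",
     "predicted", "fragment", "homolog", "like"}
)

_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


def _normalise_terms(text: str, stopwords: frozenset[str], synonyms: Mapping[str, str]) -> list[str]:
    terms = []
    for raw in text.lower().translate(_PUNCT_TABLE).split():
        term = synonyms.get(raw, raw)
        if not term or term.isdigit() or term in stopwords:
            continue
        terms.append(term)
    return terms


def sequence_identity_pct(a: str, b: str) -> float:
    """Global sequence identity as 100 * (1 - edit_distance / max length)."""
    import edlib

    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 100.0 * (1.0 - dist / max(len(a), len(b)))


@dataclass
class NamingResult:
    name: str
    representative_descriptions: list[tuple[str, str]]  # (sequence ID, description)
    term_scores: dict[str, int]
    description_scores: dict[str, float]


def name_cluster(
    descriptions: Sequence[tuple[str, str, str]],
    stopwords: frozenset[str] = DEFAULT_STOPWORDS,
    synonyms: Mapping[str, str] | None = None,
    identity_pct: float = 95.0,
) -> NamingResult:
    """Choose the description that best represents a cluster of sequences.

    ``descriptions`` is a list of (sequence ID, free-text description,
    sequence).  The five steps: (1) drop redundant sequences — longest
    first, a sequence joins an existing representative at >= 95% global
    identity and only representatives keep their description; (2) normalise
    terms (lowercase, strip punctuation, drop numerals, stopwords and mapped
    synonyms); (3) score each term by the number of retained descriptions
    containing it; (4) score each description as the sum of its term scores;
    (5) divide by ``1 + |n_terms - mean_terms|`` so descriptions of typical
    length win over over-specific ones.  Ties go to the lexicographically
    smaller description; clusters with no informative terms are named
    ``uncharacterized``.
    """
    if not descriptions:
        raise ValueError("no descriptions given")
    synonyms = synonyms or {}

    # step 1: greedy redundancy reduction, longest sequence first
    reps: list[tuple[str, str, str]] = []
    for rec in sorted(descriptions, key=lambda r: (-len(r[2]), r[0])):
        if all(sequence_identity_pct(rec[2], rep[2]) < identity_pct for rep in reps):
            reps.append(rec)
    retained = [(seq_id, text) for seq_id, text, _ in reps]

    # steps 2-3: term frequencies across retained descriptions
    term_lists = {seq_id: _normalise_terms(text, stopwords, synonyms) for seq_id, text in retained}
    term_scores: dict[str, int] = {}
    for terms in term_lists.values():
        for term in set(terms):
            term_scores[term] = term_scores.get(term, 0) + 1

    scored = [(seq_id, text, term_lists[seq_id]) for seq_id, text in retained if term_lists[seq_id]]
    if not scored:
        return NamingResult("uncharacterized", retained, term_scores, {})

    # steps 4-5: sum term scores, then favour typical-length descriptions
    mean_terms = float(np.mean([len(terms) for _, _, terms in scored]))
    description_scores: dict[str, float] = {}
    for _, text, terms in scored:
        raw = sum(term_scores[t] for t in terms)
        description_scores[text] = raw / (1.0 + abs(len(terms) - mean_terms))
    winner = min(description_scores, key=lambda text: (-description_scores[text], text))
    return NamingResult(winner, retained, term_scores, description_scores)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


def build_funfam_network(
    funfams: Sequence[FunFamRecord],
    pairwise_bits: Mapping[tuple[str, str], float],
    threshold: float = 10.0,
    annotations: Mapping[str, Mapping[str, object]] | None = None,
):
    """Similarity network over families: node size = member count, edge iff
    the profile-profile score is **strictly above** ``threshold`` bits.
    """
    import networkx as nx

    graph = nx.Graph()
    for ff in funfams:
        attrs = {"size": len(ff.members), "name": ff.name}
        if annotations and ff.funfam_id in annotations:
            attrs.update(annotations[ff.funfam_id])
        graph.add_node(ff.funfam_id, **attrs)
    ids = {ff.funfam_id for ff in funfams}
    for (a, b), bits in pairwise_bits.items():
        if a == b or a not in ids or b not in ids:
            continue
        if bits > threshold:
            graph.add_edge(a, b, bits=float(bits))
    return graph
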