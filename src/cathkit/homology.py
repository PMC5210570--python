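"""SVM-based superfamily assignment: benchmark, classifier and protocol.

The classifier combines structural and profile similarity of a (query,
candidate) domain pair into one decision value.  The assignment protocol is
three-tiered:

1. the best candidate whose SVM decision value reaches the benchmarked
   threshold and whose structural overlap is at least 70% assigns the query
   to that candidate's superfamily (unless the superfamily is on a known
   problematic-node exclusion list);
2. otherwise the highest structural score of at least 70 with overlap of at
   least 60% creates a *new* superfamily inside that candidate's fold;
3. otherwise the query is documented for manual assessment — it may be a
   new fold.

The benchmark mirrors the published construction: "easy" positive pairs are
removed (high sequence identity, or structural score above 80) before pair
sampling, positives are same-superfamily pairs, and negatives are stratified
across the hierarchy in proportions 8:4:2:1 for topology-, architecture-,
class-level matches and different-class pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.metrics import auc, precision_recall_curve

from .types import CathCode, DomainID, Thresholds

FEATURE_NAMES = ("ssap_score", "ssap_overlap", "prc_bits")


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairFeature:
    """Feature vector of one domain pair, each component scaled into [0, 1].

    Structural score and overlap are divided by 100; the profile score is
    divided by 50 bits and capped at 1.
    """

    ssap_score: float
    ssap_overlap: float
    prc_bits: float

    @classmethod
    def from_raw(cls, ssap_score: float, ssap_overlap: float, prc_bits: float) -> "PairFeature":
        return cls(
            min(1.0, max(0.0, ssap_score / 100.0)),
            min(1.0, max(0.0, ssap_overlap / 100.0)),
            min(1.0, max(0.0, prc_bits / 50.0)),
        )

    def vector(self) -> np.ndarray:
        return np.array([self.ssap_score, self.ssap_overlap, self.prc_bits])


# ---------------------------------------------------------------------------
# benchmark construction
# ---------------------------------------------------------------------------

STRATA = ("T", "A", "C", "X")
_STRATUM_WEIGHTS = {"T": 8, "A": 4, "C": 2, "X": 1}


@dataclass(frozen=True)
class BenchmarkPair:
    domain_a: DomainID
    domain_b: DomainID
    label: bool  # True = homologous
    stratum: str  # H for positives; T/A/C/X for negatives

    def __post_init__(self) -> None:
        if self.label != (self.stratum == "H"):
            raise ValueError("homologous pairs must carry stratum H and vice versa")
        if self.stratum not in ("H",) + STRATA:
            raise ValueError(f"unknown stratum {self.stratum}")


def stratify_negatives(n_total: int) -> tuple[int, int, int, int]:
    """Allocate negatives over (T, A, C, X) in proportions 8:4:2:1 of 15ths.

    Counts are rounded to the nearest integer; if rounding breaks the total,
    a largest-remainder correction restores it.  For the published benchmark
    size of 10 788 this yields (5754, 2877, 1438, 719).
    """
    if n_total < 15:
        raise ValueError(f"need n_total >= 15 to populate all four strata, got {n_total}")
    exact = {s: n_total * w / 15.0 for s, w in _STRATUM_WEIGHTS.items()}
    counts = {s: round(v) for s, v in exact.items()}
    deficit = n_total - sum(counts.values())
    if deficit != 0:
        # push the correction onto the strata whose rounding moved furthest
        residuals = sorted(STRATA, key=lambda s: (exact[s] - counts[s]), reverse=deficit > 0)
        for s in residuals[: abs(deficit)]:
            counts[s] += 1 if deficit > 0 else -1
    return counts["T"], counts["A"], counts["C"], counts["X"]


def remove_easy_positives(
    domains: Sequence[DomainID],
    identity_table: pd.DataFrame,
    ssap_table: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
) -> list[DomainID]:
    """Greedily drop domains until no remaining pair is an "easy" match.

    A pair violates if sequence identity >= the identity cut-off (default
    35%) or the structural score is strictly above 80.  At each step the
    domain in the most violating pairs is removed; ties break toward the
    lexicographically smaller ID.
    """
    keep = sorted(domains)

    def violating_pairs(pool: list[DomainID]) -> list[tuple[DomainID, DomainID]]:
        pairs = []
        for idx, a in enumerate(pool):
            for b in pool[idx + 1 :]:
                ident = float(identity_table.loc[a.render(), b.render()])
                ssap = float(ssap_table.loc[a.render(), b.render()])
                if ident >= thresholds.easy_positive_identity_pct or ssap > thresholds.easy_positive_ssap_max:
                    pairs.append((a, b))
        return pairs

    while True:
        pairs = violating_pairs(keep)
        if not pairs:
            return keep
        degree: dict[DomainID, int] = {}
        for a, b in pairs:
            degree[a] = degree.get(a, 0) + 1
            degree[b] = degree.get(b, 0) + 1
        worst = min(degree, key=lambda d: (-degree[d], d.render()))
        keep.remove(worst)


def _stratum_of(code_a: CathCode, code_b: CathCode) -> str:
    """Deepest level at which two 4-level codes agree: H, T, A, C or X."""
    for depth, stratum in ((4, "H"), (3, "T"), (2, "A"), (1, "C")):
        if code_a.same_at_level(code_b, depth):
            return stratum
    return "X"


def build_benchmark(
    classification: Mapping[DomainID, CathCode],
    n_pos: int,
    n_neg: int,
    seed: int,
    identity_table: pd.DataFrame,
    ssap_table: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
) -> list[BenchmarkPair]:
    """Balanced benchmark of homologous and stratified non-homologous pairs.

    Easy positives are removed first; positives are then sampled from
    same-superfamily pairs of the reduced list and negatives per stratum
    from across the classification, all without replacement, shuffled.
    """
    rng = np.random.default_rng(seed)
    reduced = remove_easy_positives(list(classification), identity_table, ssap_table, thresholds)
    by_stratum: dict[str, list[tuple[DomainID, DomainID]]] = {s: [] for s in ("H",) + STRATA}
    for idx, a in enumerate(reduced):
        for b in reduced[idx + 1 :]:
            by_stratum[_stratum_of(classification[a], classification[b])].append((a, b))

    def sample(stratum: str, count: int) -> list[tuple[DomainID, DomainID]]:
        pool = by_stratum[stratum]
        if len(pool) < count:
            raise ValueError(
                f"stratum {stratum}: only {len(pool)} eligible pairs, need {count}"
            )
        picked = rng.choice(len(pool), size=count, replace=False)
        return [pool[i] for i in picked]

    pairs = [BenchmarkPair(a, b, True, "H") for a, b in sample("H", n_pos)]
    for stratum, count in zip(STRATA, stratify_negatives(n_neg)):
        pairs.extend(BenchmarkPair(a, b, False, stratum) for a, b in sample(stratum, count))
    rng.shuffle(pairs)  # type: ignore[arg-type]
    return list(pairs)


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------


@dataclass
class TrainedClassifier:
    """Linear soft-margin classifier with non-negative weights.

    Non-negativity makes the decision value monotone in every similarity
    feature.  ``threshold`` is calibrated on the training decision values to
    maximise F1.
    """

    weights: np.ndarray
    bias: float
    threshold: float
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def decision_values(self, features: Sequence[PairFeature]) -> np.ndarray:
        x = np.array([f.vector() for f in features])
        return x @ self.weights + self.bias

    def predict(self, features: Sequence[PairFeature]) -> np.ndarray:
        return self.decision_values(features) >= self.threshold

    def to_dict(self) -> dict:
        return {
            "weights": [float(w) for w in self.weights],
            "bias": float(self.bias),
            "threshold": float(self.threshold),
            "feature_names": list(self.feature_names),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TrainedClassifier":
        return cls(
            np.array(data["weights"], dtype=float),
            float(data["bias"]),
            float(data["threshold"]),
            tuple(data["feature_names"]),
        )


def train_classifier(
    features: Sequence[PairFeature],
    labels: Sequence[bool],
    seed: int = 0,
    reg: float = 1e-3,
) -> TrainedClassifier:
    """Fit the linear soft-margin classifier (squared hinge, weights >= 0).

    The optimisation is deterministic (L-BFGS-B from a fixed start); ``seed``
    is accepted for interface symmetry with the samplers.
    """
    y = np.where(np.asarray(labels, dtype=bool), 1.0, -1.0)
    if len(set(y)) < 2:
        raise ValueError("training data must contain both labels")
    x = np.array([f.vector() for f in features])

    def objective(params: np.ndarray) -> tuple[float, np.ndarray]:
        w, b = params[:-1], params[-1]
        margins = y * (x @ w + b)
        slack = np.maximum(0.0, 1.0 - margins)
        loss = 0.5 * reg * float(w @ w) + float(np.mean(slack**2))
        grad_margin = -2.0 * slack * y / len(y)
        grad_w = reg * w + x.T @ grad_margin
        grad_b = float(np.sum(grad_margin))
        return loss, np.concatenate([grad_w, [grad_b]])

    n_feat = x.shape[1]
    bounds = [(0.0, None)] * n_feat + [(None, None)]
    result = minimize(
        objective, np.zeros(n_feat + 1), jac=True, bounds=bounds, method="L-BFGS-B"
    )
    weights, bias = result.x[:-1], float(result.x[-1])
    decisions = x @ weights + bias
    threshold = _calibrate_threshold(decisions, y > 0)
    return TrainedClassifier(weights, bias, threshold)


def _calibrate_threshold(decisions: np.ndarray, labels: np.ndarray) -> float:
    """Smallest threshold maximising F1 over the training decision values."""
    candidates = np.concatenate([[decisions.min() - 1e-9], np.unique(decisions)])
    best_f1, best_thr = -1.0, float(candidates[0])
    for thr in candidates:
        pred = decisions >= thr
        tp = int(np.sum(pred & labels))
        fp = int(np.sum(pred & ~labels))
        fn = int(np.sum(~pred & labels))
        f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
        if f1 > best_f1:
            best_f1, best_thr = f1, float(thr)
    return best_thr


def split_pairs(
    items: Sequence, seed: int, train_fraction: float = 0.5
) -> tuple[list, list]:
    """Random train/test split (default 50/50) of benchmark pairs."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(items))
    cut = int(round(train_fraction * len(items)))
    return [items[i] for i in order[:cut]], [items[i] for i in order[cut:]]


def evaluate_precision_recall(
    classifier: TrainedClassifier,
    features: Sequence[PairFeature],
    labels: Sequence[bool],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Precision-recall curve and area under it for a test set."""
    if len(features) == 0:
        raise ValueError("empty test set")
    decisions = classifier.decision_values(features)
    precision, recall, _ = precision_recall_curve(np.asarray(labels, dtype=int), decisions)
    return precision, recall, float(auc(recall, precision))


# ---------------------------------------------------------------------------
# assignment protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidateHit:
    """Evidence for one (query, assigned-domain) comparison."""

    match_id: str
    cath_code: CathCode  # 4-level superfamily code of the candidate
    svm_score: float
    ssap_score: float
    ssap_overlap: float


@dataclass
class AssignmentDecision:
    outcome: str  # assign_existing | new_superfamily_in_fold | manual_review
    target: Optional[CathCode]
    best_svm_hit: Optional[CandidateHit]
    best_ssap_hit: Optional[CandidateHit]

    def __post_init__(self) -> None:
        if self.outcome not in ("assign_existing", "new_superfamily_in_fold", "manual_review"):
            raise ValueError(f"unknown outcome {self.outcome}")
        if (self.target is None) != (self.outcome == "manual_review"):
            raise ValueError("target must be present iff a code is assigned")


def _excluded(code: CathCode, exclusion_nodes: Sequence[CathCode]) -> bool:
    return any(node.is_prefix_of(code) for node in exclusion_nodes)


def decide_assignment(
    candidate_hits: Sequence[CandidateHit],
    thresholds: Thresholds = Thresholds(),
    exclusion_nodes: Sequence[CathCode] = (),
) -> AssignmentDecision:
    """Three-step assignment protocol over a query's candidate hits.

    All threshold comparisons are inclusive (>=).  Ties between equally good
    hits break toward higher structural overlap, then lexicographic match
    ID.  With no candidates at all the decision is manual review with empty
    evidence.
    """
    best_svm = max(
        candidate_hits,
        key=lambda h: (h.svm_score, h.ssap_overlap, _reverse_id(h.match_id)),
        default=None,
    )
    best_ssap = max(
        candidate_hits,
        key=lambda h: (h.ssap_score, h.ssap_overlap, _reverse_id(h.match_id)),
        default=None,
    )

    step1 = [
        h
        for h in candidate_hits
        if h.svm_score >= thresholds.svm_decision
        and h.ssap_overlap >= thresholds.svm_overlap_min_pct
        and not _excluded(h.cath_code, exclusion_nodes)
    ]
    if step1:
        hit = max(step1, key=lambda h: (h.svm_score, h.ssap_overlap, _reverse_id(h.match_id)))
        return AssignmentDecision("assign_existing", hit.cath_code, best_svm, best_ssap)

    step2 = [
        h
        for h in candidate_hits
        if h.ssap_score >= thresholds.ssap_fallback_score_min
        and h.ssap_overlap >= thresholds.ssap_fallback_overlap_min_pct
    ]
    if step2:
        hit = max(step2, key=lambda h: (h.ssap_score, h.ssap_overlap, _reverse_id(h.match_id)))
        return AssignmentDecision(
            "new_superfamily_in_fold", hit.cath_code.prefix(3), best_svm, best_ssap
        )

    return AssignmentDecision("manual_review", None, best_svm, best_ssap)


class _reverse_id(str):
    """String wrapper whose ordering is reversed, for use inside max() keys."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other) -> bool:  # type: ignore[override]
        return str.__lt__(self, other)
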