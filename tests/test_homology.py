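"""Benchmark construction, classifier training and the assignment protocol."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cathkit import fixtures
from cathkit.homology import (
    BenchmarkPair,
    CandidateHit,
    PairFeature,
    build_benchmark,
    decide_assignment,
    evaluate_precision_recall,
    remove_easy_positives,
    split_pairs,
    stratify_negatives,
    train_classifier,
)
from cathkit.types import CathCode, DomainID, Thresholds, parse_cath_code

# ---------------------------------------------------------------------------
# stratification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "n_total,expected",
    [
        (10788, (5754, 2877, 1438, 719)),  # published benchmark composition
        (15, (8, 4, 2, 1)),
        (30, (16, 8, 4, 2)),
        (100, (53, 27, 13, 7)),
    ],
)
def test_stratify_negatives_allocation(n_total, expected):
    counts = stratify_negatives(n_total)
    assert counts == expected
    assert sum(counts) == n_total


def test_stratify_negatives_sums_for_arbitrary_totals():
    for n in range(15, 400):
        assert sum(stratify_negatives(n)) == n


def test_stratify_negatives_rejects_small_totals():
    with pytest.raises(ValueError):
        stratify_negatives(14)


# ---------------------------------------------------------------------------
# easy-positive removal
# ---------------------------------------------------------------------------


def _tables(ids, ssap=None, ident=None):
    keys = [d.render() for d in ids]
    ssap_df = pd.DataFrame(0.0, index=keys, columns=keys)
    ident_df = pd.DataFrame(0.0, index=keys, columns=keys)
    for (a, b), v in (ssap or {}).items():
        ssap_df.loc[a, b] = ssap_df.loc[b, a] = v
    for (a, b), v in (ident or {}).items():
        ident_df.loc[a, b] = ident_df.loc[b, a] = v
    return ident_df, ssap_df


def _dom(i):
    return DomainID(f"{i:04d}", "A", 1)


def test_high_ssap_pair_loses_one_domain():
    doms = [_dom(1), _dom(2)]
    ident, ssap = _tables(doms, ssap={("0001A01", "0002A01"): 85.0})
    kept = remove_easy_positives(doms, ident, ssap)
    assert len(kept) == 1


def test_compatible_triplet_fully_kept():
    doms = [_dom(1), _dom(2), _dom(3)]
    ident, ssap = _tables(doms, ssap={("0001A01", "0002A01"): 80.0}, ident={("0001A01", "0003A01"): 30.0})
    assert remove_easy_positives(doms, ident, ssap) == doms  # 80 and 30% are below the cut-offs


def test_star_pattern_removes_the_hub():
    doms = [_dom(1), _dom(2), _dom(3)]
    ident, ssap = _tables(
        doms, ssap={("0001A01", "0002A01"): 90.0, ("0001A01", "0003A01"): 90.0}
    )
    kept = remove_easy_positives(doms, ident, ssap)
    assert kept == [_dom(2), _dom(3)]


def test_identity_threshold_inclusive():
    doms = [_dom(1), _dom(2)]
    ident, ssap = _tables(doms, ident={("0001A01", "0002A01"): 35.0})
    assert len(remove_easy_positives(doms, ident, ssap)) == 1


# ---------------------------------------------------------------------------
# benchmark construction
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def wide_hierarchy():
    """2x2x2x2 hierarchy with 5 members per superfamily (80 domains)."""
    spec = fixtures.FixtureSpec(seed=3, domains_per_superfam=5)
    return fixtures.make_hierarchy(spec)


def _neutral_tables(classification):
    ids = sorted(classification)
    keys = [d.render() for d in ids]
    zero = pd.DataFrame(0.0, index=keys, columns=keys)
    return zero, zero.copy()


def test_benchmark_counts_and_strata(wide_hierarchy):
    ident, ssap = _neutral_tables(wide_hierarchy.classification)
    pairs = build_benchmark(wide_hierarchy.classification, 60, 60, seed=1,
                            identity_table=ident, ssap_table=ssap)
    assert len(pairs) == 120
    strata = {s: sum(p.stratum == s for p in pairs) for s in "HTACX"}
    assert strata == {"H": 60, "T": 32, "A": 16, "C": 8, "X": 4}
    assert sum(p.label for p in pairs) == sum(not p.label for p in pairs)


def test_benchmark_pairs_respect_declared_strata(wide_hierarchy):
    ident, ssap = _neutral_tables(wide_hierarchy.classification)
    pairs = build_benchmark(wide_hierarchy.classification, 30, 30, seed=2,
                            identity_table=ident, ssap_table=ssap)
    cls = wide_hierarchy.classification
    depth = {"H": 4, "T": 3, "A": 2, "C": 1}
    for p in pairs:
        a, b = cls[p.domain_a], cls[p.domain_b]
        if p.stratum == "X":
            assert not a.same_at_level(b, 1)
        else:
            d = depth[p.stratum]
            assert a.same_at_level(b, d)
            if d < 4:
                assert not a.same_at_level(b, d + 1)


def test_single_class_hierarchy_errors_for_stratum_x():
    spec = fixtures.FixtureSpec(seed=3, n_classes=1, domains_per_superfam=5)
    h = fixtures.make_hierarchy(spec)
    ident, ssap = _neutral_tables(h.classification)
    with pytest.raises(ValueError, match="stratum X"):
        build_benchmark(h.classification, 20, 20, seed=1, identity_table=ident, ssap_table=ssap)


def test_benchmark_pair_invariant():
    with pytest.raises(ValueError):
        BenchmarkPair(_dom(1), _dom(2), True, "T")


# ---------------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------------


def _synthetic_features(seed, n=200, separated=True):
    rng = np.random.default_rng(seed)
    features, labels = [], []
    for label in (True, False):
        centre = 0.8 if (label and separated) else 0.2 if separated else 0.5
        for _ in range(n // 2):
            x = np.clip(rng.normal(centre, 0.05, 3), 0, 1)
            features.append(PairFeature(*x))
            labels.append(label)
    return features, labels


def test_separable_features_perfectly_classified():
    features, labels = _synthetic_features(seed=1)
    train_x, test_x = split_pairs(features, seed=1)
    train_y, test_y = split_pairs(labels, seed=1)
    clf = train_classifier(train_x, train_y, seed=1)
    accuracy = np.mean(clf.predict(test_x) == np.asarray(test_y))
    assert accuracy == 1.0


def test_shuffled_labels_give_chance_accuracy():
    features, labels = _synthetic_features(seed=2)
    rng = np.random.default_rng(7)
    shuffled = list(rng.permutation(labels))
    train_x, test_x = split_pairs(features, seed=2)
    train_y, test_y = split_pairs(shuffled, seed=2)
    clf = train_classifier(train_x, train_y, seed=2)
    accuracy = np.mean(clf.predict(test_x) == np.asarray(test_y))
    assert abs(accuracy - 0.5) <= 0.1


def test_two_point_training_separates_them():
    features = [PairFeature(0.9, 0.9, 0.9), PairFeature(0.1, 0.1, 0.1)]
    clf = train_classifier(features, [True, False])
    assert list(clf.predict(features)) == [True, False]


def test_single_label_input_rejected():
    features = [PairFeature(0.9, 0.9, 0.9), PairFeature(0.8, 0.8, 0.8)]
    with pytest.raises(ValueError):
        train_classifier(features, [True, True])


def test_weights_non_negative():
    features, labels = _synthetic_features(seed=3)
    clf = train_classifier(features, labels)
    assert np.all(clf.weights >= 0)


def test_classifier_json_round_trip():
    features, labels = _synthetic_features(seed=4)
    clf = train_classifier(features, labels)
    from cathkit.homology import TrainedClassifier

    back = TrainedClassifier.from_dict(clf.to_dict())
    np.testing.assert_allclose(back.weights, clf.weights)
    assert back.threshold == clf.threshold


# ---------------------------------------------------------------------------
# precision-recall
# ---------------------------------------------------------------------------


def test_perfect_separation_gives_aupr_one():
    features, labels = _synthetic_features(seed=5)
    clf = train_classifier(features, labels)
    _, _, aupr = evaluate_precision_recall(clf, features, labels)
    assert aupr == pytest.approx(1.0, abs=1e-9)


def test_random_scores_aupr_near_positive_fraction():
    features, labels = _synthetic_features(seed=6, separated=False)
    clf = train_classifier(features, labels)
    _, _, aupr = evaluate_precision_recall(clf, features, labels)
    assert abs(aupr - 0.5) < 0.15  # positive fraction is 0.5


def test_empty_test_set_rejected():
    features, labels = _synthetic_features(seed=7)
    clf = train_classifier(features, labels)
    with pytest.raises(ValueError):
        evaluate_precision_recall(clf, [], [])


# ---------------------------------------------------------------------------
# assignment protocol
# ---------------------------------------------------------------------------

SF = parse_cath_code("3.40.50.620")


def _hit(svm=0.0, ssap=0.0, overlap=0.0, code=SF, match="m001"):
    return CandidateHit(match, code, svm, ssap, overlap)


def test_good_svm_hit_assigns_existing_superfamily():
    decision = decide_assignment([_hit(svm=3.50, overlap=72.0)])
    assert decision.outcome == "assign_existing"
    assert decision.target == SF


def test_fallback_creates_new_superfamily_in_fold():
    hits = [_hit(svm=3.10, ssap=75.0, overlap=65.0)]
    decision = decide_assignment(hits)
    assert decision.outcome == "new_superfamily_in_fold"
    assert decision.target == parse_cath_code("3.40.50")


def test_excluded_superfamily_falls_through_to_manual_review():
    hits = [_hit(svm=3.50, ssap=60.0, overlap=72.0)]
    decision = decide_assignment(hits, exclusion_nodes=[parse_cath_code("3.40")])
    assert decision.outcome == "manual_review"
    assert decision.target is None
    assert decision.best_svm_hit is not None


def test_empty_candidate_list_is_manual_review():
    decision = decide_assignment([])
    assert decision.outcome == "manual_review"
    assert decision.best_svm_hit is None and decision.best_ssap_hit is None


def test_protocol_truth_table_at_boundaries():
    """Exhaustive three-branch check around 3.47 / 70 / 70 / 60 (inclusive)."""
    thresholds = Thresholds()
    svm_values = (3.46, 3.47, 3.48)
    ssap_values = (69.9, 70.0, 70.1)
    overlap_values = (59.9, 60.0, 69.9, 70.0, 70.1)
    for svm, ssap, overlap in itertools.product(svm_values, ssap_values, overlap_values):
        decision = decide_assignment([_hit(svm=svm, ssap=ssap, overlap=overlap)], thresholds)
        if svm >= 3.47 and overlap >= 70.0:
            expected = "assign_existing"
        elif ssap >= 70.0 and overlap >= 60.0:
            expected = "new_superfamily_in_fold"
        else:
            expected = "manual_review"
        assert decision.outcome == expected, (svm, ssap, overlap)


def test_tie_breaking_prefers_overlap_then_id():
    a = _hit(svm=3.5, overlap=80.0, match="m002", code=parse_cath_code("1.10.10.10"))
    b = _hit(svm=3.5, overlap=90.0, match="m003", code=parse_cath_code("2.20.20.20"))
    c = _hit(svm=3.5, overlap=90.0, match="m001", code=parse_cath_code("3.30.30.30"))
    decision = decide_assignment([a, b, c])
    assert decision.target == parse_cath_code("3.30.30.30")  # m001 wins the tie
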