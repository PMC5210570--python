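"""Conservation, DOPs, freezing, version mapping, inclusion, naming, networks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cathkit import fixtures
from cathkit.funfam import (
    ConservationProfile,
    FunFamRecord,
    admits,
    build_funfam_network,
    column_conservation,
    conservation_profile,
    dops_score,
    inclusion_threshold,
    map_version_overlap,
    name_cluster,
    select_frozen,
    sequence_identity_pct,
)
from cathkit.prc import build_profile
from cathkit.types import MSA, parse_region

# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------


def test_fully_conserved_column_scores_one():
    msa = MSA([(f"s{i}", "W") for i in range(10)])
    assert column_conservation(msa) == [1.0]


def test_maximal_entropy_column_scores_zero():
    msa = MSA([(f"s{i}", aa) for i, aa in enumerate("ACDEFGHIKLMNPQRSTVWY")])
    assert column_conservation(msa)[0] == pytest.approx(0.0, abs=1e-12)


def test_gap_fraction_scales_conservation():
    # column A,A,-,-: (1 - 0) * (1 - 0.5) = 0.5
    msa = MSA([("1", "A"), ("2", "A"), ("3", "-"), ("4", "-")])
    assert column_conservation(msa) == [0.5]


def test_all_gap_column_scores_zero():
    msa = MSA([("1", "A-"), ("2", "A-")])
    assert column_conservation(msa) == [1.0, 0.0]


def test_conservation_bounds_on_random_alignments():
    msa = fixtures.make_msa_with_conservation([0.1, 0.35, 0.62, 0.9], depth=40, seed=5)
    scores = column_conservation(msa)
    assert all(0.0 <= s <= 1.0 for s in scores)
    for score, target in zip(scores, [0.1, 0.35, 0.62, 0.9]):
        assert abs(score - target) <= 0.05


# ---------------------------------------------------------------------------
# DOPs
# ---------------------------------------------------------------------------


def test_dops_zero_when_all_columns_identical():
    assert dops_score([0.4] * 12) == 0.0


def test_dops_hundred_when_all_columns_distinct():
    assert dops_score([i / 20 for i in range(12)]) == 100.0


def test_dops_hand_computed_intermediate():
    # (0.2, 0.2, 0.8): u=2, L=3 -> 100 * (2-1)/(3-1) = 50
    assert dops_score([0.2, 0.2, 0.8]) == 50.0


def test_dops_rounding_merges_nearby_scores():
    assert dops_score([0.2004, 0.2001, 0.8], precision=3) == 50.0
    assert dops_score([0.2004, 0.2001, 0.8], precision=4) == 100.0


def test_dops_single_column_and_empty():
    assert dops_score([0.7]) == 0.0
    with pytest.raises(ValueError):
        dops_score([])


@given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=30), st.randoms())
@settings(max_examples=100, derandomize=True)
def test_dops_invariant_under_column_permutation(scores, rnd):
    permuted = scores[:]
    rnd.shuffle(permuted)
    assert dops_score(permuted) == dops_score(scores)


# ---------------------------------------------------------------------------
# freezing
# ---------------------------------------------------------------------------


def _record(ff_id, dops):
    rec = FunFamRecord(ff_id, members=["a"])
    rec.conservation = ConservationProfile([0.5], dops)
    return rec


def test_frozen_partition_boundary_inclusive():
    frozen, updatable = select_frozen([_record("1.1.1.1/FF/1", 70.0), _record("1.1.1.1/FF/2", 69.9)])
    assert [f.funfam_id for f in frozen] == ["1.1.1.1/FF/1"]
    assert [u.funfam_id for u in updatable] == ["1.1.1.1/FF/2"]
    assert frozen[0].frozen and not updatable[0].frozen


def test_frozen_partition_empty_input():
    assert select_frozen([]) == ([], [])


# ---------------------------------------------------------------------------
# version mapping
# ---------------------------------------------------------------------------


def test_identical_regions_fully_overlap():
    region = parse_region("1-100")
    overlap, keep = map_version_overlap(region, region)
    assert overlap == 100.0 and keep


def test_truncated_domain_below_70_is_removed():
    overlap, keep = map_version_overlap(parse_region("1-100"), parse_region("1-69"))
    assert overlap == 69.0 and not keep


def test_disjoint_regions_do_not_map():
    overlap, keep = map_version_overlap(parse_region("1-50"), parse_region("60-110"))
    assert overlap == 0.0 and not keep


def test_discontiguous_overlap_uses_longer_denominator():
    old = parse_region("1-40,61-100")  # 80 residues
    new = parse_region("1-40")  # 40 residues
    overlap, keep = map_version_overlap(old, new)
    assert overlap == 50.0 and not keep


# ---------------------------------------------------------------------------
# inclusion thresholds
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def family():
    members = {
        "m1": "ACDEFGHIKLMNPQRSTVWY",
        "m2": "ACDEFGHIKLMNPQRSTVWA",
        "m3": "ACDEFGHIKLMNPQRSTVCY",
    }
    msa = MSA([(name, seq) for name, seq in members.items()])
    return build_profile(msa, pseudocount=0.5), members


def test_threshold_is_minimum_member_score(family):
    profile, members = family
    threshold = inclusion_threshold(profile, members, pseudocount=0.5)
    from cathkit.prc import compare_profiles, sequence_profile

    scores = [compare_profiles(sequence_profile(s, 0.5), profile).score for s in members.values()]
    assert threshold == min(scores)


def test_single_member_family_threshold(family):
    profile, members = family
    only = {"m1": members["m1"]}
    threshold = inclusion_threshold(profile, only, pseudocount=0.5)
    from cathkit.prc import compare_profiles, sequence_profile

    assert threshold == compare_profiles(sequence_profile(members["m1"], 0.5), profile).score


def test_admission_is_strict(family):
    profile, members = family
    threshold = inclusion_threshold(profile, members, pseudocount=0.5)
    # the weakest member itself scores == threshold, so it is NOT re-admitted
    weakest = min(
        members.values(),
        key=lambda s: inclusion_threshold(profile, {"x": s}, pseudocount=0.5),
    )
    assert not admits(profile, threshold, weakest, pseudocount=0.5)


def test_unrelated_candidate_rejected(family):
    profile, members = family
    threshold = inclusion_threshold(profile, members, pseudocount=0.5)
    rng = np.random.default_rng(12)
    unrelated = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=20))
    assert not admits(profile, threshold, unrelated, pseudocount=0.5)


# ---------------------------------------------------------------------------
# naming
# ---------------------------------------------------------------------------


def test_naming_hand_worked_example():
    records = [
        ("s1", "Alanine racemase", "ACDEFGHIKLMNPQRSTVWY"),
        ("s2", "Alanine racemase", "YWVTSRQPNMLKIHGFEDCA"),
        ("s3", "Putative protein", "AAAACCCCDDDDEEEEFFFF"),
    ]
    result = name_cluster(records, stopwords=frozenset({"putative", "protein"}))
    assert result.name == "Alanine racemase"
    assert result.term_scores == {"alanine": 2, "racemase": 2}


def test_single_description_names_itself():
    result = name_cluster([("s1", "Polyketide synthase", "ACDE")])
    assert result.name == "Polyketide synthase"


def test_redundant_sequences_keep_one_description():
    seq = "ACDEFGHIKLMNPQRSTVWY" * 3
    near = seq[:-1] + "A"  # > 95% identical
    records = [("s1", "Alpha name", seq), ("s2", "Beta name", near)]
    result = name_cluster(records)
    assert len(result.representative_descriptions) == 1


def test_all_stopword_descriptions_fall_back_to_sentinel():
    records = [("s1", "putative protein", "ACDE"), ("s2", "predicted fragment", "WYWY")]
    assert name_cluster(records).name == "uncharacterized"


def test_naming_deterministic_and_dedup_idempotent():
    records = [
        ("s1", "Alanine racemase", "ACDEFGHIKLMNPQRSTVWY"),
        ("s2", "Serine kinase", "YWVTSRQPNMLKIHGFEDCA"),
        ("s3", "Alanine racemase", "ACDEFGHIKLMNPQRSTVWA"),  # near-duplicate of s1
    ]
    first = name_cluster(records)
    again = name_cluster(records)
    assert first.name == again.name
    without_dup = name_cluster(records[:2])
    assert first.name == without_dup.name


def test_sequence_identity_measure():
    assert sequence_identity_pct("ACDE", "ACDE") == 100.0
    assert sequence_identity_pct("ACDE", "ACDF") == 75.0


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


def _families(n):
    return [FunFamRecord(f"1.10.10.10/FF/{i}", members=[f"s{i}a", f"s{i}b"]) for i in range(n)]


def test_edge_threshold_is_strict():
    fams = _families(2)
    ids = [f.funfam_id for f in fams]
    no_edge = build_funfam_network(fams, {(ids[0], ids[1]): 10.0}, threshold=10.0)
    assert no_edge.number_of_edges() == 0
    edge = build_funfam_network(fams, {(ids[0], ids[1]): 10.5}, threshold=10.0)
    assert edge.number_of_edges() == 1
    assert edge.nodes[ids[0]]["size"] == 2


def test_all_pairs_above_threshold_give_complete_graph():
    fams = _families(5)
    ids = [f.funfam_id for f in fams]
    scores = {(a, b): 25.0 for i, a in enumerate(ids) for b in ids[i + 1 :]}
    graph = build_funfam_network(fams, scores, threshold=10.0)
    assert graph.number_of_edges() == 5 * 4 // 2


def test_network_reproducible_from_score_table(tmp_path):
    import networkx as nx

    from cathkit.io import write_graphml

    fams = _families(3)
    ids = [f.funfam_id for f in fams]
    scores = {(ids[0], ids[1]): 12.0, (ids[1], ids[2]): 3.0}
    graph = build_funfam_network(fams, scores, threshold=10.0)
    path = tmp_path / "net.graphml"
    write_graphml(graph, path)
    back = nx.read_graphml(path)
    assert set(back.edges()) == {(ids[0], ids[1])}


def test_conservation_profile_combines_scores_and_dops():
    msa = fixtures.make_msa_with_conservation([1.0, 0.5, 0.1], depth=30, seed=1)
    profile = conservation_profile(msa)
    assert len(profile.scores) == 3
    assert 0.0 <= profile.dops <= 100.0
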