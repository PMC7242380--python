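"""Marker tracking: identity, clustering, breadth, presence, abundance, ranks."""

import numpy as np
import pytest

from lipidlink.markers import (
    AlignmentRecord,
    DepthProfile,
    MarkerScaffold,
    breadth,
    call_presence,
    cluster_markers,
    depth_from_alignments,
    filter_alignments,
    pairwise_identity,
    relative_abundance,
    taxonomic_rank_from_identity,
)

# --- pairwise identity -----------------------------------------------------

def enumerate_global_alignments(a, b):
    """All global alignments of a and b as lists of column pairs
    ((char|None), (char|None)); exhaustive recursion for tiny strings."""
    if not a and not b:
        return [[]]
    out = []
    if a and b:
        out += [[(a[0], b[0])] + rest for rest in enumerate_global_alignments(a[1:], b[1:])]
    if a:
        out += [[(a[0], None)] + rest for rest in enumerate_global_alignments(a[1:], b)]
    if b:
        out += [[(None, b[0])] + rest for rest in enumerate_global_alignments(a, b[1:])]
    return out


def alignment_score_and_identity(columns):
    score = 0.0
    matches = 0
    for x, y in columns:
        if x is None or y is None:
            score -= 1.0
        elif x == y:
            score += 1.0
            matches += 1
    return score, matches / len(columns)


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("A" * 100, "A" * 100, 1.0),
        ("AAAA", "AAAT", 0.75),
        ("MKLV", "MKIV", 0.75),
    ],
)
def test_identity_known_values(a, b, expected):
    assert pairwise_identity(a, b) == pytest.approx(expected)


def test_identity_symmetric_bounded_and_errors():
    assert pairwise_identity("MKLVA", "MKV") == pytest.approx(
        pairwise_identity("MKV", "MKLVA")
    )
    assert 0.0 <= pairwise_identity("AAAA", "WWWW") <= 1.0
    with pytest.raises(ValueError):
        pairwise_identity("", "AAA")


def test_identity_matches_exhaustive_alignment_enumeration():
    """On short random pairs the returned identity must equal the identity
    of some maximum-score global alignment (match +1, mismatch 0, gap -1)."""
    rng = np.random.default_rng(11)
    alphabet = np.array(list("ACDMKLV"))
    for _ in range(40):
        la, lb = rng.integers(1, 5, size=2)
        a = "".join(rng.choice(alphabet, size=la))
        b = "".join(rng.choice(alphabet, size=lb))
        scored = [alignment_score_and_identity(c)
                  for c in enumerate_global_alignments(a, b)]
        best = max(s for s, _ in scored)
        optimal_identities = {i for s, i in scored if s == best}
        got = pairwise_identity(a, b)
        assert any(got == pytest.approx(i) for i in optimal_identities)


# --- clustering ------------------------------------------------------------

def scaf(id_, seq, length=None):
    return MarkerScaffold(id=id_, length_bp=length or 3 * len(seq), protein_seq=seq)


def test_identical_sequences_one_cluster():
    cs = cluster_markers([scaf("a", "MKLVQD" * 30, 1000), scaf("b", "MKLVQD" * 30, 900)])
    assert len(cs.clusters) == 1
    assert cs.clusters[0]["representative_id"] == "a"  # longest founds the cluster


def test_below_threshold_pair_splits():
    base = "MKLVQDAERT" * 10  # 100 aa
    variant = "WW" + base[2:]  # identity 0.98
    cs = cluster_markers([scaf("a", base, 400), scaf("b", variant, 300)], threshold=0.99)
    assert len(cs.clusters) == 2


def test_greedy_chain_resolution():
    """B joins A, but C (close to B, too far from A) founds its own cluster."""
    base = list("MKLVQDAERTGHSWYN" * 25)  # 400 aa
    a = "".join(base)
    b_l = list(base); b_l[0] = "W"; b_l[1] = "C"  # A~B = 398/400 = 0.995
    c_l = list(b_l); c_l[10] = "H"; c_l[11] = "P"; c_l[12] = "G" if b_l[12] != "G" else "A"
    b, c = "".join(b_l), "".join(c_l)
    assert pairwise_identity(a, b) >= 0.995
    assert pairwise_identity(b, c) >= 0.99
    assert pairwise_identity(a, c) < 0.99
    cs = cluster_markers(
        [scaf("A", a, 600), scaf("B", b, 500), scaf("C", c, 400)], threshold=0.99
    )
    members = sorted(tuple(sorted(cl["member_ids"])) for cl in cs.clusters)
    assert members == [("A", "B"), ("C",)]


def test_threshold_extremes():
    seqs = [scaf(f"s{i}", s, 300 - i) for i, s in
            enumerate(["MKLV" * 20, "WWWW" * 20, "ACDE" * 20])]
    assert len(cluster_markers(seqs, threshold=1.0).clusters) == 3
    assert len(cluster_markers(seqs, threshold=0.0).clusters) == 1


# --- mismatch filter, breadth, presence ------------------------------------

def test_filter_alignments_threshold():
    recs = [AlignmentRecord("r", "s", 0, 50, m) for m in (0, 3, 4)]
    kept = filter_alignments(recs, max_mismatches=3)
    assert [r.mismatches for r in kept] == [0, 3]
    assert filter_alignments([]) == []


def test_breadth_examples():
    s = MarkerScaffold("x", 4, "M")
    p = DepthProfile("x", "S1", np.array([2, 0, 3, 1]))
    assert breadth(p, s) == pytest.approx(0.75)
    s_amb = MarkerScaffold("x", 4, "M", ambiguous_positions={1})
    assert breadth(p, s_amb) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        breadth(p, MarkerScaffold("x", 4, "M", ambiguous_positions={0, 1, 2, 3}))


def test_breadth_matches_naive_oracle():
    rng = np.random.default_rng(3)
    for _ in range(300):
        n = int(rng.integers(1, 200))
        depth = rng.integers(0, 4, size=n)
        amb = set(int(i) for i in rng.choice(n, size=int(rng.integers(0, n)), replace=False))
        if len(amb) == n:
            amb.pop()
        s = MarkerScaffold("x", n, "M", ambiguous_positions=amb)
        p = DepthProfile("x", "S", depth)
        num = sum(1 for i in range(n) if i not in amb and depth[i] >= 1)
        den = sum(1 for i in range(n) if i not in amb)
        assert breadth(p, s) == pytest.approx(num / den)


@pytest.mark.parametrize(
    "assembled, b, expected",
    [(False, 0.96, True), (True, 0.10, True), (False, 0.94, False),
     (False, 0.95, True)],
)
def test_call_presence(assembled, b, expected):
    assert call_presence(assembled, b) is expected


def test_depth_from_alignments_applies_mismatch_filter():
    s = MarkerScaffold("x", 10, "M")
    recs = [
        AlignmentRecord("r1", "x", 0, 5, 0),
        AlignmentRecord("r2", "x", 3, 8, 4),  # dropped: too many mismatches
    ]
    p = depth_from_alignments(recs, s, "S1")
    assert list(p.depth) == [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]


# --- relative abundance and rank assignment --------------------------------

def test_relative_abundance_closure():
    cov = {"a": {"S1": 10.0, "S2": 5.0}, "b": {"S1": 30.0, "S2": 0.0}}
    t = relative_abundance(cov)
    np.testing.assert_allclose(t.values["S1"].to_numpy(), [25.0, 75.0])
    np.testing.assert_allclose(t.values["S2"].to_numpy(), [100.0, 0.0])
    rng = np.random.default_rng(5)
    cov = {f"s{i}": {"S1": float(rng.uniform(0.1, 50))} for i in range(5)}
    assert relative_abundance(cov).values["S1"].sum() == pytest.approx(100.0)


@pytest.mark.parametrize(
    "identity, rank",
    [(99.2, "species"), (99.0, "species"), (95.0, "genus"), (92.0, "family"),
     (90.0, "family"), (40.0, "phylum/domain"), (49.9, "phylum/domain"),
     (70.0, "above-family (unresolved)")],
)
def test_taxonomic_rank_cutoffs(identity, rank):
    assert taxonomic_rank_from_identity(identity) == rank


def test_taxonomic_rank_out_of_range():
    with pytest.raises(ValueError):
        taxonomic_rank_from_identity(101.0)
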