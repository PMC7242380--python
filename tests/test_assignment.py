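"""Correlation statistics, weighting, assignment, roles and network."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import brute_force_assignment, random_instance
from lipidlink.abundance import AbundanceTable, FeatureKind
from lipidlink.assignment import (
    ConstantVectorError,
    CorrelationRecord,
    assign_primary,
    bonferroni,
    build_network,
    classify_roles,
    correlate_tables,
    lipid_cocorrelation,
    pearson_with_p,
    summarize_assignments,
    weight_score,
)


def table(vals, prefix, kind):
    vals = np.asarray(vals, dtype=float)
    return AbundanceTable(
        pd.DataFrame(
            vals,
            index=[f"{prefix}{i}" for i in range(vals.shape[0])],
            columns=[f"S{i}" for i in range(vals.shape[1])],
        ),
        kind,
    )


# --- pearson ---------------------------------------------------------------

def test_pearson_known_values():
    r, p = pearson_with_p([1, 2, 3], [2, 4, 6])
    assert r == pytest.approx(1.0, abs=1e-12) and p < 1e-7
    r, p = pearson_with_p([1, 2, 3, 4], [1, 3, 2, 4])
    assert r == pytest.approx(0.8)


def test_pearson_constant_vector_raises():
    with pytest.raises(ConstantVectorError):
        pearson_with_p([1, 2, 3], [5, 5, 5])


def test_pearson_matches_scipy_reference():
    rng = np.random.default_rng(2)
    for n in (5, 10, 14, 30):
        x = rng.normal(size=n)
        y = 0.4 * x + rng.normal(size=n)
        r, p = pearson_with_p(x, y)
        ref = stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


# --- bonferroni and weighting ---------------------------------------------

@pytest.mark.parametrize(
    "p, m, q", [(0.001, 100, 0.1), (0.02, 100, 1.0), (0.5, 1, 0.5)]
)
def test_bonferroni_values(p, m, q):
    assert bonferroni([p], m) == [pytest.approx(q)]


def test_bonferroni_rejects_invalid_p():
    with pytest.raises(ValueError):
        bonferroni([1.2], 10)


@given(
    p1=st.floats(0, 1), p2=st.floats(0, 1),
    m1=st.integers(1, 1000), m2=st.integers(1, 1000),
)
@settings(max_examples=200, deadline=None)
def test_bonferroni_monotone_in_p_and_m(p1, p2, m1, m2):
    lo_p, hi_p = sorted((p1, p2))
    lo_m, hi_m = sorted((m1, m2))
    assert bonferroni([lo_p], hi_m)[0] <= bonferroni([hi_p], hi_m)[0]
    assert bonferroni([lo_p], lo_m)[0] <= bonferroni([lo_p], hi_m)[0]


def test_weight_score_scaling():
    assert weight_score(0.004, 2.0) == pytest.approx(0.002)
    assert weight_score(0.004, 0.1) == pytest.approx(0.04)
    assert weight_score(0.01, 4.0) == pytest.approx(weight_score(0.01, 2.0) / 2)
    with pytest.raises(ValueError):
        weight_score(0.01, 0.0)


# --- assignment ------------------------------------------------------------

def rec(org, lip, r=0.9, p=1e-6, q=1e-4, score=1e-4):
    return CorrelationRecord(org, lip, r, p, q, score)


def test_assign_primary_picks_best_score():
    records = [rec("A", "L", score=0.001), rec("B", "L", score=0.01)]
    out = assign_primary(records)
    assert out["L"].organism_id == "A"


def test_assign_primary_alpha_gate():
    assert assign_primary([rec("A", "L", q=0.005)]) == {}  # q not < alpha
    assert "L" in assign_primary([rec("A", "L", q=0.00499)])


def test_assign_primary_tie_breaks():
    # equal score: lower q wins; then higher |r|; then organism id
    out = assign_primary([rec("A", "L", q=2e-4, score=0.1),
                          rec("B", "L", q=1e-4, score=0.1)])
    assert out["L"].organism_id == "B"
    out = assign_primary([rec("A", "L", r=0.8), rec("B", "L", r=-0.95)])
    assert out["L"].organism_id == "B"
    out = assign_primary([rec("B", "L"), rec("A", "L")])
    assert out["L"].organism_id == "A"


def test_assign_primary_matches_exhaustive_argmin():
    """Planted 5-organism x 10-lipid record set: assignment equals a
    brute-force argmin with the tie-break chain."""
    rng = np.random.default_rng(9)
    records = []
    for org in [f"O{i}" for i in range(5)]:
        for lip in [f"L{j}" for j in range(10)]:
            q = float(rng.uniform(0, 0.01))
            records.append(
                CorrelationRecord(org, lip, float(rng.uniform(-1, 1)),
                                  q / 5, q, q / float(rng.uniform(0.5, 5)))
            )
    result = assign_primary(records, alpha=0.005)
    for lip in {r.lipid_id for r in records}:
        qualifying = [r for r in records if r.lipid_id == lip and r.q < 0.005]
        if not qualifying:
            assert lip not in result
            continue
        best = min(qualifying, key=lambda r: (r.score, r.q, -abs(r.r), r.organism_id))
        assert result[lip].organism_id == best.organism_id


# --- co-correlation --------------------------------------------------------

def test_cocorrelation_detects_covarying_pair():
    rng = np.random.default_rng(4)
    base = rng.lognormal(0, 1, 14)
    vals = np.vstack([base, base * 3.0, rng.lognormal(0, 1, 14)])
    edges = lipid_cocorrelation(table(vals, "L", FeatureKind.LIPID), min_presence=7)
    pairs = {frozenset((a, b)) for a, b, *_ in edges}
    assert frozenset(("L0", "L1")) in pairs


def test_cocorrelation_null_yields_no_edges():
    rng = np.random.default_rng(6)
    vals = rng.lognormal(0, 1, size=(10, 14))
    edges = lipid_cocorrelation(table(vals, "L", FeatureKind.LIPID), min_presence=7)
    assert edges == []


def test_cocorrelation_single_lipid_empty():
    vals = np.random.default_rng(0).lognormal(0, 1, size=(1, 14))
    assert lipid_cocorrelation(table(vals, "L", FeatureKind.LIPID)) == []


# --- roles and network -----------------------------------------------------

def test_classify_roles_partition():
    assignments = {"P1": rec("A", "P1"), "P2": rec("B", "P2")}
    edges = [("P1", "S1", 0.9, 1e-6, 1e-4), ("P1", "U1", 0.9, 1e-6, 1e-4),
             ("P2", "U1", 0.9, 1e-6, 1e-4)]
    roles = classify_roles(assignments, edges, all_lipids=["P1", "P2", "S1", "U1", "X"])
    assert roles == {"P1": "primary", "P2": "primary", "S1": "secondary",
                     "U1": "unspecific", "X": "unassigned"}


def test_network_role_invariants():
    assignments = {"P1": rec("A", "P1"), "P2": rec("B", "P2")}
    edges = [("P1", "S1", 0.9, 1e-6, 1e-4), ("P1", "P2", 0.9, 1e-6, 1e-4)]
    g = build_network(assignments, edges)
    for node, data in g.nodes(data=True):
        if data.get("kind") == "lipid":
            n_org = sum(1 for nb in g.neighbors(node)
                        if g.nodes[nb].get("kind") == "organism")
            assert n_org <= 1
    s = summarize_assignments(g)
    assert s["n_primary_lipids"] == 2 and s["n_secondary_lipids"] == 1


def test_summarize_empty_network():
    s = summarize_assignments(nx.Graph())
    assert all(v == 0 for v in s.values())


def test_reference_table_counts(reference_network):
    s = summarize_assignments(reference_network)
    assert s["n_primary_lipids"] == 44
    assert s["n_organisms_with_lipids"] == 22
    assert s["n_secondary_lipids"] == 63


# --- oracle equivalence on random instances --------------------------------

@pytest.mark.parametrize("seed", range(25))
def test_pipeline_equals_brute_force(seed):
    """Full assignment output equals a naive reimplementation on random
    coupled instances (<= 8 organisms x 12 lipids x 14 samples)."""
    rng = np.random.default_rng(1000 + seed)
    n_org = int(rng.integers(2, 9))
    n_lip = int(rng.integers(2, 13))
    org_df, lip_df = random_instance(rng, n_org, n_lip)
    oracle = brute_force_assignment(org_df, lip_df, min_presence=7, alpha=0.005)

    org_t = AbundanceTable(org_df, FeatureKind.ORGANISM)
    lip_t = AbundanceTable(lip_df, FeatureKind.LIPID)
    records = correlate_tables(org_t, lip_t, min_presence=7)
    assignments = assign_primary(records, alpha=0.005)
    edges = lipid_cocorrelation(lip_t, min_presence=7, alpha=0.005)
    roles = classify_roles(assignments, edges, all_lipids=lip_t.feature_ids)

    assert {l: r.organism_id for l, r in assignments.items()} == oracle["assignments"]
    assert {frozenset((a, b)) for a, b, *_ in edges} == oracle["edges"]
    assert roles == oracle["roles"]


# --- planted-truth recovery ------------------------------------------------

def test_planted_truth_recovery_zero_noise():
    from lipidlink import default_truth, simulate_community, simulate_lipidome
    from lipidlink.assignment import score_against_truth

    truth = default_truth(42, noise_sd=0.0)
    org = simulate_community(truth)
    lip = simulate_lipidome(org, truth)
    records = correlate_tables(org, lip, min_presence=7)
    assignments = assign_primary(records, alpha=0.005)
    pr = score_against_truth(assignments, truth.producer_map)
    assert pr["precision"] == 1.0 and pr["recall"] == 1.0


def test_planted_truth_recovery_with_noise():
    from lipidlink import default_truth, simulate_community, simulate_lipidome
    from lipidlink.assignment import score_against_truth

    precisions = []
    for seed in range(200, 220):
        truth = default_truth(seed, noise_sd=0.1)
        org = simulate_community(truth)
        lip = simulate_lipidome(org, truth)
        records = correlate_tables(org, lip, min_presence=7)
        assignments = assign_primary(records, alpha=0.005)
        precisions.append(score_against_truth(assignments, truth.producer_map)["precision"])
    assert np.mean(precisions) >= 0.9
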