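"""Shared fixtures and independent oracle implementations.

The brute-force assignment oracle here deliberately re-derives every
statistic with naive formulas and scipy.stats.pearsonr (a different code
path from the package's own t-distribution computation) so that pipeline
tests compare two independent routes.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidlink import load_reference_assignments


@pytest.fixture(scope="session")
def reference_network():
    return load_reference_assignments()


@pytest.fixture(scope="session")
def reference_lipid_names(reference_network) -> List[str]:
    return sorted(
        n for n, d in reference_network.nodes(data=True) if d.get("kind") == "lipid"
    )


# --- brute-force assignment oracle ----------------------------------------

def brute_force_assignment(
    org_df: pd.DataFrame,
    lip_df: pd.DataFrame,
    min_presence: int = 7,
    alpha: float = 0.005,
) -> Dict[str, object]:
    """Naive reimplementation of the full assignment procedure.

    All-pairs Pearson via scipy.stats.pearsonr, Bonferroni with the count of
    tested pairs, abundance weighting, per-lipid argmin with the full
    tie-break chain, lipid co-correlation and role classification — written
    as plain loops with no shared code with the package.
    """
    samples = list(org_df.columns)
    orgs = [o for o in org_df.index if (org_df.loc[o] > 0).sum() >= min_presence]
    lips = [l for l in lip_df.index if (lip_df.loc[l] > 0).sum() >= min_presence]

    tested = []
    for o in orgs:
        x = org_df.loc[o, samples].to_numpy(float)
        if x.mean() <= 0:
            continue
        for l in lips:
            y = lip_df.loc[l, samples].to_numpy(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            r, p = stats.pearsonr(x, y)
            tested.append((o, l, float(r), float(p), float(x.mean())))
    m = len(tested)
    best: Dict[str, Tuple] = {}
    for o, l, r, p, mean_ab in tested:
        q = min(1.0, p * m)
        if q >= alpha:
            continue
        score = q / mean_ab
        key = (score, q, -abs(r), o)
        if l not in best or key < best[l][0]:
            best[l] = (key, o, r, q, score)
    assignments = {l: v[1] for l, v in best.items()}

    pair_tested = []
    for a, b in itertools.combinations(lips, 2):
        x = lip_df.loc[a, samples].to_numpy(float)
        y = lip_df.loc[b, samples].to_numpy(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            continue
        r, p = stats.pearsonr(x, y)
        pair_tested.append((a, b, float(r), float(p)))
    m2 = len(pair_tested)
    edges = {
        frozenset((a, b))
        for a, b, r, p in pair_tested
        if min(1.0, p * m2) < alpha
    }

    roles: Dict[str, str] = {}
    for l in lip_df.index:
        if l in assignments:
            roles[l] = "primary"
            continue
        neighbour_orgs = {
            assignments[other]
            for other in assignments
            if frozenset((l, other)) in edges
        }
        if len(neighbour_orgs) >= 2:
            roles[l] = "unspecific"
        elif len(neighbour_orgs) == 1:
            roles[l] = "secondary"
        else:
            roles[l] = "unassigned"
    return {"assignments": assignments, "edges": edges, "roles": roles}


def random_instance(
    rng: np.random.Generator,
    n_org: int,
    n_lip: int,
    n_samples: int = 14,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Random coupled tables: some lipids track organisms, some are noise."""
    samples = [f"S{i:02d}" for i in range(n_samples)]
    org = rng.lognormal(0, 1, size=(n_org, n_samples))
    org = org / org.sum(axis=0) * 100
    org_df = pd.DataFrame(org, index=[f"O{i}" for i in range(n_org)], columns=samples)
    lip = np.empty((n_lip, n_samples))
    for i in range(n_lip):
        if rng.random() < 0.5:
            src = int(rng.integers(0, n_org))
            lip[i] = org[src] * rng.lognormal(0, 0.2, size=n_samples)
        else:
            lip[i] = rng.lognormal(0, 1, size=n_samples)
    # random sparsity so presence filtering is exercised
    drop = rng.random(lip.shape) < 0.15
    lip[drop] = 0.0
    totals = lip.sum(axis=0)
    totals[totals == 0] = 1.0
    lip = lip / totals * 100
    lip_df = pd.DataFrame(lip, index=[f"L{i}" for i in range(n_lip)], columns=samples)
    return org_df, lip_df
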