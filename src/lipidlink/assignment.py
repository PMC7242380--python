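"""Organism-lipid correlation assignment and network construction.

The central statistical procedure of the package.  Organism (marker gene)
and lipid percent-abundance trajectories over the same sample series are
correlated pairwise (Pearson); p-values are Bonferroni-corrected and then
weighted by dividing the corrected value by the organism's percent relative
abundance, so that abundant organisms — which are far more likely to leave a
detectable lipid signal — are favoured.  Each lipid may be assigned to at
most one organism (best, i.e. lowest, score).  Lipids are additionally
co-correlated with each other; lipids that are not directly assigned but
correlate with an assigned ("primary") lipid are "secondary", and secondary
candidates touching primary lipids of two or more different organisms are
"unspecific".  The result is a bipartite-plus-lipid-lipid network.

Note on terminology: the correction applied is the Bonferroni procedure, a
family-wise error rate control, although the field often loosely calls this
"false discovery correction".  We implement Bonferroni literally.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .abundance import AbundanceTable, present_features

__all__ = [
    "CorrelationRecord",
    "ConstantVectorError",
    "pearson_with_p",
    "bonferroni",
    "weight_score",
    "correlate_tables",
    "assign_primary",
    "lipid_cocorrelation",
    "classify_roles",
    "build_network",
    "summarize_assignments",
    "score_against_truth",
    "load_reference_assignments",
    "write_correlation_tsv",
    "write_assignment_table",
    "write_network",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.005
DEFAULT_MIN_PRESENCE = 7

ROLE_PRIMARY = "primary"
ROLE_SECONDARY = "secondary"
ROLE_UNSPECIFIC = "unspecific"
ROLE_UNASSIGNED = "unassigned"


class ConstantVectorError(ValueError):
    """Pearson correlation is undefined for a constant vector."""


@dataclass(frozen=True)
class CorrelationRecord:
    """One organism-lipid correlation with corrected and weighted statistics.

    ``score = q / organism mean percent abundance``; lower is better.
    """

    organism_id: str
    lipid_id: str
    r: float
    p: float
    q: float
    score: float


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Sample Pearson r and two-sided p-value (t distribution, n-2 df).

    Raises :class:`ConstantVectorError` if either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(np.sqrt((xd * xd).sum()))
    sy = float(np.sqrt((yd * yd).sum()))
    if sx == 0.0 or sy == 0.0:
        raise ConstantVectorError("constant input vector")
    r = float((xd * yd).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, min(p, 1.0)


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> List[float]:
    """Bonferroni correction: q = min(1, p * m); order preserving."""
    ps = list(p_values)
    if m is None:
        m = len(ps)
    if m < 1:
        raise ValueError("m must be >= 1")
    for p in ps:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {p}")
    return [min(1.0, p * m) for p in ps]


def weight_score(q: float, organism_mean_percent_abundance: float) -> float:
    """Weight a corrected p-value by organism abundance (q / percent)."""
    if organism_mean_percent_abundance <= 0:
        raise ValueError("organism abundance must be > 0 to score")
    return q / organism_mean_percent_abundance


def correlate_tables(
    organisms: AbundanceTable,
    lipids: AbundanceTable,
    min_presence: int = DEFAULT_MIN_PRESENCE,
    organism_presence: Optional[pd.DataFrame] = None,
    copresent_only: bool = False,
) -> List[CorrelationRecord]:
    """All organism x lipid correlations over features passing the presence
    filter, Bonferroni-corrected over the pairs actually tested.

    By default trajectories span the full common sample set, treating
    absences as 0% (absence itself carries the depth-sourcing signal); with
    ``copresent_only`` each pair is restricted to samples where both
    features are detected.
    """
    common = [s for s in organisms.sample_ids if s in set(lipids.sample_ids)]
    if len(common) < 3:
        raise ValueError("need at least 3 shared samples")
    org_kept = present_features(
        AbundanceTable(organisms.values[common], organisms.feature_kind),
        min_presence,
        presence=organism_presence,
    )
    lip_kept = present_features(
        AbundanceTable(lipids.values[common], lipids.feature_kind), min_presence
    )

    raw: List[Tuple[str, str, float, float, float]] = []
    for org in org_kept:
        xfull = organisms.values.loc[org, common].to_numpy(dtype=float)
        mean_abund = float(xfull.mean())
        if mean_abund <= 0:
            logger.warning("organism %s has zero mean abundance; skipped", org)
            continue
        for lip in lip_kept:
            yfull = lipids.values.loc[lip, common].to_numpy(dtype=float)
            if copresent_only:
                mask = (xfull > 0) & (yfull > 0)
                if int(mask.sum()) < 3:
                    continue
                x, y = xfull[mask], yfull[mask]
            else:
                x, y = xfull, yfull
            try:
                r, p = pearson_with_p(x, y)
            except ConstantVectorError:
                logger.warning("constant trajectory for (%s, %s); pair skipped", org, lip)
                continue
            raw.append((org, lip, r, p, mean_abund))

    m = len(raw)
    records = []
    for org, lip, r, p, mean_abund in raw:
        q = min(1.0, p * m)
        records.append(
            CorrelationRecord(
                organism_id=org, lipid_id=lip, r=r, p=p, q=q,
                score=weight_score(q, mean_abund),
            )
        )
    return records


def assign_primary(
    records: Iterable[CorrelationRecord],
    alpha: float = DEFAULT_ALPHA,
) -> Dict[str, CorrelationRecord]:
    """Assign each lipid to at most one organism.

    Among records with q < alpha, the organism with the minimum score wins;
    ties break by lower q, then higher \\|r\\|, then lexicographic organism id.
    Lipids with no qualifying record stay unassigned.
    """
    best: Dict[str, CorrelationRecord] = {}
    for rec in records:
        if not rec.q < alpha:
            continue
        cur = best.get(rec.lipid_id)
        if cur is None:
            best[rec.lipid_id] = rec
            continue
        key_new = (rec.score, rec.q, -abs(rec.r), rec.organism_id)
        key_cur = (cur.score, cur.q, -abs(cur.r), cur.organism_id)
        if key_new < key_cur:
            best[rec.lipid_id] = rec
    return best


def lipid_cocorrelation(
    lipids: AbundanceTable,
    min_presence: int = DEFAULT_MIN_PRESENCE,
    alpha: float = DEFAULT_ALPHA,
) -> List[Tuple[str, str, float, float, float]]:
    """Significant lipid-lipid co-correlations.

    All unordered pairs of presence-filtered lipids are tested; Bonferroni m
    is the number of pairs actually tested (its own correction universe,
    separate from the organism-lipid stage).  Returns (a, b, r, p, q) for
    pairs with q < alpha.
    """
    kept = present_features(lipids, min_presence)
    tested: List[Tuple[str, str, float, float]] = []
    for a, b in itertools.combinations(kept, 2):
        x = lipids.values.loc[a].to_numpy(dtype=float)
        y = lipids.values.loc[b].to_numpy(dtype=float)
        try:
            r, p = pearson_with_p(x, y)
        except ConstantVectorError:
            logger.warning("constant lipid trajectory in pair (%s, %s); skipped", a, b)
            continue
        tested.append((a, b, r, p))
    m = len(tested)
    edges = []
    for a, b, r, p in tested:
        q = min(1.0, p * m)
        if q < alpha:
            edges.append((a, b, r, p, q))
    return edges


def classify_roles(
    primary_assignments: Mapping[str, CorrelationRecord],
    lipid_edges: Iterable[Tuple[str, str, float, float, float]],
    all_lipids: Optional[Iterable[str]] = None,
) -> Dict[str, str]:
    """Partition lipids into primary / secondary / unspecific / unassigned.

    Primary lipids carry a direct organism assignment.  A non-primary lipid
    adjacent (via co-correlation) to >=1 primary lipid is secondary; if its
    primary neighbours belong to >=2 different organisms it is unspecific.
    Role precedence: primary > unspecific > secondary.
    """
    edges = list(lipid_edges)
    roles: Dict[str, str] = {}
    lipid_universe = set(primary_assignments)
    for a, b, *_ in edges:
        lipid_universe.update((a, b))
    if all_lipids is not None:
        lipid_universe.update(all_lipids)

    adjacency: Dict[str, set] = {l: set() for l in lipid_universe}
    for a, b, *_ in edges:
        adjacency[a].add(b)
        adjacency[b].add(a)

    for lipid in lipid_universe:
        if lipid in primary_assignments:
            roles[lipid] = ROLE_PRIMARY
            continue
        neighbour_orgs = {
            primary_assignments[nb].organism_id
            for nb in adjacency[lipid]
            if nb in primary_assignments
        }
        if len(neighbour_orgs) >= 2:
            roles[lipid] = ROLE_UNSPECIFIC
        elif len(neighbour_orgs) == 1:
            roles[lipid] = ROLE_SECONDARY
        else:
            roles[lipid] = ROLE_UNASSIGNED
    return roles


def build_network(
    primary_assignments: Mapping[str, CorrelationRecord],
    lipid_edges: Iterable[Tuple[str, str, float, float, float]],
    roles: Optional[Mapping[str, str]] = None,
    all_lipids: Optional[Iterable[str]] = None,
) -> nx.Graph:
    """Assemble the organism-lipid assignment network.

    Nodes carry ``kind`` (organism/lipid) and, for lipids, ``role``; edges
    carry ``type`` ("primary" organism-lipid, or "cocorrelation") plus r and
    q.  Invariant: each lipid touches at most one organism.
    """
    edges = list(lipid_edges)
    if roles is None:
        roles = classify_roles(primary_assignments, edges, all_lipids=all_lipids)
    g = nx.Graph()
    for lipid, role in roles.items():
        g.add_node(lipid, kind="lipid", role=role)
    for lipid, rec in primary_assignments.items():
        if not g.has_node(rec.organism_id):
            g.add_node(rec.organism_id, kind="organism")
        g.add_edge(rec.organism_id, lipid, type="primary", r=rec.r, q=rec.q,
                   score=rec.score)
    for a, b, r, p, q in edges:
        g.add_edge(a, b, type="cocorrelation", r=r, q=q)
    # one-organism-per-lipid invariant
    for node, data in g.nodes(data=True):
        if data.get("kind") == "lipid":
            n_org = sum(
                1 for nb in g.neighbors(node) if g.nodes[nb].get("kind") == "organism"
            )
            if n_org > 1:
                raise AssertionError(f"lipid {node} linked to {n_org} organisms")
    return g


def summarize_assignments(network: nx.Graph) -> Dict[str, int]:
    """Role counts: primary/secondary/unspecific lipids and organisms with
    at least one primary lipid."""
    n_primary = n_secondary = n_unspecific = n_unassigned = 0
    orgs = set()
    for node, data in network.nodes(data=True):
        if data.get("kind") != "lipid":
            continue
        role = data.get("role", ROLE_UNASSIGNED)
        if role == ROLE_PRIMARY:
            n_primary += 1
            for nb in network.neighbors(node):
                if network.nodes[nb].get("kind") == "organism":
                    orgs.add(nb)
        elif role == ROLE_SECONDARY:
            n_secondary += 1
        elif role == ROLE_UNSPECIFIC:
            n_unspecific += 1
        else:
            n_unassigned += 1
    return {
        "n_primary_lipids": n_primary,
        "n_organisms_with_lipids": len(orgs),
        "n_secondary_lipids": n_secondary,
        "n_unspecific": n_unspecific,
        "n_unassigned": n_unassigned,
    }


def score_against_truth(
    primary_assignments: Mapping[str, CorrelationRecord],
    producer_map: Mapping[str, Iterable[str]],
) -> Dict[str, float]:
    """Precision/recall of recovered producers over the planted primary
    lipids.

    ``producer_map`` maps organism -> its planted primary lipids.  Recall is
    the fraction of planted (organism, lipid) pairs recovered; precision is
    the fraction of assignments *of planted primary lipids* that name the
    true producer.  Assignments of lipids outside the planted primary set
    (e.g. symbiont-derived lipids, which are collinear with their host's
    primaries by construction) are not counted against precision.
    """
    truth_pairs = {
        (org, lip) for org, lips in producer_map.items() for lip in lips
    }
    truth_lipids = {lip for _, lip in truth_pairs}
    assigned = {
        (rec.organism_id, lip)
        for lip, rec in primary_assignments.items()
        if lip in truth_lipids
    }
    correct = len(assigned & truth_pairs)
    precision = correct / len(assigned) if assigned else 0.0
    recall = correct / len(truth_pairs) if truth_pairs else 0.0
    return {"precision": precision, "recall": recall,
            "n_assigned": len(assigned), "n_truth": len(truth_pairs)}


# --- reference table and serialization ------------------------------------

def load_reference_assignments(path: Optional[Union[str, Path]] = None) -> nx.Graph:
    """Load the packaged organism/lipid role table into a network.

    The table (organism_id, classification, role, lipid) records, per marker
    gene, its directly correlated (primary) lipids and the lipids that
    co-correlate with those (secondary).  Statistics are not re-derived;
    roles and edges are taken as annotated.
    """
    if path is None:
        from importlib.resources import files

        path = files("lipidlink").joinpath("data/reference_assignments.tsv")
    with open(str(path)) as fh:
        df = pd.read_csv(fh, sep="\t")
    g = nx.Graph()
    last_primary: Dict[str, str] = {}
    for row in df.itertuples(index=False):
        org, role, lipid = str(row.organism_id), str(row.role), str(row.lipid)
        if not g.has_node(org):
            g.add_node(org, kind="organism", classification=str(row.classification))
        if role == ROLE_PRIMARY:
            g.add_node(lipid, kind="lipid", role=ROLE_PRIMARY)
            g.add_edge(org, lipid, type="primary")
            last_primary[org] = lipid
        elif role == ROLE_SECONDARY:
            g.add_node(lipid, kind="lipid", role=ROLE_SECONDARY)
            # secondary lipids hang off one of the organism's primary lipids
            anchor = last_primary.get(org)
            if anchor is not None:
                g.add_edge(anchor, lipid, type="cocorrelation")
        else:
            raise ValueError(f"unknown role {role!r} in reference table")
    return g


def write_correlation_tsv(
    records: Iterable[CorrelationRecord], path: Union[str, Path]
) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {"organism": r.organism_id, "lipid": r.lipid_id, "r": r.r,
             "p": r.p, "q": r.q, "score": r.score}
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_assignment_table(network: nx.Graph, path: Union[str, Path]) -> None:
    """Per-organism table mirroring the (organism | primary | secondary)
    layout: secondary lipids are attached to the organism whose primary
    lipid they co-correlate with."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for org, data in sorted(network.nodes(data=True)):
        if data.get("kind") != "organism":
            continue
        primaries = sorted(
            nb for nb in network.neighbors(org)
            if network.nodes[nb].get("role") == ROLE_PRIMARY
        )
        secondaries = set()
        for p in primaries:
            for nb in network.neighbors(p):
                if network.nodes[nb].get("role") == ROLE_SECONDARY:
                    secondaries.add(nb)
        rows.append(
            {"organism": org, "primary_lipids": ", ".join(primaries),
             "secondary_lipids": ", ".join(sorted(secondaries))}
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_network(network: nx.Graph, edge_tsv: Union[str, Path],
                  graphml: Union[str, Path]) -> None:
    """Export the network as an edge-list TSV and GraphML."""
    Path(edge_tsv).parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for a, b, data in network.edges(data=True):
        rows.append(
            {"source": a, "target": b, "type": data.get("type", ""),
             "r": data.get("r", ""), "q": data.get("q", "")}
        )
    pd.DataFrame(rows).to_csv(edge_tsv, sep="\t", index=False)
    nx.write_graphml(network, str(graphml))
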