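"""Marker-gene (rpS3) tracking across a sample time series.

Ribosomal protein S3 is a single-copy phylogenetic marker; scaffolds
carrying it are tracked over samples to follow organisms through the geyser
eruption cycle.  This module implements the bookkeeping around that idea:

* greedy identity clustering of marker amino-acid sequences (99% default,
  collapsing most strains of a species) with the longest scaffold as the
  cluster representative,
* a read-alignment mismatch filter (<= 3 mismatches, consistent with the
  99% clustering identity),
* per-scaffold breadth of coverage, excluding ambiguous bases from both
  numerator and denominator,
* presence calling (assembled in the sample, or breadth >= 95%),
* coverage-based percent relative abundance,
* identity-based taxonomic rank assignment.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner

from .abundance import AbundanceTable, FeatureKind

__all__ = [
    "MarkerScaffold",
    "DepthProfile",
    "AlignmentRecord",
    "ClusterSet",
    "pairwise_identity",
    "cluster_markers",
    "filter_alignments",
    "breadth",
    "call_presence",
    "relative_abundance",
    "taxonomic_rank_from_identity",
    "read_marker_fasta",
    "read_sam_alignments",
    "depth_from_alignments",
    "read_depth_tsv",
    "write_depth_tsv",
    "write_presence_calls",
]

logger = logging.getLogger(__name__)

DEFAULT_CLUSTER_IDENTITY = 0.99
DEFAULT_MAX_MISMATCHES = 3
DEFAULT_MIN_BREADTH = 0.95


@dataclass
class MarkerScaffold:
    """A scaffold carrying a marker gene, with its protein sequence."""

    id: str
    length_bp: int
    protein_seq: str
    ambiguous_positions: Set[int] = field(default_factory=set)
    taxonomy: str = ""

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        bad = {p for p in self.ambiguous_positions if not (0 <= p < self.length_bp)}
        if bad:
            raise ValueError(f"ambiguous positions outside scaffold: {sorted(bad)}")


@dataclass
class DepthProfile:
    """Per-position read depth for one scaffold in one sample."""

    scaffold_id: str
    sample_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=int)
        if (self.depth < 0).any():
            raise ValueError("negative depth")


@dataclass(frozen=True)
class AlignmentRecord:
    """One mapped read: 0-based half-open interval plus mismatch count."""

    read_id: str
    scaffold_id: str
    start: int
    end: int
    mismatches: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")
        if self.mismatches < 0:
            raise ValueError("mismatches must be >= 0")


@dataclass
class ClusterSet:
    """Partition of scaffolds into identity clusters with representatives."""

    clusters: List[Dict[str, object]]  # {"representative_id": str, "member_ids": [str]}
    threshold: float

    @property
    def representative_ids(self) -> List[str]:
        return [str(c["representative_id"]) for c in self.clusters]


# --- sequence identity and clustering -------------------------------------

def _aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = -1.0
    a.extend_gap_score = -1.0
    return a


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity between two amino-acid sequences.

    Alignment scoring: match +1, mismatch 0, linear gap -1.  Identity is the
    fraction of alignment columns (including gap columns) that are identical
    matches; symmetric and in [0, 1].
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aln = _aligner().align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def cluster_markers(
    scaffolds: Sequence[MarkerScaffold],
    threshold: float = DEFAULT_CLUSTER_IDENTITY,
) -> ClusterSet:
    """Greedy centroid clustering of marker sequences.

    Scaffolds are processed by decreasing length (ties broken by id); each
    joins the first existing cluster whose representative it matches at
    >= ``threshold`` identity, else founds a new cluster.  Because founders
    are processed longest-first, the representative is always the longest
    member.
    """
    if not scaffolds:
        raise ValueError("no scaffolds to cluster")
    ordered = sorted(scaffolds, key=lambda s: (-s.length_bp, s.id))
    clusters: List[Dict[str, object]] = []
    reps: List[MarkerScaffold] = []
    for scaf in ordered:
        placed = False
        for cluster, rep in zip(clusters, reps):
            if pairwise_identity(scaf.protein_seq, rep.protein_seq) >= threshold:
                cluster["member_ids"].append(scaf.id)  # type: ignore[union-attr]
                placed = True
                break
        if not placed:
            clusters.append({"representative_id": scaf.id, "member_ids": [scaf.id]})
            reps.append(scaf)
    return ClusterSet(clusters=clusters, threshold=threshold)


# --- read filtering, breadth, presence ------------------------------------

def filter_alignments(
    records: Iterable[AlignmentRecord],
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> List[AlignmentRecord]:
    """Keep alignments with at most ``max_mismatches`` mismatches."""
    return [r for r in records if r.mismatches <= max_mismatches]


def breadth(profile: DepthProfile, scaffold: MarkerScaffold) -> float:
    """Fraction of non-ambiguous positions covered by at least one read.

    Ambiguous scaffold bases are excluded from numerator and denominator.
    """
    if profile.scaffold_id != scaffold.id:
        raise ValueError("profile does not match scaffold")
    if len(profile.depth) != scaffold.length_bp:
        raise ValueError("depth profile length does not match scaffold length")
    mask = np.ones(scaffold.length_bp, dtype=bool)
    if scaffold.ambiguous_positions:
        mask[sorted(scaffold.ambiguous_positions)] = False
    n_valid = int(mask.sum())
    if n_valid == 0:
        raise ValueError("breadth undefined: all positions ambiguous")
    covered = int(((profile.depth >= 1) & mask).sum())
    return covered / n_valid


def call_presence(
    assembled_in_sample: bool,
    breadth_value: float,
    min_breadth: float = DEFAULT_MIN_BREADTH,
) -> bool:
    """An organism is present if its marker scaffold was assembled in the
    sample or is near-fully covered by mapped reads."""
    if not (0.0 <= breadth_value <= 1.0):
        raise ValueError("breadth must be in [0, 1]")
    return assembled_in_sample or breadth_value >= min_breadth


def relative_abundance(
    per_scaffold_coverage: Mapping[str, Mapping[str, float]],
) -> AbundanceTable:
    """Percent relative abundance from per-sample scaffold coverages.

    ``per_scaffold_coverage`` maps scaffold id -> {sample id -> mean depth}.
    Each sample is closed to 100% over all representative scaffolds;
    zero-total samples yield a zero column (logged).
    """
    df = pd.DataFrame(per_scaffold_coverage).T.fillna(0.0).astype(float)
    if (df.to_numpy() < 0).any():
        raise ValueError("negative coverage")
    totals = df.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning("relative_abundance: zero total coverage in samples %s",
                       list(totals.index[zero]))
    out = df.divide(totals.where(~zero, 1.0), axis=1) * 100.0
    return AbundanceTable(values=out, feature_kind=FeatureKind.ORGANISM)


RANK_SPECIES = "species"
RANK_GENUS = "genus"
RANK_FAMILY = "family"
RANK_ABOVE_FAMILY = "above-family (unresolved)"
RANK_PHYLUM_DOMAIN = "phylum/domain"


def taxonomic_rank_from_identity(best_hit_identity: float) -> str:
    """Taxonomic rank implied by percent identity of the best database hit.

    >=99% species, >=95% genus, >=90% family, <50% phylum/domain.  The band
    between 50% and 90% has no conventional rank here and is reported as
    "above-family (unresolved)".
    """
    if not (0.0 <= best_hit_identity <= 100.0):
        raise ValueError("identity must be a percentage in [0, 100]")
    if best_hit_identity >= 99.0:
        return RANK_SPECIES
    if best_hit_identity >= 95.0:
        return RANK_GENUS
    if best_hit_identity >= 90.0:
        return RANK_FAMILY
    if best_hit_identity < 50.0:
        return RANK_PHYLUM_DOMAIN
    return RANK_ABOVE_FAMILY


# --- I/O ------------------------------------------------------------------

def read_marker_fasta(path: Union[str, Path]) -> List[MarkerScaffold]:
    """Load marker protein sequences from FASTA.

    The scaffold length (bp) is taken from a ``length=<n>`` token in the
    description when present, else 3x the protein length.
    """
    scaffolds = []
    for rec in SeqIO.parse(str(path), "fasta"):
        length = None
        for token in rec.description.split():
            if token.startswith("length="):
                length = int(token.split("=", 1)[1])
        seq = str(rec.seq)
        scaffolds.append(
            MarkerScaffold(
                id=rec.id,
                length_bp=length if length is not None else 3 * len(seq),
                protein_seq=seq,
            )
        )
    return scaffolds


def read_sam_alignments(path: Union[str, Path]) -> List[AlignmentRecord]:
    """Extract (read, scaffold, interval, NM) from a SAM file via pysam."""
    import pysam

    records = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    scaffold_id=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    mismatches=int(nm),
                )
            )
    return records


def depth_from_alignments(
    records: Iterable[AlignmentRecord],
    scaffold: MarkerScaffold,
    sample_id: str,
    max_mismatches: Optional[int] = DEFAULT_MAX_MISMATCHES,
) -> DepthProfile:
    """Accumulate a per-position depth profile from filtered alignments."""
    depth = np.zeros(scaffold.length_bp, dtype=int)
    recs = list(records)
    if max_mismatches is not None:
        recs = filter_alignments(recs, max_mismatches)
    for r in recs:
        if r.scaffold_id != scaffold.id:
            continue
        depth[r.start : min(r.end, scaffold.length_bp)] += 1
    return DepthProfile(scaffold_id=scaffold.id, sample_id=sample_id, depth=depth)


def read_depth_tsv(path: Union[str, Path]) -> List[DepthProfile]:
    """Read long-format depth TSV (scaffold, sample, position, depth)."""
    df = pd.read_csv(path, sep="\t")
    profiles = []
    for (scaf, sample), grp in df.groupby(["scaffold", "sample"], sort=True):
        grp = grp.sort_values("position")
        n = int(grp["position"].max()) + 1
        depth = np.zeros(n, dtype=int)
        depth[grp["position"].to_numpy(dtype=int)] = grp["depth"].to_numpy(dtype=int)
        profiles.append(DepthProfile(scaffold_id=str(scaf), sample_id=str(sample), depth=depth))
    return profiles


def write_depth_tsv(profiles: Iterable[DepthProfile], path: Union[str, Path]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in profiles:
        for pos, d in enumerate(p.depth):
            rows.append((p.scaffold_id, p.sample_id, pos, int(d)))
    pd.DataFrame(rows, columns=["scaffold", "sample", "position", "depth"]).to_csv(
        path, sep="\t", index=False
    )


def write_presence_calls(
    calls: Mapping[str, Mapping[str, bool]], path: Union[str, Path]
) -> None:
    """Write scaffold x sample boolean presence calls as TSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(calls).T.fillna(False).astype(bool).to_csv(path, sep="\t")
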