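"""Seeded generator of coupled organism/lipid/isotope data with known truth.

Emulates the study design the pipeline targets: a 14-sample series spanning
three eruption phases of a cold CO2-driven geyser (recovery = intermediate
aquifer, minor eruptions = deep aquifer, major eruptions = shallow aquifer),
with

* organism trajectories = per-organism phase-preference profiles times
  multiplicative lognormal noise, closed to 100% per sample;
* a lipidome generated from the community through a production-coefficient
  matrix: planted primary lipids (exactly one producer), symbiont-derived
  (secondary) lipids tied to a host, shared lipids with >= 2 producers
  (unspecific truth) and diffuse background lipids (>= 3 producers);
* depth profiles for marker scaffolds exercising breadth/presence calling;
* delta13C series generated from known two-endmember mixtures.

Every organism's production coefficients sum to 1, so the per-sample raw
lipid total is constant and compositional closure is a global scalar: at
zero noise a primary lipid is *exactly* proportional to its producer, which
is what makes planted-truth recovery exact.

Determinism: all draws come from ``numpy.random.default_rng`` streams
seeded as ``[seed, k]`` with a fixed stream index k per stage
(0 = truth construction, 1 = community noise, 2 = lipidome noise,
3 = depth profiles, 4 = isotope noise), in a fixed order of draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .abundance import (
    AbundanceTable,
    FeatureKind,
    FilterFraction,
    Phase,
    SampleMetadata,
    normalize_percent,
    write_metadata,
    write_table,
)
from .isotopes import EndmemberSet, IsotopeRecord, dic_to_co2, write_isotope_tsv
from .markers import DepthProfile, MarkerScaffold

__all__ = [
    "TruthModel",
    "default_truth",
    "simulate_community",
    "simulate_lipidome",
    "simulate_depth_profiles",
    "simulate_isotopes",
    "write_bundle",
]

# stream indices for the per-stage RNGs
_STREAM_TRUTH = 0
_STREAM_COMMUNITY = 1
_STREAM_LIPIDOME = 2
_STREAM_DEPTH = 3
_STREAM_ISOTOPE = 4

_BETAINE = ("DGTS", "DGTA", "DGCC")
_PHOSPHO = ("PC", "PE", "PG", "OL", "DPG")


@dataclass
class TruthModel:
    """Planted generative structure behind one synthetic data set."""

    seed: int
    sample_ids: List[str]
    phase_labels: List[Phase]
    organism_ids: List[str]
    profiles: pd.DataFrame            # organism x sample phase-preference profile
    coefficients: pd.DataFrame        # lipid x organism production coefficients
    producer_map: Dict[str, Tuple[str, ...]]       # organism -> primary lipids
    symbiont_links: Dict[str, Tuple[str, ...]]     # host organism -> derived lipids
    shared_lipids: Dict[str, Tuple[str, ...]]      # lipid -> >=2 producers
    background_lipids: Tuple[str, ...]
    noise_sd: float
    f_rTCA: Dict[str, float]          # per-sample bacterial rTCA fraction
    f_auto: Dict[str, float]          # per-sample archaeal autotrophic fraction
    delta_DIC: Dict[str, float]
    endmembers: EndmemberSet = field(default_factory=lambda: EndmemberSet(apply_lipid_offset=True))
    volumes: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        primary = [l for lips in self.producer_map.values() for l in lips]
        if len(primary) != len(set(primary)):
            raise ValueError("a planted primary lipid has two producers")
        for lipid, orgs in self.shared_lipids.items():
            if len(orgs) < 2:
                raise ValueError(f"shared lipid {lipid} needs >= 2 producers")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def metadata(self) -> List[SampleMetadata]:
        return [
            SampleMetadata(
                sample_id=s,
                phase=ph,
                filter_fraction=FilterFraction.F01,
                volume_liters=self.volumes.get(s, 0.0),
            )
            for s, ph in zip(self.sample_ids, self.phase_labels)
        ]


def _phase_sequence(n_samples: int) -> List[Phase]:
    """Three-phase layout scaled from the 6/4/4 recovery/minor/major design."""
    n_rec = max(1, round(n_samples * 6 / 14))
    n_min = max(1, round(n_samples * 4 / 14))
    n_maj = max(1, n_samples - n_rec - n_min)
    seq = [Phase.RECOVERY] * n_rec + [Phase.MINOR] * n_min + [Phase.MAJOR] * n_maj
    return seq[:n_samples]


def _unique_name(base: str, taken: set) -> str:
    name = base
    bump = 0
    while name in taken:
        bump += 1
        c, rest = base.split(":", 1)
        name = f"{c[:1]}{int(c[1:]) + 2 * bump}:{rest}" if base.startswith("C") else f"{base}_{bump}"
        if base.startswith("lyso_C"):
            head, rest2 = base.split(":", 1)
            name = f"lyso_C{int(head[len('lyso_C'):]) + 2 * bump}:{rest2}"
    taken.add(name)
    return name


def default_truth(
    seed: int,
    n_samples: int = 14,
    n_organisms: int = 20,
    n_lipids: int = 40,
    noise_sd: float = 0.0,
) -> TruthModel:
    """Construct the default planted truth at desk scale.

    Requires ``n_lipids >= n_organisms`` so every organism produces one
    planted primary lipid (the property that makes zero-noise recovery
    exact).  Organisms preferring the deep (minor-phase) aquifer produce
    polyunsaturated primary lipids (>= 7 double bonds); symbiont-derived
    lipids are betaine lysolipids.
    """
    if n_lipids < n_organisms:
        raise ValueError("need n_lipids >= n_organisms (one primary lipid each)")
    rng = np.random.default_rng([seed, _STREAM_TRUTH])

    phases = _phase_sequence(n_samples)
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    organism_ids = [f"ORG{i + 1:03d}" for i in range(n_organisms)]

    # phase-preference profiles: preferred phase factor 1, others 0.15, plus
    # per-sample within-phase detail so no two organisms are collinear
    phase_cycle = [Phase.RECOVERY, Phase.MINOR, Phase.MAJOR]
    mean_abund = rng.lognormal(mean=0.0, sigma=1.0, size=n_organisms)
    detail = rng.lognormal(mean=0.0, sigma=0.4, size=(n_organisms, n_samples))
    prof = np.empty((n_organisms, n_samples))
    preferred = [phase_cycle[i % 3] for i in range(n_organisms)]
    for i in range(n_organisms):
        for j, ph in enumerate(phases):
            pref_factor = 1.0 if ph == preferred[i] else 0.15
            prof[i, j] = mean_abund[i] * pref_factor * detail[i, j]
    profiles = pd.DataFrame(prof, index=organism_ids, columns=sample_ids)

    # lipid role allocation
    n_primary = n_organisms
    rest = n_lipids - n_primary
    n_secondary = round(rest * 0.4)
    n_shared = round(rest * 0.3)
    n_background = rest - n_secondary - n_shared

    taken: set = set()
    coeff = pd.DataFrame(0.0, index=range(n_lipids), columns=organism_ids)
    lipid_names: List[str] = [""] * n_lipids
    k = 0

    # symbiont-derived (secondary) lipids: betaine lysolipids off the first hosts
    symbiont_links: Dict[str, Tuple[str, ...]] = {}
    secondary_load = np.zeros(n_organisms)
    sec_idx = []
    for s in range(n_secondary):
        host = s % n_organisms
        c = int(rng.integers(16, 23))
        u = int(rng.integers(0, 6))
        name = _unique_name(f"lyso_C{c}:{u}-{_BETAINE[s % 3]}", taken)
        lipid_names[k] = name
        coeff.iloc[k, host] = 0.2
        secondary_load[host] += 0.2
        symbiont_links.setdefault(organism_ids[host], ())
        symbiont_links[organism_ids[host]] += (name,)
        sec_idx.append(k)
        k += 1

    # shared lipids: equal coefficients for each of exactly two producers so
    # the lipid tracks the unweighted producer sum
    shared: Dict[str, Tuple[str, ...]] = {}
    pool = list(rng.permutation(n_organisms))
    for s in range(n_shared):
        if len(pool) < 2:
            pool = list(rng.permutation(n_organisms))
        a, b = int(pool.pop()), int(pool.pop())
        c = int(rng.integers(28, 40)) * 2 // 2
        u = int(rng.integers(0, 4))
        name = _unique_name(f"C{c}:{u}-{_PHOSPHO[s % len(_PHOSPHO)]}", taken)
        lipid_names[k] = name
        coeff.iloc[k, a] = 0.08
        coeff.iloc[k, b] = 0.08
        shared[name] = (organism_ids[a], organism_ids[b])
        k += 1

    # diffuse background lipids: small equal contributions from 4 organisms
    background: List[str] = []
    for s in range(n_background):
        members = rng.choice(n_organisms, size=min(4, n_organisms), replace=False)
        c = int(rng.integers(30, 45))
        u = int(rng.integers(0, 3))
        name = _unique_name(f"C{c}:{u}-{_PHOSPHO[(s + 2) % len(_PHOSPHO)]}", taken)
        lipid_names[k] = name
        for midx in members:
            coeff.iloc[k, int(midx)] = 0.04
        background.append(name)
        k += 1

    # planted primary lipids: each organism's remaining budget goes to one
    # dedicated lipid; deep-phase producers get polyunsaturated chains
    producer_map: Dict[str, Tuple[str, ...]] = {}
    for i in range(n_organisms):
        load = float(coeff.iloc[:, i].sum())
        remaining = 1.0 - load
        if remaining <= 0.05:
            raise RuntimeError("organism production budget exhausted")
        c = int(rng.integers(28, 45))
        if preferred[i] == Phase.MINOR:  # deep aquifer: high unsaturation
            u = int(rng.integers(7, 13))
        else:
            u = int(rng.integers(0, 5))
        name = _unique_name(f"C{c}:{u}-{_PHOSPHO[i % len(_PHOSPHO)]}", taken)
        lipid_names[k] = name
        coeff.iloc[k, i] = remaining
        producer_map[organism_ids[i]] = (name,)
        k += 1

    coeff.index = lipid_names
    col_sums = coeff.sum(axis=0).to_numpy()
    assert np.allclose(col_sums, 1.0), "production budgets must close to 1"

    # isotope truth: shallow (major) phase rich in rTCA-fixed bacterial
    # carbon, deep (minor) phase rich in archaeal WL autotrophy
    f_rTCA, f_auto, delta_DIC, volumes = {}, {}, {}, {}
    for s, ph in zip(sample_ids, phases):
        if ph == Phase.MAJOR:
            f_rTCA[s] = float(rng.uniform(0.55, 0.78))
            f_auto[s] = float(rng.uniform(0.25, 0.45))
        elif ph == Phase.MINOR:
            f_rTCA[s] = float(rng.uniform(0.10, 0.25))
            f_auto[s] = float(rng.uniform(0.55, 0.70))
        else:
            f_rTCA[s] = float(rng.uniform(0.15, 0.35))
            f_auto[s] = float(rng.uniform(0.40, 0.60))
        delta_DIC[s] = float(np.clip(rng.normal(5.0, 1.4), 3.6, 8.0))
        volumes[s] = float(rng.uniform(114.0, 338.0))

    return TruthModel(
        seed=seed,
        sample_ids=sample_ids,
        phase_labels=phases,
        organism_ids=organism_ids,
        profiles=profiles,
        coefficients=coeff,
        producer_map=producer_map,
        symbiont_links=symbiont_links,
        shared_lipids=shared,
        background_lipids=tuple(background),
        noise_sd=noise_sd,
        f_rTCA=f_rTCA,
        f_auto=f_auto,
        delta_DIC=delta_DIC,
        volumes=volumes,
    )


def simulate_community(truth: TruthModel) -> AbundanceTable:
    """Organism abundance table: profile x lognormal noise, closed to 100%."""
    rng = np.random.default_rng([truth.seed, _STREAM_COMMUNITY])
    vals = truth.profiles.to_numpy(dtype=float).copy()
    if truth.noise_sd > 0:
        vals *= rng.lognormal(mean=0.0, sigma=truth.noise_sd, size=vals.shape)
    table = AbundanceTable(
        values=pd.DataFrame(vals, index=truth.organism_ids, columns=truth.sample_ids),
        feature_kind=FeatureKind.ORGANISM,
    )
    return normalize_percent(table)


def simulate_lipidome(
    organism_table: AbundanceTable, truth: TruthModel
) -> AbundanceTable:
    """Lipid abundance table from the production-coefficient matrix.

    raw lipid = coefficients @ organism percents, times lognormal noise,
    then closed to 100%.  At zero noise, closure is a global scalar (see
    module docstring), so each primary lipid is exactly proportional to its
    producer.
    """
    missing = [o for o in truth.organism_ids if o not in organism_table.feature_ids]
    if missing:
        raise ValueError(f"organisms missing from table: {missing}")
    rng = np.random.default_rng([truth.seed, _STREAM_LIPIDOME])
    P = organism_table.values.loc[truth.organism_ids, truth.sample_ids].to_numpy(dtype=float)
    raw = truth.coefficients.to_numpy(dtype=float) @ P
    if truth.noise_sd > 0:
        raw *= rng.lognormal(mean=0.0, sigma=truth.noise_sd, size=raw.shape)
    table = AbundanceTable(
        values=pd.DataFrame(raw, index=list(truth.coefficients.index),
                            columns=truth.sample_ids),
        feature_kind=FeatureKind.LIPID,
    )
    return normalize_percent(table)


def simulate_depth_profiles(
    truth: TruthModel,
    scaffolds: Sequence[MarkerScaffold],
    gap_fraction: float = 0.02,
    absent_hit_fraction: float = 0.05,
    presence_threshold_percent: float = 0.1,
) -> Tuple[Dict[Tuple[str, str], DepthProfile], Dict[Tuple[str, str], bool]]:
    """Depth profiles + assembled flags for marker scaffolds.

    Scaffold i tracks organism i.  Where the organism is present (closed
    abundance above ``presence_threshold_percent``), coverage is uniform
    with a ``gap_fraction`` of uncovered positions (breadth ~= 1 - gap);
    where absent, only a sparse ``absent_hit_fraction`` of positions is
    hit.  Assembled flags are set for present organisms in roughly half the
    samples.
    """
    rng = np.random.default_rng([truth.seed, _STREAM_DEPTH])
    community = simulate_community(truth)
    profiles: Dict[Tuple[str, str], DepthProfile] = {}
    assembled: Dict[Tuple[str, str], bool] = {}
    for i, scaf in enumerate(scaffolds):
        org = truth.organism_ids[i % len(truth.organism_ids)]
        for s in truth.sample_ids:
            present = float(community.values.loc[org, s]) >= presence_threshold_percent
            depth = np.zeros(scaf.length_bp, dtype=int)
            if present:
                depth[:] = int(rng.integers(2, 20))
                n_gap = int(round(gap_fraction * scaf.length_bp))
                if n_gap:
                    gaps = rng.choice(scaf.length_bp, size=n_gap, replace=False)
                    depth[gaps] = 0
                assembled[(scaf.id, s)] = bool(rng.random() < 0.5)
            else:
                n_hit = int(round(absent_hit_fraction * scaf.length_bp))
                if n_hit:
                    hits = rng.choice(scaf.length_bp, size=n_hit, replace=False)
                    depth[hits] = 1
                assembled[(scaf.id, s)] = False
            profiles[(scaf.id, s)] = DepthProfile(
                scaffold_id=scaf.id, sample_id=s, depth=depth
            )
    return profiles, assembled


def simulate_isotopes(
    truth: TruthModel, noise_sd_delta: float = 0.0
) -> List[IsotopeRecord]:
    """delta13C series generated from the planted mixing fractions.

    Per sample: DIC (drawn in truth), CO2 = DIC - eps_DIC_CO2, the bacterial
    fatty-acid pool as an rTCA/CBB mixture on the epsilon scale relative to
    CO2, and phytane as an autotrophy/heterotrophy mixture on the delta
    scale (WL endmember relative to DIC, heterotrophic endmember = the
    bacterial pool).  Gaussian noise of sd ``noise_sd_delta`` (per mil) is
    added to the lipid values.
    """
    rng = np.random.default_rng([truth.seed, _STREAM_ISOTOPE])
    em = truth.endmembers
    records: List[IsotopeRecord] = []
    for s in truth.sample_ids:
        d_dic = truth.delta_DIC[s]
        d_co2 = dic_to_co2(d_dic, em.eps_DIC_CO2)
        eps_obs = (
            truth.f_rTCA[s] * em.eps_rTCA_effective
            + (1.0 - truth.f_rTCA[s]) * em.eps_CBB_effective
        )
        d_bact = d_co2 - eps_obs
        d_auto = d_dic - em.eps_WL
        d_phytane = truth.f_auto[s] * d_auto + (1.0 - truth.f_auto[s]) * d_bact
        if noise_sd_delta > 0:
            d_bact += float(rng.normal(0.0, noise_sd_delta))
            d_phytane += float(rng.normal(0.0, noise_sd_delta))
        records.extend(
            [
                IsotopeRecord(s, "DIC", d_dic),
                IsotopeRecord(s, "CO2", d_co2),
                IsotopeRecord(s, "bacterial_weighted_mean", d_bact),
                IsotopeRecord(s, "phytane", d_phytane),
            ]
        )
    return records


def write_bundle(truth: TruthModel, outdir: Union[str, Path]) -> Dict[str, Path]:
    """Emit the full synthetic input bundle into a directory.

    Writes organisms.tsv, lipids.tsv, metadata.tsv, isotopes.tsv and
    truth.json (planted structure), returning the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    community = simulate_community(truth)
    lipidome = simulate_lipidome(community, truth)
    isotopes = simulate_isotopes(truth)

    paths = {
        "organisms": outdir / "organisms.tsv",
        "lipids": outdir / "lipids.tsv",
        "metadata": outdir / "metadata.tsv",
        "isotopes": outdir / "isotopes.tsv",
        "truth": outdir / "truth.json",
    }
    write_table(community, paths["organisms"])
    write_table(lipidome, paths["lipids"])
    write_metadata(truth.metadata(), paths["metadata"])
    write_isotope_tsv(isotopes, paths["isotopes"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "seed": truth.seed,
                "noise_sd": truth.noise_sd,
                "sample_ids": truth.sample_ids,
                "phases": [p.value for p in truth.phase_labels],
                "producer_map": {k: list(v) for k, v in truth.producer_map.items()},
                "symbiont_links": {k: list(v) for k, v in truth.symbiont_links.items()},
                "shared_lipids": {k: list(v) for k, v in truth.shared_lipids.items()},
                "background_lipids": list(truth.background_lipids),
                "f_rTCA": truth.f_rTCA,
                "f_auto": truth.f_auto,
                "delta_DIC": truth.delta_DIC,
            },
            fh,
            indent=1,
        )
    return paths
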