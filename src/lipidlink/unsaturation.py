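"""Lipidome unsaturation profiles and lysolipid statistics.

Aggregates percent relative abundance by double-bond class per sample
(classes 0..cap-1 plus an open "cap+" class, default cap 7) and computes
lysolipid counts/shares with a betaine-headgroup breakdown.  By default the
unsaturation profile is restricted to diacylglycerol backbones (archaeal
ether lipids and lysolipids excluded), the membrane-fluidity-relevant pool.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Union

import pandas as pd

from .abundance import AbundanceTable
from .lipids import Backbone, LipidParseError, parse_lipid_name, unsaturation_class

__all__ = [
    "UnsaturationProfile",
    "aggregate_unsaturation",
    "lysolipid_stats",
    "profiles_to_frame",
    "round_half_away",
]

logger = logging.getLogger(__name__)

DEFAULT_CAP = 7


@dataclass
class UnsaturationProfile:
    """Per-sample percent abundance by double-bond class."""

    sample_id: str
    class_abundance: Dict[Union[int, str], float]


def _class_labels(cap: int) -> List[Union[int, str]]:
    return [*range(cap), f"{cap}+"]


def aggregate_unsaturation(
    lipid_table: AbundanceTable,
    cap: int = DEFAULT_CAP,
    restrict_to: Optional[Backbone] = Backbone.DIACYL,
    renormalize_subset: bool = False,
) -> List[UnsaturationProfile]:
    """Sum lipid abundance into double-bond classes per sample.

    ``restrict_to`` limits the aggregation to one backbone (default:
    diacyl); pass ``None`` to include every parseable lipid.  With
    ``renormalize_subset`` the class abundances are re-closed to 100% of
    the restricted pool instead of being reported as percent of all IPLs.
    Unparseable lipid ids are excluded with a warning.
    """
    labels = _class_labels(cap)
    kept_rows: Dict[str, Union[int, str]] = {}
    for lipid_id in lipid_table.feature_ids:
        try:
            sp = parse_lipid_name(lipid_id)
        except LipidParseError:
            logger.warning("unparseable lipid %r excluded from unsaturation profile",
                           lipid_id)
            continue
        if restrict_to is not None and sp.backbone is not restrict_to:
            continue
        kept_rows[lipid_id] = unsaturation_class(sp, cap=cap)

    profiles = []
    for sample in lipid_table.sample_ids:
        acc: Dict[Union[int, str], float] = {lab: 0.0 for lab in labels}
        for lipid_id, cls in kept_rows.items():
            acc[cls] += float(lipid_table.values.loc[lipid_id, sample])
        if renormalize_subset:
            total = sum(acc.values())
            if total > 0:
                acc = {k: v / total * 100.0 for k, v in acc.items()}
        profiles.append(UnsaturationProfile(sample_id=sample, class_abundance=acc))
    return profiles


def profiles_to_frame(profiles: Iterable[UnsaturationProfile]) -> pd.DataFrame:
    """Sample x class DataFrame for TSV export."""
    profiles = list(profiles)
    return pd.DataFrame(
        [p.class_abundance for p in profiles],
        index=[p.sample_id for p in profiles],
    )


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (reporting style)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def lysolipid_stats(
    lipids: Union[AbundanceTable, Iterable[str]],
) -> Dict[str, object]:
    """Lysolipid share of a lipid inventory.

    Accepts either an abundance table (per-sample abundance share is then
    the mean over samples of the summed lyso abundance) or a bare list of
    lipid names.  Reports species counts, the species fraction (with its
    integer-percent rendering), the headgroup breakdown of the lyso
    species, and — for tables — the abundance share.
    """
    if isinstance(lipids, AbundanceTable):
        names = lipids.feature_ids
        table: Optional[AbundanceTable] = lipids
    else:
        names = list(lipids)
        table = None
    if not names:
        raise ValueError("empty lipid inventory")

    species = []
    for name in names:
        try:
            species.append(parse_lipid_name(name))
        except LipidParseError:
            logger.warning("unparseable lipid %r excluded from lysolipid stats", name)
    if not species:
        raise ValueError("no parseable lipids")

    lyso = [sp for sp in species if sp.lyso]
    n_total = len(species)
    n_lyso = len(lyso)
    fraction = n_lyso / n_total
    headgroups: Dict[str, int] = {}
    for sp in lyso:
        headgroups[sp.headgroup_class] = headgroups.get(sp.headgroup_class, 0) + 1

    out: Dict[str, object] = {
        "n_lyso": n_lyso,
        "n_total": n_total,
        "fraction_of_species": fraction,
        "percent_of_species": round_half_away(100.0 * fraction),
        "lyso_headgroups": headgroups,
    }
    if table is not None:
        lyso_names = [sp.name for sp in lyso]
        per_sample = table.values.loc[lyso_names].sum(axis=0)
        out["abundance_share_per_sample"] = per_sample.to_dict()
        out["abundance_share"] = float(per_sample.mean())
    return out
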