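"""Sample x feature relative-abundance tables and sample metadata.

The whole pipeline works on percent relative abundances (columns sum to 100
per sample).  Tables travel as TSV: first column = feature id, remaining
columns = sample ids.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "FeatureKind",
    "AbundanceTable",
    "SampleMetadata",
    "read_table",
    "write_table",
    "read_metadata",
    "write_metadata",
    "normalize_percent",
    "presence_filter",
    "present_features",
]

logger = logging.getLogger(__name__)

CLOSURE_TOTAL = 100.0  # percent scale


class FeatureKind(str, enum.Enum):
    ORGANISM = "organism"
    LIPID = "lipid"


class Phase(str, enum.Enum):
    """Eruption phase of the geyser cycle during which a sample was taken."""

    RECOVERY = "recovery"      # intermediate-depth aquifer
    MINOR = "minor"            # deep aquifer
    MAJOR = "major"            # shallow aquifer
    TRANSITION = "transition"


class FilterFraction(str, enum.Enum):
    F02 = "0.2um"
    F01 = "0.1um"
    UNFRACTIONATED = "unfractionated"


@dataclass
class SampleMetadata:
    sample_id: str
    phase: Phase
    filter_fraction: FilterFraction = FilterFraction.F01
    volume_liters: float = 0.0

    def __post_init__(self) -> None:
        self.phase = Phase(self.phase)
        self.filter_fraction = FilterFraction(self.filter_fraction)
        if self.volume_liters < 0:
            raise ValueError("volume_liters must be >= 0")


@dataclass
class AbundanceTable:
    """Feature x sample matrix of percent relative abundances.

    ``values`` is a DataFrame with feature ids as index and sample ids as
    columns; entries are non-negative percentages.
    """

    values: pd.DataFrame
    feature_kind: FeatureKind = FeatureKind.ORGANISM

    def __post_init__(self) -> None:
        self.feature_kind = FeatureKind(self.feature_kind)
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("non-finite abundance values")
        if (arr < 0).any():
            raise ValueError("negative abundance values")
        self.values = self.values.astype(float)

    @property
    def sample_ids(self) -> List[str]:
        return [str(c) for c in self.values.columns]

    @property
    def feature_ids(self) -> List[str]:
        return [str(i) for i in self.values.index]

    def feature(self, feature_id: str) -> np.ndarray:
        """Abundance trajectory of one feature across samples."""
        return self.values.loc[feature_id].to_numpy(dtype=float)


def read_table(
    path: Union[str, Path], feature_kind: FeatureKind = FeatureKind.ORGANISM
) -> AbundanceTable:
    """Read a feature x sample TSV (header = sample ids, col 0 = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: ragged rows or missing values")
    return AbundanceTable(values=df, feature_kind=feature_kind)


def write_table(table: AbundanceTable, path: Union[str, Path]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = table.values.copy()
    out.index.name = table.feature_kind.value
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_metadata(path: Union[str, Path]) -> List[SampleMetadata]:
    df = pd.read_csv(path, sep="\t")
    return [
        SampleMetadata(
            sample_id=str(row.sample_id),
            phase=Phase(row.phase),
            filter_fraction=FilterFraction(row.filter_fraction),
            volume_liters=float(row.volume_liters),
        )
        for row in df.itertuples(index=False)
    ]


def write_metadata(metadata: Iterable[SampleMetadata], path: Union[str, Path]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "phase": m.phase.value,
                "filter_fraction": m.filter_fraction.value,
                "volume_liters": m.volume_liters,
            }
            for m in metadata
        ]
    ).to_csv(path, sep="\t", index=False)


def normalize_percent(table: AbundanceTable) -> AbundanceTable:
    """Close each sample to 100%.  All-zero samples stay zero (logged).

    Idempotent and order-preserving within each sample.
    """
    vals = table.values.to_numpy(dtype=float)
    totals = vals.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning(
            "normalize_percent: all-zero samples left at zero: %s",
            [s for s, z in zip(table.sample_ids, zero) if z],
        )
    safe = np.where(zero, 1.0, totals)
    out = vals / safe * CLOSURE_TOTAL
    return AbundanceTable(
        values=pd.DataFrame(out, index=table.values.index, columns=table.values.columns),
        feature_kind=table.feature_kind,
    )


def present_features(
    table: AbundanceTable,
    min_samples: int,
    presence: Optional[pd.DataFrame] = None,
) -> List[str]:
    """Feature ids present (value > 0, or external boolean call) in at least
    ``min_samples`` samples."""
    if min_samples > len(table.sample_ids):
        raise ValueError("min_samples exceeds number of samples")
    if presence is None:
        mask = table.values.to_numpy(dtype=float) > 0
        counts = mask.sum(axis=1)
        return [f for f, c in zip(table.feature_ids, counts) if c >= min_samples]
    kept = []
    for f in table.feature_ids:
        if f in presence.index:
            n = int(presence.loc[f].astype(bool).sum())
        else:
            n = int((table.values.loc[f] > 0).sum())
        if n >= min_samples:
            kept.append(f)
    return kept


def presence_filter(
    table: AbundanceTable,
    min_samples: int,
    presence: Optional[pd.DataFrame] = None,
) -> AbundanceTable:
    """Restrict the table to features present in >= ``min_samples`` samples.

    Presence defaults to detection (value > 0); an external boolean
    feature x sample frame (e.g. breadth/assembly-based calls for marker
    genes) may override it.  Antitone in ``min_samples``.
    """
    kept = present_features(table, min_samples, presence=presence)
    return AbundanceTable(values=table.values.loc[kept], feature_kind=table.feature_kind)
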