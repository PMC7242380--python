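"""Stable carbon isotope bookkeeping and two-endmember mixing models.

All values are delta13C in per mil (vs. VPDB) or fractionations (epsilon) in
per mil.  Two mass balances are provided:

* bacterial carbon fixation on the epsilon scale — the observed
  CO2-to-lipid fractionation of the bacterial fatty-acid pool is decomposed
  into contributions of the rTCA cycle (small fractionation, ~12 per mil)
  versus the CBB cycle (large, ~30 per mil);
* archaeal autotrophy versus heterotrophy on the delta scale — the observed
  delta13C of phytane (released from archaeol) is decomposed into carbon
  fixed through the Wood-Ljungdahl pathway versus uptake of bacterial
  organic carbon.

Fractionation is linear by default (epsilon = deltaA - deltaB); the exact
ratio form epsilon = 1000*((1000+deltaA)/(1000+deltaB) - 1) is available
via ``mode="exact"``.  Mixing is linear in delta; at the per-mil magnitudes
involved the deviation from exact ratio mixing is negligible.  A
lipid-biomass offset (up to 5 per mil additional 13C depletion of lipids
relative to biomass) can be added to pathway endmembers ("paper mode").
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "IsotopeRecord",
    "EndmemberSet",
    "MixingResult",
    "MixingScale",
    "epsilon",
    "dic_to_co2",
    "weighted_mean_delta",
    "mixing_fraction_eps",
    "mixing_fraction_delta",
    "series_summary",
    "read_isotope_tsv",
    "write_isotope_tsv",
]

logger = logging.getLogger(__name__)

DELTA_PLAUSIBLE = (-120.0, 50.0)  # per mil, sanity bounds for delta13C

COMPONENTS = {"phytane", "bacterial_weighted_mean", "DIC", "CO2", "DOC"}


class MixingScale(str, enum.Enum):
    EPSILON = "epsilon"
    DELTA = "delta"


@dataclass(frozen=True)
class IsotopeRecord:
    """A delta13C measurement of one carbon pool in one sample.

    ``component`` is either one of the named pools (phytane,
    bacterial_weighted_mean, DIC, CO2, DOC) or an individual fatty acid
    such as ``C16:0``.
    """

    sample_id: str
    component: str
    delta13C: float

    def __post_init__(self) -> None:
        lo, hi = DELTA_PLAUSIBLE
        if not (lo < self.delta13C < hi):
            raise ValueError(
                f"delta13C {self.delta13C} outside plausible range {DELTA_PLAUSIBLE}"
            )


@dataclass
class EndmemberSet:
    """Pathway fractionations (per mil) used in the mass balances.

    Defaults: CBB 30, rTCA 12, WL 63 (Altiarchaeum-type), DIC-CO2 offset 10
    (at ~15 C), and an optional 5 per mil lipid-vs-biomass depletion applied
    to pathway endmembers when ``apply_lipid_offset`` is on.
    """

    eps_CBB: float = 30.0
    eps_rTCA: float = 12.0
    eps_WL: float = 63.0
    eps_DIC_CO2: float = 10.0
    lipid_biomass_offset: float = 5.0
    apply_lipid_offset: bool = False

    def __post_init__(self) -> None:
        for name in ("eps_CBB", "eps_rTCA", "eps_WL", "eps_DIC_CO2",
                     "lipid_biomass_offset"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def _off(self) -> float:
        return self.lipid_biomass_offset if self.apply_lipid_offset else 0.0

    @property
    def eps_CBB_effective(self) -> float:
        return self.eps_CBB + self._off()

    @property
    def eps_rTCA_effective(self) -> float:
        return self.eps_rTCA + self._off()

    @property
    def eps_WL_effective(self) -> float:
        return self.eps_WL + self._off()


@dataclass(frozen=True)
class MixingResult:
    """Fraction of endmember A in a two-endmember mixture (clamped to [0,1])."""

    sample_id: str
    fraction: float
    clamped: bool
    endmembers_used: Tuple[float, float]
    scale: MixingScale


def epsilon(deltaA: float, deltaB: float, mode: str = "linear") -> float:
    """Fractionation of pool A relative to pool B, in per mil."""
    if mode == "linear":
        return deltaA - deltaB
    if mode == "exact":
        if deltaB == -1000.0:
            raise ValueError("deltaB = -1000 leaves the exact formula undefined")
        return 1000.0 * ((1000.0 + deltaA) / (1000.0 + deltaB) - 1.0)
    raise ValueError(f"unknown mode {mode!r}")


def dic_to_co2(delta_DIC: float, eps_DIC_CO2: float = 10.0) -> float:
    """delta13C of dissolved CO2 from DIC via the equilibrium offset."""
    return delta_DIC - eps_DIC_CO2


def weighted_mean_delta(
    deltas: Sequence[float], abundances: Sequence[float]
) -> float:
    """Abundance-weighted mean delta13C (e.g. the bacterial fatty-acid pool)."""
    d = np.asarray(deltas, dtype=float)
    w = np.asarray(abundances, dtype=float)
    if d.shape != w.shape:
        raise ValueError("deltas and abundances must have equal length")
    if (w < 0).any():
        raise ValueError("abundances must be >= 0")
    total = w.sum()
    if total == 0:
        raise ValueError("all-zero weights")
    return float((d * w).sum() / total)


def _clamp_fraction(raw: float, sample_id: str, endmembers: Tuple[float, float],
                    scale: MixingScale) -> MixingResult:
    clamped = not (0.0 <= raw <= 1.0)
    if clamped:
        logger.info("mixing fraction %.4f for %s clamped to [0, 1]", raw, sample_id)
    return MixingResult(
        sample_id=sample_id,
        fraction=min(1.0, max(0.0, raw)),
        clamped=clamped,
        endmembers_used=endmembers,
        scale=scale,
    )


def mixing_fraction_eps(
    eps_obs: float, eps_A: float, eps_B: float, sample_id: str = ""
) -> MixingResult:
    """Fraction of pathway A from an observed fractionation.

    ``f_A = (eps_B - eps_obs) / (eps_B - eps_A)``, clamped to [0, 1] with a
    flag when the observation falls outside the endmember envelope.
    """
    if eps_A == eps_B:
        raise ValueError("degenerate endmembers: eps_A == eps_B")
    raw = (eps_B - eps_obs) / (eps_B - eps_A)
    return _clamp_fraction(raw, sample_id, (eps_A, eps_B), MixingScale.EPSILON)


def mixing_fraction_delta(
    delta_obs: float, delta_auto: float, delta_het: float, sample_id: str = ""
) -> MixingResult:
    """Autotrophic fraction from an observed delta13C.

    ``f_auto = (delta_obs - delta_het) / (delta_auto - delta_het)``, clamped
    with a flag.
    """
    if delta_auto == delta_het:
        raise ValueError("degenerate endmembers: delta_auto == delta_het")
    raw = (delta_obs - delta_het) / (delta_auto - delta_het)
    return _clamp_fraction(raw, sample_id, (delta_auto, delta_het), MixingScale.DELTA)


def series_summary(
    observations: Iterable[Tuple[str, float]],
    endmember_A: float,
    endmember_B: float,
    scale: MixingScale = MixingScale.EPSILON,
) -> Dict[str, object]:
    """Per-sample mixing fractions plus extrema ("up to" statistics).

    ``observations`` yields (sample_id, observed value on the chosen
    scale).  Returns the per-sample :class:`MixingResult` list and the
    min/max fraction, suitable for plotting against eruption phase.
    """
    scale = MixingScale(scale)
    results: List[MixingResult] = []
    for sample_id, obs in observations:
        if scale is MixingScale.EPSILON:
            results.append(mixing_fraction_eps(obs, endmember_A, endmember_B, sample_id))
        else:
            results.append(mixing_fraction_delta(obs, endmember_A, endmember_B, sample_id))
    if not results:
        raise ValueError("no observations")
    fractions = [r.fraction for r in results]
    return {
        "results": results,
        "max_fraction": max(fractions),
        "min_fraction": min(fractions),
    }


def read_isotope_tsv(path) -> List[IsotopeRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        IsotopeRecord(str(r.sample_id), str(r.component), float(r.delta13C))
        for r in df.itertuples(index=False)
    ]


def write_isotope_tsv(records: Iterable[IsotopeRecord], path) -> None:
    from pathlib import Path

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"sample_id": r.sample_id, "component": r.component, "delta13C": r.delta13C}
         for r in records]
    ).to_csv(path, sep="\t", index=False)
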