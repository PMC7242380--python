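"""Intact polar lipid (IPL) nomenclature: grammar, parser, canonical names.

IPL annotations of the form ``C36:4-PC`` (diacyl), ``lyso_C18:2-DGTA``
(single acyl chain), ``AEG_C36:2-2G`` (acyl-ether glycerolipid) and
``2G-1uns-ext-AR`` (archaeal ether lipids built on archaeol) are parsed into
a structured :class:`LipidSpecies`.  The grammar is::

    acyl      := [lyso_|AEG_] "C" carbons ":" unsaturations "-" headgroup
    archaeal  := <n> "G-" [<m> "pentose-"] [<k> "uns-"] ["ext-"] "AR"

``carbons`` is the summed acyl-chain carbon count and ``unsaturations`` the
summed double-bond equivalents over all chains (cycloalkyl rings cannot be
distinguished from double bonds by the underlying MS detection; see the
``unsaturations_may_include_rings`` caveat flag).  Archaeal lipids carry
glycosyl (``nG``) and pentose counts on an isoprenoid (archaeol) core, with
``ext`` marking extended archaeol.

The headgroup vocabulary is open: unknown but well-formed tokens are kept
verbatim (backbone ``other``) so that novel lipids flow through the pipeline
instead of crashing it.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Union

__all__ = [
    "Backbone",
    "LipidSpecies",
    "LipidParseError",
    "parse_lipid_name",
    "canonical_name",
    "unsaturation_class",
    "KNOWN_HEADGROUPS",
    "BETAINE_HEADGROUPS",
]


class Backbone(str, enum.Enum):
    """Structural backbone category of an IPL."""

    DIACYL = "diacyl"
    LYSO_ACYL = "lyso-acyl"
    ETHER_ARCHAEAL = "ether-archaeal"
    OTHER = "other"


#: Headgroup tokens attested in the reference assignment table.
KNOWN_HEADGROUPS = frozenset(
    {"PC", "PE", "PG", "DPG", "DGTS", "DGTA", "DGCC", "OL", "2Gly-DAG", "2G", "1G"}
)

#: Betaine-type headgroups (relevant for lysolipid profiling).
BETAINE_HEADGROUPS = frozenset({"DGTS", "DGTA", "DGCC"})


class LipidParseError(ValueError):
    """Raised when a lipid annotation does not conform to the grammar."""


@dataclass(frozen=True)
class LipidSpecies:
    """Parsed representation of one IPL annotation.

    Attributes
    ----------
    name:
        Canonical annotation string (round-trips through the parser).
    backbone:
        Structural class of the lipid core.
    headgroup_class:
        Polar headgroup token (``AR-based`` for archaeal lipids).
    glyco_units, pentose_units:
        Sugar counts for archaeal glyco-ether lipids (0 for acyl lipids).
    acyl_carbons:
        Summed carbon number over acyl chains; 0 for archaeal isoprenoid
        cores.
    unsaturations:
        Summed double-bond equivalents over all chains.
    lyso:
        True when exactly one acyl chain is present (the second was lost).
    extended_archaeol:
        True for extended-archaeol (``ext-AR``) cores.
    archaeal:
        True for ether-linked isoprenoid (archaeol-based) lipids.
    aeg:
        True for acyl-ether glycerolipids (``AEG_`` prefix).
    unsaturations_may_include_rings:
        Caveat: counted double-bond equivalents may include cycloalkyl
        rings, which the detection mode cannot exclude.
    """

    name: str
    backbone: Backbone
    headgroup_class: str
    glyco_units: int = 0
    pentose_units: int = 0
    acyl_carbons: int = 0
    unsaturations: int = 0
    lyso: bool = False
    extended_archaeol: bool = False
    archaeal: bool = False
    aeg: bool = False
    unsaturations_may_include_rings: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        if self.lyso and self.backbone is not Backbone.LYSO_ACYL:
            raise ValueError("lyso species must have lyso-acyl backbone")
        if self.archaeal and (
            self.acyl_carbons != 0 or self.backbone is not Backbone.ETHER_ARCHAEAL
        ):
            raise ValueError("archaeal species must be ether-archaeal with no acyl carbons")


_ARCHAEAL_RE = re.compile(
    r"^(?P<g>\d+)G"
    r"(?:-(?P<p>\d+)pentose)?"
    r"(?:-(?P<k>\d+)uns)?"
    r"(?:-(?P<ext>ext))?"
    r"-AR$"
)

_ACYL_RE = re.compile(
    r"^(?P<prefix>lyso_|AEG_)?"
    r"C(?P<c>\d+):(?P<u>\d+)"
    r"-(?P<hg>[A-Za-z0-9][A-Za-z0-9-]*)$"
)


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse an IPL annotation into a :class:`LipidSpecies`.

    Raises
    ------
    LipidParseError
        If the name is empty or does not match the grammar; the message
        names the offending token.
    """
    if not name or not name.strip():
        raise LipidParseError("empty lipid name")
    name = name.strip()

    m = _ARCHAEAL_RE.match(name)
    if m is not None:
        return LipidSpecies(
            name=name,
            backbone=Backbone.ETHER_ARCHAEAL,
            headgroup_class="AR-based",
            glyco_units=int(m.group("g")),
            pentose_units=int(m.group("p") or 0),
            unsaturations=int(m.group("k") or 0),
            extended_archaeol=m.group("ext") is not None,
            archaeal=True,
        )

    m = _ACYL_RE.match(name)
    if m is not None:
        prefix = m.group("prefix")
        lyso = prefix == "lyso_"
        aeg = prefix == "AEG_"
        hg = m.group("hg")
        if lyso:
            backbone = Backbone.LYSO_ACYL
        elif aeg or hg not in KNOWN_HEADGROUPS:
            backbone = Backbone.OTHER
        else:
            backbone = Backbone.DIACYL
        return LipidSpecies(
            name=name,
            backbone=backbone,
            headgroup_class=hg,
            acyl_carbons=int(m.group("c")),
            unsaturations=int(m.group("u")),
            lyso=lyso,
            aeg=aeg,
        )

    # Diagnose the common failure mode for a useful message.
    if re.match(r"^(lyso_|AEG_)?C\d+-", name):
        raise LipidParseError(
            f"malformed lipid name {name!r}: missing ':<unsaturations>' after carbon count"
        )
    raise LipidParseError(f"malformed lipid name {name!r}")


def canonical_name(species: LipidSpecies) -> str:
    """Rebuild the canonical annotation string from a parsed species.

    Inverse of :func:`parse_lipid_name`: ``canonical_name(parse(s)) == s``.
    """
    if species.archaeal:
        parts = [f"{species.glyco_units}G"]
        if species.pentose_units:
            parts.append(f"{species.pentose_units}pentose")
        if species.unsaturations:
            parts.append(f"{species.unsaturations}uns")
        if species.extended_archaeol:
            parts.append("ext")
        parts.append("AR")
        return "-".join(parts)
    prefix = "lyso_" if species.lyso else ("AEG_" if species.aeg else "")
    return (
        f"{prefix}C{species.acyl_carbons}:{species.unsaturations}"
        f"-{species.headgroup_class}"
    )


def unsaturation_class(species: LipidSpecies, cap: int = 7) -> Union[int, str]:
    """Double-bond class of a lipid: 0..cap-1, or ``"<cap>+"`` at saturation.

    The open top class pools heavily polyunsaturated lipids (``cap`` or more
    double bonds) into a single bin, e.g. ``"7+"`` with the default cap.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if species.unsaturations >= cap:
        return f"{cap}+"
    return int(species.unsaturations)
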