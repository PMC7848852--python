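"""Lipid shorthand nomenclature parsing.

Quantitative lipidomics software emits species names in a number of
shorthand dialects: sum-composition names (``PC 38:4``), chain-resolved
names with ``/``, ``_`` or space separators (``PC 18:0/20:4``), optional
double-bond position and stereochemistry annotations
(``PC 18:0/20:4(5Z,8Z,11Z,14Z)``), legacy class synonyms with the
composition in parentheses (``DAG(16:0/20:1(Z11))``), and sphingolipid
notations where the first chain is the long-chain base
(``SM d18:1/20:4`` or ``Cer 18:1;O2/20:4``).

This module normalises all of those to a *sum composition*: the lipid
subclass code plus the total number of acyl/alkyl carbons and
carbon-carbon double-bond equivalents summed over all chains, rendered
canonically as ``PC(38:4)``.  Positional, stereochemical and sn-order
information is deliberately discarded — reaction matching operates on
bulk compositions only.

Parsing is total: malformed or unsupported names are returned with
``status="unrecognised"`` and a reason, never raised as an exception.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "SumComposition",
    "ParsedLipid",
    "parse_lipid",
    "canonical_label",
    "CLASS_SYNONYMS",
]

#: Legacy / alternative class spellings accepted on input.
CLASS_SYNONYMS: dict[str, str] = {
    "DAG": "DG",
    "TAG": "TG",
    "MAG": "MG",
    "SPB": "Sph",
    "SPBP": "S1P",
}

# One acyl/alkyl chain or long-chain base, e.g. "18:0", "d18:1", "18:1;O2",
# "20:4(5Z,8Z,11Z,14Z)" after annotation stripping.  Hydroxyl prefixes:
# m/d/t = mono/di/tri-hydroxy long-chain base ("d" itself adds no double bond).
_CHAIN_RE = re.compile(r"^(?P<pref>[mdt]|dh)?(?P<c>\d+):(?P<d>\d+)(?:;O(?P<ox>\d*))?$")

_PREFIX_OXYGENS = {None: 0, "m": 1, "d": 2, "dh": 2, "t": 3}

# Leading subclass token: letters/digits with an optional O-/P- ether prefix
# (O-PC, P-PE, Cer1P, dhSM, S1P ...).
_CLASS_RE = re.compile(r"^(?P<cls>(?:[OP]-)?[A-Za-z][A-Za-z0-9]*)\s*(?P<rest>.*)$")

# Parenthesised annotation carrying no composition, e.g. "(5Z,8Z,11Z,14Z)",
# "(Z11)", "(2R)".  Groups containing ':' are compositions and are kept.
_ANNOT_RE = re.compile(r"\([^():]*\)")


@dataclass(frozen=True)
class SumComposition:
    """Total chain carbons, double-bond equivalents and extra oxygens."""

    carbons: int
    double_bonds: int
    oxygens: int = 0

    def __post_init__(self) -> None:
        if self.carbons < 0 or self.double_bonds < 0 or self.oxygens < 0:
            raise ValueError("composition counts must be non-negative")
        if self.double_bonds >= 1 and self.carbons < 1:
            raise ValueError("double bonds require at least one carbon")

    def __str__(self) -> str:  # canonical "C:D" rendering
        return f"{self.carbons}:{self.double_bonds}"


@dataclass(frozen=True)
class ParsedLipid:
    """A species name resolved to subclass + sum composition, or rejected."""

    raw_name: str
    subclass: str | None = None
    composition: SumComposition | None = None
    status: str = "parsed"  # "parsed" | "unrecognised"
    rejection_reason: str | None = None

    @property
    def parsed(self) -> bool:
        return self.status == "parsed"


def _reject(raw: str, reason: str) -> ParsedLipid:
    return ParsedLipid(raw_name=raw, status="unrecognised", rejection_reason=reason)


def _strip_annotations(text: str) -> str:
    """Remove parenthesised double-bond position/stereo annotations."""
    prev = None
    while prev != text:
        prev = text
        text = _ANNOT_RE.sub("", text)
    return text


def _known_subclasses() -> frozenset[str]:
    from .reaction_db import load_database  # local import: no module cycle

    return frozenset(load_database().subclasses)


def parse_lipid(raw_name: str, known_subclasses=None) -> ParsedLipid:
    """Parse a lipid shorthand name into subclass + sum composition.

    Parameters
    ----------
    raw_name:
        The species name as given in the input file.
    known_subclasses:
        Collection of accepted subclass codes.  Defaults to the shipped
        subclass registry; pass an explicit set to parse against a custom
        database, or ``False``-y container semantics are not used — pass
        ``None`` for the default.

    Returns
    -------
    ParsedLipid
        ``status="parsed"`` with the summed composition, or
        ``status="unrecognised"`` with a ``rejection_reason``.  Never raises
        for malformed text.
    """
    if raw_name is None or not str(raw_name).strip():
        return _reject(str(raw_name), "empty name")
    raw = str(raw_name)
    s = raw.strip()

    m = _CLASS_RE.match(s)
    if m is None:
        return _reject(raw, "no subclass token")
    cls, rest = m.group("cls"), m.group("rest").strip()
    cls = CLASS_SYNONYMS.get(cls, cls)

    # "P-" plasmalogen prefix: normalised to the O- ether subclass with one
    # extra double-bond equivalent (vinyl-ether bond).
    extra_db = 0
    if cls.startswith("P-"):
        cls = "O-" + cls[2:]
        extra_db = 1
    if cls in CLASS_SYNONYMS:
        cls = CLASS_SYNONYMS[cls]

    if not rest:
        return _reject(raw, "no composition given")

    # Composition may be wrapped in parentheses: "PC(34:0)", "DAG(16:0/20:1(Z11))".
    if rest.startswith("("):
        rest = rest[1:]
        if rest.endswith(")"):
            rest = rest[:-1]
    rest = _strip_annotations(rest).strip()
    if not rest:
        return _reject(raw, "no composition given")

    chains = [tok for tok in re.split(r"[/_\s]+", rest) if tok]
    carbons = dbonds = oxygens = 0
    for tok in chains:
        cm = _CHAIN_RE.match(tok)
        if cm is None:
            return _reject(raw, f"non-conventional nomenclature: {tok!r}")
        carbons += int(cm.group("c"))
        dbonds += int(cm.group("d"))
        ox = cm.group("ox")
        if ox is not None:
            oxygens += int(ox) if ox else 1
        else:
            oxygens += _PREFIX_OXYGENS[cm.group("pref")]
    dbonds += extra_db

    if known_subclasses is None:
        known_subclasses = _known_subclasses()
    if cls not in known_subclasses:
        return _reject(raw, f"subclass {cls!r} not in registry")

    try:
        comp = SumComposition(carbons, dbonds, oxygens)
    except ValueError as exc:  # e.g. "0:1"
        return _reject(raw, str(exc))
    return ParsedLipid(raw_name=raw, subclass=cls, composition=comp)


def canonical_label(p: ParsedLipid) -> str:
    """Deterministic ``"<subclass>(<C>:<D>)"`` label for a parsed species.

    Two species with equal subclass and sum composition produce identical
    labels; hydroxylation counts are carried on the composition object but
    do not appear in the label.
    """
    if not p.parsed:
        raise ValueError(f"cannot label unrecognised species {p.raw_name!r}")
    return f"{p.subclass}({p.composition})"
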