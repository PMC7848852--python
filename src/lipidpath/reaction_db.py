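"""Curated mammalian lipid reaction database.

The shipped database covers 41 lipid subclasses (glycerophospholipids and
their lyso and ether forms, glycerolipids, sphingolipids, fatty acyls and
sterols) connected by 94 directed enzymatic reactions, each annotated with
the human (HGNC) gene symbols whose products catalyse the step.  Reactions
carry a *kind* that states how the sum compositions of substrate and
product species must balance when the reaction is instantiated on a
dataset:

``headgroup_transfer``
    composition preserved (e.g. PE -> PC by PEMT);
``acylation`` / ``deacylation``
    product = substrate +/- one fatty-acyl chain, requiring a
    composition-balancing FA species in the dataset;
``fa_elongation`` / ``fa_desaturation``
    fatty-acid steps between fixed compositions (+2 carbons, or +1 double
    bond), e.g. FA(22:5) -> FA(24:5) by ELOVL2;
``sphingoid_step``
    composition-preserving interconversion within the sphingolipid
    backbone series (e.g. Cer -> Cer1P by CERK).

Collapsed intermediates: routes through CDP-diacylglycerol are stored as
single edges (PA -> PG, PA -> PI, PA -> PS) carrying the CDS/CDIPT/PTPMT1
genes of the collapsed step, so no CDP-DG node exists in the network.

The database is stored as user-inspectable TSV resources and can be
overridden with files in the same schema.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "Subclass",
    "Reaction",
    "PathwaySubset",
    "ReactionDatabase",
    "DatabaseError",
    "load_database",
    "genes_for",
    "chain_genes",
    "REACTION_KINDS",
]

REACTION_KINDS = frozenset(
    {
        "headgroup_transfer",
        "acylation",
        "deacylation",
        "fa_elongation",
        "fa_desaturation",
        "sphingoid_step",
    }
)

CATEGORIES = frozenset(
    {"glycerophospholipid", "glycerolipid", "sphingolipid", "fatty acyl", "sterol"}
)


class DatabaseError(ValueError):
    """Raised when a database resource violates the schema."""


@dataclass(frozen=True)
class Subclass:
    code: str
    category: str


@dataclass(frozen=True)
class Reaction:
    """A directed subclass->subclass transformation."""

    id: str
    substrate: str
    product: str
    kind: str
    genes: tuple[str, ...]
    #: Fixed "C:D" compositions for fatty-acid steps; None for bulk reactions.
    substrate_comp: str | None = None
    product_comp: str | None = None

    @property
    def substrate_label(self) -> str:
        if self.substrate_comp:
            return f"{self.substrate}({self.substrate_comp})"
        return self.substrate

    @property
    def product_label(self) -> str:
        if self.product_comp:
            return f"{self.product}({self.product_comp})"
        return self.product


@dataclass(frozen=True)
class PathwaySubset:
    name: str
    member_reactions: tuple[str, ...]


def _parse_comp(comp: str) -> tuple[int, int]:
    c, d = comp.split(":")
    return int(c), int(d)


@dataclass(frozen=True)
class ReactionDatabase:
    subclasses: dict[str, Subclass]
    reactions: dict[str, Reaction]
    subsets: dict[str, PathwaySubset]

    @property
    def n_subclasses(self) -> int:
        return len(self.subclasses)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def reaction_for_pair(self, substrate: str, product: str) -> Reaction:
        """Look up the reaction joining two subclass codes or node labels.

        Accepts either bare subclass codes (``"PE"``, ``"PC"``) or
        composition-qualified fatty-acid labels (``"FA(22:5)"``).
        """
        rid = f"{substrate}->{product}"
        if rid in self.reactions:
            return self.reactions[rid]
        for r in self.reactions.values():
            if r.substrate_label == substrate and r.product_label == product:
                return r
        raise KeyError(f"no reaction {substrate} -> {product} in database")

    def genes_for(self, substrate: str, product: str) -> list[str]:
        """Ordered, de-duplicated gene symbols for one reaction step."""
        return _dedup(self.reaction_for_pair(substrate, product).genes)

    def chain_genes(self, chain: list[Reaction | str]) -> list[str]:
        """Genes predicted for a chain of consecutive reactions.

        Concatenates the per-step gene lists in chain order, de-duplicated
        preserving first occurrence — the gene set a change in the whole
        route implicates.
        """
        steps = [self.reactions[s] if isinstance(s, str) else s for s in chain]
        for a, b in zip(steps, steps[1:]):
            if a.product_label != b.substrate_label:
                raise ValueError(
                    f"chain is not consecutive: {a.id} does not feed {b.id}"
                )
        out: list[str] = []
        for s in steps:
            out.extend(s.genes)
        return _dedup(out)


def _dedup(genes) -> list[str]:
    seen: dict[str, None] = {}
    for g in genes:
        seen.setdefault(g, None)
    return list(seen)


def _read_tsv(path_or_trav) -> list[dict[str, str]]:
    if hasattr(path_or_trav, "open"):
        fh = path_or_trav.open("r", encoding="utf-8")
    else:
        fh = open(path_or_trav, "r", encoding="utf-8")
    with fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    return rows


def _validate(
    sub_rows: list[dict], rxn_rows: list[dict], subset_rows: list[dict]
) -> ReactionDatabase:
    if not sub_rows:
        raise DatabaseError("subclass registry is empty")
    if not rxn_rows:
        raise DatabaseError("reaction table is empty")

    subclasses: dict[str, Subclass] = {}
    for row in sub_rows:
        code = (row.get("code") or "").strip()
        cat = (row.get("category") or "").strip()
        if not code:
            raise DatabaseError(f"subclass row without code: {row!r}")
        if code in subclasses:
            raise DatabaseError(f"duplicate subclass code {code!r}")
        if cat not in CATEGORIES:
            raise DatabaseError(f"subclass {code!r}: unknown category {cat!r}")
        subclasses[code] = Subclass(code, cat)

    reactions: dict[str, Reaction] = {}
    for row in rxn_rows:
        rid = (row.get("id") or "").strip()
        sub = (row.get("substrate") or "").strip()
        prod = (row.get("product") or "").strip()
        kind = (row.get("kind") or "").strip()
        genes = tuple(g for g in (row.get("genes") or "").split(";") if g)
        scomp = (row.get("substrate_comp") or "").strip() or None
        pcomp = (row.get("product_comp") or "").strip() or None
        if not rid:
            raise DatabaseError(f"reaction row without id: {row!r}")
        if rid in reactions:
            raise DatabaseError(f"duplicate reaction id {rid!r}")
        if sub not in subclasses or prod not in subclasses:
            raise DatabaseError(f"reaction {rid!r}: unknown subclass {sub!r}/{prod!r}")
        if kind not in REACTION_KINDS:
            raise DatabaseError(f"reaction {rid!r}: unknown kind {kind!r}")
        if not genes:
            raise DatabaseError(f"reaction {rid!r}: empty gene list")
        r = Reaction(rid, sub, prod, kind, genes, scomp, pcomp)
        if r.substrate_label == r.product_label:
            raise DatabaseError(f"reaction {rid!r} is a self-loop")
        if kind in ("fa_elongation", "fa_desaturation"):
            if subclasses[sub].category != "fatty acyl" or sub != "FA" or prod != "FA":
                raise DatabaseError(f"reaction {rid!r}: {kind} must join FA nodes")
            if not (scomp and pcomp):
                raise DatabaseError(f"reaction {rid!r}: {kind} needs fixed compositions")
            sc, sd = _parse_comp(scomp)
            pc, pd = _parse_comp(pcomp)
            if kind == "fa_elongation" and not (pc == sc + 2 and pd == sd):
                raise DatabaseError(f"reaction {rid!r}: elongation must add 2 carbons")
            if kind == "fa_desaturation" and not (pc == sc and pd == sd + 1):
                raise DatabaseError(
                    f"reaction {rid!r}: desaturation must add 1 double bond"
                )
        elif scomp or pcomp:
            raise DatabaseError(f"reaction {rid!r}: fixed compositions only for FA steps")
        reactions[rid] = r

    subsets: dict[str, PathwaySubset] = {}
    for row in subset_rows:
        name = (row.get("name") or "").strip()
        members = tuple(m for m in (row.get("reactions") or "").split(";") if m)
        if not name:
            raise DatabaseError(f"subset row without name: {row!r}")
        for m in members:
            if m not in reactions:
                raise DatabaseError(f"subset {name!r}: unknown reaction {m!r}")
        subsets[name] = PathwaySubset(name, members)

    return ReactionDatabase(subclasses, reactions, subsets)


def load_database(path: str | Path | None = None) -> ReactionDatabase:
    """Load and validate the reaction database.

    Parameters
    ----------
    path:
        Directory holding ``subclasses.tsv``, ``reactions.tsv`` and
        ``subsets.tsv`` in the shipped schema.  ``None`` loads the packaged
        default database.

    Raises
    ------
    DatabaseError
        On any schema violation, naming the offending record.
    """
    if path is None:
        base = resources.files(__package__) / "data"
    else:
        base = Path(path)
        if not base.is_dir():
            raise DatabaseError(f"database path {base} is not a directory")
    sub_rows = _read_tsv(base / "subclasses.tsv")
    rxn_rows = _read_tsv(base / "reactions.tsv")
    subsets_path = base / "subsets.tsv"
    try:
        subset_rows = _read_tsv(subsets_path)
    except FileNotFoundError:
        subset_rows = []
    return _validate(sub_rows, rxn_rows, subset_rows)


_DEFAULT_DB: ReactionDatabase | None = None


def default_database() -> ReactionDatabase:
    """The packaged database, loaded once and cached."""
    global _DEFAULT_DB
    if _DEFAULT_DB is None:
        _DEFAULT_DB = load_database()
    return _DEFAULT_DB


def genes_for(substrate: str, product: str) -> list[str]:
    """Module-level convenience over :meth:`ReactionDatabase.genes_for`."""
    return default_database().genes_for(substrate, product)


def chain_genes(chain) -> list[str]:
    """Module-level convenience over :meth:`ReactionDatabase.chain_genes`."""
    return default_database().chain_genes(chain)
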