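"""Reaction-network construction from a lipidomics dataset.

A reaction from the database is *instantiated* on a dataset when species
with balancing sum compositions are present: composition-preserving
steps need a substrate and product species with identical C:D;
acylation/deacylation additionally need a fatty-acid species accounting
for the gained/lost chain; fatty-acid elongation (+2 carbons) and
desaturation (+1 double bond) join FA species of fixed compositions.

Species are classified as *unrecognised* (parse failure or subclass not
in the registry), *processed* (participate in at least one instantiated
reaction edge) or *unprocessed* (recognised but unmatchable).  Only
processed species feed the downstream statistics.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .datasets import Dataset, SpeciesRecord
from .reaction_db import Reaction, ReactionDatabase, default_database
from .stats import ConditionDesign, reaction_activity, reaction_z

log = logging.getLogger(__name__)

__all__ = [
    "SpeciesIndex",
    "ClassificationReport",
    "build_species_index",
    "match_reaction",
    "instantiate_reactions",
    "classify_species",
    "build_network",
    "score_network",
]

_FA_KINDS = frozenset({"fa_elongation", "fa_desaturation"})


@dataclass(frozen=True)
class ClassificationReport:
    n_unrecognised: int
    n_unprocessed: int
    n_processed: int

    @property
    def total(self) -> int:
        return self.n_unrecognised + self.n_unprocessed + self.n_processed


class SpeciesIndex:
    """Species present in a dataset, indexed by subclass and composition."""

    def __init__(self, labels_with_comps):
        # labels_with_comps: iterable of (label, subclass, carbons, double_bonds)
        self.by_subclass: dict[str, list[tuple[str, int, int]]] = defaultdict(list)
        for label, subclass, c, d in labels_with_comps:
            self.by_subclass[subclass].append((label, c, d))
        for lst in self.by_subclass.values():
            lst.sort()

    @classmethod
    def from_dataset(cls, dataset: Dataset) -> "SpeciesIndex":
        items = []
        for rec in dataset.records:
            if rec.label is None or rec.label not in dataset.abundances.index:
                continue
            comp = rec.parsed.composition
            items.append((rec.label, rec.parsed.subclass, comp.carbons, comp.double_bonds))
        # duplicates collapse to one entry per canonical label
        return cls(sorted(set(items)))

    def species(self, subclass: str) -> list[tuple[str, int, int]]:
        return self.by_subclass.get(subclass, [])

    @property
    def fa_pool(self) -> list[tuple[str, int, int]]:
        return self.species("FA")


def match_reaction(
    reaction: Reaction,
    index: SpeciesIndex,
    require_fa_for_deacylation: bool = True,
) -> list[tuple]:
    """Species tuples instantiating one reaction on a dataset.

    Returns ``(substrate, product)`` pairs for composition-preserving
    kinds and fatty-acid steps, and ``(substrate, product, fa)`` triples
    for acylation/deacylation, in deterministic lexicographic order.  An
    empty result is valid and means the reaction is absent from the
    induced network.
    """
    subs = index.species(reaction.substrate)
    prods = index.species(reaction.product)
    kind = reaction.kind
    pairs: list[tuple] = []

    if kind in ("headgroup_transfer", "sphingoid_step"):
        prod_by_comp = {(c, d): lab for lab, c, d in prods}
        for lab, c, d in subs:
            p = prod_by_comp.get((c, d))
            if p is not None:
                pairs.append((lab, p))
    elif kind == "acylation":
        for s_lab, sc, sd in subs:
            for p_lab, pc, pd_ in prods:
                for f_lab, fc, fd in index.fa_pool:
                    if pc == sc + fc and pd_ == sd + fd:
                        pairs.append((s_lab, p_lab, f_lab))
    elif kind == "deacylation":
        for s_lab, sc, sd in subs:
            for p_lab, pc, pd_ in prods:
                if require_fa_for_deacylation:
                    for f_lab, fc, fd in index.fa_pool:
                        if sc == pc + fc and sd == pd_ + fd:
                            pairs.append((s_lab, p_lab, f_lab))
                else:
                    if sc > pc and sd >= pd_:
                        pairs.append((s_lab, p_lab))
    elif kind in _FA_KINDS:
        want_s = reaction.substrate_label
        want_p = reaction.product_label
        have = {lab for lab, _, _ in subs}
        if want_s in have and want_p in have:
            pairs.append((want_s, want_p))
    else:  # pragma: no cover - guarded by database validation
        raise ValueError(f"unknown reaction kind {kind!r}")
    return sorted(set(pairs))


def instantiate_reactions(
    dataset: Dataset,
    db: ReactionDatabase | None = None,
    require_fa_for_deacylation: bool = True,
) -> dict[str, list[tuple]]:
    """Map reaction id -> species tuples for every instantiated reaction."""
    db = db or default_database()
    index = SpeciesIndex.from_dataset(dataset)
    out: dict[str, list[tuple]] = {}
    for rid in sorted(db.reactions):
        pairs = match_reaction(db.reactions[rid], index, require_fa_for_deacylation)
        if pairs:
            out[rid] = pairs
    return out


def classify_species(
    dataset: Dataset,
    db: ReactionDatabase | None = None,
    require_fa_for_deacylation: bool = True,
) -> ClassificationReport:
    """Classify every input row and return the partition counts.

    Sets ``classification`` on each dataset record in place:
    every row becomes exactly one of unrecognised / unprocessed /
    processed, and the three counts sum to the row count.
    """
    db = db or default_database()
    matched = instantiate_reactions(dataset, db, require_fa_for_deacylation)
    processed_labels: set[str] = set()
    for pairs in matched.values():
        for tup in pairs:
            processed_labels.update(tup)

    counts = {"unrecognised": 0, "unprocessed": 0, "processed": 0}
    for rec in dataset.records:
        if rec.label is None or rec.parsed.subclass not in db.subclasses:
            rec.classification = "unrecognised"
        elif rec.label in processed_labels:
            rec.classification = "processed"
        else:
            rec.classification = "unprocessed"
        counts[rec.classification] += 1
    return ClassificationReport(
        n_unrecognised=counts["unrecognised"],
        n_unprocessed=counts["unprocessed"],
        n_processed=counts["processed"],
    )


def _reaction_visible(r: Reaction, db: ReactionDatabase, network_type: str) -> bool:
    if network_type == "fa":
        return r.kind in _FA_KINDS
    # lipid view: hide the FA-only network and other fatty-acyl nodes
    return (
        db.subclasses[r.substrate].category != "fatty acyl"
        and db.subclasses[r.product].category != "fatty acyl"
    )


def build_network(
    dataset: Dataset,
    db: ReactionDatabase | None = None,
    level: str = "subclass",
    network_type: str = "lipid",
    subset: str | None = None,
    require_fa_for_deacylation: bool = True,
) -> nx.DiGraph:
    """Directed reaction graph induced by a dataset.

    Parameters
    ----------
    level:
        ``"subclass"`` aggregates nodes to subclass codes; ``"species"``
        keeps canonical species labels.  Fatty-acid nodes always carry
        their composition (``FA(22:5)``) since the FA network is defined
        between compositions.
    network_type:
        ``"lipid"`` (glycerophospholipid/glycerolipid/sphingolipid/sterol
        nodes) or ``"fa"`` (FA nodes with elongation/desaturation edges).
    subset:
        Optional named pathway subset restricting the reactions used.

    Notes
    -----
    Nodes appear only with at least one incident instantiated edge; a
    dataset with no matchable species yields an empty graph whose
    ``"diagnostic"`` attribute explains why.
    """
    if level not in ("subclass", "species"):
        raise ValueError(f"level must be 'subclass' or 'species', got {level!r}")
    if network_type not in ("lipid", "fa"):
        raise ValueError(f"type must be 'lipid' or 'fa', got {network_type!r}")
    db = db or default_database()
    if subset is not None and subset not in db.subsets:
        raise KeyError(f"unknown pathway subset {subset!r}")

    matched = instantiate_reactions(dataset, db, require_fa_for_deacylation)
    allowed = set(db.subsets[subset].member_reactions) if subset else None

    G = nx.DiGraph(level=level, type=network_type, diagnostic="")
    for rid in sorted(matched):
        r = db.reactions[rid]
        if allowed is not None and rid not in allowed:
            continue
        if not _reaction_visible(r, db, network_type):
            continue
        pairs = matched[rid]
        if level == "species" or r.kind in _FA_KINDS:
            for tup in pairs:
                u, v = tup[0], tup[1]
                fa = tup[2] if len(tup) > 2 else None
                if G.has_edge(u, v):
                    # same directed species pair reachable via two reactions:
                    # keep the first (lexicographic reaction id), warn
                    log.warning("edge %s->%s already present; keeping %s",
                                u, v, G.edges[u, v]["reaction"])
                    continue
                G.add_edge(
                    u, v,
                    reaction=rid, kind=r.kind, genes=list(r.genes),
                    species_pairs=[tup], fa_species=[fa] if fa else [],
                )
        else:
            u, v = r.substrate, r.product
            fa = sorted({t[2] for t in pairs if len(t) > 2})
            if G.has_edge(u, v):
                log.warning("subclass edge %s->%s already present; keeping %s",
                            u, v, G.edges[u, v]["reaction"])
                continue
            G.add_edge(
                u, v,
                reaction=rid, kind=r.kind, genes=list(r.genes),
                species_pairs=[tuple(t) for t in pairs], fa_species=fa,
            )
    if G.number_of_edges() == 0:
        G.graph["diagnostic"] = (
            "no reactions could be instantiated: no pair of species with "
            "balancing sum compositions (and required FA partners) was found"
        )
    return G


def score_network(
    G: nx.DiGraph,
    dataset: Dataset,
    design: ConditionDesign,
    alpha: float = 0.05,
) -> nx.DiGraph:
    """Attach z, p and status to every edge of an induced network.

    For each edge, the per-sample activity is the log ratio of summed
    product-species abundance to summed substrate-species abundance over
    the edge's instantiating pairs (FA partners are not part of the
    ratio); activities are compared between conditions with
    :func:`lipidpath.stats.reaction_z`.
    """
    dataset.validate_design(design)
    ab = dataset.abundances
    interest = [s for s in design.samples(design.condition_of_interest) if s in ab.columns]
    control = [s for s in design.samples(design.control) if s in ab.columns]
    if design.paired:
        pairs = [(a, b) for a, b in design.pairs if a in ab.columns and b in ab.columns]
        interest = [a for a, _ in pairs]
        control = [b for _, b in pairs]

    for u, v, attrs in G.edges(data=True):
        sub_species = sorted({t[0] for t in attrs["species_pairs"]})
        prod_species = sorted({t[1] for t in attrs["species_pairs"]})
        sub_tot = ab.loc[sub_species].sum(axis=0, skipna=True, min_count=1)
        prod_tot = ab.loc[prod_species].sum(axis=0, skipna=True, min_count=1)
        act = reaction_activity(sub_tot.to_numpy(), prod_tot.to_numpy(), dataset.epsilon)
        act = dict(zip(ab.columns, act))
        ai = np.array([act[s] for s in interest])
        ac = np.array([act[s] for s in control])
        score = reaction_z(ai, ac, paired=design.paired, alpha=alpha)
        attrs["z"] = score.z
        attrs["p"] = score.p
        attrs["status"] = score.status
    G.graph["alpha"] = alpha
    G.graph["condition_of_interest"] = design.condition_of_interest
    G.graph["control"] = design.control
    G.graph["paired"] = design.paired
    return G
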