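"""Pathway (reaction-chain) enumeration, calling and node filtering.

A pathway is a simple directed path of consecutive reactions in the
scored network.  Chains of every length from a single reaction up to a
configurable cap are scored with the Stouffer combiner and called
*active* (z above the one-sided critical value) or *suppressed* (below
its negative).  The "most active/suppressed" rule walks greedily from
each starting substrate, at each branch taking the continuation reaction
with the extreme z, and reports one route per starting substrate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
from scipy.stats import norm

from .reaction_db import ReactionDatabase, default_database
from .stats import PathwayScore, combine_pathway, z_crit

__all__ = [
    "ChainQuery",
    "enumerate_chains",
    "most_extreme_routes",
    "filter_nodes",
]

DEFAULT_MAX_CHAIN_LENGTH = 6


@dataclass(frozen=True)
class ChainQuery:
    """Options controlling chain enumeration and calling."""

    status_filter: str = "active"  # "active" | "suppressed"
    mode: str = "all_significant"  # "all_significant" | "most_extreme"
    alpha: float = 0.05
    max_chain_length: int = DEFAULT_MAX_CHAIN_LENGTH

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.status_filter not in ("active", "suppressed"):
            raise ValueError("status_filter must be 'active' or 'suppressed'")
        if self.mode not in ("all_significant", "most_extreme"):
            raise ValueError("mode must be 'all_significant' or 'most_extreme'")
        if self.max_chain_length < 1:
            raise ValueError("max_chain_length must be >= 1")


def _finite_edges(G: nx.DiGraph):
    for u, v, attrs in G.edges(data=True):
        if "z" not in attrs:
            raise ValueError("network is not scored; run score_network first")
        if math.isfinite(attrs["z"]):
            yield u, v, attrs


def _passes(z: float, query: ChainQuery) -> bool:
    zc = z_crit(query.alpha)
    if query.status_filter == "active":
        return z > zc
    return z < -zc


def _score_path(G: nx.DiGraph, nodes: list[str], query: ChainQuery,
                db: ReactionDatabase) -> PathwayScore:
    zs = [G.edges[u, v]["z"] for u, v in zip(nodes, nodes[1:])]
    rids = [G.edges[u, v]["reaction"] for u, v in zip(nodes, nodes[1:])]
    z = combine_pathway(zs)
    status = "active" if z > z_crit(query.alpha) else (
        "suppressed" if z < -z_crit(query.alpha) else "none"
    )
    return PathwayScore(
        chain=tuple(nodes),
        reactions=tuple(rids),
        z=z,
        p=float(norm.sf(z)),
        status=status,
        genes=tuple(db.chain_genes(rids)),
    )


def _sorted_output(scores: list[PathwayScore]) -> list[PathwayScore]:
    return sorted(scores, key=lambda s: (-abs(s.z), s.label))


def enumerate_chains(
    G: nx.DiGraph,
    query: ChainQuery,
    db: ReactionDatabase | None = None,
) -> list[PathwayScore]:
    """All significant simple reaction chains in a scored network.

    Every node seeds chains; every simple directed path of one to
    ``query.max_chain_length`` reactions is scored with the Stouffer
    combiner, and paths whose combined z clears the one-sided critical
    value on the queried side are returned sorted by \\|z\\| descending
    (ties broken by chain label).  Edges with non-finite z (degenerate
    zero-variance sentinels) are left out of enumeration.
    """
    db = db or default_database()
    H = nx.DiGraph()
    H.add_nodes_from(G.nodes)
    for u, v, attrs in _finite_edges(G):
        H.add_edge(u, v, **attrs)

    out: list[PathwayScore] = []

    def extend(path: list[str]) -> None:
        if len(path) > 1:
            score = _score_path(H, path, query, db)
            if _passes(score.z, query):
                out.append(score)
        if len(path) - 1 >= query.max_chain_length:
            return
        for nxt in sorted(H.successors(path[-1])):
            if nxt not in path:  # simple paths only
                extend(path + [nxt])

    for start in sorted(H.nodes):
        extend([start])
    return _sorted_output(out)


def most_extreme_routes(
    G: nx.DiGraph,
    query: ChainQuery,
    db: ReactionDatabase | None = None,
) -> list[PathwayScore]:
    """One most-active (or most-suppressed) route per starting substrate.

    From each node with outgoing reactions, a greedy walk takes the
    continuation with the highest z (lowest for the suppressed side) at
    every branching, ties broken by the lexicographically smaller product
    label.  Among the walk's prefixes the one with the extreme combined z
    is reported, provided it clears the significance threshold.
    """
    db = db or default_database()
    H = nx.DiGraph()
    H.add_nodes_from(G.nodes)
    for u, v, attrs in _finite_edges(G):
        H.add_edge(u, v, **attrs)
    want_active = query.status_filter == "active"

    out: list[PathwayScore] = []
    for start in sorted(H.nodes):
        path = [start]
        while len(path) - 1 < query.max_chain_length:
            candidates = [
                (H.edges[path[-1], v]["z"], v)
                for v in H.successors(path[-1])
                if v not in path
            ]
            if not candidates:
                break
            if want_active:
                best_z = max(z for z, _ in candidates)
                if best_z <= 0:
                    break
            else:
                best_z = min(z for z, _ in candidates)
                if best_z >= 0:
                    break
            nxt = min(v for z, v in candidates if z == best_z)
            path.append(nxt)
        if len(path) < 2:
            continue
        prefixes = [
            _score_path(H, path[: k + 1], query, db) for k in range(1, len(path))
        ]
        best = max(prefixes, key=lambda s: s.z if want_active else -s.z)
        if _passes(best.z, query):
            out.append(best)
    return _sorted_output(out)


def filter_nodes(
    G: nx.DiGraph,
    query1: str,
    op: str | None = None,
    query2: str | None = None,
) -> set[str]:
    """Case-insensitive substring search over node labels.

    ``AND`` keeps nodes whose label contains both substrings, ``OR``
    either; with no operator only ``query1`` is matched.  Empty query
    strings match nothing.
    """
    if op is not None and op.upper() not in ("AND", "OR"):
        raise ValueError("op must be 'AND' or 'OR'")
    q1 = (query1 or "").lower()
    q2 = (query2 or "").lower()

    def hit(label: str) -> bool:
        lab = label.lower()
        m1 = bool(q1) and q1 in lab
        m2 = bool(q2) and q2 in lab
        if op is None:
            return m1
        if op.upper() == "AND":
            return m1 and m2
        return m1 or m2

    return {n for n in G.nodes if hit(str(n))}
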