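"""Graph and result-table export.

Exports are byte-stable for a fixed input and configuration: node and
edge arrays are sorted, JSON keys are sorted, and z-scores are formatted
to three decimal places throughout, matching the precision of the
result tables.

Formats
-------
JSON
    A node-link graph document (see ``data/graph_schema.json``): nodes
    carry label and status, edges carry reaction id, kind, z, p, status,
    genes and the instantiating species tuples.
TXT
    A human-readable edge list, one ``"substrate -> product\\tz\\tstatus"``
    line per reaction.
TSV
    Four result tables mirroring the analysis output — active and
    suppressed chains, active and suppressed single reactions — with
    columns chain, z and predicted genes, plus a per-edge table of
    selected and non-selected molecular species.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import networkx as nx

from .stats import PathwayScore

__all__ = [
    "export_graph",
    "import_graph",
    "export_tables",
    "graph_to_document",
    "validate_graph_document",
    "load_graph_schema",
]


def _fmt_z(z: float) -> str:
    return f"{z:.3f}"


def graph_to_document(G: nx.DiGraph) -> dict:
    """Deterministic node-link dictionary for a (scored) network."""
    nodes = []
    for n in sorted(G.nodes):
        status = "none"
        for _, _, attrs in list(G.in_edges(n, data=True)) + list(G.out_edges(n, data=True)):
            if attrs.get("status") == "active":
                status = "active"
                break
            if attrs.get("status") == "suppressed":
                status = "suppressed"
        nodes.append({"id": str(n), "status": status})
    edges = []
    for u, v in sorted(G.edges):
        attrs = G.edges[u, v]
        edges.append(
            {
                "source": str(u),
                "target": str(v),
                "reaction": attrs.get("reaction", ""),
                "kind": attrs.get("kind", ""),
                "genes": list(attrs.get("genes", [])),
                "z": round(float(attrs["z"]), 3) if "z" in attrs else None,
                "p": round(float(attrs["p"]), 6) if "p" in attrs else None,
                "status": attrs.get("status", "none"),
                "species_pairs": [list(t) for t in attrs.get("species_pairs", [])],
            }
        )
    meta = {
        "level": G.graph.get("level", ""),
        "type": G.graph.get("type", ""),
        "alpha": G.graph.get("alpha"),
        "condition_of_interest": G.graph.get("condition_of_interest"),
        "control": G.graph.get("control"),
    }
    return {"meta": meta, "nodes": nodes, "edges": edges}


def load_graph_schema() -> dict:
    with (resources.files(__package__) / "data" / "graph_schema.json").open(
        "r", encoding="utf-8"
    ) as fh:
        return json.load(fh)


def validate_graph_document(doc: dict) -> None:
    """Structural check of a graph document against the shipped schema.

    A minimal validator (required keys and primitive types) sufficient
    for round-trip safety; raises ``ValueError`` naming the offence.
    """
    schema = load_graph_schema()
    for key in schema["required"]:
        if key not in doc:
            raise ValueError(f"graph document missing key {key!r}")
    if not isinstance(doc["nodes"], list) or not isinstance(doc["edges"], list):
        raise ValueError("nodes and edges must be arrays")
    node_req = schema["properties"]["nodes"]["items"]["required"]
    for node in doc["nodes"]:
        for key in node_req:
            if key not in node:
                raise ValueError(f"node {node!r} missing key {key!r}")
    edge_req = schema["properties"]["edges"]["items"]["required"]
    ids = {n["id"] for n in doc["nodes"]}
    for edge in doc["edges"]:
        for key in edge_req:
            if key not in edge:
                raise ValueError(f"edge {edge!r} missing key {key!r}")
        if edge["source"] not in ids or edge["target"] not in ids:
            raise ValueError(f"edge {edge['source']}->{edge['target']} references unknown node")


def export_graph(G: nx.DiGraph, fmt: str, path) -> None:
    """Write a network to ``path`` as ``"json"`` or ``"txt"``."""
    path = Path(path)
    if fmt == "json":
        doc = graph_to_document(G)
        validate_graph_document(doc)
        path.write_text(
            json.dumps(doc, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )
    elif fmt == "txt":
        lines = []
        for u, v in sorted(G.edges):
            attrs = G.edges[u, v]
            z = _fmt_z(attrs["z"]) if "z" in attrs else "NA"
            lines.append(f"{u} -> {v}\t{z}\t{attrs.get('status', 'none')}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown export format {fmt!r} (use 'json' or 'txt')")


def import_graph(path) -> nx.DiGraph:
    """Re-import an exported JSON graph document."""
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    validate_graph_document(doc)
    G = nx.DiGraph()
    meta = doc.get("meta", {})
    G.graph.update({k: v for k, v in meta.items() if v is not None})
    for node in doc["nodes"]:
        G.add_node(node["id"])
    for e in doc["edges"]:
        G.add_edge(
            e["source"],
            e["target"],
            reaction=e["reaction"],
            kind=e["kind"],
            genes=list(e["genes"]),
            z=e["z"],
            p=e["p"],
            status=e["status"],
            species_pairs=[tuple(t) for t in e["species_pairs"]],
        )
    return G


def _chain_rows(scores: list[PathwayScore]) -> list[str]:
    rows = ["chain\tz\tpredicted_genes"]
    for s in scores:
        rows.append(f"{s.label}\t{_fmt_z(s.z)}\t{', '.join(s.genes)}")
    return rows


def export_tables(
    outdir,
    active_chains: list[PathwayScore],
    suppressed_chains: list[PathwayScore],
    G: nx.DiGraph | None = None,
) -> dict[str, Path]:
    """Write the four result tables (plus species-pair detail) as TSV.

    ``active_pathways.tsv`` / ``suppressed_pathways.tsv`` hold all called
    chains; ``active_reactions.tsv`` / ``suppressed_reactions.tsv`` the
    single-reaction subset; ``species_pairs.tsv`` lists, per scored edge,
    the molecular species selected into the reaction and the non-selected
    species of the two subclasses.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def write(name: str, rows: list[str]) -> None:
        p = outdir / name
        p.write_text("\n".join(rows) + "\n", encoding="utf-8")
        written[name] = p

    write("active_pathways.tsv", _chain_rows(active_chains))
    write("suppressed_pathways.tsv", _chain_rows(suppressed_chains))
    write(
        "active_reactions.tsv",
        _chain_rows([s for s in active_chains if len(s.reactions) == 1]),
    )
    write(
        "suppressed_reactions.tsv",
        _chain_rows([s for s in suppressed_chains if len(s.reactions) == 1]),
    )

    if G is not None:
        rows = ["reaction\tsubstrate_species\tproduct_species\tfa_species\tselected"]
        for u, v in sorted(G.edges):
            attrs = G.edges[u, v]
            selected: set[str] = set()
            for tup in attrs.get("species_pairs", []):
                selected.update(tup)
                fa = tup[2] if len(tup) > 2 else ""
                rows.append(f"{attrs['reaction']}\t{tup[0]}\t{tup[1]}\t{fa}\tyes")
            for node in (u, v):
                for sp in _node_species(G, node):
                    if sp not in selected:
                        rows.append(f"{attrs['reaction']}\t{sp}\t\t\tno")
        write("species_pairs.tsv", rows)
    return written


def _node_species(G: nx.DiGraph, node: str) -> list[str]:
    species: set[str] = set()
    for _, _, attrs in list(G.in_edges(node, data=True)) + list(G.out_edges(node, data=True)):
        for tup in attrs.get("species_pairs", []):
            species.update(tup[:2])
    return sorted(species)
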