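"""Seed-gene protein-protein interaction subnetworks and hub ranking.

A per-family network is built by projecting the family's candidate ("seed")
genes onto an interaction database: the node set is the seeds found in the
database plus their first neighbors, and the edge set is the full induced
subgraph on those nodes (seed-neighbor *and* neighbor-neighbor edges).  Seeds
absent from the database are reported, not silently included.  Hub genes are
the nodes whose degree centrality reaches a threshold (the published hub
criterion is degree >= 50).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)


class NetworkError(ValueError):
    pass


@dataclass
class InteractionTable:
    """Deduplicated undirected gene-symbol pairs (symbols upper-cased)."""

    pairs: list[tuple[str, str, str | None]] = field(default_factory=list)

    def symbols(self) -> set[str]:
        s: set[str] = set()
        for a, b, _ in self.pairs:
            s.add(a)
            s.add(b)
        return s

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for a, b, _ in self.pairs:
            g.add_edge(a, b)
        return g


@dataclass
class PPINetwork:
    """Undirected gene graph plus the seed subset it was grown from."""

    graph: nx.Graph
    seeds: frozenset[str] = frozenset()
    missing_seeds: tuple[str, ...] = ()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def validate(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise NetworkError("self-loop in network")
        if not self.seeds <= set(self.graph.nodes):
            raise NetworkError("seeds not a subset of nodes")


def _norm(symbol: str) -> str:
    return symbol.strip().upper()


def load_interactions(
    path: str | Path, dialect: str = "two_column_tsv"
) -> InteractionTable:
    """Read an interaction edge list.

    ``two_column_tsv``: header ``gene_a  gene_b  [source]``.
    ``psi_mitab``: PSI-MITAB 2.5; gene symbols are taken from the alias
    columns' ``(gene name)`` entries.

    Symbols are upper-cased; self-pairs dropped; duplicate undirected pairs
    collapsed.  Unparseable rows are skipped with a counted warning; zero
    usable rows is a hard error.
    """
    seen: set[frozenset[str]] = set()
    pairs: list[tuple[str, str, str | None]] = []
    skipped = 0

    def add(a: str, b: str, source: str | None) -> None:
        a, b = _norm(a), _norm(b)
        if not a or not b or a == b:
            return
        key = frozenset((a, b))
        if key in seen:
            return
        seen.add(key)
        pairs.append((min(a, b), max(a, b), source))

    with open(path, encoding="utf-8") as fh:
        if dialect == "two_column_tsv":
            header = fh.readline()
            if not header.lower().startswith("gene_a"):
                fh.seek(0)  # headerless files are accepted too
            for line in fh:
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 2 or not cols[0].strip() or not cols[1].strip():
                    skipped += 1
                    continue
                add(cols[0], cols[1], cols[2] if len(cols) > 2 and cols[2] else None)
        elif dialect == "psi_mitab":
            for line in fh:
                if line.startswith("#"):
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 6:
                    skipped += 1
                    continue
                ga = _mitab_gene_name(cols[4])
                gb = _mitab_gene_name(cols[5])
                if ga is None or gb is None:
                    skipped += 1
                    continue
                add(ga, gb, "psi_mitab")
        else:
            raise NetworkError(f"unknown dialect {dialect!r}")

    if skipped:
        logger.warning("load_interactions: skipped %d unparseable rows", skipped)
    if not pairs:
        raise NetworkError(f"{path}: no usable interaction rows")
    return InteractionTable(pairs)


def _mitab_gene_name(alias_field: str) -> str | None:
    for entry in alias_field.split("|"):
        if "(gene name)" in entry:
            val = entry.split("(gene name)")[0]
            if ":" in val:
                val = val.split(":", 1)[1]
            return val
    return None


def build_seed_network(
    seeds: Sequence[str],
    db: InteractionTable,
    depth: int = 1,
    induced: bool = True,
) -> PPINetwork:
    """Grow the seed subnetwork: seeds found in the database plus their
    ``depth``-step neighbors, with the database's induced edges on that node
    set (or, with ``induced=False``, only edges incident to a seed).

    Seeds absent from the database end up in ``missing_seeds``; no seed found
    at all is a hard error.
    """
    if not seeds:
        raise NetworkError("empty seed list")
    norm_seeds = sorted({_norm(s) for s in seeds})
    g = db.to_graph()
    present = [s for s in norm_seeds if s in g]
    missing = tuple(s for s in norm_seeds if s not in g)
    if not present:
        raise NetworkError(f"no seed found in interaction database: {missing}")
    if missing:
        logger.info("seeds absent from database: %s", ",".join(missing))

    nodes = set(present)
    frontier = set(present)
    for _ in range(depth):
        frontier = {n for f in frontier for n in g.neighbors(f)} - nodes
        nodes |= frontier

    if induced:
        sub = g.subgraph(nodes).copy()
    else:
        sub = nx.Graph()
        sub.add_nodes_from(nodes)
        seed_set = set(present)
        for u, v in g.subgraph(nodes).edges:
            if u in seed_set or v in seed_set:
                sub.add_edge(u, v)
    net = PPINetwork(graph=sub, seeds=frozenset(present), missing_seeds=missing)
    net.validate()
    return net


def degree_centrality(net: PPINetwork) -> dict[str, int]:
    """Degree (count of incident edges) for every node."""
    return {n: int(d) for n, d in net.graph.degree()}


def hub_genes(
    net_or_degrees: PPINetwork | Mapping[str, int], min_degree: int = 50
) -> list[tuple[str, int]]:
    """Nodes at or above ``min_degree``, sorted by degree descending, ties
    lexicographic.  Accepts either a network or a precomputed degree map."""
    if isinstance(net_or_degrees, PPINetwork):
        degrees: Mapping[str, int] = degree_centrality(net_or_degrees)
    else:
        degrees = net_or_degrees
    hubs = [(g, int(d)) for g, d in degrees.items() if d >= min_degree]
    return sorted(hubs, key=lambda gd: (-gd[1], gd[0]))


def network_summary(net: PPINetwork) -> tuple[int, int, int]:
    """(n_nodes, n_edges, n_seeds)."""
    return (
        net.graph.number_of_nodes(),
        net.graph.number_of_edges(),
        len(net.seeds),
    )


def write_network(
    net: PPINetwork,
    edge_path: str | Path,
    node_path: str | Path,
    modules: Mapping[str, int] | None = None,
) -> None:
    """Edge-list TSV + node-attribute TSV (node, is_seed, degree, module_id)."""
    edges = sorted((min(u, v), max(u, v)) for u, v in net.graph.edges)
    pd.DataFrame(edges, columns=["gene_a", "gene_b"]).to_csv(
        edge_path, sep="\t", index=False
    )
    deg = degree_centrality(net)
    rows = [
        {
            "node": n,
            "is_seed": int(n in net.seeds),
            "degree": deg[n],
            "module_id": "" if modules is None else modules.get(n, ""),
        }
        for n in sorted(net.graph.nodes)
    ]
    pd.DataFrame(rows).to_csv(node_path, sep="\t", index=False)
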