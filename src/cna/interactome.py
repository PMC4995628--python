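"""Protein-interaction network handling.

Interactomes are undirected simple graphs over gene identifiers (Entrez ids
or symbols, treated as opaque strings). Edge lists arrive as two-column TSV
or SIF files; self-interactions (homodimers) and rows with missing
identifiers are dropped at parse time, and analyses run on the largest
connected component. A degree-preserving, connectedness-preserving
double-edge-swap randomizer provides the null network model.
"""

from __future__ import annotations

import logging
import math
import random
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

logger = logging.getLogger(__name__)

#: identifiers treated as "no assigned identifier" placeholders
_PLACEHOLDERS = {"", "-", "na", "n/a", "nan", "none", "null"}


@dataclass
class EdgeFilterReport:
    """Counts of edge-list rows dropped or collapsed during loading."""

    n_rows: int = 0
    n_self_interactions: int = 0
    n_unidentified: int = 0
    n_duplicates: int = 0
    n_edges: int = 0


@dataclass
class Interactome:
    """An undirected simple protein-interaction graph.

    Wraps a :class:`networkx.Graph`; nodes are gene identifier strings,
    edges are unordered pairs stored once, with no self-loops.
    """

    graph: nx.Graph
    provenance: str = ""
    report: EdgeFilterReport | None = field(default=None, repr=False)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree_sequence(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def is_connected(self) -> bool:
        return self.n_nodes > 0 and nx.is_connected(self.graph)


def _is_placeholder(ident: str) -> bool:
    return ident.strip().lower() in _PLACEHOLDERS


def load_edge_list(
    path: str | Path,
    format: str = "tsv",
    provenance: str | None = None,
) -> Interactome:
    """Parse a two-column TSV or SIF edge list into an :class:`Interactome`.

    Rows whose two endpoints are identical (homodimers / self-loops) and rows
    with a missing or placeholder identifier are dropped; duplicate pairs
    collapse to a single undirected edge. Dropped-row counts are kept in
    ``result.report``.

    Parameters
    ----------
    path:
        Edge-list file. TSV: two identifier columns, optional ``#`` comments
        and an optional header line. SIF: ``A <relation> B`` triples.
    format:
        ``"tsv"`` or ``"sif"``.

    Raises
    ------
    ValueError
        If the file yields zero edges after filtering, or format is unknown.
    """
    path = Path(path)
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format: {format!r}")
    g = nx.Graph()
    report = EdgeFilterReport()
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if format == "sif":
                if len(fields) == 1:
                    fields = line.split()
                if len(fields) < 3:
                    report.n_rows += 1
                    report.n_unidentified += 1
                    continue
                a, b = fields[0], fields[2]
            else:
                if len(fields) < 2:
                    report.n_rows += 1
                    report.n_unidentified += 1
                    continue
                a, b = fields[0], fields[1]
            # skip a header row (first line, non-numeric-looking duplicates are
            # indistinguishable from data; only an explicit header is caught)
            if lineno == 0 and format == "tsv" and _looks_like_header(a, b):
                continue
            report.n_rows += 1
            a, b = a.strip(), b.strip()
            if _is_placeholder(a) or _is_placeholder(b):
                report.n_unidentified += 1
                continue
            if a == b:
                report.n_self_interactions += 1
                continue
            if g.has_edge(a, b):
                report.n_duplicates += 1
                continue
            g.add_edge(a, b)
    report.n_edges = g.number_of_edges()
    if report.n_edges == 0:
        raise ValueError(f"no edges remain after filtering {path}")
    logger.info(
        "loaded %d edges (%d nodes) from %s; dropped %d self, %d unidentified, "
        "%d duplicate rows",
        report.n_edges, g.number_of_nodes(), path,
        report.n_self_interactions, report.n_unidentified, report.n_duplicates,
    )
    return Interactome(g, provenance or str(path), report)


_HEADER_TOKENS = {
    "gene1", "gene2", "genea", "geneb", "node1", "node2", "source", "target",
    "protein1", "protein2", "interactor_a", "interactor_b", "from", "to",
}


def _looks_like_header(a: str, b: str) -> bool:
    return a.strip().lower() in _HEADER_TOKENS and b.strip().lower() in _HEADER_TOKENS


def main_component(inter: Interactome) -> Interactome:
    """Return the subgraph induced by the largest connected component.

    Ties in component size break toward the component containing the
    lexicographically smallest node label, for determinism. Idempotent.
    """
    g = inter.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph has no main component")
    best = min(
        nx.connected_components(g),
        key=lambda c: (-len(c), min(c)),
    )
    sub = g.subgraph(best).copy()
    logger.info(
        "main component: %d/%d nodes, %d/%d edges",
        sub.number_of_nodes(), g.number_of_nodes(),
        sub.number_of_edges(), g.number_of_edges(),
    )
    return Interactome(sub, inter.provenance, inter.report)


def _connected_after_swap(adj: dict[str, set], a: str, b: str) -> bool:
    """BFS from ``a`` toward ``b`` with early exit.

    After swapping edges {a,b},{c,d} -> {a,d},{c,b} on a connected graph,
    the result is connected iff ``b`` is reachable from ``a``: any surviving
    component must contain one of a,b,c,d (every old path enters the swap
    quadruple at its first removed edge), and the new edges a-d, c-b chain
    all four together once a reaches b.
    """
    if b in adj[a]:
        return True
    seen = {a}
    queue = deque((a,))
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v == b:
                return True
            if v not in seen:
                seen.add(v)
                queue.append(v)
    return False


def degree_preserving_randomize(
    inter: Interactome,
    swap_factor: float = 10.0,
    seed: int = 0,
) -> Interactome:
    """Rewire a connected graph preserving every node's degree and connectivity.

    Attempts ``ceil(swap_factor * |E|)`` double-edge swaps
    ({a,b},{c,d} -> {a,d},{c,b}); swaps that would create a self-loop, a
    multi-edge, or disconnect the graph are rejected. Reproducible for a
    fixed seed.
    """
    if swap_factor <= 0:
        raise ValueError("swap_factor must be positive")
    g = inter.graph
    if not nx.is_connected(g):
        raise ValueError("degree-preserving randomization requires a connected graph")
    rng = random.Random(seed)
    edges: list[tuple[str, str]] = [tuple(e) for e in g.edges]
    adj: dict[str, set] = {n: set(g.adj[n]) for n in g.nodes}
    n_attempts = max(1, math.ceil(swap_factor * len(edges)))
    accepted = 0
    m = len(edges)
    for _ in range(n_attempts):
        i = rng.randrange(m)
        j = rng.randrange(m)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # proposed new edges: a-d and c-b
        if len({a, b, c, d}) < 4:
            continue
        if d in adj[a] or b in adj[c]:
            continue
        adj[a].remove(b); adj[b].remove(a)
        adj[c].remove(d); adj[d].remove(c)
        adj[a].add(d); adj[d].add(a)
        adj[c].add(b); adj[b].add(c)
        if _connected_after_swap(adj, a, b):
            edges[i] = (a, d)
            edges[j] = (c, b)
            accepted += 1
        else:  # revert
            adj[a].remove(d); adj[d].remove(a)
            adj[c].remove(b); adj[b].remove(c)
            adj[a].add(b); adj[b].add(a)
            adj[c].add(d); adj[d].add(c)
    if accepted == 0:
        logger.warning("no valid degree-preserving swap found; returning input unchanged")
        return Interactome(g.copy(), inter.provenance + " [rewired:0 swaps]")
    out = nx.Graph()
    out.add_nodes_from(g.nodes)
    out.add_edges_from(edges)
    logger.info("rewired: %d/%d swaps accepted", accepted, n_attempts)
    return Interactome(out, inter.provenance + f" [rewired seed={seed}]")


def write_edge_list(inter: Interactome, path: str | Path) -> None:
    """Write the edge set as a sorted two-column TSV (bit-reproducible)."""
    rows = sorted(tuple(sorted(e)) for e in inter.graph.edges)
    with open(path, "w") as fh:
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")
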