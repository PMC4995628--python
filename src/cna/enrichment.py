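"""Over-representation analysis with Fisher's exact test and BH FDR control.

Gene-set collections (GO terms, pathways, TF-target sets) come in as GMT
files; the query is typically the high-centrality tertile of the network and
the universe defaults to the main-component node set. Sets covering < 5 % of
the universe are dropped before testing, mirroring standard frequency
filtering of sparse annotation terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "read_gmt",
    "write_gmt",
    "filter_sets",
    "fisher_enrichment",
    "fdr_adjust",
    "enrich_collection",
    "EnrichmentResult",
    "reassign_to_level",
]


@dataclass
class EnrichmentResult:
    name: str
    table: tuple[int, int, int, int]  # a, b, c, d of the 2x2 contingency table
    odds_ratio: float
    p: float
    q: float | None = None


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: name <TAB> description <TAB> member genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            members = {g for g in fields[2:] if g}
            if members:
                sets[name] = members
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def filter_sets(
    collection: dict[str, set[str]],
    universe: set[str],
    min_freq: float = 0.05,
    relative_to: str = "universe",
    query: set[str] | None = None,
) -> dict[str, set[str]]:
    """Intersect sets with the universe and drop low-frequency sets.

    A set is retained when its in-universe membership covers at least
    ``min_freq`` (inclusive) of the reference population — the universe by
    default, or the query set with ``relative_to="query"``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if relative_to == "universe":
        denom_set = universe
    elif relative_to == "query":
        if query is None:
            raise ValueError("relative_to='query' requires the query set")
        denom_set = set(query) & universe
    else:
        raise ValueError(f"unknown relative_to: {relative_to!r}")
    denom = len(denom_set)
    out = {}
    for name, members in collection.items():
        inside = members & (universe if relative_to == "universe" else denom_set)
        if denom and len(inside) / denom >= min_freq:
            out[name] = members & universe
    return out


def fisher_enrichment(
    query: set[str],
    gene_set: set[str],
    universe: set[str],
) -> EnrichmentResult:
    """One-sided (over-representation) Fisher exact test for one gene set.

    Builds the 2×2 table [[a, b], [c, d]] with a = |query ∩ set|,
    b = |query \\ set|, c = |set \\ query|, d = the rest of the universe;
    p is the hypergeometric upper tail P(X >= a); the odds ratio is ad/bc
    (inf when bc = 0 and ad > 0).
    """
    universe = set(universe)
    query = set(query)
    if not query:
        raise ValueError("empty query set")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    gene_set = set(gene_set) & universe
    a = len(query & gene_set)
    b = len(query) - a
    c = len(gene_set) - a
    d = len(universe) - a - b - c
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    # P(X >= a) for X ~ Hypergeom(N=|U|, K=|set|, n=|query|)
    p = float(stats.hypergeom.sf(a - 1, len(universe), len(gene_set), len(query)))
    return EnrichmentResult("", (a, b, c, d), odds, min(p, 1.0))


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_collection(
    query: set[str],
    collection: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
    min_freq: float = 0.05,
    relative_to: str = "universe",
) -> pd.DataFrame:
    """Frequency-filter, test, and FDR-adjust a whole gene-set collection.

    Returns a DataFrame sorted by q then p, one row per tested set, with the
    2×2 counts, odds ratio, Fisher p, BH q, and a ``significant`` flag at
    q < ``alpha``. The same machinery serves GO, pathway, and TF-target
    collections.
    """
    kept = filter_sets(collection, universe, min_freq, relative_to, query=query)
    if not kept:
        raise ValueError("no gene set passed the frequency filter")
    rows = []
    for name in sorted(kept):
        res = fisher_enrichment(query, kept[name], universe)
        a, b, c, d = res.table
        rows.append({"set": name, "overlap": a, "query_only": b,
                     "set_only": c, "background": d,
                     "odds_ratio": res.odds_ratio, "p": res.p})
    df = pd.DataFrame(rows).set_index("set")
    df["q"] = fdr_adjust(df["p"].to_numpy())
    df["significant"] = df["q"] < alpha
    return df.sort_values(["q", "p"])


def reassign_to_level(
    annotations: pd.DataFrame,
    parents: pd.DataFrame,
    target_level: int = 4,
    exclude_level: int = 3,
) -> dict[str, set[str]]:
    """Collapse a term hierarchy onto one depth level, emitting a GMT-style dict.

    ``annotations`` has columns ``gene`` and ``term``; ``parents`` has
    columns ``term`` and ``parent`` (roots appear only as parents). Term
    depth is the shortest root-to-term path length (roots at level 1).
    Genes annotated at ``target_level`` or deeper are propagated up to their
    ``target_level`` ancestors; genes that also occur at ``exclude_level``
    (or shallower) are removed. The ontology itself is a user-supplied
    input — only the term-parent table is consumed.
    """
    child_to_parents: dict[str, set[str]] = {}
    all_terms: set[str] = set()
    for _, row in parents.iterrows():
        child_to_parents.setdefault(str(row["term"]), set()).add(str(row["parent"]))
        all_terms.update((str(row["term"]), str(row["parent"])))
    roots = {t for t in all_terms if t not in child_to_parents}
    if not roots:
        raise ValueError("term hierarchy has no root (cycle?)")
    # BFS depth from roots (roots = level 1)
    level = {t: 1 for t in roots}
    frontier = set(roots)
    while frontier:
        nxt = set()
        for child, ps in child_to_parents.items():
            if child not in level and ps & frontier:
                level[child] = min(level[p] for p in ps if p in level) + 1
                nxt.add(child)
        frontier = nxt

    def ancestors_at(term: str, lvl: int) -> set[str]:
        found, seen, stack = set(), set(), [term]
        while stack:
            t = stack.pop()
            if t in seen:
                continue
            seen.add(t)
            if level.get(t) == lvl:
                found.add(t)
            stack.extend(child_to_parents.get(t, ()))
        return found

    shallow_genes: set[str] = set()
    collapsed: dict[str, set[str]] = {}
    for _, row in annotations.iterrows():
        gene, term = str(row["gene"]), str(row["term"])
        lvl = level.get(term)
        if lvl is None:
            continue
        if lvl <= exclude_level:
            shallow_genes.add(gene)
            continue
        targets = {term} if lvl == target_level else ancestors_at(term, target_level)
        for t in targets:
            collapsed.setdefault(t, set()).add(gene)
    out = {}
    for t, genes in collapsed.items():
        kept = genes - shallow_genes
        if kept:
            out[t] = kept
    return out
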