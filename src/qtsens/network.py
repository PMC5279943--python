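"""Interactome assembly and direct-neighbor candidate-gene discovery.

A human protein-interaction graph is assembled by pooling edge lists,
re-mapping non-human (lower-cased) symbols through an orthology map, and
dropping nodes that are not official human gene symbols.  Candidate genes are
the differentially expressed direct neighbors (path length 1) of a seed set
of congenital long-QT genes; an optional hypergeometric enrichment ranks
transcription factors by overlap of their target sets with the candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SeedSet",
    "NeighborHit",
    "merge_interactome",
    "direct_neighbors",
    "de_neighbors",
    "tf_enrichment",
]


@dataclass(frozen=True)
class SeedSet:
    """Seed genes (upper-case official symbols), default-free by design."""

    symbols: tuple

    def __init__(self, symbols):
        symbols = tuple(str(s).upper() for s in symbols)
        if not symbols:
            raise ValueError("seed set must be non-empty")
        object.__setattr__(self, "symbols", symbols)

    def __iter__(self):
        return iter(self.symbols)

    def __len__(self):
        return len(self.symbols)


@dataclass(frozen=True)
class NeighborHit:
    gene: str
    direction: str  # "up" or "down"
    seed_links: tuple


def merge_interactome(edge_lists, ortholog_map=None, valid_symbols=None) -> nx.Graph:
    """Pool edge lists into one undirected graph with provenance.

    ``edge_lists`` is a mapping ``source name -> iterable of (u, v) pairs`` (a
    2-column DataFrame also works).  Symbols that are not fully upper-case are
    treated as non-human gene symbols: they are renamed through
    ``ortholog_map`` or dropped (with their edges) when unmapped.  Nodes
    absent from ``valid_symbols`` (when given) are dropped.  Self-loops and
    duplicate undirected edges are removed; each surviving edge keeps the list
    of sources it came from.
    """
    ortholog_map = dict(ortholog_map or {})
    graph = nx.Graph()
    for source, edges in dict(edge_lists).items():
        if isinstance(edges, pd.DataFrame):
            edges = edges.itertuples(index=False)
        for i, row in enumerate(edges):
            row = tuple(row)
            if len(row) != 2 or not all(isinstance(x, str) and x for x in row):
                raise ValueError(f"{source}: malformed edge row {i + 1}: {row!r}")
            u, v = row
            mapped = []
            for sym in (u, v):
                if not sym.isupper():
                    sym = ortholog_map.get(sym)
                    if sym is None:
                        break
                mapped.append(sym)
            if len(mapped) != 2:
                continue  # unmapped non-human symbol: drop edge
            u, v = mapped
            if u == v:
                continue
            if graph.has_edge(u, v):
                if source not in graph[u][v]["sources"]:
                    graph[u][v]["sources"].append(source)
            else:
                graph.add_edge(u, v, sources=[source])
    if valid_symbols is not None:
        valid = set(valid_symbols)
        graph.remove_nodes_from([n for n in list(graph) if n not in valid])
    return graph


def direct_neighbors(graph: nx.Graph, seeds) -> set:
    """Union of the adjacency of present seed genes, minus the seeds.

    Seeds absent from the graph are warned about and skipped.
    """
    seeds = set(seeds)
    absent = seeds - set(graph)
    if absent:
        warnings.warn(f"seeds absent from interactome: {sorted(absent)}", stacklevel=2)
    out = set()
    for s in seeds & set(graph):
        out.update(graph.neighbors(s))
    return out - seeds


def de_neighbors(neighbors, deg_results: pd.DataFrame, graph: nx.Graph, seeds) -> list:
    """Differentially expressed direct neighbors with direction and seed links.

    ``deg_results`` is a DataFrame indexed by gene with ``is_de`` and ``lfc``
    columns (genes without a row are treated as not differential).  Returns
    :class:`NeighborHit` records sorted by gene symbol; seed genes themselves
    are never reported as hits.
    """
    seeds = set(seeds)
    hits = []
    for gene in sorted(set(neighbors) - seeds):
        if gene not in deg_results.index:
            continue
        row = deg_results.loc[gene]
        if not bool(row["is_de"]):
            continue
        links = tuple(sorted(s for s in seeds if graph.has_edge(gene, s)))
        hits.append(
            NeighborHit(gene=gene, direction="up" if row["lfc"] > 0 else "down", seed_links=links)
        )
    return hits


def tf_enrichment(deg_genes, gene_set_collection, background_size: int) -> pd.DataFrame:
    """Hypergeometric enrichment of DE genes in transcription-factor target sets.

    For each TF with target set T within a background universe of
    ``background_size`` genes, the one-sided p is
    P[X ≥ overlap] for X ~ Hypergeom(M=background, K=|T|, n=|DEG|).
    Rows are ranked by ascending p, ties broken by larger overlap then symbol.
    """
    deg = set(deg_genes)
    sets = {tf: set(targets) for tf, targets in dict(gene_set_collection).items()}
    union = set().union(*sets.values()) if sets else set()
    if background_size < len(union | deg):
        raise ValueError("background smaller than the union of gene sets and DEGs")
    rows = []
    for tf, targets in sets.items():
        k = len(deg & targets)
        p = float(stats.hypergeom.sf(k - 1, background_size, len(targets), len(deg))) if k else 1.0
        rows.append({"tf": tf, "overlap": k, "set_size": len(targets), "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(
            ["p", "overlap", "tf"], ascending=[True, False, True], kind="mergesort"
        ).reset_index(drop=True)
        out["rank"] = np.arange(1, len(out) + 1)
    return out
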