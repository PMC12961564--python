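"""Seed-protein network expansion and hypergeometric pathway enrichment.

Given a scored protein–protein interaction edge list, the seed
receptors are expanded by their n nearest interacting partners —
"nearest" meaning highest maximum edge score to any seed, ties broken
lexicographically.  The expanded node set is then tested for gene-set
(pathway) over-representation with the one-sided hypergeometric test

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

where N is the background size, K the term size within the background,
n the query size and k the observed overlap, followed by
Benjamini–Hochberg FDR adjustment.  Terms with FDR <= 0.05 (inclusive)
are flagged significant.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DualScreenError


@dataclass(frozen=True)
class ScoredEdge:
    node_u: str
    node_v: str
    score: float

    def __post_init__(self) -> None:
        if self.node_u == self.node_v:
            raise DualScreenError(f"self-edge not allowed: {self.node_u}")
        if not 0 < self.score <= 1:
            raise DualScreenError(f"edge score must be in (0, 1]: {self.score}")


@dataclass
class GeneSet:
    term_id: str
    term_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise DualScreenError(f"gene set {self.term_id} has no members")


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    fdr: float
    rank: int
    significant: bool


def read_edge_tsv(path: str | Path) -> list[ScoredEdge]:
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            u, v, s = line.split("\t")[:3]
            edges.append(ScoredEdge(u, v, float(s)))
    return edges


def write_edge_tsv(edges: Iterable[ScoredEdge], path: str | Path) -> None:
    with open(path, "w") as fh:
        for e in edges:
            fh.write(f"{e.node_u}\t{e.node_v}\t{e.score:g}\n")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from GMT (term, description, members...) lines."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(parts[0], parts[1], frozenset(p for p in parts[2:] if p)))
    return sets


def write_gmt(genesets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in genesets:
            fh.write("\t".join([gs.term_id, gs.term_name, *sorted(gs.members)]) + "\n")


def build_graph(edges: Iterable[ScoredEdge]) -> nx.Graph:
    g = nx.Graph()
    for e in edges:
        # keep the strongest score if an edge is listed twice
        if g.has_edge(e.node_u, e.node_v):
            g[e.node_u][e.node_v]["score"] = max(g[e.node_u][e.node_v]["score"], e.score)
        else:
            g.add_edge(e.node_u, e.node_v, score=e.score)
    return g


def expand_network(
    edges: Iterable[ScoredEdge] | nx.Graph,
    seeds: set[str],
    n_extra: int,
) -> set[str]:
    """Seeds plus their n_extra highest-scoring non-seed neighbors.

    A non-seed node is ranked by the maximum edge score linking it to
    any seed; ties are broken lexicographically by identifier.  Seeds
    absent from the edge list are kept (with a warning via the return
    semantics: they simply contribute no neighbors).
    """
    if n_extra < 0:
        raise DualScreenError("n_extra must be >= 0")
    g = edges if isinstance(edges, nx.Graph) else build_graph(edges)
    best: dict[str, float] = {}
    for s in seeds:
        if s not in g:
            continue
        for nb, attrs in g[s].items():
            if nb in seeds:
                continue
            sc = attrs["score"]
            if sc > best.get(nb, -1.0):
                best[nb] = sc
    ranked = sorted(best, key=lambda n: (-best[n], n))
    return set(seeds) | set(ranked[:n_extra])


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts successes in a draw of n from a population of N containing
    K successes.  Delegates to scipy's log-space survival function.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise DualScreenError(
            f"invalid hypergeometric bounds: k={k} K={K} n={n} N={N}"
        )
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise DualScreenError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def enrich(
    query_nodes: set[str],
    genesets: Sequence[GeneSet],
    background: set[str],
    fdr_cutoff: float = 0.05,
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of each term in the query.

    Term memberships are intersected with the background; terms with no
    query hit (k = 0) are omitted.  Rows are ranked by ascending FDR,
    ties broken by p-value then term id.
    """
    if not background:
        raise DualScreenError("background set is empty")
    if not query_nodes <= background:
        raise DualScreenError("query nodes must be a subset of the background")
    N = len(background)
    n = len(query_nodes)
    tested: list[tuple[GeneSet, int, int, float]] = []
    for gs in genesets:
        members = gs.members & background
        k = len(gs.members & query_nodes)
        if k == 0 or not members:
            continue
        K = len(members)
        tested.append((gs, k, K, hypergeom_upper(k, K, n, N)))
    if not tested:
        return []
    fdrs = bh_fdr([t[3] for t in tested])
    rows = [
        EnrichmentRow(
            term_id=gs.term_id,
            term_name=gs.term_name,
            k=k, K=K, n=n, N=N,
            p_value=p, fdr=f, rank=0,
            significant=f <= fdr_cutoff,
        )
        for (gs, k, K, p), f in zip(tested, fdrs)
    ]
    rows.sort(key=lambda r: (r.fdr, r.p_value, r.term_id))
    for i, r in enumerate(rows, start=1):
        r.rank = i
    return rows


def enrichment_to_csv(rows: Sequence[EnrichmentRow], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["rank", "term_id", "term_name", "k", "K", "n", "N",
             "p_value", "fdr", "significant"]
        )
        for r in rows:
            w.writerow(
                [r.rank, r.term_id, r.term_name, r.k, r.K, r.n, r.N,
                 f"{r.p_value:.6g}", f"{r.fdr:.6g}", r.significant]
            )
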