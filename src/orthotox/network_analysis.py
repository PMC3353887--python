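"""Interactome connectivity analysis for a projected gene set.

Given an undirected protein-protein interaction network and a query gene
set (here, the modulator homologs), the central statistic is the size of
the largest connected component (LCC) of the subgraph induced by the
query. Its significance is assessed by permutation: repeatedly draw node
sets of the same size from the network (uniformly, or matched to the query
degree distribution within geometric degree bins) and compare LCC sizes.
The p-value uses the add-one estimator (n_geq + 1)/(n_permutations + 1),
which can never be zero; when no permutation reaches the observed LCC the
result is flagged as an upper bound.

Functional enrichment of subnetworks is scored with the upper-tail
hypergeometric test, with Benjamini-Hochberg adjustment reported alongside
the raw p-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


def build_network(edge_rows: Iterable[Sequence[str]]) -> nx.Graph:
    """Construct a simple undirected graph from edge rows.

    Self-loops are dropped and duplicate edges (in either orientation)
    collapsed; counts of dropped rows are logged and stored in
    ``graph.graph``. Gene symbols are upper-cased.
    """
    g = nx.Graph()
    n_self, n_dup = 0, 0
    for i, row in enumerate(edge_rows, start=1):
        row = tuple(row)
        if len(row) != 2 or not row[0] or not row[1]:
            raise ValueError(f"malformed edge row at line {i}: {row!r}")
        a, b = str(row[0]).upper(), str(row[1]).upper()
        if a == b:
            n_self += 1
            continue
        if g.has_edge(a, b):
            n_dup += 1
            continue
        g.add_edge(a, b)
    if n_self or n_dup:
        logger.info("build_network: dropped %d self-loops, %d duplicate edges",
                    n_self, n_dup)
    g.graph["n_self_loops_dropped"] = n_self
    g.graph["n_duplicates_dropped"] = n_dup
    return g


@dataclass
class LCCResult:
    """Largest connected component of the query-induced subgraph.

    ``lcc_fraction`` is None (explicitly undefined) when no query gene is
    in the network; ``lcc_fraction_of_query`` uses the full query size as
    denominator, for the case where some query genes are absent from the
    interactome.
    """

    query_size: int
    in_network: int
    lcc_size: int
    lcc_members: frozenset[str]

    def __post_init__(self):
        if not (0 <= self.lcc_size <= self.in_network <= self.query_size):
            raise ValueError("require 0 <= lcc_size <= in_network <= query_size")

    @property
    def lcc_fraction(self) -> float | None:
        if self.in_network == 0:
            return None
        return self.lcc_size / self.in_network

    @property
    def lcc_fraction_of_query(self) -> float | None:
        if self.query_size == 0:
            return None
        return self.lcc_size / self.query_size


def induced_lcc(net: nx.Graph, query: Iterable[str]) -> LCCResult:
    """LCC of the subgraph induced on ``query`` ∩ network nodes.

    Ties on component size are broken by the lexicographically smallest
    member, so the reported member set is deterministic.
    """
    query = {str(q).upper() for q in query}
    present = query & set(net.nodes)
    if not present:
        return LCCResult(len(query), 0, 0, frozenset())
    sub = net.subgraph(present)
    components = [sorted(c) for c in nx.connected_components(sub)]
    # largest by size; among equal sizes the lexicographically smallest head
    best = sorted(components, key=lambda c: (-len(c), c[0]))[0]
    return LCCResult(len(query), len(present), len(best), frozenset(best))


def _degree_bin(degree: int) -> int:
    """Geometric degree bins: 0 | 1 | 2 | 3-4 | 5-8 | 9-16 | ..."""
    if degree <= 0:
        return 0
    return int(math.ceil(math.log2(degree))) + 1


@dataclass
class PermutationResult:
    observed_lcc: int
    n_permutations: int
    n_geq: int
    null_model: str
    seed: int | None
    null_mean: float
    null_sd: float
    null_max: int

    def __post_init__(self):
        if self.n_geq > self.n_permutations:
            raise ValueError("n_geq cannot exceed n_permutations")

    @property
    def p_estimate(self) -> float:
        return (self.n_geq + 1) / (self.n_permutations + 1)

    @property
    def p_is_upper_bound(self) -> bool:
        return self.n_geq == 0


def permutation_test_lcc(
    net: nx.Graph,
    query: Iterable[str],
    n_permutations: int = 1000,
    null_model: Literal["uniform", "degree_matched"] = "uniform",
    seed: int | None = None,
) -> PermutationResult:
    """Permutation significance of the query's induced-LCC size.

    Each permutation draws ``in_network`` nodes without replacement —
    uniformly from all network nodes, or bin-by-bin matching the query's
    degree-bin profile for the ``degree_matched`` null. Permutations are
    independent of one another.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if null_model not in ("uniform", "degree_matched"):
        raise ValueError(f"unknown null_model {null_model!r}")
    query = {str(q).upper() for q in query}
    present = sorted(query & set(net.nodes))
    if not present:
        raise ValueError("no query gene is present in the network")
    observed = induced_lcc(net, present).lcc_size

    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes)
    sizes = np.empty(n_permutations, dtype=np.int64)

    if null_model == "uniform":
        node_arr = np.array(nodes, dtype=object)
        for i in range(n_permutations):
            draw = rng.choice(node_arr, size=len(present), replace=False)
            sizes[i] = _lcc_size(net, draw)
    else:
        by_bin: dict[int, list[str]] = {}
        for node in nodes:
            by_bin.setdefault(_degree_bin(net.degree(node)), []).append(node)
        need: dict[int, int] = {}
        for q in present:
            b = _degree_bin(net.degree(q))
            need[b] = need.get(b, 0) + 1
        bin_arrays = {b: np.array(members, dtype=object) for b, members in by_bin.items()}
        for i in range(n_permutations):
            draw = np.concatenate([
                rng.choice(bin_arrays[b], size=k, replace=False)
                for b, k in sorted(need.items())
            ])
            sizes[i] = _lcc_size(net, draw)

    n_geq = int(np.sum(sizes >= observed))
    return PermutationResult(
        observed_lcc=observed,
        n_permutations=n_permutations,
        n_geq=n_geq,
        null_model=null_model,
        seed=seed,
        null_mean=float(np.mean(sizes)),
        null_sd=float(np.std(sizes, ddof=1)) if n_permutations > 1 else 0.0,
        null_max=int(np.max(sizes)),
    )


def _lcc_size(net: nx.Graph, node_set) -> int:
    sub = net.subgraph(node_set)
    if sub.number_of_nodes() == 0:
        return 0
    return max(len(c) for c in nx.connected_components(sub))


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(min(stats.hypergeom.sf(k - 1, N, K, n), 1.0))


@dataclass
class EnrichmentResult:
    term: str
    k: int          # term members in query
    K: int          # term members in background
    n: int          # query size
    N: int          # background size
    p_hypergeom: float
    p_bh: float | None = None

    def __post_init__(self):
        if self.k > min(self.K, self.n):
            raise ValueError("k cannot exceed min(K, n)")

    @property
    def fold(self) -> float:
        return (self.k / self.n) / (self.K / self.N)


def hypergeom_enrichment(
    query: Iterable[str],
    background: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric term enrichment of ``query`` vs ``background``.

    Terms with no query member (k = 0) are excluded from the output. Results
    are sorted by raw p-value (then term) and carry Benjamini-Hochberg
    adjusted values over the reported terms.
    """
    query = {str(g).upper() for g in query}
    background = {str(g).upper() for g in background}
    if not query <= background:
        missing = sorted(query - background)[:5]
        raise ValueError(f"query is not a subset of background (e.g. {missing})")
    term_bg: dict[str, int] = {}
    term_q: dict[str, int] = {}
    for gene in background:
        for term in annotation.get(gene, ()):  # genes without annotation allowed
            term_bg[term] = term_bg.get(term, 0) + 1
            if gene in query:
                term_q[term] = term_q.get(term, 0) + 1
    N, n = len(background), len(query)
    results = []
    for term, k in term_q.items():
        K = term_bg[term]
        results.append(EnrichmentResult(term, k, K, n, N, hypergeom_upper_tail(k, N, K, n)))
    results.sort(key=lambda r: (r.p_hypergeom, r.term))
    if results:
        _, p_bh, _, _ = multipletests([r.p_hypergeom for r in results], method="fdr_bh")
        for r, adj in zip(results, p_bh):
            r.p_bh = float(adj)
    return results
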