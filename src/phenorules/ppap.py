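"""PPAP ego-modules, pathway-like conversion, and gene ranking.

A PPAP (phenotype-phenotype association pair set) is the ego-module of a
query phenotype in the directed rule graph: the query, its direct in/out
neighbors, and every atlas rule among those nodes (neighbor-neighbor
edges carry the indirectly related phenotypes).  Converting a PPAP to a
pathway-like configuration keeps, for every outgoing neighbor, the
longest simple path from the query to it (and symmetrically from every
incoming neighbor to the query), then unions the kept paths' edges.  The
union of all convertible PPAPs' pathways is the phenome-wide pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .calls import CallMatrix, ABNORMAL
from .mining import fisher_two_tailed_p, compute_qvalues
from .selection import SignificantRuleSet

MAX_PATHS_DEFAULT = 100_000

EDGE_ATTRS = (
    "support",
    "confidence_fwd",
    "confidence_rev",
    "lift",
    "polarity",
    "significance_p",
    "q",
    "n11",
)


class TooComplexError(RuntimeError):
    """Simple-path enumeration exceeded the configured cap."""


@dataclass
class PPAP:
    """Ego-module of a query phenotype: nodes, rules, derived statistics."""

    query: str
    graph: nx.DiGraph
    stats: dict = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def related(self) -> set[str]:
        return self.nodes - {self.query}


@dataclass
class PathwayGraph:
    """Union of longest-path conversions; provenance tracks contributing PPAPs."""

    graph: nx.DiGraph
    queries: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class DegreeDeviation:
    """In/out-degree imbalance of a query phenotype in the rule graph."""

    query: str
    indegree: int
    outdegree: int
    p: float
    score: float  # sign * (-log10 p); negative when outdegree > indegree
    q: float = float("nan")
    cls: str = "neutral"  # rare | common | neutral


def build_rule_graph(atlas: SignificantRuleSet) -> nx.DiGraph:
    """Directed graph: one node per phenotype in a rule, one edge per rule."""
    g = nx.DiGraph()
    for r in atlas.rules.itertuples():
        attrs = {a: getattr(r, a) for a in EDGE_ATTRS if hasattr(r, a)}
        g.add_edge(r.lhs, r.rhs, **attrs)
    return g


def extract_ppap(
    graph: nx.DiGraph,
    query: str,
    systems_of: dict[str, tuple[str, ...]] | None = None,
) -> PPAP:
    """Closed one-hop neighborhood of the query plus all induced edges."""
    if query not in graph:
        raise KeyError(f"phenotype not in rule graph: {query}")
    nodes = {query} | set(graph.successors(query)) | set(graph.predecessors(query))
    sub = graph.subgraph(nodes).copy()
    stats = {
        "n_phenotypes": len(nodes) - 1,  # excludes the query
        "indegree": sub.in_degree(query),
        "outdegree": sub.out_degree(query),
        "n_edges": sub.number_of_edges(),
    }
    if systems_of is not None:
        related = nodes - {query}
        rel_systems = {s for ph in related for s in systems_of.get(ph, ())}
        q_systems = set(systems_of.get(query, ()))
        stats["n_distinct_biological_systems"] = len(rel_systems)
        stats["n_same_system_as_query"] = sum(
            1 for ph in related if q_systems & set(systems_of.get(ph, ()))
        )
    return PPAP(query=query, graph=sub, stats=stats)


def all_ppaps(
    graph: nx.DiGraph, systems_of: dict[str, tuple[str, ...]] | None = None
) -> dict[str, PPAP]:
    """One PPAP per rule-graph phenotype (count = number of atlas phenotypes)."""
    return {q: extract_ppap(graph, q, systems_of) for q in graph.nodes}


# ---------------------------------------------------------------------------
# Degree deviation
# ---------------------------------------------------------------------------

def degree_deviation(graph: nx.DiGraph, query: str) -> DegreeDeviation:
    """Two-tailed Fisher test of indegree/degree vs outdegree/degree.

    The 2x2 is [[indegree, outdegree], [outdegree, indegree]]; the score
    is negative when outdegree exceeds indegree (relatively rare
    phenotype), non-negative otherwise.
    """
    ind = graph.in_degree(query)
    out = graph.out_degree(query)
    if ind + out == 0:
        raise ValueError(f"query has zero degree: {query}")
    p = fisher_two_tailed_p(ind, out, out, ind)
    sign = -1.0 if out > ind else 1.0
    return DegreeDeviation(query=query, indegree=ind, outdegree=out, p=p, score=sign * -np.log10(p))


def degree_deviation_table(graph: nx.DiGraph, fdr: float = 0.05) -> pd.DataFrame:
    """Degree deviation for every query, with q-values and rare/common classes."""
    recs = [degree_deviation(graph, q) for q in sorted(graph.nodes)]
    qvals = compute_qvalues([r.p for r in recs])
    rows = []
    for r, qv in zip(recs, qvals):
        if qv < fdr:
            cls = "rare" if r.score < 0 else "common"
        else:
            cls = "neutral"
        rows.append(
            {
                "query": r.query,
                "indegree": r.indegree,
                "outdegree": r.outdegree,
                "p": r.p,
                "score": r.score,
                "q": qv,
                "class": cls,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pathway conversion
# ---------------------------------------------------------------------------

def _longest_simple_path(
    graph: nx.DiGraph, source: str, target: str, max_paths: int
) -> list[str] | None:
    """Longest simple path source -> target; lexicographically smallest
    node sequence on ties.  Raises TooComplexError past ``max_paths``."""
    best: list[str] | None = None
    count = 0
    for path in nx.all_simple_paths(graph, source, target):
        count += 1
        if count > max_paths:
            raise TooComplexError(
                f"more than {max_paths} simple paths from {source} to {target}"
            )
        if best is None or len(path) > len(best) or (len(path) == len(best) and path < best):
            best = list(path)
    return best


def convert_to_pathway(ppap: PPAP, max_paths: int = MAX_PATHS_DEFAULT) -> PathwayGraph:
    """Union of longest simple paths query->outgoing and incoming->query.

    Shortcut edges absorbed by a longer route disappear; every kept edge
    is a PPAP (hence atlas) edge.
    """
    g = ppap.graph
    q = ppap.query
    out_edges: set[tuple[str, str]] = set()
    # every phenotype reachable from the query is an outgoing phenotype of
    # the module (in an ego-module all of them are direct neighbors, but a
    # converted pathway may reach them only through longer routes; targeting
    # the reachable set makes conversion idempotent)
    for o in sorted(nx.descendants(g, q)):
        path = _longest_simple_path(g, q, o, max_paths)
        if path:
            out_edges.update(zip(path[:-1], path[1:]))
    for i in sorted(nx.ancestors(g, q)):
        path = _longest_simple_path(g, i, q, max_paths)
        if path:
            out_edges.update(zip(path[:-1], path[1:]))
    pg = nx.DiGraph()
    pg.add_node(q)
    for u, v in sorted(out_edges):
        pg.add_edge(u, v, **g.edges[u, v])
    return PathwayGraph(graph=pg, queries=[q])


def build_phenome_pathway(pathways: list[PathwayGraph]) -> PathwayGraph:
    """Edge union of sub-pathways; per-edge provenance lists contributing PPAPs."""
    g = nx.DiGraph()
    queries: list[str] = []
    for pw in pathways:
        queries.extend(pw.queries)
        for u, v, attrs in pw.graph.edges(data=True):
            if g.has_edge(u, v):
                g.edges[u, v]["ppaps"] = sorted(set(g.edges[u, v]["ppaps"]) | set(pw.queries))
            else:
                g.add_edge(u, v, **attrs, ppaps=list(pw.queries))
        g.add_nodes_from(pw.graph.nodes)
    return PathwayGraph(graph=g, queries=sorted(set(queries)))


def longest_path_oracle(
    edges: list[tuple[str, str]], source: str, target: str
) -> list[str] | None:
    """Brute-force longest-simple-path by depth-first enumeration.

    Independent test oracle for small graphs (<= 12 nodes): recursive DFS
    over the raw edge list, no graph library involved.  Ties break to the
    lexicographically smallest node sequence.
    """
    adj: dict[str, list[str]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
    for vs in adj.values():
        vs.sort()
    best: list[list[str]] = []

    def dfs(node: str, path: list[str]) -> None:
        if node == target:
            if not best or len(path) > len(best[0]) or (
                len(path) == len(best[0]) and path < best[0]
            ):
                best[:] = [list(path)]
            return
        for nxt in adj.get(node, ()):
            if nxt not in path:
                path.append(nxt)
                dfs(nxt, path)
                path.pop()

    if source != target:
        dfs(source, [source])
    return best[0] if best else None


# ---------------------------------------------------------------------------
# Gene ranking
# ---------------------------------------------------------------------------

def rank_genes(ppap: PPAP, calls: CallMatrix) -> pd.DataFrame:
    """Rank strains abnormal for the query by PPAP-phenotype overlap.

    Eligible strains are abnormal for the query phenotype; each is scored
    by the number (and proportion) of PPAP-constituting phenotypes
    (query included) abnormal in that strain.  Descending by count, ties
    by gene symbol.
    """
    phenos = [p for p in ppap.nodes if p in calls.df.index]
    if ppap.query not in calls.df.index:
        raise KeyError(f"call matrix lacks query phenotype {ppap.query}")
    sub = calls.df.loc[phenos]
    ab = sub.to_numpy() == ABNORMAL
    eligible = calls.df.loc[ppap.query].to_numpy() == ABNORMAL
    counts = ab.sum(axis=0)
    strains = np.asarray(calls.strains)
    out = pd.DataFrame(
        {
            "strain_id": strains[eligible],
            "n_overlap": counts[eligible].astype(int),
            "proportion": counts[eligible] / len(phenos),
        }
    )
    return out.sort_values(
        ["n_overlap", "strain_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
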