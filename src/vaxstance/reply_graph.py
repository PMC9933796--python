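"""Reply network construction, pruning and per-user network statistics.

The reply network is directed at the event level (who replied to whom, with
multiplicity) but the analysis graph is its undirected simple projection: an
edge joins users u and v whenever either replied to the other, counted once.
Low-activity users (fewer than three distinct neighbors by default) are
pruned in a single pass before any embedding or centrality computation.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ReplyGraph:
    """Directed reply multigraph (as weighted digraph) + undirected projection."""

    directed: nx.DiGraph = field(default_factory=nx.DiGraph)
    undirected: nx.Graph = field(default_factory=nx.Graph)
    n_dropped_rows: int = 0
    n_dropped_self: int = 0

    @property
    def nodes(self) -> set:
        return set(self.undirected.nodes())

    @property
    def n_nodes(self) -> int:
        return self.undirected.number_of_nodes()

    @property
    def n_simple_edges(self) -> int:
        return self.undirected.number_of_edges()

    @property
    def n_directed_multiedges(self) -> int:
        return int(sum(d["weight"] for _, _, d in self.directed.edges(data=True)))


def build_reply_graph(replies) -> ReplyGraph:
    """Build the reply graph from (src_user, dst_user[, timestamp]) rows.

    Accepts a DataFrame with ``src_user``/``dst_user`` columns or any
    iterable of 2+-tuples.  Self-replies are dropped; rows with a missing
    endpoint are counted and skipped (logged, not fatal).
    """
    if isinstance(replies, pd.DataFrame):
        pairs = replies[["src_user", "dst_user"]].itertuples(index=False, name=None)
    else:
        pairs = ((row[0], row[1]) for row in replies)

    counts: Counter = Counter()
    dropped_rows = 0
    dropped_self = 0
    for src, dst in pairs:
        if src is None or dst is None or _is_nan(src) or _is_nan(dst):
            dropped_rows += 1
            continue
        if src == dst:
            dropped_self += 1
            continue
        counts[(src, dst)] += 1
    if dropped_rows:
        logger.warning("dropped %d malformed reply rows", dropped_rows)

    directed = nx.DiGraph()
    undirected = nx.Graph()
    for (src, dst), w in counts.items():
        directed.add_edge(src, dst, weight=w)
        undirected.add_edge(src, dst)
    return ReplyGraph(directed, undirected, dropped_rows, dropped_self)


def _is_nan(x) -> bool:
    return isinstance(x, float) and math.isnan(x)


def prune_min_degree(
    graph: ReplyGraph, min_connections: int = 3, iterative: bool = False
) -> ReplyGraph:
    """Remove users with fewer than ``min_connections`` distinct neighbors.

    Single pass by default: degrees are evaluated once on the input graph and
    every node below the threshold is removed with its incident edges;
    survivors are *not* re-checked, so the result can contain nodes whose
    residual degree is below the threshold (including isolated ones).
    ``iterative=True`` instead peels to the ``min_connections``-core.
    """
    if min_connections < 0:
        raise ValueError("min_connections must be >= 0")
    und = graph.undirected
    if iterative:
        keep = set(nx.k_core(und, k=min_connections).nodes()) if und.number_of_nodes() else set()
    else:
        keep = {n for n in und.nodes() if und.degree(n) >= min_connections}
    new_und = und.subgraph(keep).copy()
    new_dir = graph.directed.subgraph(keep).copy()
    return ReplyGraph(new_dir, new_und, graph.n_dropped_rows, graph.n_dropped_self)


def compute_node_stats(graph: ReplyGraph, profiles: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-node statistics table.

    indegree/outdegree count replies with multiplicity on the directed view;
    core number and PageRank (damping 0.85, tolerance 1e-10) are computed on
    the undirected simple graph.  Profile counts are joined by user id, 0
    when missing.
    """
    nodes = sorted(graph.undirected.nodes())
    stats = pd.DataFrame(index=pd.Index(nodes, name="user_id"))
    if not nodes:
        for col in ("followers", "friends", "posts", "likes", "indegree",
                    "outdegree", "core_number", "pagerank"):
            stats[col] = pd.Series(dtype=float)
        return stats

    indeg = dict(graph.directed.in_degree(weight="weight"))
    outdeg = dict(graph.directed.out_degree(weight="weight"))
    core = nx.core_number(graph.undirected)
    pr = nx.pagerank(graph.undirected, alpha=0.85, tol=1e-10, max_iter=1000)

    if profiles is not None:
        prof = profiles.set_index("user_id") if "user_id" in profiles.columns else profiles
    else:
        prof = pd.DataFrame()
    for col in ("followers", "friends", "posts", "likes"):
        if col in prof.columns:
            stats[col] = prof[col].reindex(stats.index).fillna(0).astype(np.int64)
        else:
            stats[col] = 0
    stats["indegree"] = [indeg.get(n, 0) for n in nodes]
    stats["outdegree"] = [outdeg.get(n, 0) for n in nodes]
    stats["core_number"] = [core[n] for n in nodes]
    stats["pagerank"] = [pr[n] for n in nodes]
    return stats


@dataclass(frozen=True)
class GraphSummary:
    n_nodes: int
    n_simple_edges: int
    degree_hist: dict


def graph_summary(graph: ReplyGraph) -> GraphSummary:
    """Node count, simple-edge count and undirected degree histogram."""
    degrees = [d for _, d in graph.undirected.degree()]
    return GraphSummary(
        n_nodes=graph.n_nodes,
        n_simple_edges=graph.n_simple_edges,
        degree_hist=dict(sorted(Counter(degrees).items())),
    )


def log_binned_degree_table(summary: GraphSummary, base: float = 2.0) -> pd.DataFrame:
    """Log-binned view of a degree histogram (bin edges are powers of ``base``)."""
    rows = []
    if summary.degree_hist:
        max_deg = max(summary.degree_hist)
        lo = 1
        while lo <= max(max_deg, 1):
            hi = int(lo * base)
            count = sum(c for d, c in summary.degree_hist.items() if lo <= d < hi)
            rows.append({"degree_lo": lo, "degree_hi": hi, "count": count})
            lo = hi
        zero = summary.degree_hist.get(0, 0)
        if zero:
            rows.insert(0, {"degree_lo": 0, "degree_hi": 1, "count": zero})
    return pd.DataFrame(rows, columns=["degree_lo", "degree_hi", "count"])
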