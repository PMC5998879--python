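"""Bi-partite betweenness centrality (BpBC) and key-factor ranking.

BpBC scores a node v by

    g(v) = sum over unordered pairs (s, t), s in the source group,
           t in the target group, of  delta_st(v) / delta_st

where delta_st is the number of unweighted shortest s-t paths and
delta_st(v) those passing through v as a strictly interior vertex. It
measures how much of the shortest-path communication between two labeled
sub-networks (e.g. the microbes and the antiviral-response genes) is
mediated by v; nodes at the top of the ranking are candidate key risk
factors.

The implementation is a Brandes-style accumulation with the backward pass
restricted to the target set, one BFS per source node; it matches the
brute-force definition exactly (the test suite enumerates shortest paths in
rational arithmetic on small random graphs).
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass
from itertools import count

import networkx as nx

from .io_model import GROUPS, BpBCRanking, HostMicrobialNetwork

__all__ = ["GroupPair", "bpbc", "rank_key_factors", "DEFAULT_GROUP_PAIRS"]


@dataclass(frozen=True)
class GroupPair:
    """An ordered label pair naming the two sub-networks to bridge."""

    source_group: str
    target_group: str

    def __post_init__(self):
        for g in (self.source_group, self.target_group):
            if g not in GROUPS:
                raise ValueError(f"unknown group label {g!r}")
        if self.source_group == self.target_group:
            raise ValueError(f"source and target group are both "
                             f"{self.source_group!r}")


#: The three canonical pairs: the microbe sub-network against each
#: cancer-associated functional gene group.
DEFAULT_GROUP_PAIRS = (
    GroupPair("microbe", "antiviral_response"),
    GroupPair("microbe", "cell_cycle"),
    GroupPair("microbe", "epithelial_cell_differentiation"),
)


def _shortest_path_dag(g: nx.Graph, s, weight: str | None):
    """Shortest-path counts, predecessors and a distance-ordered node list
    from one source: BFS for hop counts, Dijkstra when edges carry a
    weight attribute."""
    sigma = {s: 1.0}
    preds: dict = {s: []}
    order = []
    if weight is None:
        dist = {s: 0}
        queue = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in g[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    sigma[w] = 0.0
                    preds[w] = []
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        return sigma, preds, order

    dist: dict = {}
    seen = {s: 0.0}
    tie = count()
    heap = [(0.0, next(tie), s)]
    while heap:
        d, _, v = heapq.heappop(heap)
        if v in dist:
            continue
        dist[v] = d
        order.append(v)
        for w, attrs in g[v].items():
            dw = d + attrs[weight]
            if w not in dist and (w not in seen or dw < seen[w] - 1e-12):
                seen[w] = dw
                sigma[w] = sigma[v]
                preds[w] = [v]
                heapq.heappush(heap, (dw, next(tie), w))
            elif w not in dist and abs(dw - seen[w]) <= 1e-12:
                sigma[w] += sigma[v]
                preds[w].append(v)
    return sigma, preds, order


def _single_source_accumulate(g: nx.Graph, s, targets: frozenset,
                              scores: dict, weight: str | None) -> None:
    """Add delta_st(v)/delta_st over t in targets to scores, for one s.

    Standard Brandes machinery: shortest-path counts sigma and predecessor
    lists from s, then a reverse-order dependency pass whose path credit
    is seeded only at target nodes. The source takes no credit; a target
    earns credit only as an interior vertex of a pair ending at a
    different, more distant target.
    """
    sigma, preds, order = _shortest_path_dag(g, s, weight)
    delta = dict.fromkeys(order, 0.0)
    for w in reversed(order):
        coeff = delta[w] + (1.0 if w in targets and w != s else 0.0)
        for v in preds[w]:
            delta[v] += sigma[v] / sigma[w] * coeff
    for v in order:
        # delta[v] is pure pass-through credit: the indicator seeded at a
        # target w is handed to w's predecessors, so endpoints of a pair
        # never take credit for that pair
        if v != s:
            scores[v] += delta[v]


def bpbc(net: HostMicrobialNetwork, pair: GroupPair,
         weighted: bool = False, normalized: bool = False) -> BpBCRanking:
    """Bi-partite betweenness centrality between two annotation groups.

    Every node in the network receives a score (0 for nodes off all
    cross-group shortest paths); unordered (s, t) pairs are counted once,
    and disconnected pairs contribute nothing. The ranking sorts by
    descending score with lexicographic tie-breaks.

    ``weighted=True`` replaces hop counts with 1 - |rho| edge lengths
    (strong correlations are short); ``normalized=True`` divides by the
    number of cross-group pairs. Both are off by default: the printed
    formula is an unweighted raw sum.
    """
    g = net.simple_graph()
    weight = None
    if weighted:
        for u, v, d in g.edges(data=True):
            d["_len"] = 1.0 - abs(d["rho"])
        weight = "_len"
    sources = [n for n, d in g.nodes(data=True) if d["group"] == pair.source_group]
    targets = [n for n, d in g.nodes(data=True) if d["group"] == pair.target_group]
    if not sources:
        raise ValueError(f"empty group: {pair.source_group!r}")
    if not targets:
        raise ValueError(f"empty group: {pair.target_group!r}")
    scores = dict.fromkeys(g.nodes, 0.0)
    target_set = frozenset(targets)
    for s in sources:
        _single_source_accumulate(g, s, target_set, scores, weight)
    if normalized:
        n_pairs = len(sources) * len(targets)
        scores = {v: s / n_pairs for v, s in scores.items()}
    return BpBCRanking(pair.source_group, pair.target_group, scores)


def rank_key_factors(net: HostMicrobialNetwork,
                     pairs=DEFAULT_GROUP_PAIRS, top_n: int = 20) -> dict:
    """Top-n BpBC tables, one per group pair.

    Returns a dict mapping ``"source:target"`` to a DataFrame with columns
    node_id, kind, group, score, rank (rank-ordered, deterministic).
    """
    if not pairs:
        raise ValueError("no group pairs given")
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    tables = {}
    for pair in pairs:
        ranking = bpbc(net, pair)
        frame = ranking.to_frame(net).head(top_n)
        tables[f"{pair.source_group}:{pair.target_group}"] = frame
    return tables
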