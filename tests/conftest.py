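from fractions import Fraction

import networkx as nx
import numpy as np
import pytest

from kfnet.io_model import Edge, HostMicrobialNetwork, NodeAnnotation


def spearman_oracle(x, y):
    """Independent rank-then-Pearson Spearman: average ranks by sorting,
    then the explicit product-moment formula."""
    def avg_ranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / (vx * vy) ** 0.5


def bpbc_bruteforce(g: nx.Graph, sources, targets):
    """Exhaustive shortest-path enumeration in rational arithmetic: for each
    cross-group pair, list every shortest path and count strictly interior
    occurrences of each node."""
    scores = {v: Fraction(0) for v in g}
    for s in sources:
        for t in targets:
            if s == t or not nx.has_path(g, s, t):
                continue
            paths = list(nx.all_shortest_paths(g, s, t))
            for v in g:
                if v in (s, t):
                    continue
                hits = sum(1 for p in paths if v in p[1:-1])
                if hits:
                    scores[v] += Fraction(hits, len(paths))
    return scores


def simple_network(gene_edges=(), microbe_edges=(), genes=(), microbes=()):
    """Small hand-built network helper: genes is a list of (id, regulation,
    group); edges are (u, v, rho, p)."""
    net = HostMicrobialNetwork()
    for gid, reg, grp in genes:
        net.add_node(NodeAnnotation(gid, "gene", reg, grp))
    for mid in microbes:
        net.add_node(NodeAnnotation(mid, "microbe", "none", "microbe"))
    for u, v, rho, p in tuple(gene_edges) + tuple(microbe_edges):
        sign = "positive" if rho > 0 else "negative"
        net.add_edge(Edge(u, v, rho, p, sign, "measured"))
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)
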