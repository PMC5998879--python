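"""Correlation network construction and coherence-based error correction.

Edges are Spearman rank correlations between node profiles (microbial
relative abundances and host gene expression measured on the same samples),
kept when |rho| > 0.4 and p < 0.05 (both strict). Two correction passes
follow:

* false positives — a negative edge between two genes regulated the same
  way, or a positive edge between an up- and a down-regulated gene,
  contradicts the regulation labels and is removed, as are self-loops and
  parallel edges;
* false negatives — a collapsed OTU whose sub-OTUs *all* correlate strongly
  (same sign, same thresholds) with a gene gains an inferred edge to that
  gene even though the collapsed profile itself fell below threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io_model import (AbundanceMatrix, CollapseMap, Edge, ExpressionMatrix,
                       HostMicrobialNetwork, NodeAnnotation)

__all__ = [
    "CorrelationRecord",
    "spearman",
    "correlate_all",
    "build_network",
    "remove_false_positives",
    "add_false_negatives",
    "DEFAULT_RHO_MIN",
    "DEFAULT_P_MAX",
]

DEFAULT_RHO_MIN = 0.4
DEFAULT_P_MAX = 0.05


@dataclass(frozen=True)
class CorrelationRecord:
    """Spearman statistic for one unordered node pair.

    A pair involving a constant profile has no defined rank correlation and
    is represented with ``rho = p_value = nan`` — the "no correlation"
    sentinel, which can never pass the edge thresholds.
    """

    u: str
    v: str
    rho: float
    p_value: float

    def __post_init__(self):
        if self.u == self.v:
            raise ValueError(f"self-pair {self.u!r}")

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rho)

    def key(self) -> tuple[str, str]:
        return (self.u, self.v) if self.u <= self.v else (self.v, self.u)


def _p_from_rho(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value via the t approximation with n-2 df."""
    rho = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / ((1.0 - rho) * (1.0 + rho)))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    # |rho| == 1 -> infinite t -> p = 0
    p = np.where(np.isinf(t), 0.0, p)
    return np.where(np.isnan(rho), np.nan, p)


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray) -> float:
    """Two-sided exact permutation p-value on centered rank vectors."""
    import itertools

    obs = abs(float(rx @ ry))
    hits = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        hits += abs(float(rx @ np.asarray(perm))) >= obs - 1e-12
    return hits / total


def spearman(x: Sequence[float], y: Sequence[float],
             p_method: str = "t_approx") -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of average-ranked values (average-tie
    method). With ``p_method="t_approx"`` (default) p uses the
    large-sample t statistic with n-2 degrees of freedom, standard at the
    study's sample size; ``"permutation"`` enumerates all n! rank
    permutations exactly and is offered for very small n (< 10). A
    constant input has zero rank variance: (nan, nan) is returned and no
    edge can be formed from it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("spearman requires two equal-length 1-d vectors")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if p_method not in ("t_approx", "permutation"):
        raise ValueError(f"unknown p_method {p_method!r}")
    if p_method == "permutation" and n >= 10:
        raise ValueError("exact permutation p-values are limited to n < 10; "
                         "use p_method='t_approx'")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))
    rho = max(-1.0, min(1.0, rho))
    if p_method == "permutation":
        return rho, _exact_permutation_p(rx, ry)
    return rho, float(_p_from_rho(rho, n))


def correlate_all(microbes: AbundanceMatrix,
                  genes: ExpressionMatrix,
                  p_method: str = "t_approx") -> list[CorrelationRecord]:
    """Spearman statistics for every unordered pair over the union of
    microbe and gene nodes (microbe-microbe, microbe-gene and gene-gene).

    Columns are aligned by sample id before ranking, so column order in the
    input files is irrelevant. Pairs with a constant profile yield the nan
    sentinel record.
    """
    su, sv = set(microbes.sample_ids), set(genes.sample_ids)
    if su != sv:
        raise ValueError(
            "sample id mismatch between matrices; symmetric difference: "
            f"{sorted(su ^ sv)}")
    overlap = set(microbes.otu_ids) & set(genes.gene_ids)
    if overlap:
        raise ValueError(f"node ids shared by both matrices: {sorted(overlap)}")
    order = microbes.sample_ids
    g = genes.reorder_samples(order)
    node_ids = list(microbes.otu_ids) + list(g.gene_ids)
    data = np.vstack([microbes.values, g.values])
    n = len(order)
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    if p_method == "permutation":
        profiles = {nid: data[i] for i, nid in enumerate(node_ids)}
        return [CorrelationRecord(u, v, *spearman(profiles[u], profiles[v],
                                                  "permutation"))
                for i, u in enumerate(node_ids)
                for v in node_ids[i + 1:]]
    if p_method != "t_approx":
        raise ValueError(f"unknown p_method {p_method!r}")

    constant = np.ptp(data, axis=1) == 0
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks * ranks).sum(axis=1))
    norms[constant] = 1.0  # avoid 0/0; overwritten with nan below
    rho = (ranks @ ranks.T) / np.outer(norms, norms)
    np.clip(rho, -1.0, 1.0, out=rho)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    p = _p_from_rho(rho, n)

    records = []
    m = len(node_ids)
    for i in range(m):
        for j in range(i + 1, m):
            records.append(CorrelationRecord(node_ids[i], node_ids[j],
                                             float(rho[i, j]), float(p[i, j])))
    return records


def _passes(rho: float, p: float, rho_min: float, p_max: float) -> bool:
    return (not math.isnan(rho)) and abs(rho) > rho_min and p < p_max


def build_network(records: Iterable[CorrelationRecord],
                  annotations: Iterable[NodeAnnotation],
                  rho_min: float = DEFAULT_RHO_MIN,
                  p_max: float = DEFAULT_P_MAX) -> HostMicrobialNetwork:
    """Threshold correlation records into a network.

    An edge is created iff |rho| > rho_min and p < p_max (strict, so a
    record at exactly rho = 0.4 or p = 0.05 makes no edge). Every record
    endpoint must be annotated; endpoints that form no edge remain in the
    node set as isolated nodes.
    """
    ann_by_id = {a.node_id: a for a in annotations}
    net = HostMicrobialNetwork()
    for rec in records:
        for end in (rec.u, rec.v):
            if end not in ann_by_id:
                raise ValueError(f"unannotated node id {end!r}")
            if end not in net.g:
                net.add_node(ann_by_id[end])
        if _passes(rec.rho, rec.p_value, rho_min, p_max):
            sign = "positive" if rec.rho > 0 else "negative"
            net.add_edge(Edge(rec.u, rec.v, rec.rho, rec.p_value, sign,
                              "measured"))
    return net


@dataclass(frozen=True)
class RemovalLogEntry:
    u: str
    v: str
    rho: float
    rule: str  # incoherent_negative | incoherent_positive | self_loop | parallel


def remove_false_positives(net: HostMicrobialNetwork
                           ) -> tuple[HostMicrobialNetwork, list[RemovalLogEntry]]:
    """Remove the four false-positive edge scenes; returns (network, log).

    1. negative edges joining two genes with the same regulation label;
    2. positive edges joining an up- and a down-regulated gene;
    3. self-loops;
    4. parallel edges (the copy with largest |rho|, then smallest p, survives).

    Edges with an unlabeled endpoint (any microbe-involved edge) are exempt
    from the coherence rules 1-2. Idempotent.
    """
    out = HostMicrobialNetwork()
    for ann in net.annotations():
        out.add_node(ann)
    log: list[RemovalLogEntry] = []

    best: dict[frozenset, Edge] = {}
    for e in net.edges():
        if e.u == e.v:
            log.append(RemovalLogEntry(e.u, e.v, e.rho, "self_loop"))
            continue
        key = frozenset((e.u, e.v))
        prev = best.get(key)
        if prev is None:
            best[key] = e
        else:
            keep, drop = sorted((prev, e),
                                key=lambda d: (-abs(d.rho), d.p_value))[:2]
            best[key] = keep
            log.append(RemovalLogEntry(drop.u, drop.v, drop.rho, "parallel"))

    for e in best.values():
        ru = net.annotation(e.u).regulation
        rv = net.annotation(e.v).regulation
        if ru in ("up", "down") and rv in ("up", "down"):
            if e.sign == "negative" and ru == rv:
                log.append(RemovalLogEntry(e.u, e.v, e.rho, "incoherent_negative"))
                continue
            if e.sign == "positive" and ru != rv:
                log.append(RemovalLogEntry(e.u, e.v, e.rho, "incoherent_positive"))
                continue
        out.add_edge(e)
    out.validate()
    return out, log


def add_false_negatives(net: HostMicrobialNetwork,
                        cmap: CollapseMap,
                        raw_records: Iterable[CorrelationRecord],
                        rho_min: float = DEFAULT_RHO_MIN,
                        p_max: float = DEFAULT_P_MAX,
                        min_subnodes: int = 2) -> HostMicrobialNetwork:
    """Add inferred edges implied by uncollapsed sub-OTU correlations.

    For each (collapsed OTU O, gene g) with no existing edge, where O
    absorbs at least ``min_subnodes`` raw OTUs and every raw (sub-OTU, g)
    record passes |rho| > rho_min, p < p_max with a common sign, an edge is
    added with rho = mean of the sub-node rhos, p = max of their p-values
    and origin = inferred. Idempotent: a second pass finds every such edge
    already present.

    ``raw_records`` are correlations of the raw (uncollapsed) sub-OTUs
    against the same genes. A missing (sub-OTU, gene) record (the constant-
    profile case) fails the all-sub-nodes condition; a collapse-map member
    absent from the raw record universe entirely is an inconsistency error.
    """
    by_pair: dict[tuple[str, str], CorrelationRecord] = {}
    raw_nodes: set[str] = set()
    for rec in raw_records:
        by_pair[rec.key()] = rec
        raw_nodes.add(rec.u)
        raw_nodes.add(rec.v)

    out = net.copy()
    gene_ids = [a.node_id for a in net.annotations() if a.kind == "gene"]
    for node in net.node_ids:
        members = cmap.members.get(node)
        if members is None or len(members) < min_subnodes:
            continue
        missing = members - raw_nodes
        if missing:
            raise ValueError(
                f"collapse-map members of {node!r} absent from raw "
                f"correlation records: {sorted(missing)}")
        for g in gene_ids:
            if out.has_edge(node, g):
                continue
            recs = [by_pair.get((min(s, g), max(s, g))) for s in sorted(members)]
            if any(r is None or not r.defined for r in recs):
                continue
            if not all(_passes(r.rho, r.p_value, rho_min, p_max) for r in recs):
                continue
            signs = {r.rho > 0 for r in recs}
            if len(signs) != 1:
                continue
            rho = float(np.mean([r.rho for r in recs]))
            p = float(max(r.p_value for r in recs))
            sign = "positive" if rho > 0 else "negative"
            out.add_edge(Edge(node, g, rho, p, sign, "inferred"))
    out.validate()
    return out
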