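"""Seeded generators of co-measured abundance/expression fixtures.

The study design being emulated: 16S amplicon profiles and host gene
expression measured on the same ~58 tumour samples, with a known set of
monotone microbe-gene and gene-gene associations planted, up/down labels on
the genes, functional group labels, and groups of redundant OTUs that share
a best reference hit (so the collapse stage has work to do).

Planting uses a Gaussian copula: a latent multivariate normal carries the
pairwise dependence, with the latent Pearson correlation set to
``2 sin(pi * rho_s / 6)`` so that the latent Spearman correlation equals
the requested ``target_rho``. Abundances are obtained by pushing each OTU's
latent normal through a log-normal intensity and drawing multinomial read
counts per sample (depth uniform on [10k, 50k], exercising normalization
under unequal depths); the log-normal map is monotone, so the planted rank
correlations survive up to multinomial counting noise. Expression is the
latent normal plus small independent Gaussian measurement noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io_model import (AbundanceMatrix, BlastHit, Edge, ExpressionMatrix,
                       GENE_GROUPS, HostMicrobialNetwork, NodeAnnotation)

__all__ = ["SyntheticSpec", "generate", "make_fp_fixture",
           "make_bridge_network"]

_DEFAULT_GROUP_PROPORTIONS = {g: 0.25 for g in GENE_GROUPS}


@dataclass
class SyntheticSpec:
    """Declarative description of one synthetic co-measured data set.

    planted_edges entries are (node_u, node_v, target_rho) with node ids of
    the form ``OTU_<i>`` / ``GENE_<i>``; collapse_groups are sets of raw
    OTU ids that should share one reference hit and hence collapse.
    """

    n_otus: int
    n_genes: int
    n_samples: int = 58
    planted_edges: list = field(default_factory=list)
    deg_fraction_up: float = 0.5
    group_proportions: dict = field(default_factory=lambda: dict(_DEFAULT_GROUP_PROPORTIONS))
    collapse_groups: list = field(default_factory=list)
    seed: int = 0
    expression_noise_sd: float = 0.1
    lognormal_sd: float = 1.0
    depth_range: tuple = (10_000, 50_000)

    def otu_ids(self) -> list[str]:
        return [f"OTU_{i + 1}" for i in range(self.n_otus)]

    def gene_ids(self) -> list[str]:
        return [f"GENE_{i + 1}" for i in range(self.n_genes)]

    def __post_init__(self):
        if abs(sum(self.group_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("group_proportions must sum to 1")
        if not (0.0 <= self.deg_fraction_up <= 1.0):
            raise ValueError("deg_fraction_up must be in [0, 1]")
        known = set(self.otu_ids()) | set(self.gene_ids())
        for u, v, r in self.planted_edges:
            if u not in known or v not in known:
                raise ValueError(f"planted edge references unknown node "
                                 f"{u!r} or {v!r}")
            if abs(r) > 1.0:
                raise ValueError(f"|target_rho| > 1 on planted edge {u}-{v}")
        for grp in self.collapse_groups:
            unknown = set(grp) - set(self.otu_ids())
            if unknown:
                raise ValueError(f"collapse group references unknown OTUs "
                                 f"{sorted(unknown)}")


def _latent_correlation(spec: SyntheticSpec, node_index: dict) -> np.ndarray:
    m = len(node_index)
    corr = np.eye(m)
    for u, v, rho_s in spec.planted_edges:
        r = 2.0 * math.sin(math.pi * rho_s / 6.0)  # Spearman -> latent Pearson
        i, j = node_index[u], node_index[v]
        corr[i, j] = corr[j, i] = r
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-10:
        raise ValueError(
            f"planted correlation structure is not positive semidefinite "
            f"(min eigenvalue {eig.min():.3g})")
    return corr


def _coherent_labels(spec: SyntheticSpec, rng: np.random.Generator) -> dict:
    """Up/down labels such that planted gene-gene pairs are sign-coherent:
    positive target_rho -> same label, negative -> opposite labels.
    Constraint propagation by 2-coloring; an odd cycle of constraints is an
    unsatisfiable spec and raises."""
    genes = spec.gene_ids()
    gene_set = set(genes)
    adj: dict[str, list] = {g: [] for g in genes}
    for u, v, r in spec.planted_edges:
        if u in gene_set and v in gene_set and r != 0:
            same = r > 0
            adj[u].append((v, same))
            adj[v].append((u, same))
    labels: dict[str, str] = {}
    for g in genes:
        if g in labels:
            continue
        labels[g] = "up" if rng.random() < spec.deg_fraction_up else "down"
        stack = [g]
        while stack:
            a = stack.pop()
            for b, same in adj[a]:
                want = labels[a] if same else ("down" if labels[a] == "up" else "up")
                if b in labels:
                    if labels[b] != want:
                        raise ValueError(
                            "planted gene-gene signs admit no coherent "
                            f"up/down labeling (conflict at {b})")
                else:
                    labels[b] = want
                    stack.append(b)
    return labels


def generate(spec: SyntheticSpec):
    """Draw one data set; same seed gives bit-identical outputs.

    Returns (AbundanceMatrix of raw counts, ExpressionMatrix, annotations,
    BlastHit list, ground-truth planted edge list [(u, v, target_rho), ...]).
    """
    rng = np.random.default_rng(spec.seed)
    otus, genes = spec.otu_ids(), spec.gene_ids()
    nodes = otus + genes
    node_index = {n: i for i, n in enumerate(nodes)}
    corr = _latent_correlation(spec, node_index)

    # latent normals with the planted rank dependence
    jitter = 1e-10 * np.eye(len(nodes))
    chol = np.linalg.cholesky(corr + jitter)
    z = rng.standard_normal((spec.n_samples, len(nodes))) @ chol.T  # samples x nodes

    samples = [f"S{j + 1}" for j in range(spec.n_samples)]

    # abundance: per-OTU log-normal intensity -> per-sample multinomial draw
    base_log_mean = rng.normal(0.0, 1.0, size=spec.n_otus)
    z_otu = z[:, : spec.n_otus]
    intensity = np.exp(base_log_mean + spec.lognormal_sd * z_otu)  # samples x otus
    probs = intensity / intensity.sum(axis=1, keepdims=True)
    lo, hi = spec.depth_range
    depths = rng.integers(lo, hi + 1, size=spec.n_samples)
    counts = np.empty((spec.n_otus, spec.n_samples))
    for j in range(spec.n_samples):
        counts[:, j] = rng.multinomial(depths[j], probs[j])
    abundance = AbundanceMatrix(otus, samples, counts, is_normalized=False)

    # expression: latent + small independent measurement noise
    z_gene = z[:, spec.n_otus:]
    expr = z_gene + spec.expression_noise_sd * rng.standard_normal(z_gene.shape)
    expression = ExpressionMatrix(genes, samples, expr.T)

    # annotations: coherent up/down labels, functional groups by proportion
    labels = _coherent_labels(spec, rng)
    group_names = sorted(spec.group_proportions)
    group_p = np.array([spec.group_proportions[g] for g in group_names])
    gene_groups = rng.choice(group_names, size=spec.n_genes, p=group_p)
    annotations = [NodeAnnotation(o, "microbe", "none", "microbe") for o in otus]
    annotations += [NodeAnnotation(g, "gene", labels[g], grp)
                    for g, grp in zip(genes, gene_groups)]

    # BLAST hits: each collapse group shares one strong reference hit;
    # every other OTU gets a decoy hit failing the filter thresholds
    grouped = set()
    hits = []
    for i, grp in enumerate(spec.collapse_groups):
        ref = f"HMP_ref_{i + 1}"
        for otu in sorted(grp):
            hits.append(BlastHit(otu, ref, 99.0, 1e-20))
            grouped.add(otu)
    for otu in otus:
        if otu not in grouped:
            hits.append(BlastHit(otu, "HMP_decoy", 60.0, 1e-3))

    truth = [(u, v, r) for u, v, r in spec.planted_edges]
    return abundance, expression, annotations, hits, truth


# ---------------------------------------------------------------------------
# hand-built fixtures
# ---------------------------------------------------------------------------

def make_fp_fixture():
    """Network with exactly one instance of each false-positive scene.

    Scenes: (1) a negative edge between two up-regulated genes, (2) a
    positive edge between an up- and a down-regulated gene, (3) a
    self-loop, (4) a parallel edge pair; plus three coherent edges that
    must survive. Returns (raw network, expected corrected network).
    """
    anns = [
        NodeAnnotation("GA", "gene", "up", "cell_cycle"),
        NodeAnnotation("GB", "gene", "up", "cell_cycle"),
        NodeAnnotation("GC", "gene", "down", "antiviral_response"),
        NodeAnnotation("GD", "gene", "down", "other"),
        NodeAnnotation("M1", "microbe", "none", "microbe"),
    ]
    raw = HostMicrobialNetwork()
    expected = HostMicrobialNetwork()
    for a in anns:
        raw.add_node(a)
        expected.add_node(a)

    coherent = [
        Edge("GB", "GC", -0.55, 0.002, "negative", "measured"),  # up/down, neg
        Edge("GC", "GD", 0.62, 0.001, "positive", "measured"),   # down/down, pos
        Edge("M1", "GC", -0.48, 0.010, "negative", "measured"),  # microbe edge
    ]
    survivor = Edge("M1", "GA", 0.60, 0.001, "positive", "measured")
    for e in coherent + [survivor]:
        raw.add_edge(e)
        expected.add_edge(e)

    raw.add_edge(Edge("GA", "GB", -0.50, 0.010, "negative", "measured"))  # scene 1
    raw.add_edge(Edge("GA", "GC", 0.45, 0.020, "positive", "measured"))   # scene 2
    raw.add_edge(Edge("GA", "GA", 0.90, 0.001, "positive", "measured"))   # scene 3
    raw.add_edge(Edge("M1", "GA", 0.41, 0.040, "positive", "measured"))   # scene 4
    return raw, expected


def make_bridge_network(seed: int = 0, n_microbes: int = 6, n_genes: int = 6,
                        target_group: str = "antiviral_response"):
    """Random network in which one microbe is the unique cut vertex between
    the microbe sub-network and a gene group.

    The microbe side and the gene side are each a random connected graph;
    the only edges between the sides leave one bridge microbe (attached to
    two genes, so no single gene matches its score), hence every
    cross-group shortest path runs through the bridge. Returns
    (network, bridge node id).
    """
    rng = np.random.default_rng(seed)
    net = HostMicrobialNetwork()
    microbes = [f"OTU_{i + 1}" for i in range(n_microbes)]
    genes = [f"GENE_{i + 1}" for i in range(n_genes)]
    for m in microbes:
        net.add_node(NodeAnnotation(m, "microbe", "none", "microbe"))
    for g in genes:
        net.add_node(NodeAnnotation(g, "gene", "up", target_group))

    def random_connected(ids):
        edges = set()
        for i, a in enumerate(ids[1:], start=1):  # random spanning tree
            b = ids[rng.integers(0, i)]
            edges.add(frozenset((a, b)))
        for a in ids:  # extra density
            for b in ids:
                if a < b and rng.random() < 0.3:
                    edges.add(frozenset((a, b)))
        return edges

    bridge = microbes[0]
    for e in random_connected(microbes) | random_connected(genes):
        u, v = sorted(e)
        rho = float(rng.uniform(0.45, 0.9))
        net.add_edge(Edge(u, v, rho, 0.001, "positive", "measured"))
    for hub in genes[:2]:
        net.add_edge(Edge(bridge, hub, 0.8, 0.001, "positive", "measured"))
    return net, bridge
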