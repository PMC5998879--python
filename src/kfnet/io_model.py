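"""Domain types and readers/writers for host-microbial network analysis.

The in-memory containers here are deliberately small: a feature-by-sample
matrix for microbial abundances and host expression, per-node annotations
(node kind, up/down regulation, functional group), BLAST tabular hits used
to collapse redundant OTUs against a reference set, and an undirected
network whose edges carry the Spearman statistic that created them.

All on-disk formats are plain text: tab-separated, UTF-8, ``#``-prefixed
comment lines ignored. Networks export to an edge-list TSV (edges only,
endpoints sorted lexicographically) or GraphML (lossless, including
isolated nodes and annotations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "GENE_GROUPS",
    "KINDS",
    "REGULATIONS",
    "AbundanceMatrix",
    "ExpressionMatrix",
    "NodeAnnotation",
    "BlastHit",
    "CollapseMap",
    "Edge",
    "HostMicrobialNetwork",
    "BpBCRanking",
    "read_matrix",
    "read_annotations",
    "read_blast_tab",
    "write_network",
    "read_network",
    "write_ranking",
]

#: Closed vocabulary of functional groups: the four DEG categories plus the
#: microbe pseudo-group. Unknown labels are rejected everywhere.
GENE_GROUPS = (
    "cell_cycle",
    "antiviral_response",
    "epithelial_cell_differentiation",
    "other",
)
GROUPS = GENE_GROUPS + ("microbe",)
KINDS = ("microbe", "gene")
REGULATIONS = ("up", "down", "none")


def _check_ids(ids: list[str], what: str) -> None:
    if not ids:
        raise ValueError(f"no features: empty {what} id list")
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate feature id in {what}: {i!r}")
        seen.add(i)


class _FeatureMatrix:
    """Shared behaviour of the two feature-by-sample matrices."""

    feature_axis_name = "feature"

    def __init__(self, feature_ids: Iterable[str], sample_ids: Iterable[str],
                 values: np.ndarray):
        feature_ids = [str(i) for i in feature_ids]
        sample_ids = [str(s) for s in sample_ids]
        values = np.asarray(values, dtype=float)
        _check_ids(feature_ids, self.feature_axis_name)
        _check_ids(sample_ids, "sample")
        if values.shape != (len(feature_ids), len(sample_ids)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(feature_ids)} features x {len(sample_ids)} samples"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("matrix contains non-finite values")
        self.feature_ids = feature_ids
        self.sample_ids = sample_ids
        self.values = values

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids,
                            columns=self.sample_ids)

    def reorder_samples(self, sample_ids: list[str]):
        """Return a copy with sample columns in the given order."""
        if set(sample_ids) != set(self.sample_ids) or len(sample_ids) != self.n_samples:
            raise ValueError("sample id set mismatch in reorder_samples")
        idx = [self.sample_ids.index(s) for s in sample_ids]
        out = self.__class__.__new__(self.__class__)
        out.__dict__.update(self.__dict__)
        out.sample_ids = list(sample_ids)
        out.values = self.values[:, idx]
        return out

    def __eq__(self, other) -> bool:
        return (type(self) is type(other)
                and self.feature_ids == other.feature_ids
                and self.sample_ids == other.sample_ids
                and np.array_equal(self.values, other.values))


class AbundanceMatrix(_FeatureMatrix):
    """OTU x sample matrix of non-negative counts or per-sample proportions.

    ``is_normalized`` records whether each sample column has been scaled to
    sum to one; downstream steps that require proportions check it.
    """

    feature_axis_name = "OTU"

    def __init__(self, otu_ids, sample_ids, values, is_normalized: bool = False):
        super().__init__(otu_ids, sample_ids, values)
        if np.any(self.values < 0):
            raise ValueError("abundance values must be non-negative")
        if is_normalized:
            # proportions of each sample's library; a row-subset matrix may
            # sum below 1, but never above
            colsums = self.values.sum(axis=0)
            bad = np.nonzero(colsums > 1.0 + 1e-9)[0]
            if bad.size:
                s = self.sample_ids[bad[0]]
                raise ValueError(
                    f"is_normalized set but sample {s!r} sums to {colsums[bad[0]]!r}"
                )
        self.is_normalized = bool(is_normalized)

    @property
    def otu_ids(self) -> list[str]:
        return self.feature_ids

    def __eq__(self, other) -> bool:
        return super().__eq__(other) and self.is_normalized == other.is_normalized


class ExpressionMatrix(_FeatureMatrix):
    """Gene x sample matrix of continuous expression values."""

    feature_axis_name = "gene"

    def __init__(self, gene_ids, sample_ids, values):
        super().__init__(gene_ids, sample_ids, values)

    @property
    def gene_ids(self) -> list[str]:
        return self.feature_ids


@dataclass(frozen=True)
class NodeAnnotation:
    """Kind (microbe/gene), up/down regulation, and functional group of a node.

    Microbes carry no regulation label and always belong to the ``microbe``
    pseudo-group; genes belong to one of the four DEG categories.
    """

    node_id: str
    kind: str
    regulation: str
    group: str

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r} for {self.node_id!r}")
        if self.regulation not in REGULATIONS:
            raise ValueError(
                f"unknown regulation {self.regulation!r} for {self.node_id!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r} for {self.node_id!r}")
        if self.kind == "microbe" and (self.regulation != "none"
                                       or self.group != "microbe"):
            raise ValueError(
                f"microbe {self.node_id!r} must have regulation=none and "
                f"group=microbe")
        if self.kind == "gene" and self.group == "microbe":
            raise ValueError(f"gene {self.node_id!r} cannot have group=microbe")


@dataclass(frozen=True)
class BlastHit:
    """One row of blastn tabular output, reduced to the fields consumed here."""

    query_id: str
    subject_id: str
    pident: float
    evalue: float

    def __post_init__(self):
        if not (0.0 <= self.pident <= 100.0):
            raise ValueError(f"pident {self.pident} outside [0, 100]")
        if self.evalue < 0:
            raise ValueError(f"negative evalue {self.evalue}")


class CollapseMap:
    """Many-to-one assignment of raw OTUs to collapsed OTUs.

    ``member_of`` maps every raw OTU id to its collapsed id; ``members``
    maps each collapsed id to the set of raw ids it absorbs. Raw OTUs
    without a surviving reference hit map to themselves (singleton sets).
    """

    def __init__(self, member_of: Mapping[str, str]):
        self.member_of: dict[str, str] = dict(member_of)
        members: dict[str, set[str]] = {}
        for raw, coll in self.member_of.items():
            members.setdefault(coll, set()).add(raw)
        self.members = members

    @classmethod
    def identity(cls, otu_ids: Iterable[str]) -> "CollapseMap":
        return cls({o: o for o in otu_ids})

    def collapsed_ids_in_order(self, raw_order: Iterable[str]) -> list[str]:
        """Collapsed ids in order of first appearance along ``raw_order``."""
        seen: set[str] = set()
        out: list[str] = []
        for raw in raw_order:
            c = self.member_of[raw]
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    def __eq__(self, other) -> bool:
        return isinstance(other, CollapseMap) and self.member_of == other.member_of


@dataclass(frozen=True)
class Edge:
    """Undirected edge with its Spearman statistic and provenance.

    ``origin`` is ``measured`` for edges passing the correlation thresholds
    directly and ``inferred`` for edges added by the false-negative rule.
    """

    u: str
    v: str
    rho: float
    p_value: float
    sign: str
    origin: str

    def __post_init__(self):
        if self.sign not in ("positive", "negative"):
            raise ValueError(f"bad sign {self.sign!r}")
        if self.origin not in ("measured", "inferred"):
            raise ValueError(f"bad origin {self.origin!r}")
        if not (-1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12):
            raise ValueError(f"rho {self.rho} outside [-1, 1]")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if (self.sign == "positive") != (self.rho > 0):
            raise ValueError(
                f"sign {self.sign} inconsistent with rho={self.rho} "
                f"on edge {self.u}-{self.v}")

    def sorted_endpoints(self) -> tuple[str, str]:
        return (self.u, self.v) if self.u <= self.v else (self.v, self.u)


class HostMicrobialNetwork:
    """Undirected network of microbes and host genes.

    Backed by a :class:`networkx.MultiGraph` so that raw, uncorrected
    networks may transiently contain self-loops and parallel edges (the
    false-positive scenes the error-correction stage removes).
    ``validate()`` asserts the corrected-network contract: simple graph,
    annotated endpoints, sign consistent with rho.
    """

    def __init__(self):
        self.g = nx.MultiGraph()

    # -- construction -----------------------------------------------------
    def add_node(self, ann: NodeAnnotation) -> None:
        self.g.add_node(ann.node_id, kind=ann.kind, regulation=ann.regulation,
                        group=ann.group)

    def add_edge(self, edge: Edge) -> None:
        for end in (edge.u, edge.v):
            if end not in self.g:
                raise KeyError(f"edge endpoint {end!r} is not a known node")
        self.g.add_edge(edge.u, edge.v, rho=edge.rho, p_value=edge.p_value,
                        sign=edge.sign, origin=edge.origin)

    # -- access -----------------------------------------------------------
    @property
    def node_ids(self) -> list[str]:
        return list(self.g.nodes)

    def annotation(self, node_id: str) -> NodeAnnotation:
        d = self.g.nodes[node_id]
        return NodeAnnotation(node_id, d["kind"], d["regulation"], d["group"])

    def annotations(self) -> list[NodeAnnotation]:
        return [self.annotation(n) for n in self.g.nodes]

    def edges(self) -> Iterator[Edge]:
        for u, v, d in self.g.edges(data=True):
            yield Edge(u, v, d["rho"], d["p_value"], d["sign"], d["origin"])

    def has_edge(self, u: str, v: str) -> bool:
        return self.g.has_edge(u, v)

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def copy(self) -> "HostMicrobialNetwork":
        out = HostMicrobialNetwork()
        out.g = self.g.copy()
        return out

    def simple_graph(self) -> nx.Graph:
        """Collapse to a simple nx.Graph (requires a validated network)."""
        self.validate()
        sg = nx.Graph()
        sg.add_nodes_from(self.g.nodes(data=True))
        for u, v, d in self.g.edges(data=True):
            sg.add_edge(u, v, **d)
        return sg

    # -- contracts ----------------------------------------------------------
    def is_simple(self) -> bool:
        if any(u == v for u, v in self.g.edges()):
            return False
        pairs = {frozenset((u, v)) for u, v in self.g.edges()}
        return len(pairs) == self.g.number_of_edges()

    def validate(self) -> None:
        if not self.is_simple():
            raise ValueError("network is not simple (self-loop or parallel edge)")
        for e in self.edges():
            pass  # Edge.__post_init__ re-checks sign/rho consistency

    # -- equality -----------------------------------------------------------
    def _edge_key_set(self) -> set[tuple]:
        out = set()
        for e in self.edges():
            u, v = e.sorted_endpoints()
            out.add((u, v, round(e.rho, 12), round(e.p_value, 12), e.sign,
                     e.origin))
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, HostMicrobialNetwork):
            return NotImplemented
        if set(self.g.nodes) != set(other.g.nodes):
            return False
        for n in self.g.nodes:
            if self.g.nodes[n] != other.g.nodes[n]:
                return False
        return self._edge_key_set() == other._edge_key_set()


@dataclass
class BpBCRanking:
    """Bi-partite betweenness scores for one (source group, target group) pair.

    ``ordering`` sorts node ids by descending score, ties broken
    lexicographically by node id.
    """

    source_group: str
    target_group: str
    scores: dict[str, float]
    ordering: list[str] = field(default_factory=list)

    def __post_init__(self):
        if any(s < -1e-12 for s in self.scores.values()):
            raise ValueError("negative BpBC score")
        if not self.ordering:
            self.ordering = sorted(self.scores, key=lambda n: (-self.scores[n], n))

    def to_frame(self, network: HostMicrobialNetwork | None = None) -> pd.DataFrame:
        rows = []
        for rank, node in enumerate(self.ordering, start=1):
            row = {"node_id": node, "score": self.scores[node], "rank": rank}
            if network is not None:
                ann = network.annotation(node)
                row["kind"] = ann.kind
                row["group"] = ann.group
            rows.append(row)
        cols = ["node_id", "kind", "group", "score", "rank"] if network is not None \
            else ["node_id", "score", "rank"]
        return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_READ_TSV_KW = dict(sep="\t", comment="#", dtype=str, keep_default_na=False,
                    na_values=[])


def read_matrix(path, kind: str):
    """Read a feature x sample TSV (header row of sample ids, first column
    of feature ids) into an :class:`AbundanceMatrix` or
    :class:`ExpressionMatrix`.

    Parsing is strict: duplicate ids and non-numeric cells are errors, and a
    file with no data rows is rejected.
    """
    if kind not in ("abundance", "expression"):
        raise ValueError(f"kind must be 'abundance' or 'expression', got {kind!r}")
    df = pd.read_csv(path, **_READ_TSV_KW)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected feature id column plus sample columns")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no features")
    feature_ids = df.iloc[:, 0].tolist()
    sample_ids = [str(c) for c in df.columns[1:]]
    raw = df.iloc[:, 1:]
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col]):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at feature "
                    f"{feature_ids[i]!r}, sample {col!r}") from None
    try:
        if kind == "abundance":
            return AbundanceMatrix(feature_ids, sample_ids, values)
        return ExpressionMatrix(feature_ids, sample_ids, values)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def read_annotations(path) -> list[NodeAnnotation]:
    """Read a node annotation TSV with columns node_id, kind, regulation, group."""
    df = pd.read_csv(path, **_READ_TSV_KW)
    required = ["node_id", "kind", "regulation", "group"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns {missing}")
    anns = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        if row["node_id"] in seen:
            raise ValueError(f"{path}: duplicate annotation for {row['node_id']!r}")
        seen.add(row["node_id"])
        try:
            anns.append(NodeAnnotation(row["node_id"], row["kind"],
                                       row["regulation"], row["group"]))
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from None
    return anns


def write_annotations(anns: Iterable[NodeAnnotation], path) -> None:
    pd.DataFrame(
        [(a.node_id, a.kind, a.regulation, a.group) for a in anns],
        columns=["node_id", "kind", "regulation", "group"],
    ).to_csv(path, sep="\t", index=False)


def read_blast_tab(path) -> list[BlastHit]:
    """Read blastn -outfmt 6 tabular output (12 unnamed columns); only
    qseqid, sseqid, pident and evalue are consumed."""
    hits = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(parts)}")
            try:
                hits.append(BlastHit(parts[0], parts[1], float(parts[2]),
                                     float(parts[10])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return hits


_EDGE_COLUMNS = ["u", "v", "rho", "p_value", "sign", "origin"]


def write_network(net: HostMicrobialNetwork, path, format: str = "edge_tsv") -> None:
    """Write a network as an edge-list TSV or GraphML.

    The TSV has columns u, v, rho, p_value, sign, origin with endpoints
    sorted lexicographically (u < v) and rows sorted by (u, v), so repeated
    writes of equal networks are byte-identical. GraphML additionally
    carries node annotations and isolated nodes and round-trips losslessly.
    """
    if format == "edge_tsv":
        rows = []
        for e in net.edges():
            u, v = e.sorted_endpoints()
            rows.append((u, v, repr(e.rho), repr(e.p_value), e.sign, e.origin))
        rows.sort()
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(_EDGE_COLUMNS) + "\n")
            for r in rows:
                fh.write("\t".join(r) + "\n")
    elif format == "graphml":
        g = nx.Graph()
        g.add_nodes_from(net.g.nodes(data=True))
        for e in net.edges():
            u, v = e.sorted_endpoints()
            g.add_edge(u, v, rho=e.rho, p_value=e.p_value, sign=e.sign,
                       origin=e.origin)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "edge_tsv",
                 annotations: Iterable[NodeAnnotation] | None = None
                 ) -> HostMicrobialNetwork:
    """Read a network written by :func:`write_network`.

    The edge-list TSV stores edges only, so ``annotations`` must supply the
    node set (including isolated nodes); GraphML is self-contained.
    """
    net = HostMicrobialNetwork()
    if format == "edge_tsv":
        if annotations is None:
            raise ValueError("edge_tsv reader requires node annotations")
        for ann in annotations:
            net.add_node(ann)
        df = pd.read_csv(path, **_READ_TSV_KW)
        if list(df.columns) != _EDGE_COLUMNS:
            raise ValueError(f"{path}: expected columns {_EDGE_COLUMNS}")
        for _, row in df.iterrows():
            net.add_edge(Edge(row["u"], row["v"], float(row["rho"]),
                              float(row["p_value"]), row["sign"], row["origin"]))
    elif format == "graphml":
        g = nx.read_graphml(path)
        for n, d in g.nodes(data=True):
            net.add_node(NodeAnnotation(n, d["kind"], d["regulation"], d["group"]))
        for u, v, d in g.edges(data=True):
            net.add_edge(Edge(u, v, float(d["rho"]), float(d["p_value"]),
                              d["sign"], d["origin"]))
    else:
        raise ValueError(f"unknown network format {format!r}")
    return net


def write_ranking(ranking: BpBCRanking, path,
                  network: HostMicrobialNetwork | None = None) -> None:
    ranking.to_frame(network).to_csv(path, sep="\t", index=False)
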