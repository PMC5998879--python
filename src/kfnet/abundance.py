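"""Abundance-matrix preparation: normalization, OTU collapsing, top-k selection.

The preparation order mirrors the reconstruction workflow: raw OTU counts
are first collapsed against a reference OTU set (queries whose representative
sequences share a best reference hit are merged, summing counts), then
converted to per-sample proportions, then reduced to the k most abundant
OTUs (default 259) by mean relative abundance.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .io_model import AbundanceMatrix, BlastHit, CollapseMap

__all__ = [
    "normalize_counts",
    "filter_blast_hits",
    "build_collapse_map",
    "collapse_matrix",
    "select_top_k",
    "DEFAULT_EVALUE_MAX",
    "DEFAULT_PIDENT_MIN",
    "DEFAULT_TOP_K",
]

DEFAULT_EVALUE_MAX = 1e-5
DEFAULT_PIDENT_MIN = 80.0
DEFAULT_TOP_K = 259


def normalize_counts(m: AbundanceMatrix) -> AbundanceMatrix:
    """Scale each sample column to proportions (divide by its read total).

    A sample with zero total reads carries no compositional information and
    is rejected by name rather than silently dropped.
    """
    colsums = m.values.sum(axis=0)
    zeros = np.nonzero(colsums == 0)[0]
    if zeros.size:
        raise ValueError(f"zero-depth sample: {m.sample_ids[zeros[0]]!r}")
    return AbundanceMatrix(m.otu_ids, m.sample_ids, m.values / colsums,
                           is_normalized=True)


def filter_blast_hits(hits: Iterable[BlastHit],
                      evalue_max: float = DEFAULT_EVALUE_MAX,
                      pident_min: float = DEFAULT_PIDENT_MIN) -> list[BlastHit]:
    """Keep hits with evalue < evalue_max and pident > pident_min.

    Both inequalities are strict; input order is preserved.
    """
    return [h for h in hits if h.evalue < evalue_max and h.pident > pident_min]


def _best_hit(hits: Sequence[BlastHit]) -> BlastHit:
    # lowest evalue, then highest pident, then lexicographic subject id
    return min(hits, key=lambda h: (h.evalue, -h.pident, h.subject_id))


def build_collapse_map(hits: Iterable[BlastHit],
                       otu_ids: Sequence[str]) -> CollapseMap:
    """Assign each query OTU to its best reference hit; queries sharing a
    reference become one collapsed OTU named ``collapsed:<subject_id>``.

    OTUs with no surviving hit map to themselves. ``hits`` is expected to be
    pre-filtered (see :func:`filter_blast_hits`).
    """
    known = set(otu_ids)
    by_query: dict[str, list[BlastHit]] = {}
    for h in hits:
        if h.query_id not in known:
            raise ValueError(f"BLAST query {h.query_id!r} not among OTU ids")
        by_query.setdefault(h.query_id, []).append(h)
    member_of: dict[str, str] = {}
    for otu in otu_ids:
        if otu in by_query:
            member_of[otu] = f"collapsed:{_best_hit(by_query[otu]).subject_id}"
        else:
            member_of[otu] = otu
    return CollapseMap(member_of)


def collapse_matrix(m: AbundanceMatrix, cmap: CollapseMap) -> AbundanceMatrix:
    """Sum the count rows of co-mapped OTUs.

    Rows are emitted in first-appearance order of their collapsed id, and
    per-sample totals are conserved exactly (pure row additions).
    """
    unknown = set(m.otu_ids) - set(cmap.member_of)
    if unknown:
        raise ValueError(f"collapse map missing OTUs: {sorted(unknown)}")
    order = cmap.collapsed_ids_in_order(m.otu_ids)
    index = {c: i for i, c in enumerate(order)}
    out = np.zeros((len(order), m.n_samples), dtype=m.values.dtype)
    for row, otu in enumerate(m.otu_ids):
        out[index[cmap.member_of[otu]]] += m.values[row]
    return AbundanceMatrix(order, m.sample_ids, out,
                           is_normalized=m.is_normalized)


def select_top_k(m: AbundanceMatrix, k: int = DEFAULT_TOP_K) -> AbundanceMatrix:
    """Keep the k OTUs with highest mean relative abundance.

    Requires a normalized matrix so that "abundant" is comparable across
    samples of unequal depth. Ties break lexicographically by OTU id; the
    output rows are sorted by rank, making the result invariant to the
    input row order. k >= #OTUs returns all rows (still rank-sorted).
    """
    if not m.is_normalized:
        raise ValueError("select_top_k requires a normalized matrix")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    means = m.values.mean(axis=1)
    ranked = sorted(range(m.n_features), key=lambda i: (-means[i], m.otu_ids[i]))
    keep = ranked[:k]
    return AbundanceMatrix([m.otu_ids[i] for i in keep], m.sample_ids,
                           m.values[keep], is_normalized=True)
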