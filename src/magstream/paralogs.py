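"""Within-genome gene-duplication detection.

The procedure mirrors the standard minbit + Markov-clustering route for
paralog calling: every protein of a genome is compared against every other,
each cross bitscore is normalized by the smaller of the two self-alignment
bitscores,

    minbit(A, B) = bitscore(A, B) / min(bitscore(A, A), bitscore(B, B)),

matches with minbit >= 0.5 are kept as weighted edges, and the resulting
graph is clustered with the Markov Cluster algorithm (MCL).  Each
multi-member cluster is one gene-duplication event; a fully streamlined
genome yields none.

A built-in Smith-Waterman scorer (BLOSUM62, BLAST-style affine gaps where a
gap of length k costs 11 + k, Karlin-Altschul bit conversion with gapped
constants lambda = 0.267, K = 0.041) lets small instances run without an
external aligner; externally produced BLAST/DIAMOND tabular hits are
consumed unchanged.  Self-hits are mandatory in user-supplied tables: a
length-based approximation would distort the normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .errors import InputError, NumericalError

MINBIT_THRESHOLD = 0.5  # retention cutoff on the normalized bitscore
_LAMBDA = 0.267  # gapped Karlin-Altschul lambda for BLOSUM62 11/1
_K = 0.041


@dataclass(frozen=True)
class PairwiseHit:
    query_id: str
    subject_id: str
    bitscore: float
    evalue: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.bitscore) or self.bitscore < 0:
            raise InputError(
                f"hit {self.query_id}->{self.subject_id}: bitscore must be "
                f"finite and >= 0, got {self.bitscore}"
            )


@dataclass(frozen=True)
class MinbitEdge:
    protein_a: str
    protein_b: str
    minbit: float


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # BLAST convention: gap of length k costs 11 + 1*k
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def pairwise_bitscore(seq_a: str, seq_b: str) -> float:
    """Local-alignment bitscore of two protein sequences.

    Raw Smith-Waterman score S is converted to bits via
    ``(lambda*S - ln K) / ln 2``; a raw score of 0 (no positive-scoring
    cell) is clamped to 0 bits.
    """
    if not seq_a or not seq_b:
        raise InputError("cannot score an empty sequence")
    raw = _ALIGNER.score(seq_a, seq_b)
    if raw <= 0:
        return 0.0
    return (_LAMBDA * raw - math.log(_K)) / math.log(2)


def minbit(hit_ab: float, self_aa: float, self_bb: float) -> float:
    """Cross bitscore normalized by the smaller self bitscore."""
    if self_aa is None or self_bb is None or self_aa <= 0 or self_bb <= 0:
        raise InputError("self-hit required: both self bitscores must be > 0")
    return hit_ab / min(self_aa, self_bb)


def build_minbit_edges(
    hits: Iterable[PairwiseHit],
    threshold: float = MINBIT_THRESHOLD,
) -> list[MinbitEdge]:
    """Undirected minbit edges from a directional hit table.

    The two directional cross bitscores (A->B, B->A) are reconciled by
    taking their maximum before normalization, so minbit is symmetric by
    construction.  Every protein appearing in any hit must have a self-hit.
    Edges below ``threshold`` are dropped; self edges are not emitted.
    """
    selves: dict[str, float] = {}
    cross: dict[tuple[str, str], float] = {}
    nodes: set[str] = set()
    for h in hits:
        nodes.add(h.query_id)
        nodes.add(h.subject_id)
        if h.query_id == h.subject_id:
            selves[h.query_id] = max(selves.get(h.query_id, 0.0), h.bitscore)
        else:
            key = (min(h.query_id, h.subject_id), max(h.query_id, h.subject_id))
            cross[key] = max(cross.get(key, 0.0), h.bitscore)
    missing = sorted(n for n in nodes if n not in selves)
    if missing:
        raise InputError(
            f"self-hit required for: {', '.join(missing[:5])}"
            + ("..." if len(missing) > 5 else "")
        )
    edges = []
    for (a, b), score in sorted(cross.items()):
        mb = minbit(score, selves[a], selves[b])
        if mb >= threshold:
            edges.append(MinbitEdge(a, b, mb))
    return edges


def _as_graph(
    edges: Iterable[MinbitEdge] | Iterable[tuple[str, str, float]] | nx.Graph,
) -> nx.Graph:
    if isinstance(edges, nx.Graph):
        return edges
    g = nx.Graph()
    for e in edges:
        if isinstance(e, MinbitEdge):
            a, b, w = e.protein_a, e.protein_b, e.minbit
        else:
            a, b, w = e
        if w <= 0:
            raise InputError(f"edge {a}-{b}: weight must be > 0, got {w}")
        g.add_edge(a, b, weight=w)
    return g


def mcl_cluster(
    edges: Iterable[MinbitEdge] | Iterable[tuple[str, str, float]] | nx.Graph,
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-6,
    prune: float = 1e-5,
    isolated_nodes: Iterable[str] = (),
) -> list[frozenset[str]]:
    """Markov clustering of a weighted undirected graph.

    The column-stochastic transition matrix is iterated with expansion
    (matrix squaring) and inflation (elementwise power then column
    renormalization), pruning entries below ``prune`` per column, until the
    matrix change falls below ``tol``.  Self-loops of weight 1 are added to
    nodes lacking one (the standard MCL regularization).  Clusters are the
    connected components of the thresholded limit matrix; the result is a
    partition of the node set, deterministic for a fixed node order
    (nodes are sorted internally).

    ``isolated_nodes`` adds nodes with no edges; each becomes a singleton.
    """
    if inflation <= 1:
        raise InputError(f"inflation must be > 1, got {inflation}")
    g = _as_graph(edges)
    for n in isolated_nodes:
        g.add_node(n)
    nodes = sorted(g.nodes)
    if not nodes:
        raise InputError("empty graph")
    idx = {n: i for i, n in enumerate(nodes)}
    k = len(nodes)
    m = np.zeros((k, k))
    for a, b, data in g.edges(data=True):
        w = data.get("weight", 1.0)
        m[idx[a], idx[b]] = w
        m[idx[b], idx[a]] = w
    np.fill_diagonal(m, np.where(np.diag(m) > 0, np.diag(m), 1.0))
    m /= m.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        prev = m
        m = m @ m                      # expansion
        m = np.power(m, inflation)     # inflation
        m[m < prune] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        if np.any(colsum == 0):
            raise NumericalError("a column lost all mass during pruning")
        m /= colsum
        if np.abs(m - prev).max() < tol:
            break
    else:
        raise NumericalError(
            f"MCL did not converge in {max_iter} iterations "
            f"(residual {np.abs(m - prev).max():.3g})"
        )
    # components of the limit matrix define the (hard) clusters
    support = nx.Graph()
    support.add_nodes_from(range(k))
    rows, cols = np.nonzero(m > tol)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    return sorted(
        (frozenset(nodes[i] for i in comp)
         for comp in nx.connected_components(support)),
        key=lambda c: sorted(c)[0],
    )


def count_duplication_events(clusters: Sequence[frozenset[str]]) -> int:
    """Number of clusters with >= 2 members.

    Singleton clusters are every non-duplicated gene and are not events;
    counting them would make each gene an event.  Overlapping clusters are
    rejected: the input must be a partition.
    """
    seen: set[str] = set()
    for c in clusters:
        if seen & set(c):
            raise InputError("clusters overlap; expected a partition")
        seen |= set(c)
    return sum(1 for c in clusters if len(c) >= 2)


def duplication_events_from_hits(
    hits: Iterable[PairwiseHit],
    threshold: float = MINBIT_THRESHOLD,
    inflation: float = 2.0,
) -> tuple[int, list[frozenset[str]]]:
    """Full paralog-calling route: minbit filter, MCL, event count.

    Proteins whose every cross hit falls below the minbit threshold become
    singletons and do not contribute events.
    """
    hits = list(hits)
    edges = build_minbit_edges(hits, threshold=threshold)
    all_proteins = sorted({h.query_id for h in hits} | {h.subject_id for h in hits})
    connected = {e.protein_a for e in edges} | {e.protein_b for e in edges}
    isolated = [p for p in all_proteins if p not in connected]
    clusters = mcl_cluster(edges, inflation=inflation, isolated_nodes=isolated)
    return count_duplication_events(clusters), clusters


def self_and_cross_hits(
    proteins: Mapping[str, str],
    candidate_pairs: Iterable[tuple[str, str]] | None = None,
) -> list[PairwiseHit]:
    """Score a proteome with the built-in aligner.

    Emits one self-hit per protein plus cross-hits for ``candidate_pairs``
    (default: all unordered pairs).  Zero-bit cross scores are omitted, as
    an aligner reporting significant matches would do.
    """
    ids = sorted(proteins)
    if candidate_pairs is None:
        candidate_pairs = [
            (ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))
        ]
    hits = [PairwiseHit(p, p, pairwise_bitscore(proteins[p], proteins[p]))
            for p in ids]
    for a, b in candidate_pairs:
        bits = pairwise_bitscore(proteins[a], proteins[b])
        if bits > 0:
            hits.append(PairwiseHit(a, b, bits))
    return hits
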