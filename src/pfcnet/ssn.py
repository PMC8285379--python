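"""Sequence similarity network construction and cluster extraction.

Nodes are proteins; an edge joins two proteins whose best pairwise hit passes
both the percent-identity and coverage thresholds (80/80 by default, the
common choice in similarity-network studies).  Protein functional clusters
(PFCs) are the connected components with at least two members; everything
else is a singleton and excluded from downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Sequence

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

from .types import PfcPartition, ProteinRecord, SimilarityHit

CoverageMode = Literal["both", "query", "either"]


def filter_hits(
    hits: Iterable[SimilarityHit],
    id_threshold: float = 80.0,
    cov_threshold: float = 80.0,
    coverage_mode: CoverageMode = "both",
) -> nx.Graph:
    """Build the similarity graph from hits passing both thresholds.

    Comparisons are inclusive (>=).  ``coverage_mode`` selects which side(s)
    the coverage threshold applies to; the default ``both`` (mutual coverage)
    is the conservative reading.
    """
    if not (0 < id_threshold <= 100 and 0 < cov_threshold <= 100):
        raise ValueError("thresholds must lie in (0, 100]")
    g = nx.Graph()
    for h in hits:
        if h.pident < id_threshold:
            continue
        if coverage_mode == "both":
            cov_ok = min(h.cov_query, h.cov_subject) >= cov_threshold
        elif coverage_mode == "query":
            cov_ok = h.cov_query >= cov_threshold
        elif coverage_mode == "either":
            cov_ok = max(h.cov_query, h.cov_subject) >= cov_threshold
        else:  # pragma: no cover - guarded by Literal type
            raise ValueError(f"unknown coverage_mode {coverage_mode!r}")
        if cov_ok:
            g.add_edge(h.query_id, h.subject_id, pident=h.pident)
    return g


def extract_pfcs(graph: nx.Graph, all_proteins: Iterable[str]) -> PfcPartition:
    """Partition the catalog into connected components of size >= 2 plus
    singletons.  Cluster ids are assigned 1..k after sorting components by
    their smallest member id, so numbering is deterministic."""
    all_ids = set(all_proteins)
    unknown = set(graph.nodes) - all_ids
    if unknown:
        raise ValueError(f"graph contains proteins outside the catalog: {sorted(unknown)[:5]}")
    components = [frozenset(c) for c in nx.connected_components(graph) if len(c) >= 2]
    components.sort(key=lambda c: min(c))
    clustered: set[str] = set()
    for c in components:
        clustered |= c
    return PfcPartition(
        clusters={i + 1: c for i, c in enumerate(components)},
        singletons=frozenset(all_ids - clustered),
    )


# ---------------------------------------------------------------------------
# desk-scale pairwise alignment fallback


@dataclass(frozen=True)
class AlignScoring:
    """Local-alignment scoring: substitution matrix name + affine gap costs."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0


def _make_aligner(scoring: AlignScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix)
    # biopython convention: open cost applies to the first gap residue
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def align_pair(
    seq_a: str,
    seq_b: str,
    scoring: AlignScoring = AlignScoring(),
    ids: tuple[str, str] = ("a", "b"),
    aligner: Align.PairwiseAligner | None = None,
) -> SimilarityHit | None:
    """Best local (Smith-Waterman) alignment between two protein sequences.

    Returns percent identity over alignment columns and per-side coverages,
    or None when no local alignment scores positively.  This is the
    desk-scale stand-in for an external all-vs-all search tool.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    if aligner is None:
        aligner = _make_aligner(scoring)
    score = aligner.score(seq_a, seq_b)
    if score <= 0:
        return None
    aln = next(iter(aligner.align(seq_a, seq_b)))
    identities = 0
    columns = 0
    spans = [0, 0]  # aligned residue span on each side
    blocks_a, blocks_b = aln.aligned
    prev_a_end = prev_b_end = None
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        if prev_a_end is not None:
            # gap columns between consecutive aligned blocks
            columns += max(a0 - prev_a_end, b0 - prev_b_end)
        for i, j in zip(range(a0, a1), range(b0, b1)):
            columns += 1
            if seq_a[i] == seq_b[j]:
                identities += 1
        spans[0] += a1 - a0
        spans[1] += b1 - b0
        prev_a_end, prev_b_end = a1, b1
    if columns == 0:
        return None
    return SimilarityHit(
        query_id=ids[0],
        subject_id=ids[1],
        pident=100.0 * identities / columns,
        cov_query=min(100.0, 100.0 * columns / len(seq_a)),
        cov_subject=min(100.0, 100.0 * columns / len(seq_b)),
    )


def compute_all_hits(
    records: Sequence[ProteinRecord],
    scoring: AlignScoring = AlignScoring(),
    min_pident: float = 0.0,
) -> list[SimilarityHit]:
    """All-vs-all local alignment over a (desk-scale) protein catalog."""
    aligner = _make_aligner(scoring)
    hits: list[SimilarityHit] = []
    for ra, rb in combinations(sorted(records, key=lambda r: r.protein_id), 2):
        hit = align_pair(
            ra.sequence,
            rb.sequence,
            scoring,
            ids=(ra.protein_id, rb.protein_id),
            aligner=aligner,
        )
        if hit is not None and hit.pident >= min_pident:
            hits.append(hit)
    return hits
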