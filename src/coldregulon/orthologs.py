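"""One-to-one ortholog pairing from transcript-vs-gene-model alignment hits.

The pairing logic mirrors how cross-species RNA-seq studies anchor an
unannotated genome onto a reference: every query locus (genotype A) keeps its
longest alignment to a target gene model (genotype B), and when several query
loci claim the same target, the most stable mapping — operationalized as
identity × query coverage — wins.  The selection operates on plain hit tables
so output from any aligner (blat PSL, BLAST tabular) can be converted and fed
in; a small exact-seed ungapped aligner (:func:`toy_align`) is provided as
plumbing for synthetic sequences.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "AlignmentHit",
    "OrthologPair",
    "select_best_target",
    "resolve_many_to_one",
    "build_ortholog_map",
    "toy_align",
]


@dataclass(frozen=True)
class AlignmentHit:
    """A single query-vs-target alignment summary.

    identity and query_coverage are fractions in [0, 1]; aln_length is in
    bases on the alignment block.
    """

    query_id: str
    target_id: str
    aln_length: int
    identity: float
    query_coverage: float

    def __post_init__(self) -> None:
        if self.aln_length < 0:
            raise ValueError("aln_length must be >= 0")
        for name in ("identity", "query_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class OrthologPair:
    """A selected locus_a -> locus_b pairing with its selection scores."""

    locus_a: str
    locus_b: str
    aln_length: int
    stability: float


def select_best_target(hits_for_one_query: Sequence[AlignmentHit]) -> AlignmentHit | None:
    """Keep the longest alignment for one query locus.

    Ties on length are broken by higher identity, then by lexicographically
    smallest target id.  An empty hit list signals "no pair" and returns
    ``None`` rather than raising.
    """
    if not hits_for_one_query:
        return None
    queries = {h.query_id for h in hits_for_one_query}
    if len(queries) != 1:
        raise ValueError(f"hits span multiple queries: {sorted(queries)}")
    return max(hits_for_one_query, key=lambda h: (h.aln_length, h.identity, _neg_lex(h.target_id)))


class _neg_lex(str):
    """Reverses lexicographic comparison so max() prefers the smallest id."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other) -> bool:  # type: ignore[override]
        return str.__lt__(self, other)

    def __le__(self, other) -> bool:  # type: ignore[override]
        return str.__ge__(self, other)

    def __ge__(self, other) -> bool:  # type: ignore[override]
        return str.__le__(self, other)


def stability_score(hit: AlignmentHit) -> float:
    """Mapping-stability score: identity × query coverage."""
    return hit.identity * hit.query_coverage


def resolve_many_to_one(pairs: Sequence[OrthologPair]) -> list[OrthologPair]:
    """Resolve multiple locus_a claimants on one locus_b to a one-to-one map.

    For each contested locus_b, the claimant with maximal stability is kept;
    ties go to the longer alignment, then the smallest locus_a.  Output order
    follows locus_a.
    """
    by_target: dict[str, list[OrthologPair]] = defaultdict(list)
    for p in pairs:
        by_target[p.locus_b].append(p)
    kept = [
        max(claimants, key=lambda p: (p.stability, p.aln_length, _neg_lex(p.locus_a)))
        for claimants in by_target.values()
    ]
    return sorted(kept, key=lambda p: p.locus_a)


def build_ortholog_map(hits: Iterable[AlignmentHit]) -> list[OrthologPair]:
    """Full selection: best target per query, then many-to-one resolution.

    The composed map is injective in both directions (each locus_a and each
    locus_b appears at most once).
    """
    per_query: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        per_query[h.query_id].append(h)
    pairs = []
    for query in sorted(per_query):
        best = select_best_target(per_query[query])
        if best is not None:
            pairs.append(
                OrthologPair(best.query_id, best.target_id, best.aln_length, stability_score(best))
            )
    return resolve_many_to_one(pairs)


# ---------------------------------------------------------------------------
# Toy aligner: exact k-mer seeding + ungapped extension.  Test plumbing only;
# it stands in for a genome-scale aligner on short synthetic transcripts.
# ---------------------------------------------------------------------------


def toy_align(
    query_seqs: dict[str, str],
    target_seqs: dict[str, str],
    k: int = 11,
) -> list[AlignmentHit]:
    """Exact-k-mer-seeded ungapped alignment of each query against all targets.

    For every query/target pair sharing at least one k-mer, seeds are grouped
    by diagonal (target offset − query offset); the diagonal with the most
    seeds (ties: smallest diagonal) is extended ungapped to the ends of the
    overlap.  The hit reports the overlap length, the match fraction on it,
    and the query coverage.  Deterministic; one hit per (query, target).
    """
    if k < 8:
        raise ValueError("seed length k must be >= 8")
    if not query_seqs or not target_seqs:
        return []

    index: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for tid in sorted(target_seqs):
        tseq = target_seqs[tid].upper()
        for i in range(len(tseq) - k + 1):
            index[tseq[i : i + k]].append((tid, i))

    hits: list[AlignmentHit] = []
    for qid in sorted(query_seqs):
        qseq = query_seqs[qid].upper()
        diagonals: dict[str, dict[int, int]] = defaultdict(lambda: defaultdict(int))
        for qpos in range(len(qseq) - k + 1):
            for tid, tpos in index.get(qseq[qpos : qpos + k], ()):
                diagonals[tid][tpos - qpos] += 1
        for tid in sorted(diagonals):
            diag_counts = diagonals[tid]
            diag = max(diag_counts, key=lambda d: (diag_counts[d], -d))
            tseq = target_seqs[tid].upper()
            # Overlap of query [0, len(q)) with target shifted by diag.
            q_lo = max(0, -diag)
            q_hi = min(len(qseq), len(tseq) - diag)
            block_q = qseq[q_lo:q_hi]
            block_t = tseq[q_lo + diag : q_hi + diag]
            length = q_hi - q_lo
            if length <= 0:
                continue
            matches = sum(a == b for a, b in zip(block_q, block_t))
            hits.append(
                AlignmentHit(
                    query_id=qid,
                    target_id=tid,
                    aln_length=length,
                    identity=matches / length,
                    query_coverage=length / len(qseq),
                )
            )
    return hits
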