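"""Homology identification: reciprocal-best-hit orthologs between two
sequence sets, coverage-rule paralogs within one set, and single-linkage
gene families.

All-against-all search is made tractable by a shared-k-mer prescreen
(k = 12, >= 2 shared k-mers by default): only candidate pairs are aligned,
and every reported pair carries an exact-DP score. Sequences more diverged
than the prescreen can see are also beyond the Ks range the downstream
distribution uses (Ks < 2 corresponds to roughly 60% nucleotide identity,
far above the prescreen's sensitivity limit).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .aligner import DEFAULT_NT_SCORING, LocalAlignment, ScoringScheme, local_align
from .seq_io import SequenceRecord

PRESCREEN_K = 12
PRESCREEN_MIN_HITS = 2


@dataclass
class HomologPair:
    """A typed homology edge; Ks/Ka fields are filled by the Ks stage."""

    id_a: str
    id_b: str
    kind: str  # "ortholog" | "paralog"
    aligned_nt: int
    coverage_shorter: float
    evalue: float
    score: float = 0.0
    aligned_aa: int = 0
    ks: float | None = None
    ka: float | None = None
    saturated: bool = False
    alignment: LocalAlignment | None = field(default=None, repr=False, compare=False)

    @property
    def key(self) -> tuple[str, str]:
        a, b = self.id_a, self.id_b
        return (a, b) if a <= b else (b, a)


@dataclass
class GeneFamily:
    """A single-linkage component of the paralog graph (>= 2 members).

    ``ks_matrix`` maps canonical member-id pairs to Ks (None = missing:
    alignment failure, saturation or a too-short alignment); ``event_ks``
    holds the n − 1 deduplicated duplication-event Ks values (None =
    undated). Both are filled by the family-dating stage.
    """

    family_id: str
    member_ids: list[str]
    ks_matrix: dict[tuple[str, str], float | None] = field(default_factory=dict)
    event_ks: list[float | None] = field(default_factory=list)


def _kmer_profile(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _candidates_between(
    set_a: Sequence[SequenceRecord],
    set_b: Sequence[SequenceRecord],
    k: int = PRESCREEN_K,
    min_hits: int = PRESCREEN_MIN_HITS,
) -> dict[int, list[int]]:
    """For each index in set_a, indices in set_b sharing >= min_hits k-mers."""
    index: dict[str, list[int]] = defaultdict(list)
    for j, rec in enumerate(set_b):
        for kmer in _kmer_profile(rec.seq, k):
            index[kmer].append(j)
    out: dict[int, list[int]] = {}
    for i, rec in enumerate(set_a):
        hits: dict[int, int] = defaultdict(int)
        for kmer in _kmer_profile(rec.seq, k):
            for j in index.get(kmer, ()):
                hits[j] += 1
        cand = sorted(j for j, n in hits.items() if n >= min_hits)
        if cand:
            out[i] = cand
    return out


def _candidates_within(
    records: Sequence[SequenceRecord],
    k: int = PRESCREEN_K,
    min_hits: int = PRESCREEN_MIN_HITS,
) -> list[tuple[int, int]]:
    """Unordered index pairs within one set sharing >= min_hits k-mers."""
    index: dict[str, list[int]] = defaultdict(list)
    for i, rec in enumerate(records):
        for kmer in _kmer_profile(rec.seq, k):
            index[kmer].append(i)
    hits: dict[tuple[int, int], int] = defaultdict(int)
    for members in index.values():
        if len(members) < 2:
            continue
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                i, j = members[x], members[y]
                if i != j:
                    hits[(min(i, j), max(i, j))] += 1
    return sorted(p for p, n in hits.items() if n >= min_hits)


def find_orthologs(
    set_a: Sequence[SequenceRecord],
    set_b: Sequence[SequenceRecord],
    evalue_cutoff: float = 1e-20,
    min_aligned: int = 300,
    scoring: ScoringScheme = DEFAULT_NT_SCORING,
) -> list[HomologPair]:
    """Reciprocal-best-hit orthologs with an E-value and length gate.

    For every sequence the best-scoring hit in the other set is found
    (ties broken by lower E-value, then lexicographic id); a pair is
    emitted iff the two are mutually best, both E-values pass the cutoff
    and the best local alignment spans >= ``min_aligned`` columns.
    """
    if not set_a or not set_b:
        raise ValueError("both sequence sets must be non-empty")
    cand_ab = _candidates_between(set_a, set_b)

    # exact scores for every candidate edge, shared by both directions
    scores: dict[tuple[int, int], tuple[float, float]] = {}
    for i, js in cand_ab.items():
        for j in js:
            aln = local_align(set_a[i], set_b[j], scoring, score_only=True)
            if aln is not None:
                scores[(i, j)] = (aln.score, aln.evalue)

    def best_hit(edges: Iterable[tuple[int, tuple[float, float], str]]) -> int | None:
        ranked = sorted(edges, key=lambda e: (-e[1][0], e[1][1], e[2]))
        return ranked[0][0] if ranked else None

    best_a: dict[int, int] = {}
    by_a: dict[int, list] = defaultdict(list)
    by_b: dict[int, list] = defaultdict(list)
    for (i, j), sc in scores.items():
        by_a[i].append((j, sc, set_b[j].id))
        by_b[j].append((i, sc, set_a[i].id))
    for i, edges in by_a.items():
        hit = best_hit(edges)
        if hit is not None:
            best_a[i] = hit
    best_b = {}
    for j, edges in by_b.items():
        hit = best_hit(edges)
        if hit is not None:
            best_b[j] = hit

    pairs: list[HomologPair] = []
    for i, j in sorted(best_a.items()):
        if best_b.get(j) != i:
            continue
        score, ev = scores[(i, j)]
        if ev > evalue_cutoff:
            continue
        aln = local_align(set_a[i], set_b[j], scoring)
        if aln is None or aln.aligned_len < min_aligned:
            continue
        shorter = min(set_a[i].length, set_b[j].length)
        span = (
            aln.q_span if set_a[i].length <= set_b[j].length else aln.s_span
        )
        pairs.append(
            HomologPair(
                id_a=set_a[i].id,
                id_b=set_b[j].id,
                kind="ortholog",
                aligned_nt=aln.aligned_len,
                coverage_shorter=(span[1] - span[0]) / shorter,
                evalue=ev,
                score=score,
                alignment=aln,
            )
        )
    return pairs


def find_paralogs(
    records: Sequence[SequenceRecord],
    min_coverage: float = 0.70,
    max_evalue: float = 1e-10,
    scoring: ScoringScheme = DEFAULT_NT_SCORING,
) -> list[HomologPair]:
    """Within-set paralog pairs by the shorter-sequence coverage rule.

    A pair is a paralog iff its best local alignment covers >=
    ``min_coverage`` of the shorter sequence (span on the shorter one) and
    passes the E-value gate. Each unordered pair is reported once, ids
    canonical.
    """
    if len(records) < 2:
        raise ValueError("need at least two sequences")
    pairs: list[HomologPair] = []
    for i, j in _candidates_within(records):
        a, b = records[i], records[j]
        aln = local_align(a, b, scoring, max_evalue=max_evalue)
        if aln is None:
            continue
        shorter = min(a.length, b.length)
        span = aln.q_span if a.length <= b.length else aln.s_span
        coverage = (span[1] - span[0]) / shorter
        if coverage < min_coverage:
            continue
        pairs.append(
            HomologPair(
                id_a=min(a.id, b.id),
                id_b=max(a.id, b.id),
                kind="paralog",
                aligned_nt=aln.aligned_len,
                coverage_shorter=coverage,
                evalue=aln.evalue,
                score=aln.score,
                alignment=aln,
            )
        )
    pairs.sort(key=lambda p: p.key)
    return pairs


def build_families(paralog_pairs: Sequence[HomologPair]) -> list[GeneFamily]:
    """Single-linkage gene families: connected components of the paralog
    graph with >= 2 members; members sorted, families ordered and numbered
    by their first member."""
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        root = x
        while parent.get(root, root) != root:
            root = parent[root]
        while parent.get(x, x) != x:
            parent[x], x = root, parent[x]
        return root

    for p in paralog_pairs:
        parent.setdefault(p.id_a, p.id_a)
        parent.setdefault(p.id_b, p.id_b)
        ra, rb = find(p.id_a), find(p.id_b)
        if ra != rb:
            parent[ra] = rb

    groups: dict[str, list[str]] = defaultdict(list)
    for sid in parent:
        groups[find(sid)].append(sid)

    members_sorted = sorted(
        (sorted(m) for m in groups.values() if len(m) >= 2), key=lambda m: m[0]
    )
    width = max(4, len(str(len(members_sorted))))
    return [
        GeneFamily(family_id=f"F{idx:0{width}d}", member_ids=m)
        for idx, m in enumerate(members_sorted, start=1)
    ]
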