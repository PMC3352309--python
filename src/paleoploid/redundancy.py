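"""Collapse redundant contigs that are putative splice variants.

Distinct contigs assembled from one gene share identical exon-derived
blocks, so their best local alignment is a 100%-identity run of >= 100 bp.
Genuinely diverged paralogs — even recent ones — instead produce one long
alignment carrying mismatches, and are kept. The filter therefore declares
two contigs redundant when their best-scoring local alignment has identity
>= ``min_identity`` (default 1.0) over >= ``min_block`` columns (default
100, inclusive), groups redundant contigs by single linkage, and keeps the
longest member of each group as the gene's representative.

A shared 100%-identity best alignment of >= min_block columns implies an
exact common substring of that length, so candidate pairs are found first
by a k-mer anchor scan (k = 31, below the block threshold) with maximal
exact extension; only candidates are then verified by exact local DP. A
brute-force longest-common-substring oracle in the test-suite pins the
scan's correctness.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .aligner import DEFAULT_NT_SCORING, ScoringScheme, local_align
from .seq_io import SequenceRecord

ANCHOR_K = 31


@dataclass(frozen=True)
class RedundancyPair:
    """An unordered redundant pair, ids in canonical (sorted) order."""

    id_a: str
    id_b: str
    block_length: int

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValueError(f"self-pair {self.id_a!r}")
        if self.id_a > self.id_b:
            a, b = self.id_a, self.id_b
            object.__setattr__(self, "id_a", b)
            object.__setattr__(self, "id_b", a)

    @property
    def key(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


@dataclass(frozen=True)
class EvaluationReport:
    """Sensitivity / error-rate of detected pairs against a truth set."""

    detected: int
    truth: int
    true_positive: int

    def __post_init__(self) -> None:
        if self.true_positive > min(self.detected, self.truth):
            raise ValueError("true_positive exceeds detected or truth")

    @property
    def sensitivity(self) -> float:
        return self.true_positive / self.truth

    @property
    def error_rate(self) -> float:
        if self.detected == 0:
            return 0.0
        return (self.detected - self.true_positive) / self.detected


def longest_shared_run(sa: str, sb: str, min_block: int, k: int = ANCHOR_K) -> int:
    """Length of the longest exact common substring, if >= min_block, else 0.

    k-mer anchoring with maximal exact extension: any common run of length
    >= k contains a shared k-mer, and extending that anchor occurrence
    recovers the full run, so for min_block >= k the scan is exact.
    """
    k = min(k, min_block)
    pos_b: dict[str, list[int]] = defaultdict(list)
    for j in range(len(sb) - k + 1):
        pos_b[sb[j : j + k]].append(j)
    best = 0
    bound = min(len(sa), len(sb))
    for i in range(len(sa) - k + 1):
        hits = pos_b.get(sa[i : i + k])
        if not hits:
            continue
        for j in hits:
            if best >= bound:
                return best
            run = _extend_exact(sa, sb, i, j, k)
            if run > best:
                best = run
    return best if best >= min_block else 0


def _extend_exact(sa: str, sb: str, ia: int, ib: int, k: int) -> int:
    left = 0
    while ia - left - 1 >= 0 and ib - left - 1 >= 0 and sa[ia - left - 1] == sb[ib - left - 1]:
        left += 1
    right = 0
    la, lb = len(sa), len(sb)
    while ia + k + right < la and ib + k + right < lb and sa[ia + k + right] == sb[ib + k + right]:
        right += 1
    return left + k + right


def find_redundant_pairs(
    records: Sequence[SequenceRecord],
    min_block: int = 100,
    min_identity: float = 1.0,
    scoring: ScoringScheme = DEFAULT_NT_SCORING,
) -> list[RedundancyPair]:
    """All unordered pairs whose best local alignment is >= min_block
    columns at identity >= min_identity.

    Reverse-complement matches are not counted: assembled contigs are
    compared in their given orientation. Each pair is reported once, ids in
    canonical order, with the longest exact shared run as ``block_length``.
    """
    if min_block < 1:
        raise ValueError("min_block must be >= 1")
    if len(records) < 2:
        return []

    # prescreen: exact shared run of >= prescreen_run bases. At identity
    # 1.0 a qualifying alignment IS such a run; below 1.0 it still must
    # contain an exact run of ceil(min_block / (mismatches+1)) bases.
    if min_identity >= 1.0:
        prescreen_run = min_block
    else:
        max_mismatch = int(min_block * (1.0 - min_identity)) + 1
        prescreen_run = max(12, min_block // (max_mismatch + 1))

    candidates = _candidate_pairs(records, prescreen_run)
    out: list[RedundancyPair] = []
    for (ra, rb), run in sorted(candidates.items()):
        a, b = records[ra], records[rb]
        aln = local_align(a, b, scoring)
        if aln is None:
            continue
        if aln.aligned_len >= min_block and aln.identity >= min_identity:
            out.append(RedundancyPair(a.id, b.id, run))
    out.sort(key=lambda p: p.key)
    return out


def _candidate_pairs(
    records: Sequence[SequenceRecord], min_run: int
) -> dict[tuple[int, int], int]:
    """Map (i, j) -> longest exact shared run, for runs >= min_run."""
    k = min(ANCHOR_K, min_run)
    index: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for ri, rec in enumerate(records):
        seq = rec.seq
        for pos in range(len(seq) - k + 1):
            index[seq[pos : pos + k]].append((ri, pos))

    best: dict[tuple[int, int], int] = {}
    for hits in index.values():
        if len(hits) < 2:
            continue
        by_rec: dict[int, list[int]] = defaultdict(list)
        for ri, pos in hits:
            by_rec[ri].append(pos)
        recs = sorted(by_rec)
        for x, ra in enumerate(recs):
            sa = records[ra].seq
            for rb in recs[x + 1 :]:
                sb = records[rb].seq
                key = (ra, rb)
                bound = min(len(sa), len(sb))
                for ia in by_rec[ra]:
                    if best.get(key, 0) >= bound:
                        break
                    for ib in by_rec[rb]:
                        run = _extend_exact(sa, sb, ia, ib, k)
                        if run > best.get(key, 0):
                            best[key] = run
    return {key: run for key, run in best.items() if run >= min_run}


def collapse(
    records: Sequence[SequenceRecord], pairs: Iterable[RedundancyPair]
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Keep one representative per redundancy component.

    Components are connected components of the pair graph (single linkage);
    within each the longest sequence is retained, ties broken by
    lexicographically smallest id. Returns (retained records in input
    order, mapping collapsed_id -> representative_id); singletons are
    retained and absent from the map. Idempotent on its own output.
    """
    by_id = {r.id: r for r in records}
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        root = x
        while parent.get(root, root) != root:
            root = parent[root]
        while parent.get(x, x) != x:
            parent[x], x = root, parent[x]
        return root

    for p in pairs:
        for sid in (p.id_a, p.id_b):
            if sid not in by_id:
                raise KeyError(f"pair references unknown id {sid!r}")
        ra, rb = find(p.id_a), find(p.id_b)
        if ra != rb:
            parent[ra] = rb

    components: dict[str, list[str]] = defaultdict(list)
    for sid in by_id:
        components[find(sid)].append(sid)

    mapping: dict[str, str] = {}
    keep: set[str] = set()
    for members in components.values():
        rep = min(members, key=lambda s: (-by_id[s].length, s))
        keep.add(rep)
        for m in members:
            if m != rep:
                mapping[m] = rep
    retained = [r for r in records if r.id in keep]
    return retained, mapping


def evaluate_vs_truth(
    detected_pairs: Iterable[RedundancyPair | tuple[str, str]],
    truth_pairs: Iterable[RedundancyPair | tuple[str, str]],
) -> EvaluationReport:
    """Set-intersection evaluation of detected vs true redundant pairs."""
    det = {_as_key(p) for p in detected_pairs}
    tru = {_as_key(p) for p in truth_pairs}
    if not tru:
        raise ValueError("truth set is empty: sensitivity undefined")
    return EvaluationReport(
        detected=len(det), truth=len(tru), true_positive=len(det & tru)
    )


def _as_key(p) -> tuple[str, str]:
    if isinstance(p, RedundancyPair):
        return p.key
    a, b = p
    return (a, b) if a <= b else (b, a)
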