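"""Deduplicate duplication events inside gene families.

A family of n members descends from n − 1 duplication events, but its
n·(n−1)/2 pairwise Ks values date each event many times over. The
median-Ks agglomerative clustering resolves this: repeatedly merge the two
clusters whose cross-pair median Ks is smallest, emitting one duplication
event per merge dated by that median, until one cluster remains. Missing
pairwise values are excluded from medians; a merge whose cross-pairs are
all missing is deferred to the end and emits an undated event.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Mapping, Sequence

from .homology import GeneFamily
from .ks import ks_for_pair
from .seq_io import SequenceRecord


@dataclass(frozen=True)
class DuplicationEvent:
    """One deduplicated gene-duplication event within a family."""

    family_id: str
    event_ks: float | None  # None = undated (no datable cross-pair)
    merged_cluster_sizes: tuple[int, int]


def pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def family_ks_matrix(
    family: GeneFamily,
    sequences: Mapping[str, SequenceRecord],
    method: str = "ng86",
    min_aa: int = 30,
) -> GeneFamily:
    """Fill the family's pairwise Ks matrix over ALL member pairs.

    Every unordered member pair runs the full estimation path (local
    nucleotide alignment, protein alignment, codon back-translation, Ks).
    Pairs that fail to align, align over <= ``min_aa`` residues, or are
    saturated are recorded as missing (None); the matrix is emitted
    regardless.
    """
    for mid in family.member_ids:
        if mid not in sequences:
            raise KeyError(f"family member {mid!r} absent from sequence set")
    matrix: dict[tuple[str, str], float | None] = {}
    members = family.member_ids
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            key = pair_key(members[i], members[j])
            res = ks_for_pair(sequences[members[i]], sequences[members[j]], method)
            if res is None or res.aligned_aa <= min_aa or res.estimate.ks is None:
                matrix[key] = None
            else:
                matrix[key] = res.estimate.ks
    family.ks_matrix = matrix
    return family


def median_ks_clustering(
    ks_matrix: Mapping[tuple[str, str], float | None],
    members: Sequence[str],
    family_id: str = "",
) -> list[DuplicationEvent]:
    """Agglomerate members by smallest cross-cluster median Ks.

    Returns exactly ``len(members) − 1`` events in merge order. Medians of
    an even number of values are the mean of the two central values. Ties
    between candidate merges go to the pair whose combined sorted member
    list is lexicographically smallest. Merges with no datable cross-pair
    are deferred until only such merges remain, then emitted undated.
    """
    if len(members) < 2:
        raise ValueError("a family needs at least two members")
    clusters: list[list[str]] = [[m] for m in sorted(members)]
    events: list[DuplicationEvent] = []

    def cross_median(ca: Sequence[str], cb: Sequence[str]) -> float | None:
        vals = [
            v
            for a in ca
            for b in cb
            if (v := ks_matrix.get(pair_key(a, b))) is not None
        ]
        return statistics.median(vals) if vals else None

    while len(clusters) > 1:
        best: tuple[float, list[str], int, int] | None = None
        fallback: tuple[list[str], int, int] | None = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                med = cross_median(clusters[i], clusters[j])
                combined = sorted(clusters[i] + clusters[j])
                if med is None:
                    if fallback is None or combined < fallback[0]:
                        fallback = (combined, i, j)
                    continue
                if best is None or (med, combined) < (best[0], best[1]):
                    best = (med, combined, i, j)
        if best is not None:
            med, combined, i, j = best
            event_ks: float | None = med
        else:
            combined, i, j = fallback  # type: ignore[misc]
            event_ks = None
        events.append(
            DuplicationEvent(
                family_id=family_id,
                event_ks=event_ks,
                merged_cluster_sizes=(len(clusters[i]), len(clusters[j])),
            )
        )
        merged = combined
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return events


def date_family(
    family: GeneFamily,
    sequences: Mapping[str, SequenceRecord],
    method: str = "ng86",
    min_aa: int = 30,
) -> list[DuplicationEvent]:
    """Fill the Ks matrix and run the event clustering for one family."""
    family_ks_matrix(family, sequences, method, min_aa)
    events = median_ks_clustering(
        family.ks_matrix, family.member_ids, family.family_id
    )
    family.event_ks = [e.event_ks for e in events]
    return events


def collect_events(
    families: Sequence[GeneFamily], max_median_ks: float = 2.0
) -> tuple[list[float], dict[str, int]]:
    """Concatenate dated event Ks values across families.

    Returns (dated event Ks list, summary). The summary counts families,
    all events (dated + undated), dated events, and events below the
    ``max_median_ks`` cutoff — the values the downstream histogram uses.
    """
    dated: list[float] = []
    n_events = n_undated = 0
    for fam in families:
        if len(fam.event_ks) != len(fam.member_ids) - 1:
            raise ValueError(
                f"family {fam.family_id}: {len(fam.event_ks)} events for "
                f"{len(fam.member_ids)} members (expected n − 1)"
            )
        for ks in fam.event_ks:
            n_events += 1
            if ks is None:
                n_undated += 1
            else:
                dated.append(ks)
    below = [k for k in dated if k < max_median_ks]
    summary = {
        "families": len(families),
        "events": n_events,
        "events_dated": len(dated),
        "events_undated": n_undated,
        "events_below_cutoff": len(below),
    }
    return below, summary
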