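"""Annotation-composition comparison between two sequence sets.

Per-term testing uses the 2×2 Pearson chi-square (term vs not-term,
set A vs set B) without continuity correction, switching to Fisher's
exact test when an expected cell drops below 1. Per-pathway testing uses
the two-sided Fisher exact test (point-probability method) with
Benjamini–Hochberg FDR correction across pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact
from statsmodels.stats.multitest import multipletests

from .seq_io import AnnotationTable


@dataclass(frozen=True)
class EnrichmentRow:
    """Counts and test results for one term/pathway."""

    term_id: str
    count_a: int
    total_a: int
    count_b: int
    total_b: int
    p_raw: float = 1.0
    p_adj: float = 1.0
    direction: str = "none"  # enriched-in-A | enriched-in-B | none
    significant: bool = False

    def __post_init__(self) -> None:
        for c, t in ((self.count_a, self.total_a), (self.count_b, self.total_b)):
            if not 0 <= c <= t:
                raise ValueError(f"{self.term_id}: count {c} outside [0, {t}]")


def _table(count_a: int, total_a: int, count_b: int, total_b: int) -> np.ndarray:
    return np.array(
        [[count_a, total_a - count_a], [count_b, total_b - count_b]], dtype=float
    )


def _direction(count_a: int, total_a: int, count_b: int, total_b: int) -> str:
    pa, pb = count_a / total_a, count_b / total_b
    if pa > pb:
        return "enriched-in-A"
    if pb > pa:
        return "enriched-in-B"
    return "none"


def term_chisq(
    count_a: int,
    total_a: int,
    count_b: int,
    total_b: int,
    correction: bool = False,
) -> tuple[float, str]:
    """Pearson chi-square p-value (1 df) and enrichment direction.

    No continuity correction by default. If any expected cell is below 1
    the chi-square approximation is unreliable and Fisher's exact test is
    used instead, with a warning.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    direction = _direction(count_a, total_a, count_b, total_b)
    obs = _table(count_a, total_a, count_b, total_b)
    if direction == "none":
        return 1.0, direction
    col_sums = obs.sum(axis=0)
    if (col_sums == 0).any():
        return 1.0, direction
    expected = np.outer(obs.sum(axis=1), col_sums) / obs.sum()
    if (expected < 1).any():
        warnings.warn(
            "expected cell below 1; using Fisher's exact test", stacklevel=2
        )
        p = fisher_exact(obs.astype(int), alternative="two-sided")[1]
        return float(p), direction
    _, p, _, _ = chi2_contingency(obs, correction=correction)
    return float(p), direction


def pathway_fisher_fdr(
    rows: Sequence[EnrichmentRow], alpha: float = 0.05
) -> list[EnrichmentRow]:
    """Two-sided Fisher exact p per row, BH-adjusted across all rows.

    The two-sided p sums hypergeometric outcomes whose point probability
    does not exceed the observed one. Rows come back in input order with
    ``p_raw``, ``p_adj``, ``direction`` and the ``significant`` flag
    (p_adj <= alpha) filled.
    """
    if not rows:
        raise ValueError("no rows to test")
    p_raw = []
    for r in rows:
        obs = _table(r.count_a, r.total_a, r.count_b, r.total_b).astype(int)
        p_raw.append(float(fisher_exact(obs, alternative="two-sided")[1]))
    _, p_adj, _, _ = multipletests(p_raw, method="fdr_bh")
    out = []
    for r, pr, pa in zip(rows, p_raw, p_adj):
        out.append(
            replace(
                r,
                p_raw=pr,
                p_adj=float(pa),
                direction=_direction(r.count_a, r.total_a, r.count_b, r.total_b),
                significant=bool(pa <= alpha),
            )
        )
    return out


def compare_annotations(
    annot_a: AnnotationTable,
    annot_b: AnnotationTable,
    method: str = "fisher-fdr",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Term-by-term comparison of two annotation tables.

    ``method`` "chisq" runs the per-term Pearson chi-square (each term on
    its own); "fisher-fdr" runs Fisher exact per term with BH correction
    across terms. Totals are each table's annotated-sequence count.
    """
    ca, cb = annot_a.term_counts(), annot_b.term_counts()
    terms = sorted(set(ca.index) | set(cb.index))
    rows = [
        EnrichmentRow(
            term_id=t,
            count_a=int(ca.get(t, 0)),
            total_a=annot_a.total,
            count_b=int(cb.get(t, 0)),
            total_b=annot_b.total,
        )
        for t in terms
    ]
    if method == "chisq":
        out = []
        for r in rows:
            p, direction = term_chisq(r.count_a, r.total_a, r.count_b, r.total_b)
            out.append(
                replace(r, p_raw=p, p_adj=p, direction=direction,
                        significant=bool(p <= alpha))
            )
        rows = out
    elif method == "fisher-fdr":
        rows = pathway_fisher_fdr(rows, alpha)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame([r.__dict__ for r in rows])
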