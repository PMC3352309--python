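"""Pairwise alignment: local nucleotide DP with Karlin–Altschul E-values
(the homology-search workhorse) and global protein alignment with codon
back-translation (the protein-guided codon-alignment stage).

All dynamic programming is exact affine-gap DP via Bio.Align.PairwiseAligner;
results carry ``mode="exact"``. A gap of length k costs open + k·extend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

from .seq_io import CODON_TABLE, SequenceRecord, translate

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")
GAP_CODON = "---"


@dataclass(frozen=True)
class ScoringScheme:
    """Nucleotide scoring with Karlin–Altschul statistics.

    ``lambda_`` solves sum_i p_i p_j exp(lambda*s_ij) = 1 for the background
    composition (uniform by default); ``k_const`` is the Karlin–Altschul
    prefactor, taken from configuration (0.621, a BLASTN-like default for
    +1/−2 scoring) since its exact computation needs the full length
    distribution theory.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = 5
    gap_extend: int = 2
    k_const: float = 0.621
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        p_match = sum(p * p for p in self.composition)
        if p_match * self.match + (1 - p_match) * self.mismatch >= 0:
            raise ValueError("expected score per aligned pair must be negative")

    @property
    def lambda_(self) -> float:
        return _solve_lambda(self.match, self.mismatch, self.composition)


@lru_cache(maxsize=None)
def _solve_lambda(match: int, mismatch: int, composition: tuple) -> float:
    p_match = sum(p * p for p in composition)

    def f(lam: float) -> float:
        return p_match * np.exp(lam * match) + (1 - p_match) * np.exp(lam * mismatch) - 1.0

    return brentq(f, 1e-9, 20.0)


DEFAULT_NT_SCORING = ScoringScheme()


@dataclass
class LocalAlignment:
    """Best-scoring local alignment of a query/subject pair."""

    query_id: str
    subject_id: str
    score: float
    identity: float
    aligned_len: int  # alignment columns, gaps included
    q_span: tuple[int, int]  # 0-based half-open on the query
    s_span: tuple[int, int]
    evalue: float
    q_aligned: str = field(default="", repr=False)  # gapped strings, '-' gaps
    s_aligned: str = field(default="", repr=False)
    mode: str = "exact"


@dataclass
class CodonAlignment:
    """Paired, gapped, in-frame codon alignment (gap = '---')."""

    id_a: str
    id_b: str
    codons_a: str
    codons_b: str

    def __post_init__(self) -> None:
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("codon strings differ in length")
        if len(self.codons_a) % 3:
            raise ValueError("codon string length not a multiple of 3")

    def codon_pairs(self) -> list[tuple[str, str]]:
        s = self.codons_a
        return [
            (s[i : i + 3], self.codons_b[i : i + 3]) for i in range(0, len(s), 3)
        ]

    @property
    def n_codon_columns(self) -> int:
        """Columns where both sides are ungapped, stop-free and N-free."""
        n = 0
        for ca, cb in self.codon_pairs():
            if _countable(ca) and _countable(cb):
                n += 1
        return n


def _countable(codon: str) -> bool:
    return (
        codon != GAP_CODON
        and "N" not in codon
        and "-" not in codon
        and CODON_TABLE.get(codon, "*") != "*"
    )


def _nt_aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner(
        mode="local",
        match_score=scoring.match,
        mismatch_score=scoring.mismatch,
        open_gap_score=-(scoring.gap_open + scoring.gap_extend),
        extend_gap_score=-scoring.gap_extend,
    )
    return al


def evalue(score: float, m: int, n: int, scoring: ScoringScheme = DEFAULT_NT_SCORING) -> float:
    """Karlin–Altschul expectation E = K·m·n·exp(−lambda·score)."""
    if m <= 0 or n <= 0:
        raise ValueError("sequence lengths must be positive")
    return float(scoring.k_const * m * n * np.exp(-scoring.lambda_ * score))


def local_align(
    a: SequenceRecord,
    b: SequenceRecord,
    scoring: ScoringScheme = DEFAULT_NT_SCORING,
    max_evalue: float | None = None,
    score_only: bool = False,
) -> LocalAlignment | None:
    """Smith–Waterman-optimal local alignment under affine gaps.

    Returns None when the best alignment's E-value exceeds ``max_evalue``
    (if given) or the best score is not positive. With ``score_only`` the
    gapped strings/identity/spans are skipped (score and E-value only),
    which is much faster for best-hit scans.
    """
    aligner = _nt_aligner(scoring)
    score = aligner.score(a.seq, b.seq)
    if score <= 0:
        return None
    ev = evalue(score, a.length, b.length, scoring)
    if max_evalue is not None and ev > max_evalue:
        return None
    if score_only:
        return LocalAlignment(a.id, b.id, score, 0.0, 0, (0, 0), (0, 0), ev)
    aln = aligner.align(a.seq, b.seq)[0]
    q_txt, s_txt = str(aln[0]), str(aln[1])
    # PairwiseAligner renders local alignments over the aligned region only
    q_blocks, s_blocks = aln.aligned
    q_span = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    s_span = (int(s_blocks[0][0]), int(s_blocks[-1][1]))
    q_gapped, s_gapped = _gapped_region(aln)
    ncol = len(q_gapped)
    matches = sum(1 for x, y in zip(q_gapped, s_gapped) if x == y and x != "-")
    return LocalAlignment(
        query_id=a.id,
        subject_id=b.id,
        score=score,
        identity=matches / ncol if ncol else 0.0,
        aligned_len=ncol,
        q_span=q_span,
        s_span=s_span,
        evalue=ev,
        q_aligned=q_gapped,
        s_aligned=s_gapped,
    )


def _gapped_region(aln) -> tuple[str, str]:
    """Gapped strings of the locally aligned region only."""
    qa, sa = [], []
    qseq, sseq = aln.sequences
    (q_blocks, s_blocks) = aln.aligned
    for i, ((qs, qe), (ss, se)) in enumerate(zip(q_blocks, s_blocks)):
        if i:
            pqe, pse = q_blocks[i - 1][1], s_blocks[i - 1][1]
            qa.append(qseq[pqe:qs])
            qa.append("-" * (ss - pse))
            sa.append("-" * (qs - pqe))
            sa.append(sseq[pse:ss])
        qa.append(qseq[qs:qe])
        sa.append(sseq[ss:se])
    return "".join(qa), "".join(sa)


_PROTEIN_ALIGNER: Align.PairwiseAligner | None = None


def _protein_aligner() -> Align.PairwiseAligner:
    global _PROTEIN_ALIGNER
    if _PROTEIN_ALIGNER is None:
        al = Align.PairwiseAligner(mode="global")
        mat = substitution_matrices.load("BLOSUM62")
        al.substitution_matrix = mat
        al.open_gap_score = -12  # open 11 + extend 1 for the first gap base
        al.extend_gap_score = -1
        _PROTEIN_ALIGNER = al
    return _PROTEIN_ALIGNER


def global_align_protein(a: str, b: str) -> tuple[str, str]:
    """Needleman–Wunsch global protein alignment, BLOSUM62, affine 11/1.

    Deterministic: of the co-optimal tracebacks the aligner's first
    (diagonal-preferring) path is returned.
    """
    if not a or not b:
        raise ValueError("protein sequences must be non-empty")
    for s in (a, b):
        bad = set(s) - AA_ALPHABET
        if bad:
            raise ValueError(f"invalid amino-acid characters {sorted(bad)}")
    # BLOSUM62 has no '*' row; X scores are defined. Map '*' to X for scoring.
    aln = _protein_aligner().align(a.replace("*", "X"), b.replace("*", "X"))[0]
    qa, sa = str(aln[0]), str(aln[1])
    # restore original letters at ungapped positions
    qa = _restore(qa, a)
    sa = _restore(sa, b)
    return qa, sa


def _restore(gapped: str, original: str) -> str:
    out, i = [], 0
    for c in gapped:
        if c == "-":
            out.append(c)
        else:
            out.append(original[i])
            i += 1
    return "".join(out)


def codon_backtranslate(
    aligned_aa_a: str,
    aligned_aa_b: str,
    nt_a: str,
    nt_b: str,
    id_a: str = "a",
    id_b: str = "b",
) -> CodonAlignment:
    """Expand a protein alignment to codons from the source nucleotides.

    ``nt_a``/``nt_b`` are the in-frame coding regions whose translations
    equal the ungapped aligned amino acids; each amino-acid column becomes
    its source codon, each gap column becomes ``---``.
    """
    if len(aligned_aa_a) != len(aligned_aa_b):
        raise ValueError("aligned protein strings differ in length")
    for name, aa, nt in ((id_a, aligned_aa_a, nt_a), (id_b, aligned_aa_b, nt_b)):
        ungapped = aa.replace("-", "")
        expect = translate(nt)[: len(ungapped)]
        if expect != ungapped:
            col = next(
                (i for i, (x, y) in enumerate(zip(expect, ungapped)) if x != y),
                min(len(expect), len(ungapped)),
            )
            raise ValueError(
                f"{name}: protein/nucleotide disagreement at aligned residue {col}"
                f" ({expect[col:col+1]!r} vs {ungapped[col:col+1]!r})"
            )
    out_a = _expand(aligned_aa_a, nt_a)
    out_b = _expand(aligned_aa_b, nt_b)
    return CodonAlignment(id_a, id_b, out_a, out_b)


def _expand(aligned_aa: str, nt: str) -> str:
    codons, i = [], 0
    for c in aligned_aa:
        if c == "-":
            codons.append(GAP_CODON)
        else:
            codons.append(nt[3 * i : 3 * i + 3])
            i += 1
    return "".join(codons)
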