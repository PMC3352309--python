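"""Synonymous-rate (Ks) estimation on codon alignments.

Default estimator: Nei–Gojobori (1986) counting with Jukes–Cantor
multiple-hit correction. Synonymous sites per codon are the fraction of
single-base neighbours coding the same amino acid (changes creating stops
count as nonsynonymous); differences between codon pairs are resolved over
all minimal mutation paths, equally weighted, with paths through stop
codons excluded. A maximum-likelihood alternative under a Goldman–Yang-style
codon model (parameters t, kappa, omega; equal codon frequencies) is
provided for cross-checking and fidelity to CODEML-style pipelines.

``ks_for_pair`` runs the full per-pair path used by the homology stages:
local nucleotide alignment -> reading-frame selection -> global protein
alignment -> codon back-translation -> estimation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .aligner import (
    DEFAULT_NT_SCORING,
    CodonAlignment,
    LocalAlignment,
    ScoringScheme,
    codon_backtranslate,
    global_align_protein,
    local_align,
)
from .seq_io import CODON_TABLE, SENSE_CODONS, SequenceRecord, translate

BASES = "ACGT"
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class KsEstimate:
    """Per-pair substitution-rate estimate.

    ``ks``/``ka`` are substitutions per synonymous/nonsynonymous site, or
    None when the Jukes–Cantor correction is undefined (saturation,
    p >= 3/4). Site and difference counts are fractional per NG86.
    """

    s_sites: float
    n_sites: float
    sd: float
    nd: float
    method: str = "NG86"

    @property
    def p_s(self) -> float:
        return self.sd / self.s_sites if self.s_sites else 0.0

    @property
    def p_n(self) -> float:
        return self.nd / self.n_sites if self.n_sites else 0.0

    @property
    def saturated(self) -> bool:
        return self.p_s >= 0.75 or self.p_n >= 0.75

    @property
    def ks(self) -> float | None:
        return jukes_cantor(self.p_s)

    @property
    def ka(self) -> float | None:
        return jukes_cantor(self.p_n)


@dataclass(frozen=True)
class MLEstimate(KsEstimate):
    """ML estimate: counts kept for bookkeeping, rates from the codon model."""

    ks_ml: float | None = None
    ka_ml: float | None = None
    t: float = 0.0
    kappa: float = 2.0
    omega: float = 0.2
    converged: bool = True

    @property
    def saturated(self) -> bool:
        return self.ks_ml is None

    @property
    def ks(self) -> float | None:
        return self.ks_ml

    @property
    def ka(self) -> float | None:
        return self.ka_ml


def jukes_cantor(p: float) -> float | None:
    """JC69 distance −(3/4)·ln(1 − (4/3)p); None at or beyond saturation."""
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return None
    return -0.75 * math.log(arg) + 0.0  # + 0.0 normalizes -0.0


@lru_cache(maxsize=None)
def syn_site_fraction(codon: str) -> float:
    """NG86 synonymous site count of one codon (0..3).

    Per position, the fraction of the three possible single-base changes
    that are synonymous; changes creating stop codons count as
    nonsynonymous. Stop codons and codons containing N are rejected.
    """
    aa = CODON_TABLE.get(codon)
    if aa is None:
        raise ValueError(f"not a plain ACGT codon: {codon!r}")
    if aa == "*":
        raise ValueError(f"stop codon {codon!r} has no synonymous sites")
    total = 0.0
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if CODON_TABLE[mut] == aa:
                syn += 1
        total += syn / 3.0
    return total


@lru_cache(maxsize=None)
def codon_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) fractional differences between two codons.

    All minimal mutation paths (orderings of the differing positions) are
    weighted equally; paths passing through a stop codon are excluded. If
    every path is blocked by stops, all paths are used (rare; pinned
    convention).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            aa_cur, aa_nxt = CODON_TABLE[cur], CODON_TABLE[nxt]
            if aa_nxt == "*" and nxt != c2:
                through_stop = True
            if aa_cur == aa_nxt:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if through_stop else paths).append((sd, nd))
    use = paths or blocked
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


def _counted_pairs(alignment: CodonAlignment) -> list[tuple[str, str]]:
    from .aligner import _countable

    return [
        (ca, cb)
        for ca, cb in alignment.codon_pairs()
        if _countable(ca) and _countable(cb)
    ]


def ks_ng86(alignment: CodonAlignment) -> KsEstimate:
    """NG86 + Jukes–Cantor Ks/Ka over the countable codon columns.

    S is the mean of the two sequences' synonymous-site totals;
    N = 3·columns − S. Columns with gaps, Ns or stops are excluded.
    """
    pairs = _counted_pairs(alignment)
    if not pairs:
        raise ValueError("no countable codon columns")
    s_a = sum(syn_site_fraction(ca) for ca, _ in pairs)
    s_b = sum(syn_site_fraction(cb) for _, cb in pairs)
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * len(pairs) - s_sites
    sd = nd = 0.0
    for ca, cb in pairs:
        d_s, d_n = codon_pair_differences(ca, cb)
        sd += d_s
        nd += d_n
    return KsEstimate(s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd)


# ---------------------------------------------------------------------------
# ML estimator (Goldman–Yang-style codon model, equal codon frequencies)

_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


@lru_cache(maxsize=None)
def _model_structure() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sparse structure of single-nt codon exchanges among sense codons.

    Returns (pairs_ij, is_transition, is_synonymous) over ordered pairs.
    """
    rows, ts, syn = [], [], []
    for i, c1 in enumerate(SENSE_CODONS):
        for j, c2 in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [p for p in range(3) if c1[p] != c2[p]]
            if len(diff) != 1:
                continue
            p = diff[0]
            rows.append((i, j))
            ts.append((c1[p], c2[p]) in TRANSITIONS)
            syn.append(CODON_TABLE[c1] == CODON_TABLE[c2])
    return (
        np.array(rows, dtype=np.intp),
        np.array(ts, dtype=bool),
        np.array(syn, dtype=bool),
    )


def _rate_matrix(kappa: float, omega: float) -> tuple[np.ndarray, float, float]:
    """Scaled GY94 rate matrix and (synonymous flux, syn site fraction).

    Q is scaled to one expected codon substitution per unit t. Returns
    (Q, f_syn, rho_s1) where f_syn is the synonymous fraction of the flux
    under (kappa, omega) and rho_s1 the same under omega = 1 (mutational
    opportunity, defining synonymous sites as 3·rho_s1 per codon).
    """
    n = len(SENSE_CODONS)
    pairs, ts, syn = _model_structure()
    rate = np.where(ts, kappa, 1.0) * np.where(syn, 1.0, omega)
    Q = np.zeros((n, n))
    Q[pairs[:, 0], pairs[:, 1]] = rate
    total_flux = rate.sum() / n  # pi_i = 1/n
    Q /= total_flux
    np.fill_diagonal(Q, -Q.sum(axis=1))
    f_syn = rate[syn].sum() / rate.sum()
    rate1 = np.where(ts, kappa, 1.0)
    rho_s1 = rate1[syn].sum() / rate1.sum()
    return Q, f_syn, rho_s1


def ks_ml(alignment: CodonAlignment) -> MLEstimate:
    """Pairwise ML Ks/Ka under the equal-frequency codon model.

    Optimizes (t, kappa, omega) numerically; Ks = t·f_syn/(3·rho_s1) where
    f_syn is the synonymous flux fraction and 3·rho_s1 the synonymous sites
    per codon under the mutational (omega = 1) process. Deterministic for a
    given alignment. Non-convergence is reported on the estimate.
    """
    pairs = _counted_pairs(alignment)
    if not pairs:
        raise ValueError("no countable codon columns")
    counts = np.zeros((len(SENSE_CODONS), len(SENSE_CODONS)))
    for ca, cb in pairs:
        counts[_CODON_INDEX[ca], _CODON_INDEX[cb]] += 1.0

    base = ks_ng86(alignment)
    if base.sd + base.nd == 0:
        return MLEstimate(
            base.s_sites, base.n_sites, 0.0, 0.0, method="ML",
            ks_ml=0.0, ka_ml=0.0, t=0.0,
        )

    def nll(x: np.ndarray) -> float:
        t, kappa, omega = np.exp(x)
        Q, _, _ = _rate_matrix(kappa, omega)
        P = expm(Q * t)
        np.clip(P, 1e-300, None, out=P)
        return -float((counts * np.log(P)).sum())

    t0 = max((base.sd + base.nd) / len(pairs), 1e-3)
    res = minimize(
        nll,
        x0=np.log([t0, 2.0, 0.3]),
        method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 2000},
    )
    t, kappa, omega = np.exp(res.x)
    _, f_syn, rho_s1 = _rate_matrix(kappa, omega)
    ks_val = t * f_syn / (3.0 * rho_s1)
    ka_val = t * (1.0 - f_syn) / (3.0 * (1.0 - rho_s1))
    return MLEstimate(
        base.s_sites, base.n_sites, base.sd, base.nd, method="ML",
        ks_ml=float(ks_val), ka_ml=float(ka_val),
        t=float(t), kappa=float(kappa), omega=float(omega),
        converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# Full per-pair estimation path and the distribution filters


def pick_frame(region: str) -> int:
    """Reading frame (0/1/2) of a nucleotide region: fewest stop codons,
    ties to the lowest frame. Terminal stops do not count."""
    best_frame, best_stops = 0, None
    for f in range(3):
        aa = translate(region, f)
        stops = aa[:-1].count("*") if aa else 0
        if best_stops is None or stops < best_stops:
            best_frame, best_stops = f, stops
    return best_frame


@dataclass(frozen=True)
class PairKs:
    """Result of the full estimation path for one homologous pair."""

    id_a: str
    id_b: str
    estimate: KsEstimate
    aligned_aa: int  # protein-alignment columns with both sides ungapped
    local: LocalAlignment


def ks_for_pair(
    a: SequenceRecord,
    b: SequenceRecord,
    method: str = "ng86",
    scoring: ScoringScheme = DEFAULT_NT_SCORING,
    precomputed_local: LocalAlignment | None = None,
) -> PairKs | None:
    """Local-align, frame-select, protein-align, back-translate, estimate.

    Returns None when no positive-scoring local alignment exists or the
    aligned regions leave no countable codon column.
    """
    aln = precomputed_local
    if aln is None or not aln.q_aligned:
        aln = local_align(a, b, scoring)
    if aln is None:
        return None
    region_a = a.seq[aln.q_span[0] : aln.q_span[1]]
    region_b = b.seq[aln.s_span[0] : aln.s_span[1]]
    fa, fb = pick_frame(region_a), pick_frame(region_b)
    nt_a = region_a[fa : fa + 3 * ((len(region_a) - fa) // 3)]
    nt_b = region_b[fb : fb + 3 * ((len(region_b) - fb) // 3)]
    aa_a, aa_b = translate(nt_a), translate(nt_b)
    if not aa_a or not aa_b:
        return None
    ga, gb = global_align_protein(aa_a, aa_b)
    codon_aln = codon_backtranslate(ga, gb, nt_a, nt_b, a.id, b.id)
    aligned_aa = sum(1 for x, y in zip(ga, gb) if x != "-" and y != "-")
    try:
        est = ks_ml(codon_aln) if method == "ml" else ks_ng86(codon_aln)
    except ValueError:
        return None
    return PairKs(a.id, b.id, est, aligned_aa, aln)


def filter_pairs(
    pairs: list[PairKs], min_aa: int = 30, max_ks: float = 2.0
) -> list[PairKs]:
    """Keep pairs aligned over more than ``min_aa`` residues with
    unsaturated Ks strictly below ``max_ks`` (both bounds strict)."""
    out = []
    for p in pairs:
        if p.aligned_aa <= min_aa:
            continue
        if p.estimate.saturated or p.estimate.ks is None:
            continue
        if p.estimate.ks >= max_ks:
            continue
        out.append(p)
    return out
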