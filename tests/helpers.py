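"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles — plain
enumeration, no caching, no shared code with the package internals — so it
can serve as an independent cross-check.
"""

from __future__ import annotations

import itertools
import math

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_syn_sites(codon: str) -> float:
    """Synonymous site count by exhaustive neighbour enumeration."""
    aa = GENETIC_CODE[codon]
    assert aa != "*"
    total = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if GENETIC_CODE[mutant] == aa:
                total += 1.0 / 3.0
    return total


def oracle_pair_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Fractional (syn, nonsyn) differences over minimal mutation paths,
    stop-through paths excluded (all paths if every one is blocked)."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    clean, blocked = [], []
    for order in itertools.permutations(positions):
        current = c1
        sd = nd = 0.0
        hits_stop = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if GENETIC_CODE[nxt] == "*" and nxt != c2:
                hits_stop = True
            if GENETIC_CODE[current] == GENETIC_CODE[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        (blocked if hits_stop else clean).append((sd, nd))
    pool = clean if clean else blocked
    return (
        sum(x for x, _ in pool) / len(pool),
        sum(y for _, y in pool) / len(pool),
    )


def oracle_ng86(codons_a: list[str], codons_b: list[str]):
    """Full NG86+JC on paired codon lists (no gaps/N/stops expected).

    Returns (S, N, sd, nd, ks, ka); ks/ka are None at saturation.
    """
    s_a = sum(oracle_syn_sites(c) for c in codons_a)
    s_b = sum(oracle_syn_sites(c) for c in codons_b)
    S = (s_a + s_b) / 2.0
    N = 3.0 * len(codons_a) - S
    sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        d_s, d_n = oracle_pair_diffs(ca, cb)
        sd += d_s
        nd += d_n

    def jc(p: float):
        arg = 1.0 - 4.0 * p / 3.0
        return None if arg <= 0 else -0.75 * math.log(arg)

    return S, N, sd, nd, jc(sd / S), jc(nd / N)


def oracle_longest_common_substring(a: str, b: str) -> int:
    """O(len(a)·len(b)) dynamic-programming longest common substring."""
    best = 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


def oracle_affine_sw(a: str, b: str, match=1, mismatch=-2, gap_open=5, gap_extend=2):
    """Affine-gap Smith–Waterman best score (Gotoh); gap(k) = open + k·ext."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (left)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (up)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(
                H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend
            )
            F[i][j] = max(
                H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend
            )
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def oracle_fisher_two_sided(k: int, n1: int, K: int, n2: int) -> float:
    """Two-sided Fisher p for table [[k, n1-k], [K, n2-K]] by enumerating
    hypergeometric outcomes with point probability <= the observed one."""
    total = n1 + n2
    drawn = k + K  # margin: total 'successes'

    def log_comb(n, r):
        return math.lgamma(n + 1) - math.lgamma(r + 1) - math.lgamma(n - r + 1)

    def pmf(x):
        if x < 0 or x > n1 or drawn - x < 0 or drawn - x > n2:
            return 0.0
        return math.exp(
            log_comb(n1, x) + log_comb(n2, drawn - x) - log_comb(total, drawn)
        )

    p_obs = pmf(k)
    return sum(p for x in range(drawn + 1) if (p := pmf(x)) <= p_obs * (1 + 1e-9))


def random_codons(rng, n: int) -> list[str]:
    sense = [c for c in GENETIC_CODE if GENETIC_CODE[c] != "*"]
    return [sense[i] for i in rng.integers(0, len(sense), size=n)]
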