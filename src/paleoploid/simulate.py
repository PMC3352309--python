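"""Synthetic speciation + WGD transcriptome scenarios with ground truth.

Each gene family starts from one random ancestral coding sequence. The
ancestor splits into two lineages (A, carp-like; B, zebrafish-like) at a
speciation dated ``speciation_ks`` Ks units in the pairwise scale; lineage
A then undergoes a whole-genome duplication dated ``wgd_ks``, whose second
copy survives with probability ``retention``. Older duplicate turnover is
emulated by background duplications whose pairwise Ks is exponential with
rate ``background_decay`` — a monotonically decaying age distribution with
no mode. Splice-variant redundancy adds, per ``variant_rate``, a twin
contig sharing an identical block of >= 100 bp with unique random flanks.

Divergence is parameterized directly in Ks units: sequences evolve under a
continuous-time codon process whose synonymous events occur at rate 1 per
synonymous site per unit time (nonsynonymous events at relative rate
``omega``; changes creating stops rejected), so evolving for duration d
yields an expected NG86+JC-estimated Ks of d between the endpoint and the
ancestor. Branch durations are laid out so that *pairwise* Ks values hit
their targets: each lineage receives (speciation_ks − wgd_ks)/2 before the
WGD and each WGD copy wgd_ks/2 after it, making ortholog pairs diverge by
speciation_ks and WGD pairs by wgd_ks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from .peaks import ClockRate, ks_to_mya
from .seq_io import CODON_TABLE, SENSE_CODONS, SequenceRecord, write_fasta

BASES = "ACGT"


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one simulated scenario."""

    n_families: int = 300
    codons_mean: float = 300.0  # log-normal mean codon count per gene
    codons_sigma: float = 0.25  # log-scale spread
    codons_min: int = 80
    speciation_ks: float = 0.42
    wgd_ks: float = 0.03
    omega: float = 0.1
    retention: float = 0.4
    background_decay: float = 1.0  # exponential rate of old-duplicate Ks
    background_rate: float = 0.3  # expected background duplicates per lineage
    variant_rate: float = 0.1
    seed: int = 0
    clock: ClockRate = field(default_factory=ClockRate)

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.speciation_ks < 0 or self.wgd_ks < 0:
            raise ValueError("Ks targets must be >= 0")
        if self.wgd_ks > self.speciation_ks and self.speciation_ks > 0:
            raise ValueError("wgd_ks must not exceed speciation_ks")
        for name in ("retention", "variant_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.background_decay <= 0 or self.background_rate < 0:
            raise ValueError("background parameters must be positive")


@dataclass
class TruthTable:
    """Ground truth emitted alongside the simulated sequence sets."""

    orthologs: pd.DataFrame  # id_a, id_b, true_ks
    paralog_pairs: pd.DataFrame  # set, id_a, id_b, true_ks, origin
    families: pd.DataFrame  # set, family_id, member_id
    events: pd.DataFrame  # set, family_id, type, true_ks, true_time_mya
    variants: pd.DataFrame  # set, source_id, variant_id, block_length
    seed: int = 0

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("orthologs", "paralog_pairs", "families", "events", "variants"):
            df: pd.DataFrame = getattr(self, name)
            df.to_csv(out / f"truth_{name}.tsv", sep="\t", index=False,
                      float_format="%.6g")


@dataclass
class SimulationResult:
    set_a: list[SequenceRecord]
    set_b: list[SequenceRecord]
    truth: TruthTable
    config: ScenarioConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.set_a, out / "carp_like.fa")
        write_fasta(self.set_b, out / "zebrafish_like.fa")
        self.truth.write(out)


# ---------------------------------------------------------------------------
# codon-level evolution


@lru_cache(maxsize=None)
def _sim_generator(omega: float) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the symmetric codon-process generator.

    Off-diagonal rates between single-base-differing sense codons are 1/3
    (synonymous) or omega/3 (nonsynonymous); stop-codon moves are absent.
    The generator is symmetric, so the stationary distribution is uniform
    over the 61 sense codons — matching how ancestors are generated, the
    composition stays stationary along every branch.
    """
    n = len(SENSE_CODONS)
    idx = {c: i for i, c in enumerate(SENSE_CODONS)}
    Q = np.zeros((n, n))
    for i, c in enumerate(SENSE_CODONS):
        for mut, syn in _neighbours(c):
            Q[i, idx[mut]] = (1.0 if syn else omega) / 3.0
    np.fill_diagonal(Q, -Q.sum(axis=1))
    w, V = np.linalg.eigh(Q)
    return w, V


@lru_cache(maxsize=None)
def _ng86_tables() -> tuple[np.ndarray, float]:
    """(61×61 pairwise synonymous-difference matrix, mean syn sites/codon)."""
    from .ks import codon_pair_differences, syn_site_fraction

    n = len(SENSE_CODONS)
    sd = np.zeros((n, n))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            sd[i, j] = codon_pair_differences(ci, cj)[0]
    s_mean = float(np.mean([syn_site_fraction(c) for c in SENSE_CODONS]))
    return sd, s_mean


def expected_ng86_ks(duration: float, omega: float) -> float:
    """Expected NG86+JC Ks of an (ancestor, descendant) pair after evolving
    for ``duration`` units of process time (long-gene limit)."""
    from .ks import jukes_cantor

    if duration == 0.0:
        return 0.0
    w, V = _sim_generator(omega)
    P = (V * np.exp(w * duration)) @ V.T
    sd, s_mean = _ng86_tables()
    e_sd = float((P * sd).sum()) / len(SENSE_CODONS)
    ks = jukes_cantor(e_sd / s_mean)
    return ks if ks is not None else float("inf")


@lru_cache(maxsize=4096)
def duration_for_ks(ks_target: float, omega: float) -> float:
    """Process-time duration whose expected NG86-estimated Ks is the target.

    Near zero the expectation equals the duration; at larger divergences
    the heterogeneous site structure (two-fold vs four-fold degeneracy)
    departs from the Jukes–Cantor idealization and the inversion absorbs
    the difference. Durations compose additively along branches, so a
    scenario lays out branch durations from pairwise targets.
    """
    from scipy.optimize import brentq

    if ks_target == 0.0:
        return 0.0
    hi = 4.0 * ks_target + 0.05
    while expected_ng86_ks(hi, omega) < ks_target:
        hi *= 2.0
        if hi > 100.0:
            raise ValueError(f"ks_target {ks_target} beyond invertible range")
    return float(
        brentq(lambda t: expected_ng86_ks(t, omega) - ks_target, 0.0, hi, xtol=1e-10)
    )


@lru_cache(maxsize=None)
def _neighbours(codon: str) -> tuple[tuple[str, bool], ...]:
    """Non-stop single-base neighbours of a sense codon: (codon, is_syn)."""
    aa = CODON_TABLE[codon]
    out = []
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if CODON_TABLE[mut] == "*":
                continue
            out.append((mut, CODON_TABLE[mut] == aa))
    return tuple(out)


def _codon_rate(codon: str, omega: float) -> float:
    nb = _neighbours(codon)
    return sum((1.0 if syn else omega) for _, syn in nb) / 3.0


def generate_ancestral_cds(
    n: int, codons: int, rng: np.random.Generator
) -> list[SequenceRecord]:
    """Random stop-free coding sequences starting with ATG."""
    if n < 1 or codons < 1:
        raise ValueError("n and codons must be >= 1")
    sense = [c for c in SENSE_CODONS if c != "ATG"]
    records = []
    for i in range(n):
        body = rng.choice(sense, size=codons - 1)
        records.append(SequenceRecord(f"G{i + 1:04d}", "ATG" + "".join(body)))
    return records


def evolve_for_duration(
    seq: str, duration: float, omega: float, rng: np.random.Generator
) -> str:
    """Gillespie simulation of the codon process for raw process time."""
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if len(seq) % 3:
        raise ValueError("sequence length must be a multiple of 3")
    if duration == 0:
        return seq
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for c in codons:
        if CODON_TABLE.get(c, "*") == "*":
            raise ValueError(f"input contains a stop or invalid codon {c!r}")
    rates = np.array([_codon_rate(c, omega) for c in codons])
    t = 0.0
    total = rates.sum()
    while True:
        t += rng.exponential(1.0 / total)
        if t > duration:
            break
        i = rng.choice(len(codons), p=rates / total)
        nb = _neighbours(codons[i])
        weights = np.array([(1.0 if syn else omega) for _, syn in nb])
        j = rng.choice(len(nb), p=weights / weights.sum())
        codons[i] = nb[j][0]
        new_rate = _codon_rate(codons[i], omega)
        total += new_rate - rates[i]
        rates[i] = new_rate
    return "".join(codons)


def mutate_to_ks(
    seq: str, ks_target: float, omega: float, rng: np.random.Generator
) -> str:
    """Evolve a stop-free CDS so the (input, output) pair measures
    ``ks_target`` on the NG86+JC scale, in expectation.

    Multiple hits arise naturally in the underlying process and are
    compensated by the calibrated duration (see ``duration_for_ks``).
    """
    if ks_target < 0:
        raise ValueError("ks_target must be >= 0")
    if ks_target > 3.0:
        warnings.warn(
            f"ks_target {ks_target} is beyond reliable estimation (saturation)",
            stacklevel=2,
        )
    return evolve_for_duration(
        seq, duration_for_ks(ks_target, omega), omega, rng
    )


# ---------------------------------------------------------------------------
# scenario assembly


def _gene_length(cfg: ScenarioConfig, rng: np.random.Generator) -> int:
    mu = np.log(cfg.codons_mean) - cfg.codons_sigma**2 / 2.0
    return max(cfg.codons_min, int(round(rng.lognormal(mu, cfg.codons_sigma))))


def _make_variant(
    source: SequenceRecord, rng: np.random.Generator, min_block: int = 120
) -> tuple[SequenceRecord, int]:
    """A splice-variant twin: identical internal block + unique flanks."""
    L = source.length
    block_len = int(rng.integers(min_block, min(3 * min_block, L) + 1))
    start = int(rng.integers(0, L - block_len + 1))
    block = source.seq[start : start + block_len]
    flank5 = "".join(rng.choice(list(BASES), size=int(rng.integers(30, 121))))
    flank3 = "".join(rng.choice(list(BASES), size=int(rng.integers(30, 121))))
    return SequenceRecord(source.id + "v", flank5 + block + flank3), block_len


def simulate_scenario(config: ScenarioConfig) -> SimulationResult:
    """Generate (set_a, set_b, truth) for one speciation + WGD scenario."""
    rng = np.random.default_rng(config.seed)
    # branch durations in process time, from pairwise Ks targets: ortholog
    # pairs span u(speciation_ks), WGD pairs u(wgd_ks)
    u_spec = duration_for_ks(config.speciation_ks, config.omega)
    u_wgd = duration_for_ks(config.wgd_ks, config.omega)
    pre_wgd = max(u_spec - u_wgd, 0.0) / 2.0
    post_wgd = u_wgd / 2.0
    b_branch = u_spec / 2.0

    set_a: list[SequenceRecord] = []
    set_b: list[SequenceRecord] = []
    orthologs, paralogs, fam_rows, events, variants = [], [], [], [], []

    for i in range(1, config.n_families + 1):
        codons = _gene_length(config, rng)
        anc = generate_ancestral_cds(1, codons, rng)[0].seq
        b_seq = evolve_for_duration(anc, b_branch, config.omega, rng)
        a_base = evolve_for_duration(anc, pre_wgd, config.omega, rng)
        a1 = SequenceRecord(
            f"A{i:04d}a", evolve_for_duration(a_base, post_wgd, config.omega, rng)
        )
        b1 = SequenceRecord(f"B{i:04d}", b_seq)
        set_a.append(a1)
        set_b.append(b1)
        orthologs.append((a1.id, b1.id, config.speciation_ks))

        a_members = [a1.id]
        if rng.random() < config.retention:
            a2 = SequenceRecord(
                f"A{i:04d}b", evolve_for_duration(a_base, post_wgd, config.omega, rng)
            )
            set_a.append(a2)
            a_members.append(a2.id)
            orthologs.append((a2.id, b1.id, config.speciation_ks))
            paralogs.append(("A", a1.id, a2.id, config.wgd_ks, "wgd"))
            events.append(("A", f"FA{i:04d}", "wgd", config.wgd_ks))

        b_members = [b1.id]
        for lineage, members, source_rec, out_set in (
            ("A", a_members, a1, set_a),
            ("B", b_members, b1, set_b),
        ):
            n_bg = rng.poisson(config.background_rate)
            for j in range(1, n_bg + 1):
                dup_ks = float(rng.exponential(1.0 / config.background_decay))
                while dup_ks >= 2.4:
                    dup_ks = float(rng.exponential(1.0 / config.background_decay))
                dup = SequenceRecord(
                    f"{lineage}{i:04d}x{j}",
                    mutate_to_ks(source_rec.seq, dup_ks, config.omega, rng),
                )
                out_set.append(dup)
                members.append(dup.id)
                paralogs.append(
                    (lineage, source_rec.id, dup.id, dup_ks, "background")
                )
                events.append((lineage, f"F{lineage}{i:04d}", "background", dup_ks))

        for lineage, members in (("A", a_members), ("B", b_members)):
            if len(members) >= 2:
                for m in members:
                    fam_rows.append((lineage, f"F{lineage}{i:04d}", m))

        events.append(("AB", f"FA{i:04d}", "speciation", config.speciation_ks))

        for lineage, source_rec, out_set in (("A", a1, set_a), ("B", b1, set_b)):
            if rng.random() < config.variant_rate:
                var, block_len = _make_variant(source_rec, rng)
                out_set.append(var)
                variants.append((lineage, source_rec.id, var.id, block_len))

    truth = TruthTable(
        orthologs=pd.DataFrame(orthologs, columns=["id_a", "id_b", "true_ks"]),
        paralog_pairs=pd.DataFrame(
            paralogs, columns=["set", "id_a", "id_b", "true_ks", "origin"]
        ),
        families=pd.DataFrame(fam_rows, columns=["set", "family_id", "member_id"]),
        events=pd.DataFrame(
            [
                (s, f, t, k, ks_to_mya(k, config.clock))
                for s, f, t, k in events
            ],
            columns=["set", "family_id", "type", "true_ks", "true_time_mya"],
        ),
        variants=pd.DataFrame(
            variants, columns=["set", "source_id", "variant_id", "block_length"]
        ),
        seed=config.seed,
    )
    set_a.sort(key=lambda r: r.id)
    set_b.sort(key=lambda r: r.id)
    return SimulationResult(set_a, set_b, truth, config)
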