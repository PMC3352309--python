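# paleoploid

Dating whole-genome duplications (WGD) and speciations from transcriptome
data, for researchers studying paleopolyploidy in species without a genome
assembly — e.g. the extra (4R) duplication in common carp relative to
zebrafish.

## What it does

Starting from two sets of assembled transcript contigs (one per species),
the pipeline:

1. **collapses splice-variant redundancy** — contigs whose best local
   alignment is 100% identical over ≥ 100 bp are treated as variants of one
   gene and the longest is kept;
2. **finds orthologs** between the two species by reciprocal best hit
   (E ≤ 1e−20, aligned over ≥ 300 bp) and **paralogs** within each species
   (best local alignment covering ≥ 70% of the shorter sequence);
3. **estimates Ks** — synonymous substitutions per synonymous site — for
   every pair on protein-guided codon alignments, by Nei–Gojobori (1986)
   counting with Jukes–Cantor correction (a Goldman–Yang-style pairwise ML
   estimator is available with `--method ml`);
4. **deduplicates duplication events**: paralog pairs are grouped into
   single-linkage gene families; within each family of *n* members,
   agglomerative clustering on the median cross-cluster Ks dates exactly
   *n − 1* duplication events;
5. **detects modes** of the Ks age distributions (0.01-unit bins, Gaussian
   KDE) and converts them to absolute times with a synonymous molecular
   clock, by default T = Ks / r with r = 3.51 × 10⁻⁹
   substitutions/site/year;
6. optionally **compares annotation composition** between the species
   (per-term Pearson χ², per-pathway Fisher exact + Benjamini–Hochberg).

A burst of paralogs at one age — a secondary peak in the paranome Ks
distribution riding on the exponentially decaying background of ordinary
duplicate turnover — is the signature of a WGD; the peak location divided
by the clock rate dates it. The ortholog Ks mode dates the speciation the
same way.

A fully ground-truthed **scenario simulator** generates
speciation + WGD + background-duplication + splice-variant transcript sets
so every stage is testable without any external data.

## Worked example

```bash
paleoploid simulate --seed 7 --n-families 300 --out-dir sim/
paleoploid pipeline --a sim/carp_like.fa --b sim/zebrafish_like.fa --out-dir run/
```

The second command prints (seed 7):

```
{
  "ortholog_pairs": 300,
  "ortholog_pairs_filtered": 300,
  "ks_mode": 0.40691826210706494,
  "time_mya": 115.9311288054316
}
set A: secondary paralog peak: True
set B: secondary paralog peak: False
```

and `run/report.json` records, for the carp-like set,
`"duplication_mode_ks": 0.028` and `"duplication_time_mya": 7.98`: the
pipeline recovers the simulated speciation age (Ks 0.42 ≈ 120 MYA) and the
simulated duplication age (Ks 0.03 ≈ 8.5 MYA) from raw sequences, and
correctly reports no duplication peak in the zebrafish-like set, which was
simulated without a WGD. Every intermediate (retained contigs, paralog
pairs, families, per-family event Ks) is written as TSV next to the
report, so any stage can be re-run or audited on its own.

Library use mirrors the CLI: `simulate_scenario`, `find_redundant_pairs` /
`collapse`, `find_orthologs` / `find_paralogs` / `build_families`,
`ks_for_pair` / `ks_ng86` / `ks_ml`, `date_family` / `collect_events`,
`make_histogram` / `detect_peaks` / `ks_to_time`, `run_pipeline`.

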