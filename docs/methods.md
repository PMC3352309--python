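# Methods

## The inference

Synonymous substitutions accumulate approximately clock-like, so the Ks of
a homologous sequence pair is a proxy for the age of its divergence. Three
distributions carry the signal:

- **ortholog Ks** (one species vs the other): unimodal around the
  speciation age;
- **paralog-event Ks** (within one species, after event deduplication): a
  background of continuous gene duplication and loss — density decaying
  roughly exponentially with age — plus, if a WGD occurred, a burst of
  events at one age forming a secondary mode;
- a species without a recent WGD shows the decaying background only.

A mode at Ks\* converts to an absolute age through a synonymous clock rate
r. The default convention is **T = Ks\*/r** with r = 3.51 × 10⁻⁹
substitutions per synonymous site per year. The textbook alternative for a
symmetric pairwise divergence, T = Ks\*/(2r), is available
(`convention: halved`); the direct convention is the default because it is
the arithmetic under which the reference results this pipeline reproduces
were derived (0.42 → ≈120 MY; 0.02–0.04 → 5.70–11.40 MY). Note the
recomputed duplication window differs from the published "5.6 to 11.3 MYA"
by ~1–2%; the exact Ks endpoints behind those printed values are not
recoverable, so the recomputed window is reported as-is.

## Stage conventions and parameters

**Redundancy collapse** (`min_block=100`, `min_identity=1.0`). Two contigs
are splice variants of one gene iff their *best-scoring local alignment*
is ≥ `min_identity` identical over ≥ `min_block` columns. The distinction
matters: a recently duplicated gene pair at ~1% divergence almost always
still contains a ≥ 100 bp exact run, but its best alignment is one long
mismatch-carrying alignment, so it is correctly kept, while true variants
(identical exon blocks with unique flanks) align only over the shared
block at 100% identity and are collapsed. Candidates are found by a
31-mer anchor scan with maximal exact extension (an exact algorithm for
the longest shared run, and a provably necessary condition for a
100%-identity alignment); only candidates are verified by full DP.
Components are collapsed by single linkage keeping the longest member
(ties: lexicographically smallest id). Matches are evaluated in the given
orientation only; both thresholds are inclusive (≥).

**Alignment.** All DP is exact (Biopython's PairwiseAligner): local
nucleotide alignment at +1/−2 with affine gaps (open 5, extend 2; a gap of
length k costs 5 + 2k), global protein alignment under BLOSUM62 (open 11,
extend 1). E-values follow Karlin–Altschul, E = K·m·n·e^(−λS), with λ
solved from the scoring scheme and background composition (λ ≈ 1.33 for
+1/−2 uniform) and K = 0.621 as a configurable constant. Instead of an
approximate seeded alignment mode, all-against-all searches prescreen
candidate pairs by shared 12-mers (≥ 2 hits) and align only those — every
reported score is an exact DP score. The prescreen's sensitivity limit
(roughly 40% nucleotide divergence) lies far beyond the Ks < 2 analysis
window (~60% identity), so it does not truncate the usable age range.

**Orthologs**: reciprocal best hit, ties broken by (score, E-value, id);
pair kept iff E ≤ 1e−20 both ways and the best alignment spans ≥ 300
columns. **Paralogs**: best local alignment covering ≥ 70% of the shorter
sequence (span on the shorter sequence / its length), plus an E ≤ 1e−10
gate to suppress spurious short-coverage hits — the source procedure
states no explicit paralog E-value cutoff, so the gate is a documented,
configurable default. "Over 300 bp"/"over 70%" are read inclusively.

**Ks estimation** (default NG86 + JC). Per-pair path: local nucleotide
alignment → aligned regions extracted → reading frame chosen per region
(fewest internal stops, ties to the lowest frame) → global protein
alignment → codon back-translation (gaps in whole-codon units) → counting
over columns with both codons ungapped, stop-free and N-free. Synonymous
sites per codon are the fraction of the nine single-base neighbours coding
the same amino acid; **changes creating stops count as nonsynonymous**.
Pairwise differences are averaged over all minimal mutation paths, equally
weighted, excluding paths through stops (if every path is blocked — rare —
all paths are used). S is the mean of the two sequences' site totals;
p = sd/S is corrected as ks = −(3/4)·ln(1 − 4p/3), undefined (saturated,
pair flagged and excluded) when the argument is ≤ 0. NG86 was chosen as
the default over a codon-model ML estimator because it is exactly
reproducible by independent enumeration (the test suite holds it to 1e−9
against a brute-force oracle); the ML estimator (GY94-style: parameters t,
κ, ω; equal codon frequencies; Nelder–Mead on log-parameters; Ks =
t·f_syn/(3·ρ_s1) with ρ_s1 the synonymous flux fraction at ω = 1) is
selectable and agrees with NG86 within 0.05 for Ks ≤ 0.3 in simulation.
Distribution filters, applied strictly: aligned region > 30 amino acids
and Ks < 2.

**Families and events.** Paralog pairs form single-linkage families
(≥ 2 members). The Ks matrix is computed for *all* member pairs, not only
detected edges; entries failing alignment, the 30-aa filter, or saturation
are missing. Events: repeatedly merge the two clusters with the smallest
median cross-pair Ks (even-count medians: mean of the central two;
missing values excluded; ties: lexicographically smallest combined member
list; merges with no datable cross-pair are deferred to the end and
emitted undated), one event per merge, n − 1 per family. Event Ks ≥ 2 are
excluded from the histogram but counted in the summary.

**Peak detection.** Histograms use left-closed 0.01-Ks bins on [0, 2).
Modes are KDE local maxima with prominence ≥ 5% of the global density
maximum. Two bandwidth regimes: the paralog-event distribution uses a
fixed 0.01 kernel (a very recent WGD mode sits a few bin widths from 0 and
needs that resolution); the ortholog distribution uses Scott's rule, since
a fixed narrow kernel undersmooths a smooth unimodal sample and jitters
the mode location. A monotone pile-up against Ks = 0 is reported as a
*boundary* feature, never as a duplication mode. The duplication verdict
additionally requires the mode to hold ≥ 10% of all in-range events within
± 2 bandwidths: a sparse exponential background under a 0.01 kernel
produces prominence-passing sampling wiggles, and the mass requirement is
what separates a genuine synchronous burst from them. Mode significance is
reported descriptively (prominence, mass), not as a hypothesis test.

## The simulator

`simulate_scenario` emulates: one ancestral coding sequence per family
(random sense codons after ATG; lengths log-normal, mean 300 codons,
σ = 0.25, floor 80 — spread exercises the shorter-sequence coverage
rule); speciation into lineages A and B; a WGD on lineage A with per-copy
retention 0.4; background duplications (Poisson, mean 0.3 per lineage per
family) with pairwise Ks drawn from an exponential with rate 1 — the
no-mode decaying background; splice-variant twins (rate 0.1) built as an
identical 120–360 bp block from the source contig flanked by 30–120 nt of
unique sequence, the exact structure the redundancy rule detects.

Sequences evolve by a Gillespie simulation of a codon process with
synonymous events at rate 1 per synonymous site, nonsynonymous events at
relative rate ω = 0.1, and stop-creating events forbidden. The generator
is symmetric, so the uniform codon distribution used for ancestors is
stationary. Divergence is parameterized in Ks units, not years: a branch
duration is obtained by inverting the *analytically computed* expected
NG86 estimate (via the eigendecomposition of the 61-state generator), so
that a pair separated by duration u(ks) measures ks in expectation —
multiple hits, path heterogeneity and the two-fold/four-fold site mixture
are thereby compensated exactly in the long-gene limit, and branch
durations compose additively (lineage A evolves u(0.42)/2 − u(0.03)/2
before the WGD and each copy u(0.03)/2 after it, so ortholog pairs measure
0.42 and WGD pairs 0.03). Remaining finite-length effects (Jensen-type
inflation through the convex JC transform) keep the *mean* estimate within
a few percent of target (held under 10% by a 500-replicate calibration
test) while leaving the distribution *mode* — what the pipeline measures —
essentially on target.

What the simulator does **not** emulate: indels inside coding sequence
(gaps only enter through variant flanks), codon-usage and composition
bias, transition/transversion bias (the process is κ = 1 by design, so
NG86's equal-weighting assumption holds exactly — real data violate it and
NG86 is known to be biased under strong κ), assembly chimerism, and
sequencing error. Passing recovery tests therefore demonstrate the
pipeline's correctness under its own model assumptions, not robustness to
those real-data artifacts.

With WGD retention, a B-lineage gene has up to two co-orthologs in A while
RBH emits an injective matching; ortholog recall is therefore measured as
the fraction of families recovering at least one correct pair (precision
stays per-pair).

## Problem sizes and determinism

The recovery experiment uses 300 families (~530 carp-like and ~420
zebrafish-like contigs), which puts ~300 ortholog pairs and ~200 dated
duplication events under the mode detectors; the NG86 oracle comparison
uses 1,000 random 100-codon alignments; the ML recovery test 100
replicate pairs of 500 codons. Everything is seeded: identical
configuration and seed give byte-identical FASTA/TSV outputs and reports.

## Known limitations

- The Karlin–Altschul K is a configured constant, not derived from the
  full finite-length theory; E-values are accordingly approximate (they
  gate candidate pairs; they are not reported as significance claims).
- The ML estimator assumes equal codon frequencies and a single ω per
  pair; it is a cross-check, not a CODEML replacement.
- Paralogy by sequence similarity plus single linkage can chain distinct
  families through promiscuous domains; no synteny or tree-based
  correction is attempted.
- The per-term χ² treats terms independently (no ontology structure); the
  annotation tables are taken as given, flat assignments.
- Very recent duplicates (pairwise divergence ≈ 0) are indistinguishable
  from splice variants by any identity rule and are collapsed with them.
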