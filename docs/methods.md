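# Methods

## Problem setting

`hlacall` implements the computational half of an open, capture-based HLA
typing workflow: genomic DNA is enriched with 120 bp RNA baits spanning the
classical class I (HLA-A, -B, -C) and class II (DRB1, DQA1, DQB1, DPA1,
DPB1) loci, sequenced as 100 bp paired-end reads (fragments 150–300 bp),
and genotyped by aligning reads against a curated cDNA allele collection.
Because the HLA loci are the most polymorphic in the human genome — alleles
at a locus differ by only a handful of substitutions — the caller works by
exhaustive comparison of candidate allele pairs rather than by variant
calling against a single reference.

## Bait panel design

The panel starts from a non-overlapping 120 bp tiling of genomic reference
haplotypes. It is then grown iteratively: each gDNA sequence of the allele
collection, and afterwards each cDNA exon treated as a stand-alone
sequence, is aligned against the accumulated panel with an ungapped Hamming
scan (forward and reverse complement, up to 5 mismatches — the tolerance of
the hybridization chemistry). Any uncovered run of at least one bait length
is tiled to produce additional baits; processing follows input order, and
the finished panel provably leaves no such run in any input (asserted by
the completeness test). Design choices where the procedure is underspecified:

* **Tail anchoring.** A trailing partial tile window is covered by one
  extra bait anchored at the 3′ end, overlapping the previous tile. A
  strictly non-overlapping tiling would leave up to 119 bases of every
  input unbaited, violating the completeness goal.
* **Alignment model.** Bait placement uses ungapped Hamming distance on
  both strands. Hybridization capture tolerates scattered mismatches but
  not gaps at this probe length, and the model is deterministic and
  checkable against a brute-force per-offset count.
* **Coverage footprint** of a hit is the full 120 bp window.
* **Short exons.** Exon records shorter than one bait are padded with
  flanking cDNA into a single end-anchored 120 bp window where the cDNA
  allows; otherwise they are reported as uncoverable rather than silently
  dropped.
* The panel size is reported as the number of *distinct* bait sequences.

`target_fraction_percent` computes the panel target's share of the genome
(215.5 kb against 3.23 Gb ≈ 0.007%); dividing the observed on-target read
fraction by it gives the fold enrichment of the capture.

## Read mapping

Reads are placed on allele cDNAs by **perfect match only**. The one
exception is the boundary-truncated alignment: a read prefix or suffix of
at least `min_trunc_len` (default 70) bases matching exactly, with the
alignment terminating precisely at a cDNA end or an annotated internal exon
boundary on the truncated side. This admits the genomic reads that run off
an exon into intron or flanking sequence, which are the only reads able to
cover the first and last bases of each exon. Both orientations are mapped
(libraries are unstranded); `N` matches nothing; multi-mapping is expected
and kept, because the allele-specific counts need the full multi-map set.
Mate pairing is never required for a mapping to count — pairing feeds the
`mppr` score instead of acting as a filter.

The index stores 32-mer seeds at every cDNA position; every admissible
placement contains a seed flush with one read end, so lookup + extension +
boundary check is exact, not heuristic. Truncated alignments are one-sided
(matched prefix *or* suffix); infix matches truncated at both ends are not
emitted, which means exons shorter than `min_trunc_len` are unmappable
under this model (see Limitations).

**Start-point reduction.** For every (start, strand) on an allele at most
one representative mapping is kept (the longest; ties broken by read id),
collapsing PCR/optical duplicates and capping the influence of any single
fragment position. All downstream coverage and filtering statistics are
computed on these unique start-point profiles.

**Ideal profile.** The expected coverage under the assumption that every
admissible (start, length) window occurs exactly once: a flat interior
plateau of `read_len`, with ramps near boundaries shaped by the truncation
rule (position 0 is reachable by 1 full + 30 truncated windows at the
defaults). Following the module contract, the default boundary set is the
two cDNA ends; internal exon boundaries can be passed explicitly. Windows
are counted per (start, end) without strand doubling, so a saturated
two-strand library can exceed the ideal; the `auc` cap at 1 absorbs this.

## Candidate filtering

An allele survives pre-filtering iff

1. **full coverage** — every cDNA position has unique start-point coverage
   ≥ 1; and
2. **central-read ratio** — (mappings fully inside
   `[read_len/2, cdna_len − read_len/2)`) / (all other mappings) ≥ 0.2.
   The rule is "dropped below": exactly 0.2 passes. All-central profiles
   score +inf (pass); profiles with no mappings score NaN (fail).

Rejected alleles populate two machine-readable QC tables mirroring the
interactive review tables: all failures with their error count (zero-
coverage positions, ascending), and the top 50 under-covered alleles by
uncovered bases, ascending. When the sample itself is low-coverage (best
auc < 0.5) the failure list is additionally emitted as a review list, since
low-error entries are then worth manual inspection. Per-locus force-include
/ force-exclude lists reproduce the manual include/exclude interaction.

## Pair scoring and the weighted harmonic mean

All unordered candidate pairs, homozygous included, are scored on five
parameters:

| parameter | definition | default weight |
|---|---|---|
| asm  | reads mapping exclusively to one allele of the pair | 0.5 |
| req  | min(asm_a, asm_b) / max(asm_a, asm_b) | 1 |
| msl  | mean cDNA length of the pair | 0.1 |
| mppr | fraction of mapped reads whose mate co-maps the same allele | 0.1 |
| auc  | mean over the pair of Σcoverage/Σideal, capped at 1 | 1 |

Each parameter is rescaled to [0, 1] by dividing by its maximum over the
locus's pairs (an all-zero column stays 0), then merged:

    H = (Σ_k 1/w_k) · (Π_k P_k) / (Σ_k P_k / w_k)

which with w = (0.5, 1, 0.1, 0.1, 1) expands to
H = 24·asm·req·msl·mppr·auc / (2·asm + req + 10·msl + 10·mppr + auc).
H is 1 exactly at the all-ones vector, 0 whenever any parameter is 0, and
strictly increasing in each parameter when the others are positive. The
highest-H pair is the call; ranking ties break lexicographically for
determinism.

Definitional choices where the parameter list is underspecified:

* **Pair-level asm** is the size of the union of the two exclusive read
  sets: for a heterozygous pair the sets are disjoint, so this equals
  asm_a + asm_b; for a homozygous pair (where exclusivity is taken against
  the union of all *other* candidates) the single set is counted once.
  Counting it twice would hand the homozygous pair the same asm as the true
  heterozygous pair while enjoying req = 1 by definition, letting (A,A) tie
  or beat (A,B) on balanced heterozygous data. With the union definition
  the heterozygote wins robustly (asm scaled 1.0 vs ≈ 0.5, H ≈ 0.9 vs
  ≈ 0.52) and homozygous truth is still recovered, because for reads drawn
  from a single allele every heterozygous competitor has an empty exclusive
  set on the partner side (req = 0 ⇒ H = 0).
* **Homozygous req = 1** — evidence for a homozygote is perfectly balanced
  by definition.
* **Scaling is divide-by-max**, not min–max: min–max would force the worst
  pair's parameter to 0 and annihilate its H merely for ranking last.
* **Central window margins of read_len/2** make an ideally uniform library
  ratio-stable, so the 0.2 threshold is meaningful.

**Alternatives (ambiguities)** are the pairs carrying evidence identical to
the best pair's — same kept-mapping support set, e.g. two allele names with
identical cDNA — plus exact H ties. No epsilon window is used: a tolerance
would inflate ambiguity counts arbitrarily. (Implementation note: support
sets are only compared between pairs whose read-derived raw parameters
already agree, a pure shortcut since identical support implies identical
read-derived parameters.)

**Flags.** `low_coverage` when the best pair's raw auc < 0.5 (manual review
recommended); `low_read_count` when the sample has fewer than 7 million
single reads (3.5 M pairs) — a warning, not a filter; `no_call` when no
candidate survives.

**Boundary-variant discrimination.** `discriminate_boundary_variant`
reports per-exon segments where observed unique start-point coverage is 0
while the ideal expects reads. A gap hugging an exon 3′ end is the
signature of an erroneous reference allele that differs from the sequenced
one a few bases upstream of the boundary: full-length reads over the
variant mismatch, and truncated alignments reaching into the gap fall below
the 70 bp minimum. With random introns, a junction-crossing read can
chance-match 1–3 bases past the boundary (probability 1/4 per base), so
the gap occasionally stops just short of the boundary itself; the
diagnostic signal is the gap over the variant region.

## Panel (sample) selection

`select_diverse_panel` reproduces the randomized greedy benchmark-panel
selection: per restart, samples are drawn uniformly without replacement and
kept iff they contribute at least one allele not yet covered, until all
distinct alleles are covered; the smallest pool over all restarts wins
(ties: first found). Restart r uses seed + r. Any minimal cover is
reachable (each of its samples contributes a private allele in any order),
so with enough restarts the selection matches the brute-force minimum on
small instances — asserted up to 12 samples with 20,000 restarts.

## Synthetic data

The generator defines the study conditions for all tests:

* **Reference**: 8 loci × 20 alleles by default, each allele the locus
  founder plus 5 substitutions at random positions (pairwise-distinct
  sequences enforced), cDNAs of 5 exons drawn 180–300 bp (~1.2 kb total,
  class-I-like). Engineered near-identical pairs place k substitutions at
  chosen offsets from an exon 3′ end to stage the erroneous-reference
  scenario.
* **Reads**: fragments 150–300 bp drawn uniformly (either strand) from a
  per-allele genomic construct — exons separated by random introns
  (150–400 bp) and flanked by 300 bp of random sequence — with 100 bp mates
  at the fragment ends, mate 2 reverse-complemented, Casava 1.8 headers.
  The `depth` parameter targets interior unique start-point coverage (the
  fragment count solves the occupancy equation 2·read_len·(1−e^(−N/C)) =
  depth with 1.25× oversampling); the headline benchmarks run at depth 50,
  matching the >50× unique start-point coverage the capture is designed to
  deliver. Errors are independent substitutions on a separate RNG stream,
  so fragment geometry is identical across error rates; default error rate
  0 (errors stress coverage, not alignment, under a perfect-match mapper).
* **Truth tables** record each read's source allele, construct position and
  expected cDNA placement (full, truncated, or unmappable), giving the
  mapper an independent end-to-end oracle.

What the generator does **not** emulate: real exon length spectra (class I
3′ exons are shorter than the 70 bp truncation minimum and would be
unmappable under this model), capture efficiency bias and GC effects, PCR
duplicates, indel errors, quality-score structure, and homology between
loci/pseudogenes. Passing tests therefore demonstrate the correctness of
the algorithms under the stated model, not performance on real libraries.

## Problem sizes and numerics

The recovery benchmark in the test suite runs the full stated condition —
8 loci × 20 alleles, 100 random genotypes per locus at depth 50, asserting
≥ 99% exact recovery per locus; the reproduction script draws 12 genotypes
per locus as its reporting size. The mapper/oracle comparison uses 10,000
mixed reads against a ~13 kb reference; the bait fixture is 3 haplotypes +
30 gDNAs + 150 exon records. Scores are plain float64 arithmetic; the
general and expanded harmonic-mean forms agree to ~1e-13 relative. All
generators and selections are seeded; identical inputs give byte-identical
outputs.

## Known limitations

* No novel-allele discovery: reads from an unannotated allele surface only
  as no-calls, suspicious homozygotes, or anomaly-report gaps.
* Exons shorter than `min_trunc_len` cannot be covered (no double-truncated
  infix alignments), so references with very short exons will never pass
  the full-coverage filter under genomic-fragment sequencing.
* The bait designer optimizes coverage completeness only — no melting
  temperature, GC or synthesis constraints.
* Exclusion of chimeric database alleles is by explicit list; no detection
  is attempted.
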