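"""Synthetic IMGT-like references and paired-end capture reads with truth.

The reference generator emulates the salient structure of a curated HLA
allele collection: a handful of loci, each a family of highly similar
alleles derived from a locus founder by a few substitutions, with cDNAs
partitioned into exons. Engineered near-identical pairs (k substitutions at
chosen offsets from an exon 3' end) reproduce the erroneous-reference
scenario in which two alleles differ only a few bases upstream of a
boundary.

The read simulator draws genomic fragments (150-300 bp) from a per-allele
construct of exons separated by random introns and flanked by random
sequence, and emits 100 bp mates from the fragment ends (mate 2 reverse
complemented) under Casava 1.8 headers. Because introns are at least one
read length long, each read overlaps at most one exon, and its expected
cDNA placement (full-length, boundary-truncated, or none) is recorded in
the truth table.
"""

from __future__ import annotations

import gzip
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from hlacall._util import revcomp
from hlacall.reference import Allele, AlleleName, AlleleReference

_DEFAULT_LOCI = ("A", "B", "C", "DRB1", "DQA1", "DQB1", "DPA1", "DPB1")
_BASES = "ACGT"


def _random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


@dataclass(frozen=True)
class NearIdenticalSpec:
    """Request an extra allele differing from a base allele only at the given
    offsets (negative, relative to the 3' end of exon ``exon_index``)."""

    locus: str
    base_index: int
    exon_index: int
    offsets: tuple[int, ...]


@dataclass
class SimReferenceConfig:
    n_loci: int = 8
    alleles_per_locus: int = 20
    n_exons: int = 5
    exon_len_range: tuple[int, int] = (180, 300)
    divergence: int = 5           # substitutions per allele vs the locus founder
    near_identical: tuple[NearIdenticalSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.n_loci > len(_DEFAULT_LOCI):
            raise ValueError(f"n_loci must be in 1..{len(_DEFAULT_LOCI)}")
        if self.divergence < 1:
            raise ValueError("divergence must be >= 1")


@dataclass
class SimTruth:
    """Provenance of a simulated reference."""

    founders: dict[str, str] = field(default_factory=dict)
    substitutions: dict[str, tuple[tuple[int, str], ...]] = field(default_factory=dict)
    engineered: dict[str, str] = field(default_factory=dict)  # decoy -> base allele


def _mutate(rng: random.Random, seq: str, n_subs: int) -> tuple[str, tuple[tuple[int, str], ...]]:
    positions = rng.sample(range(len(seq)), n_subs)
    chars = list(seq)
    subs = []
    for p in sorted(positions):
        alt = rng.choice([b for b in _BASES if b != chars[p]])
        chars[p] = alt
        subs.append((p, alt))
    return "".join(chars), tuple(subs)


def simulate_reference(cfg: SimReferenceConfig) -> tuple[AlleleReference, SimTruth]:
    """Generate a deterministic multi-locus allele reference.

    Each allele is the locus founder with ``cfg.divergence`` substitutions;
    all allele sequences within a locus are pairwise distinct unless an
    engineered near-identical pair requests otherwise (which still differs
    at >= 1 position).
    """
    rng = random.Random(cfg.seed)
    truth = SimTruth()
    ref = AlleleReference()
    for li in range(cfg.n_loci):
        locus = _DEFAULT_LOCI[li]
        exon_lens = [rng.randint(*cfg.exon_len_range) for _ in range(cfg.n_exons)]
        total = sum(exon_lens)
        if cfg.divergence > total:
            raise ValueError(
                f"divergence {cfg.divergence} exceeds cDNA length {total} at locus {locus}"
            )
        bounds = []
        pos = 0
        for n in exon_lens:
            bounds.append((pos, pos + n))
            pos += n
        founder = _random_dna(rng, total)
        truth.founders[locus] = founder
        seen = {founder}
        for ai in range(cfg.alleles_per_locus):
            for _ in range(1000):
                cdna, subs = _mutate(rng, founder, cfg.divergence)
                if cdna not in seen:
                    break
            else:  # pragma: no cover - would need a pathological config
                raise ValueError(f"cannot generate distinct alleles at locus {locus}")
            seen.add(cdna)
            name = AlleleName(locus, (f"{ai + 1:02d}", "01", "01"))
            ref.add(Allele(name, cdna, tuple(bounds)))
            truth.substitutions[str(name)] = subs
    for spec in cfg.near_identical:
        base = ref.by_locus(spec.locus)[spec.base_index]
        new_ref, decoy = make_erroneous_reference_fixture(
            ref, str(base.name), spec.offsets, exon_index=spec.exon_index
        )
        ref = new_ref
        truth.engineered[decoy] = str(base.name)
    return ref, truth


def make_erroneous_reference_fixture(
    reference: AlleleReference,
    allele_name: str,
    offsets: Sequence[int],
    exon_index: int = -1,
) -> tuple[AlleleReference, str]:
    """Add a decoy allele differing from *allele_name* only at *offsets*.

    Offsets are negative positions relative to the 3' end of exon
    ``exon_index`` (e.g. (-34, -32) puts the two differences 34 and 32 bases
    upstream of the boundary). Returns the extended reference and the decoy
    name. Used to stage the erroneous-reference discrimination scenario.
    """
    if not offsets:
        raise ValueError("offsets empty: decoy would be identical to the base allele")
    base = reference.get(allele_name)
    es, ee = base.exon_bounds[exon_index]
    chars = list(base.cdna)
    for off in offsets:
        if off >= 0:
            raise ValueError(f"offset {off} must be negative (upstream of the 3' end)")
        p = ee + off
        if not es <= p < ee:
            raise ValueError(f"offset {off} falls outside exon {exon_index}")
        chars[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[p]]
    decoy_cdna = "".join(chars)
    for a in reference:
        if a.cdna == decoy_cdna:
            raise ValueError(f"decoy collides with existing allele {a.name}")
    group = 90
    while True:
        decoy_name = AlleleName(base.name.locus, (f"{group}", "01", "01"))
        if decoy_name not in reference:
            break
        group += 1
    out = AlleleReference(list(reference))
    out.add(Allele(decoy_name, decoy_cdna, base.exon_bounds))
    return out, str(decoy_name)


def genomic_construct(
    allele: Allele,
    seed: int,
    intron_len_range: tuple[int, int] = (150, 400),
    flank_len: int = 300,
) -> str:
    """A synthetic gDNA sequence for an allele: exons separated by random
    introns, flanked by random sequence. Used for bait-design fixtures and
    internally by the read simulator."""
    rng = random.Random(seed)
    cfg = SimReadConfig(intron_len_range=intron_len_range, fragment_range=(flank_len, flank_len))
    return _build_construct(rng, allele, cfg).seq


# ---------------------------------------------------------------------------
# Read simulation


@dataclass
class SimReadConfig:
    read_len: int = 100
    fragment_range: tuple[int, int] = (150, 300)
    depth: int = 50               # target interior unique start points per position
    error_rate: float = 0.0       # independent substitution rate per base
    with_flanks: bool = True      # random introns/flanks -> boundary-truncated reads
    intron_len_range: tuple[int, int] = (150, 400)
    min_trunc_len: int = 70
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fragment_range[0] < self.read_len:
            raise ValueError(
                f"fragment range {self.fragment_range} must admit a full "
                f"{self.read_len} bp read"
            )
        if self.with_flanks and self.intron_len_range[0] < self.read_len:
            raise ValueError("introns shorter than the read length are not supported")


@dataclass(frozen=True)
class ExpectedMapping:
    """Where an error-free read must map on its source allele (or None)."""

    cdna_start: int
    matched_len: int
    truncated_5p: bool
    truncated_3p: bool
    strand: str


@dataclass(frozen=True)
class SimRead:
    read_id: str
    seq1: str
    seq2: str
    allele: str
    construct_start1: int
    construct_start2: int
    expected1: ExpectedMapping | None
    expected2: ExpectedMapping | None


@dataclass
class SimReadSet:
    reads: list[SimRead]

    def __len__(self) -> int:
        return len(self.reads)

    def records(self):
        """Yield flat (read_id, mate, seq) tuples for the mapper."""
        for r in self.reads:
            yield (r.read_id, 1, r.seq1)
            yield (r.read_id, 2, r.seq2)

    def write_fastq(self, path1: str | Path, path2: str | Path) -> None:
        """Write both mates (gzipped when the path ends in .gz), Casava 1.8."""

        def _open(p):
            p = str(p)
            return gzip.open(p, "wt") if p.endswith(".gz") else open(p, "w")

        with _open(path1) as f1, _open(path2) as f2:
            for r in self.reads:
                q = "I" * len(r.seq1)
                f1.write(f"@{r.read_id} 1:N:0:1\n{r.seq1}\n+\n{q}\n")
                f2.write(f"@{r.read_id} 2:N:0:1\n{r.seq2}\n+\n{'I' * len(r.seq2)}\n")

    def write_truth_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "read_id\tallele\tconstruct_start1\tconstruct_start2"
                "\tcdna_start1\tmatched_len1\tcdna_start2\tmatched_len2\n"
            )
            for r in self.reads:
                e1 = r.expected1
                e2 = r.expected2
                fh.write(
                    f"{r.read_id}\t{r.allele}\t{r.construct_start1}\t{r.construct_start2}\t"
                    f"{e1.cdna_start if e1 else '.'}\t{e1.matched_len if e1 else '.'}\t"
                    f"{e2.cdna_start if e2 else '.'}\t{e2.matched_len if e2 else '.'}\n"
                )


@dataclass
class _Construct:
    seq: str
    exon_spans: list[tuple[int, int, int]]  # (construct_start, construct_end, cdna_start)


def _build_construct(rng: random.Random, allele: Allele, cfg: SimReadConfig) -> _Construct:
    if not cfg.with_flanks:
        spans = [(s, e, s) for s, e in allele.exon_bounds]
        return _Construct(allele.cdna, spans)
    flank = cfg.fragment_range[1]
    parts = [_random_dna(rng, flank)]
    pos = flank
    spans = []
    for i, (s, e) in enumerate(allele.exon_bounds):
        exon = allele.cdna[s:e]
        parts.append(exon)
        spans.append((pos, pos + len(exon), s))
        pos += len(exon)
        if i < len(allele.exon_bounds) - 1:
            intron = _random_dna(rng, rng.randint(*cfg.intron_len_range))
            parts.append(intron)
            pos += len(intron)
    parts.append(_random_dna(rng, flank))
    return _Construct("".join(parts), spans)


def _expected_mapping(
    construct: _Construct, ws: int, we: int, orient_fwd: bool, cfg: SimReadConfig
) -> ExpectedMapping | None:
    """Expected cDNA placement of a read occupying construct window [ws, we)."""
    strand = "+" if orient_fwd else "-"
    m = we - ws
    if not cfg.with_flanks:
        # construct is the contiguous cDNA itself: always a full-length match
        return ExpectedMapping(ws, m, False, False, strand)
    for es, ee, cs in construct.exon_spans:
        lo, hi = max(ws, es), min(we, ee)
        if hi - lo <= 0:
            continue
        if hi - lo < cfg.min_trunc_len:
            return None
        trunc5 = ws < es          # alignment starts at the exon 5' boundary
        trunc3 = we > ee          # alignment ends at the exon 3' boundary
        # genuinely truncated only when cut by intron/flank, i.e. read extends past
        if hi - lo == m:
            trunc5 = trunc3 = False
        return ExpectedMapping(cs + (lo - es), hi - lo, trunc5, trunc3, strand)
    return None


def _fragments_for_depth(cfg: SimReadConfig, construct_len: int) -> int:
    """Fragment count so the interior unique start-point coverage reaches the
    target depth: occupancy of the 2 * read_len (start, strand) combinations
    overlapping an interior position follows 1 - exp(-N / C), oversampled by
    1.25 to compensate for sampling noise."""
    combos = 2 * cfg.read_len
    target = min(cfg.depth, combos - 1)
    occupancy = target / combos
    return max(1, math.ceil(-construct_len * math.log(1.0 - occupancy) * 1.25))


def simulate_reads(
    genotype: tuple[str, str],
    reference: AlleleReference,
    cfg: SimReadConfig,
) -> SimReadSet:
    """Simulate paired-end capture reads for a diploid genotype.

    Each haplotype copy contributes fragments drawn uniformly from its
    genomic construct on a random strand; mates are the two fragment ends.
    Deterministic for a fixed config; ``depth`` 0 yields an empty read set.
    """
    rng = random.Random(cfg.seed)
    # separate stream: fragment geometry is identical across error rates
    err_rng = random.Random((cfg.seed << 1) + 1)
    reads: list[SimRead] = []
    serial = 0
    for copy_idx, name in enumerate(genotype):
        allele = reference.get(name)
        construct = _build_construct(rng, allele, cfg)
        c = construct.seq
        n_frags = _fragments_for_depth(cfg, len(c)) if cfg.depth > 0 else 0
        for _ in range(n_frags):
            flen = rng.randint(*cfg.fragment_range)
            start = rng.randint(0, len(c) - flen)
            fwd = rng.random() < 0.5
            frag = c[start : start + flen]
            if not fwd:
                frag = revcomp(frag)
            r1 = frag[: cfg.read_len]
            r2 = revcomp(frag[-cfg.read_len :])
            # construct windows and orientations of the two mates
            if fwd:
                w1, o1 = (start, start + cfg.read_len), True
                w2, o2 = (start + flen - cfg.read_len, start + flen), False
            else:
                w1, o1 = (start + flen - cfg.read_len, start + flen), False
                w2, o2 = (start, start + cfg.read_len), True
            e1 = _expected_mapping(construct, *w1, o1, cfg)
            e2 = _expected_mapping(construct, *w2, o2, cfg)
            if cfg.error_rate > 0:
                r1 = _sequencing_errors(err_rng, r1, cfg.error_rate)
                r2 = _sequencing_errors(err_rng, r2, cfg.error_rate)
            serial += 1
            read_id = f"SIM:1:FC1:1:{copy_idx + 1}:{serial}:{start}"
            reads.append(
                SimRead(read_id, r1, r2, str(allele.name), w1[0], w2[0], e1, e2)
            )
    return SimReadSet(reads)


def _sequencing_errors(rng: random.Random, seq: str, rate: float) -> str:
    chars = list(seq)
    for i, b in enumerate(chars):
        if rng.random() < rate:
            chars[i] = rng.choice([x for x in _BASES if x != b])
    return "".join(chars)
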