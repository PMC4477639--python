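"""Candidate filtering and allele-pair genotype calling.

Filtering keeps an allele iff its unique start-point coverage reaches every
cDNA position (full coverage) and the central/noncentral read ratio is at
least 0.2 (the rule is "dropped below": exactly 0.2 passes). Of the
surviving candidates, all unordered allele pairs (homozygous included) are
scored through five mapping-derived parameters

    asm   allele-specific mappings: reads exclusive to one of the two alleles
    req   read equality, min(asm_a, asm_b) / max(asm_a, asm_b)
    msl   mappable sequence length (mean cDNA length of the pair)
    mppr  mapped pairs per read: fraction of mapped reads whose mate
          co-maps the same allele
    auc   coverage area under the curve, normalised by the ideal profile

which are rescaled to [0, 1] by dividing by the per-locus maximum and merged
into a weighted harmonic mean H (weights 0.5, 1, 0.1, 0.1, 1). The highest-H
pair is the call; pairs with identical read support, and exact H ties, are
reported as alternatives (ambiguities).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Iterable, Mapping as TMapping, Sequence

import numpy as np

from hlacall.mapping import Mapping, StartPointProfile

DEFAULT_CENTRAL_RATIO_THRESHOLD = 0.2
DEFAULT_LOW_COV_AUC_THRESHOLD = 0.5
DEFAULT_READ_COUNT_THRESHOLD = 7_000_000
QC_TABLE_SIZE = 50


@dataclass(frozen=True)
class Weights:
    """Harmonic-mean weights for (asm, req, msl, mppr, auc)."""

    asm: float = 0.5
    req: float = 1.0
    msl: float = 0.1
    mppr: float = 0.1
    auc: float = 1.0

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.asm, self.req, self.msl, self.mppr, self.auc)

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.as_tuple()):
            raise ValueError(f"all weights must be > 0, got {self.as_tuple()}")


def harmonic_score(params: Sequence[float], weights: Weights = Weights()) -> float:
    """Weighted harmonic mean of scaled parameters in [0, 1].

    H = (sum_k 1/w_k) * (prod_k P_k) / (sum_k P_k / w_k). Any zero parameter
    annihilates the score; the all-ones vector scores exactly 1.
    """
    w = weights.as_tuple()
    if len(params) != len(w):
        raise ValueError(f"expected {len(w)} parameters, got {len(params)}")
    inv = [1.0 / wk for wk in w]
    denom = sum(ik * p for ik, p in zip(inv, params))
    if denom == 0.0:
        return 0.0
    prod = 1.0
    for p in params:
        prod *= p
    return sum(inv) * prod / denom


def central_read_ratio(
    profile: StartPointProfile, read_len: int = 100
) -> float:
    """Central/noncentral ratio of the kept mappings of one allele.

    Central mappings lie fully inside ``[read_len/2, cdna_len - read_len/2)``.
    Returns +inf when every kept mapping is central and NaN when there are no
    mappings at all (NaN compares below any threshold, so the allele fails).
    """
    if not profile.kept:
        return math.nan
    lo = read_len / 2
    hi = len(profile.coverage) - read_len / 2
    central = sum(1 for m in profile.kept if m.start >= lo and m.end <= hi)
    noncentral = len(profile.kept) - central
    if noncentral == 0:
        return math.inf
    return central / noncentral


@dataclass
class QCTables:
    """Machine-readable counterparts of the two GUI QC tables.

    ``failed``: every allele rejected by pre-filtering with its error count
    (number of cDNA positions with zero unique start-point coverage), sorted
    ascending by error. ``undercovered``: the top 50 not-fully-covered
    alleles sorted ascending by uncovered bases.
    """

    failed: list[tuple[str, int]] = field(default_factory=list)
    undercovered: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class PrefilterResult:
    candidates: list[str]
    qc: QCTables
    review: list[tuple[str, int]] = field(default_factory=list)


def prefilter_candidates(
    profiles: TMapping[str, StartPointProfile],
    low_cov_mode: bool = False,
    central_ratio_threshold: float = DEFAULT_CENTRAL_RATIO_THRESHOLD,
    read_len: int = 100,
    force_include: Iterable[str] = (),
    force_exclude: Iterable[str] = (),
) -> PrefilterResult:
    """Apply the full-coverage and central-read filters to a locus.

    In ``low_cov_mode`` (sample auc below 0.5) the rejected alleles are also
    emitted as a review list — low-error entries are worth manual inspection
    instead of being silently dropped. ``force_include``/``force_exclude``
    mirror the manual include/exclude interaction of the GUI tables.
    """
    include = {str(n) for n in force_include}
    exclude = {str(n) for n in force_exclude}
    candidates: list[str] = []
    failed: list[tuple[str, int]] = []
    under: list[tuple[str, int]] = []
    for name, prof in profiles.items():
        err = prof.n_uncovered
        ratio = central_read_ratio(prof, read_len)
        ok = err == 0 and ratio >= central_ratio_threshold
        if name in exclude:
            ok = False
        elif name in include:
            ok = True
        if ok:
            candidates.append(name)
        else:
            failed.append((name, err))
            if err > 0:
                under.append((name, err))
    failed.sort(key=lambda t: (t[1], t[0]))
    under.sort(key=lambda t: (t[1], t[0]))
    qc = QCTables(failed=failed, undercovered=under[:QC_TABLE_SIZE])
    review = failed[:] if low_cov_mode else []
    return PrefilterResult(sorted(candidates), qc, review)


# ---------------------------------------------------------------------------
# Pair parameters


@dataclass(frozen=True)
class RawPairParams:
    asm_a: int
    asm_b: int
    asm: int
    req: float
    msl: float
    mppr: float
    auc: float


@dataclass
class LocusData:
    """Per-locus read-support matrix shared by all pair computations.

    ``reads[i, j]`` is True iff read instance j (a (read_id, mate)) has at
    least one kept-compatible mapping on candidate allele i.
    """

    names: list[str]
    cdna_len: dict[str, int]
    reads: np.ndarray               # bool, (n_alleles, n_read_instances)
    paired: dict[str, int]          # per allele: instances whose mate co-maps it
    total: dict[str, int]           # per allele: mapped instances
    auc: dict[str, float]
    support: dict[str, frozenset]   # per allele: placement set for ambiguity calls

    @classmethod
    def build(
        cls,
        profiles: TMapping[str, StartPointProfile],
        candidates: Sequence[str],
        mappings_by_allele: TMapping[str, Sequence[Mapping]],
    ) -> "LocusData":
        names = list(candidates)
        instance_id: dict[tuple[str, int], int] = {}
        per_allele_instances: dict[str, set[int]] = {}
        paired: dict[str, int] = {}
        total: dict[str, int] = {}
        support: dict[str, frozenset] = {}
        for name in names:
            ms = mappings_by_allele.get(name, ())
            inst: set[int] = set()
            by_read: dict[str, set[int]] = {}
            for m in ms:
                key = (m.read_id, m.mate)
                j = instance_id.setdefault(key, len(instance_id))
                inst.add(j)
                by_read.setdefault(m.read_id, set()).add(m.mate)
            per_allele_instances[name] = inst
            total[name] = len(inst)
            paired[name] = sum(
                len(mates) for mates in by_read.values() if len(mates) == 2
            )
            support[name] = frozenset(
                (m.read_id, m.mate, m.start, m.matched_len, m.strand) for m in ms
            )
        reads = np.zeros((len(names), max(1, len(instance_id))), dtype=bool)
        for i, name in enumerate(names):
            cols = list(per_allele_instances[name])
            if cols:
                reads[i, cols] = True
        return cls(
            names=names,
            cdna_len={n: len(profiles[n].coverage) for n in names},
            reads=reads,
            paired=paired,
            total=total,
            auc={n: profiles[n].auc for n in names},
            support=support,
        )


def pair_raw_params(a: str, b: str, data: LocusData) -> RawPairParams:
    """The five raw parameters for one candidate pair (a == b: homozygous).

    Heterozygous: asm_a/asm_b are the reads mapping one allele but not the
    other, and asm is their total since the two exclusive sets are disjoint.
    Homozygous: the exclusive set is taken against the union of all *other*
    candidate alleles and counted once; req is 1 by definition (perfectly
    balanced evidence).
    """
    ia, ib = data.names.index(a), data.names.index(b)
    ra, rb = data.reads[ia], data.reads[ib]
    if a == b:
        others = np.zeros_like(ra)
        for i in range(len(data.names)):
            if i != ia:
                others |= data.reads[i]
        excl = int((ra & ~others).sum())
        asm_a = asm_b = excl
        asm = excl
        req = 1.0
        msl = float(data.cdna_len[a])
        mppr = data.paired[a] / data.total[a] if data.total[a] else 0.0
        auc = data.auc[a]
    else:
        asm_a = int((ra & ~rb).sum())
        asm_b = int((rb & ~ra).sum())
        asm = asm_a + asm_b
        hi = max(asm_a, asm_b)
        req = (min(asm_a, asm_b) / hi) if hi else 0.0
        msl = (data.cdna_len[a] + data.cdna_len[b]) / 2.0
        denom = data.total[a] + data.total[b]
        mppr = (data.paired[a] + data.paired[b]) / denom if denom else 0.0
        auc = (data.auc[a] + data.auc[b]) / 2.0
    return RawPairParams(asm_a, asm_b, asm, req, msl, mppr, auc)


def scale_params(raw: Sequence[RawPairParams]) -> list[tuple[float, ...]]:
    """Divide each parameter by its maximum over the locus's pairs.

    Keeps every value in [0, 1] with at least one pair attaining 1 whenever
    any raw value is positive; a parameter whose maximum is 0 scales to 0
    everywhere. Idempotent.
    """
    if not raw:
        return []
    cols = [
        [r.asm for r in raw],
        [r.req for r in raw],
        [r.msl for r in raw],
        [r.mppr for r in raw],
        [r.auc for r in raw],
    ]
    maxima = [max(c) for c in cols]
    return [
        tuple((c[i] / mx) if mx > 0 else 0.0 for c, mx in zip(cols, maxima))
        for i in range(len(raw))
    ]


@dataclass
class PairScore:
    pair: tuple[str, str]
    raw: RawPairParams
    scaled: tuple[float, ...]
    H: float


@dataclass
class GenotypeCall:
    locus: str
    ranked: list[PairScore]
    best: tuple[str, str] | None
    alternatives: list[tuple[str, str]]
    flags: list[str]
    qc: QCTables | None = None
    review: list[tuple[str, int]] = field(default_factory=list)

    @property
    def no_call(self) -> bool:
        return self.best is None


def call_genotype(
    locus: str,
    profiles: TMapping[str, StartPointProfile],
    candidates: Sequence[str],
    mappings_by_allele: TMapping[str, Sequence[Mapping]],
    weights: Weights = Weights(),
    total_reads: int | None = None,
    low_cov_auc_threshold: float = DEFAULT_LOW_COV_AUC_THRESHOLD,
    read_count_threshold: int = DEFAULT_READ_COUNT_THRESHOLD,
) -> GenotypeCall:
    """Exhaustively score all unordered candidate pairs and rank by H.

    Alternatives collect the pairs whose kept-mapping support set is
    identical to the best pair's (indistinguishable evidence, e.g. two
    allele names with the same cDNA) together with exact H ties. Flags:
    ``low_coverage`` when the best pair's raw auc is below 0.5 (manual
    review advised), ``low_read_count`` when the sample's total single-read
    count falls below the configured threshold (default 7 million),
    ``no_call`` when no candidate survived filtering.
    """
    flags: list[str] = []
    if total_reads is not None and total_reads < read_count_threshold:
        flags.append("low_read_count")
    if not candidates:
        return GenotypeCall(locus, [], None, [], flags + ["no_call"])

    data = LocusData.build(profiles, candidates, mappings_by_allele)
    pairs = [tuple(sorted(p)) for p in combinations_with_replacement(data.names, 2)]
    raw = [pair_raw_params(a, b, data) for a, b in pairs]
    scaled = scale_params(raw)
    scores = [
        PairScore(p, r, s, harmonic_score(s, weights))
        for p, r, s in zip(pairs, raw, scaled)
    ]
    scores.sort(key=lambda sc: (-sc.H, sc.pair))
    best = scores[0]

    def pair_support(p: tuple[str, str]) -> frozenset:
        return data.support[p[0]] | data.support[p[1]]

    best_support = pair_support(best.pair)
    read_key = (best.raw.asm_a, best.raw.asm_b, best.raw.mppr, best.raw.auc)
    alternatives = []
    for sc in scores[1:]:
        if sc.H == best.H:
            alternatives.append(sc.pair)
        elif (
            (sc.raw.asm_a, sc.raw.asm_b, sc.raw.mppr, sc.raw.auc) == read_key
            and pair_support(sc.pair) == best_support
        ):
            alternatives.append(sc.pair)
    if best.raw.auc < low_cov_auc_threshold:
        flags.append("low_coverage")
    return GenotypeCall(locus, scores, best.pair, alternatives, flags)


# ---------------------------------------------------------------------------
# Boundary-variant discrimination (erroneous-reference diagnosis)


@dataclass(frozen=True)
class GapSegment:
    """A zero-coverage run (observed 0, ideal > 0) within one exon."""

    exon_index: int
    start: int
    end: int
    abuts_exon_5p: bool
    abuts_exon_3p: bool


def discriminate_boundary_variant(
    profile: StartPointProfile, exon_bounds: Sequence[tuple[int, int]]
) -> list[GapSegment]:
    """Report per-exon segments where observed coverage is zero but the ideal
    model expects reads.

    A gap abutting an exon 3' (or 5') boundary is the signature of a
    reference allele that differs from the sequenced one near that boundary:
    full-length reads covering the variant positions mismatch, and truncated
    alignments into the gap are shorter than the admissible minimum, so the
    erroneous reference shows an abnormal read distribution instead of the
    expected profile. An empty report means full expected coverage.
    """
    gaps: list[GapSegment] = []
    zero = (profile.coverage == 0) & (profile.ideal > 0)
    for ei, (es, ee) in enumerate(exon_bounds):
        i = es
        while i < ee:
            if zero[i]:
                j = i
                while j < ee and zero[j]:
                    j += 1
                gaps.append(GapSegment(ei, i, j, i == es, j == ee))
                i = j
            else:
                i += 1
    return gaps
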