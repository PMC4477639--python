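"""Perfect-match read mapping against cDNA allele collections.

Reads are placed on allele cDNAs by exact substring match only. The single
exception is a boundary-truncated alignment: a read prefix (or suffix) of at
least ``min_trunc_len`` bases that matches exactly and whose alignment ends
(or starts) precisely at a cDNA end or an annotated internal exon boundary.
This admits the genomic reads that run off an exon into intron or flanking
sequence. Both orientations are scanned; reads containing N match nothing at
the N positions.

Mappings are reduced to *unique start points*: for every (start, strand) on
an allele at most one representative mapping is kept, which suppresses
duplicate inflation before coverage and genotype statistics are computed.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from hlacall._util import revcomp
from hlacall.reference import Allele, AlleleReference

DEFAULT_MIN_TRUNC_LEN = 70
_SEED_LEN = 32


class Mapping(NamedTuple):
    """One perfect (possibly boundary-truncated) placement of a read mate."""

    read_id: str
    mate: int
    allele: str
    start: int          # 0-based cDNA offset of the alignment's left end
    matched_len: int
    truncated_5p: bool  # alignment's left end abuts an exon boundary, read continues
    truncated_3p: bool  # alignment's right end abuts an exon boundary, read continues
    strand: str         # '+': read matches cDNA forward; '-': reverse complement

    @property
    def end(self) -> int:
        return self.start + self.matched_len


def _match_forward(q: str, target: str, pos: int) -> int:
    """Length of the common prefix of q and target[pos:]."""
    n = min(len(q), len(target) - pos)
    i = 0
    while i < n and q[i] == target[pos + i]:
        i += 1
    return i


def _match_backward(q: str, target: str, end: int) -> int:
    """Length of the common suffix of q and target[:end]."""
    n = min(len(q), end)
    i = 0
    while i < n and q[-1 - i] == target[end - 1 - i]:
        i += 1
    return i


class MappingIndex:
    """Exact-substring seed index over the non-excluded alleles of a reference.

    Seeds of length ``min(32, min_trunc_len)`` anchor both read ends; every
    admissible placement (full-length, or one-sided boundary-truncated with a
    matched prefix/suffix >= ``min_trunc_len``) contains a seed at the
    corresponding read end, so lookup is exact, not heuristic.
    """

    def __init__(self, reference: AlleleReference, min_trunc_len: int = DEFAULT_MIN_TRUNC_LEN):
        if min_trunc_len < 1:
            raise ValueError("min_trunc_len must be >= 1")
        self.min_trunc_len = min_trunc_len
        self.k = min(_SEED_LEN, min_trunc_len)
        self.alleles: list[Allele] = list(reference.non_excluded())
        self._names = [str(a.name) for a in self.alleles]
        self._cdnas = [a.cdna for a in self.alleles]
        self._bounds = [list(a.boundaries) for a in self.alleles]
        seeds: dict[str, list[tuple[int, int]]] = {}
        k = self.k
        for ai, cd in enumerate(self._cdnas):
            for pos in range(len(cd) - k + 1):
                seeds.setdefault(cd[pos : pos + k], []).append((ai, pos))
        self._seeds = seeds

    def allele(self, name: str) -> Allele:
        return self.alleles[self._names.index(name)]

    def query(self, seq: str, read_id: str = "", mate: int = 1) -> list[Mapping]:
        """All admissible placements of *seq* on the indexed cDNAs (both strands)."""
        mtl = self.min_trunc_len
        if len(seq) < mtl:
            raise ValueError(
                f"query length {len(seq)} below minimum truncated mapping length {mtl}"
            )
        k = self.k
        found: dict[tuple[int, int, int, str], Mapping] = {}
        for strand in "+-":
            q = seq if strand == "+" else revcomp(seq)
            m = len(q)
            # prefix-anchored: full-length, or truncated at the right (3') side
            for ai, pos in self._seeds.get(q[:k], ()):
                cd = self._cdnas[ai]
                if cd[pos : pos + m] == q:
                    key = (ai, pos, m, strand)
                    found[key] = Mapping(
                        read_id, mate, self._names[ai], pos, m, False, False, strand
                    )
                    continue
                e = _match_forward(q, cd, pos)
                if e >= mtl:
                    bounds = self._bounds[ai]
                    lo = bisect_left(bounds, pos + mtl)
                    hi = bisect_right(bounds, min(pos + e, pos + m - 1))
                    for b in bounds[lo:hi]:
                        key = (ai, pos, b - pos, strand)
                        found[key] = Mapping(
                            read_id, mate, self._names[ai], pos, b - pos, False, True, strand
                        )
            # suffix-anchored: truncated at the left (5') side
            for ai, pos in self._seeds.get(q[-k:], ()):
                cd = self._cdnas[ai]
                end = pos + k
                e = _match_backward(q, cd, end)
                if e >= mtl and e < m:
                    bounds = self._bounds[ai]
                    lo = bisect_left(bounds, max(end - e, end - m + 1))
                    hi = bisect_right(bounds, end - mtl)
                    for b in bounds[lo:hi]:
                        key = (ai, b, end - b, strand)
                        found[key] = Mapping(
                            read_id, mate, self._names[ai], b, end - b, True, False, strand
                        )
        return sorted(found.values())


def build_index(
    reference: AlleleReference, min_trunc_len: int = DEFAULT_MIN_TRUNC_LEN
) -> MappingIndex:
    """Build the exact-substring mapping index for *reference*."""
    return MappingIndex(reference, min_trunc_len)


def map_read(seq: str, index: MappingIndex, read_id: str = "", mate: int = 1) -> list[Mapping]:
    """Map one read: all full-length exact placements on either strand, plus
    boundary-truncated placements per the admissibility rule. Unmappable
    reads yield an empty list."""
    return index.query(seq.upper(), read_id, mate)


# ---------------------------------------------------------------------------
# Start-point reduction and coverage profiles


@dataclass
class StartPointProfile:
    """Unique start-point coverage of one allele.

    ``starts[i]`` counts distinct (start, strand) mapping start points at
    position i (0..2); ``coverage`` is the pileup of the kept representative
    mappings; ``ideal`` is the expected coverage if every admissible start
    point occurred exactly once.
    """

    allele_name: str
    starts: np.ndarray
    coverage: np.ndarray
    ideal: np.ndarray
    kept: list[Mapping]

    @property
    def n_uncovered(self) -> int:
        return int((self.coverage == 0).sum())

    @property
    def fully_covered(self) -> bool:
        return self.n_uncovered == 0

    @property
    def auc(self) -> float:
        """Observed coverage area normalised by the ideal profile, capped at 1."""
        denom = float(self.ideal.sum())
        if denom == 0:
            return 0.0
        return min(1.0, float(self.coverage.sum()) / denom)


@lru_cache(maxsize=4096)
def _ideal_cached(
    cdna_len: int, read_len: int, min_trunc_len: int, boundaries: tuple[int, ...]
) -> np.ndarray:
    windows: set[tuple[int, int]] = set()
    for s in range(0, cdna_len - read_len + 1):
        windows.add((s, s + read_len))
    for b in boundaries:
        for ell in range(min_trunc_len, read_len):
            if b - ell >= 0:
                windows.add((b - ell, b))
            if b + ell <= cdna_len:
                windows.add((b, b + ell))
    diff = np.zeros(cdna_len + 1, dtype=np.int64)
    for s, e in windows:
        diff[s] += 1
        diff[e] -= 1
    out = np.cumsum(diff[:-1])
    out.setflags(write=False)
    return out


def ideal_profile(
    cdna_len: int,
    read_len: int = 100,
    min_trunc_len: int = DEFAULT_MIN_TRUNC_LEN,
    boundaries: Sequence[int] | None = None,
) -> np.ndarray:
    """Expected per-position coverage for a perfect single start-point mapping.

    Every admissible alignment window is assumed to occur exactly once: all
    full-length windows, plus truncated windows of length
    ``min_trunc_len .. read_len - 1`` anchored at a boundary (by default the
    two cDNA ends; pass exon boundaries to model internal junctions). The
    profile shows a flat interior plateau with ramps shaped by the truncation
    rule near boundaries.
    """
    if cdna_len < min_trunc_len:
        raise ValueError(f"cdna_len {cdna_len} < min_trunc_len {min_trunc_len}")
    if boundaries is None:
        boundaries = (0, cdna_len)
    return _ideal_cached(cdna_len, read_len, min_trunc_len, tuple(sorted(set(boundaries))))


def reduce_start_points(
    mappings: Iterable[Mapping],
    allele: Allele,
    read_len: int = 100,
    min_trunc_len: int = DEFAULT_MIN_TRUNC_LEN,
) -> StartPointProfile:
    """Collapse mappings of one allele to single start-point mappings.

    For each (start, strand) the longest mapping is kept (ties resolved
    deterministically by read id and mate); coverage is the pileup of the
    kept representatives. Idempotent by construction.
    """
    name = str(allele.name)
    best: dict[tuple[int, str], Mapping] = {}
    for m in mappings:
        if m.allele != name:
            raise ValueError(f"mapping on {m.allele} passed to profile of {name}")
        key = (m.start, m.strand)
        prev = best.get(key)
        if (
            prev is None
            or (m.matched_len, prev.read_id, prev.mate) > (prev.matched_len, m.read_id, m.mate)
        ):
            best[key] = m
    n = len(allele.cdna)
    starts = np.zeros(n, dtype=np.int32)
    diff = np.zeros(n + 1, dtype=np.int64)
    kept = sorted(best.values())
    for m in kept:
        starts[m.start] += 1
        diff[m.start] += 1
        diff[m.end] -= 1
    coverage = np.cumsum(diff[:-1])
    ideal = ideal_profile(n, read_len, min_trunc_len)
    return StartPointProfile(name, starts, coverage, ideal, kept)


def write_mappings_tsv(mappings: Iterable[Mapping], path) -> None:
    """Debug export: read_id, mate, allele, start, matched_len, flags, strand."""
    with open(path, "w") as fh:
        fh.write("read_id\tmate\tallele\tstart\tmatched_len\ttruncated_5p\ttruncated_3p\tstrand\n")
        for m in mappings:
            fh.write(
                f"{m.read_id}\t{m.mate}\t{m.allele}\t{m.start}\t{m.matched_len}"
                f"\t{int(m.truncated_5p)}\t{int(m.truncated_3p)}\t{m.strand}\n"
            )
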