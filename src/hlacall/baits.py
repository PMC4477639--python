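"""Capture bait panel design.

The panel is seeded by a non-overlapping 120 bp tiling of genomic reference
haplotypes. It is then grown iteratively: each gDNA sequence, and afterwards
each cDNA exon treated as a stand-alone sequence, is scanned against the
current panel with an ungapped Hamming alignment (both orientations, up to
five mismatches); any uncovered run at least one bait length long is tiled to
produce additional baits. The finished panel leaves no such run in any input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from hlacall._util import revcomp

DEFAULT_BAIT_LEN = 120
DEFAULT_MAX_MISMATCHES = 5


@dataclass(frozen=True)
class Bait:
    """A fixed-length capture probe cut from a named source sequence."""

    sequence: str
    source_id: str
    source_interval: tuple[int, int]

    def __post_init__(self) -> None:
        s, e = self.source_interval
        if e - s != len(self.sequence):
            raise ValueError("source_interval length does not match bait sequence")


@dataclass(frozen=True)
class MismatchHit:
    """An ungapped placement of a bait on a target with <= max_mm mismatches."""

    target_id: str
    offset: int
    mismatch_count: int
    strand: str = "+"


@dataclass
class BaitPanel:
    """An ordered bait list; the reported size is the distinct-sequence count."""

    baits: list[Bait] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    @property
    def distinct_sequences(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.baits:
            seen.setdefault(b.sequence, None)
        return list(seen)

    @property
    def n_distinct(self) -> int:
        return len(self.distinct_sequences)

    def __len__(self) -> int:
        return self.n_distinct

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, seq in enumerate(self.distinct_sequences):
                fh.write(f">bait_{i:05d}\n{seq}\n")

    def write_bed(self, path: str | Path) -> None:
        """BED (0-based half-open): source_id, start, end, bait index."""
        index = {seq: i for i, seq in enumerate(self.distinct_sequences)}
        with open(path, "w") as fh:
            for b in self.baits:
                s, e = b.source_interval
                fh.write(f"{b.source_id}\t{s}\t{e}\tbait_{index[b.sequence]:05d}\n")


def target_fraction_percent(target_bp: float, genome_bp: float) -> float:
    """Share of the genome covered by the capture target, in percent.

    E.g. a 215.5 kb panel target against a 3.23 Gb genome is ~0.007% of the
    genome; the on-target read fraction divided by this share gives the
    fold enrichment.
    """
    if target_bp <= 0 or genome_bp <= 0:
        raise ValueError("sizes must be positive")
    return 100.0 * target_bp / genome_bp


def tile_sequence(seq: str, bait_len: int = DEFAULT_BAIT_LEN, source_id: str = "seq") -> list[Bait]:
    """Non-overlapping tiling at offsets 0, L, 2L, ...

    A trailing partial window is covered by one extra bait anchored at the
    3' end (overlapping the previous tile). Sequences shorter than the bait
    length yield an empty list with a warning.
    """
    n = len(seq)
    if n < bait_len:
        warnings.warn(f"{source_id}: length {n} < bait length {bait_len}; no baits")
        return []
    offsets = list(range(0, n - bait_len + 1, bait_len))
    if offsets[-1] + bait_len < n:
        offsets.append(n - bait_len)
    return [Bait(seq[o : o + bait_len], source_id, (o, o + bait_len)) for o in offsets]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _window_matrix(target: str, bait_len: int) -> np.ndarray:
    return sliding_window_view(_encode(target), bait_len)


def scan_mismatch_hits(
    bait: Bait | str,
    target: str,
    max_mm: int = DEFAULT_MAX_MISMATCHES,
    target_id: str = "target",
) -> list[MismatchHit]:
    """All ungapped placements of the bait (either orientation) on *target*
    with at most *max_mm* mismatches, by Hamming distance at every offset."""
    seq = bait.sequence if isinstance(bait, Bait) else bait
    if len(target) < len(seq):
        return []
    win = _window_matrix(target, len(seq))
    hits: dict[int, MismatchHit] = {}
    for strand, probe in (("+", seq), ("-", revcomp(seq))):
        mm = (win != _encode(probe)).sum(axis=1)
        for off in np.flatnonzero(mm <= max_mm):
            off = int(off)
            cand = MismatchHit(target_id, off, int(mm[off]), strand)
            prev = hits.get(off)
            if prev is None or cand.mismatch_count < prev.mismatch_count:
                hits[off] = cand
    return [hits[o] for o in sorted(hits)]


def _coverage_mask(
    target: str, bait_seqs: Sequence[str], max_mm: int, bait_len: int
) -> np.ndarray:
    """Boolean per-position mask of *target*: covered by any bait footprint."""
    covered = np.zeros(len(target), dtype=bool)
    if len(target) < bait_len or not bait_seqs:
        return covered
    win = _window_matrix(target, bait_len)
    footprint = np.zeros(len(target) - bait_len + 1, dtype=bool)
    for seq in bait_seqs:
        for probe in (seq, revcomp(seq)):
            mm = (win != _encode(probe)).sum(axis=1)
            footprint |= mm <= max_mm
    for off in np.flatnonzero(footprint):
        covered[off : off + bait_len] = True
    return covered


def uncovered_runs(
    target: str,
    panel: BaitPanel | Sequence[str],
    max_mm: int = DEFAULT_MAX_MISMATCHES,
    min_len: int = DEFAULT_BAIT_LEN,
    bait_len: int | None = None,
) -> list[tuple[int, int]]:
    """Maximal runs of positions not covered by any bait hit footprint,
    restricted to runs of length >= *min_len*; 0-based half-open intervals."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    seqs = panel.distinct_sequences if isinstance(panel, BaitPanel) else list(panel)
    if bait_len is None:
        bait_len = len(seqs[0]) if seqs else DEFAULT_BAIT_LEN
    covered = _coverage_mask(target, seqs, max_mm, bait_len)
    runs: list[tuple[int, int]] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([True], covered, [True])).astype(np.int8)))
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s >= min_len:
            runs.append((int(s), int(e)))
    return runs


def design_panel(
    genomic_refs: dict[str, str],
    gdna_collection: dict[str, str] | None = None,
    cdna_exon_collection: dict[str, str] | None = None,
    bait_len: int = DEFAULT_BAIT_LEN,
    max_mm: int = DEFAULT_MAX_MISMATCHES,
) -> BaitPanel:
    """Design a complete bait panel.

    Genomic reference haplotypes are tiled outright; then every gDNA, then
    every exon record, is checked against the accumulated panel and any
    uncovered run >= *bait_len* is tiled to add baits. Processing follows
    input order, which determines which baits are added; the result is
    deterministic for identical inputs. Records shorter than the bait length
    that cannot be covered are listed in ``panel.skipped`` with a warning.
    """
    panel = BaitPanel()
    seen: set[str] = set()

    def add(baits: Iterable[Bait]) -> None:
        for b in baits:
            panel.baits.append(b)
            seen.add(b.sequence)

    for name, seq in genomic_refs.items():
        add(tile_sequence(seq, bait_len, source_id=name))

    for collection in (gdna_collection or {}), (cdna_exon_collection or {}):
        for name, seq in collection.items():
            if len(seq) < bait_len:
                warnings.warn(
                    f"{name}: length {len(seq)} < bait length {bait_len}; cannot cover"
                )
                panel.skipped.append(name)
                continue
            for s, e in uncovered_runs(seq, list(seen), max_mm, bait_len, bait_len):
                add(
                    Bait(b.sequence, name, (s + b.source_interval[0], s + b.source_interval[1]))
                    for b in tile_sequence(seq[s:e], bait_len, source_id=name)
                )
    return panel


def exon_records_from_reference(reference, bait_len: int = DEFAULT_BAIT_LEN) -> dict[str, str]:
    """Stand-alone exon records for panel design, one per allele exon.

    Exons shorter than the bait length are padded with flanking cDNA to a
    single end-anchored window of exactly *bait_len* when the cDNA is long
    enough; otherwise the record is emitted as-is (and will be skipped with
    a warning by :func:`design_panel`).
    """
    records: dict[str, str] = {}
    for allele in reference.non_excluded():
        for i, (s, e) in enumerate(allele.exon_bounds):
            name = f"{allele.name}|exon{i + 1}"
            if e - s >= bait_len or len(allele.cdna) < bait_len:
                records[name] = allele.cdna[s:e]
            else:
                start = min(s, len(allele.cdna) - bait_len)
                end = max(e, start + bait_len)
                start = min(start, end - bait_len)
                records[name] = allele.cdna[start:end]
    return records
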