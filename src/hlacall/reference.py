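"""Allele reference collections: parsing, validation, naming and panel selection.

The reference dialect is a FASTA of cDNA (spliced, exon-only) sequences plus a
tab-separated sidecar annotation giving per-allele exon boundaries
(``allele_name  exon_index  start  end``, 0-based half-open) and an optional
plain-text exclusion list of allele names (one per line, optionally followed
by a reason) for database artifacts such as chimeric reference sequences.
"""

from __future__ import annotations

import csv
import random
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping as TMapping

from Bio import SeqIO

from hlacall._util import check_dna

# IMGT-style allele name: locus, "*", 1-4 colon-separated numeric fields.
_NAME_RE = re.compile(r"^(?P<locus>[A-Za-z][A-Za-z0-9-]*)\*(?P<fields>\d+(?::\d+){0,3})$")


@dataclass(frozen=True, order=True)
class AlleleName:
    """An HLA-style allele name, e.g. ``B*38:02:01``.

    ``fields`` are the colon-separated resolution fields: allele group,
    protein, synonymous cDNA variant, (non-coding variant).
    """

    locus: str
    fields: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.locus:
            raise ValueError("allele name: empty locus")
        if not 1 <= len(self.fields) <= 4:
            raise ValueError(f"allele name: need 1-4 fields, got {self.fields!r}")

    def __str__(self) -> str:
        return f"{self.locus}*{':'.join(self.fields)}"

    @classmethod
    def parse(cls, text: str) -> "AlleleName":
        m = _NAME_RE.match(text.strip())
        if m is None:
            raise ValueError(f"not a valid allele name: {text!r}")
        return cls(m.group("locus"), tuple(m.group("fields").split(":")))

    @classmethod
    def is_valid(cls, text: str) -> bool:
        return _NAME_RE.match(text.strip()) is not None


def truncate_resolution(name: AlleleName, n_fields: int) -> AlleleName:
    """Reduce *name* to its first *n_fields* fields (e.g. three-field -> two-field).

    Idempotent: asking for more fields than present returns the name unchanged.
    """
    if n_fields < 1:
        raise ValueError(f"n_fields must be >= 1, got {n_fields}")
    return AlleleName(name.locus, name.fields[: min(n_fields, len(name.fields))])


@dataclass(frozen=True)
class Allele:
    """A named cDNA sequence partitioned into exons."""

    name: AlleleName
    cdna: str
    exon_bounds: tuple[tuple[int, int], ...]
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if not self.cdna:
            raise ValueError(f"{self.name}: empty cDNA")
        pos = 0
        for i, (s, e) in enumerate(self.exon_bounds):
            if s != pos or e <= s:
                raise ValueError(
                    f"{self.name}: exon bounds {self.exon_bounds} do not partition "
                    f"[0,{len(self.cdna)}) (problem at exon {i}, position {pos})"
                )
            pos = e
        if pos != len(self.cdna):
            raise ValueError(
                f"{self.name}: exon bounds {self.exon_bounds} do not partition "
                f"[0,{len(self.cdna)}) (end at {pos})"
            )

    @property
    def boundaries(self) -> tuple[int, ...]:
        """All exon boundary coordinates including the two cDNA ends."""
        return (0,) + tuple(e for _, e in self.exon_bounds)

    def exon_seq(self, i: int) -> str:
        s, e = self.exon_bounds[i]
        return self.cdna[s:e]


class AlleleReference:
    """A multi-locus collection of alleles with unique names."""

    def __init__(self, alleles: Iterable[Allele] = ()):
        self._alleles: dict[str, Allele] = {}
        for a in alleles:
            self.add(a)

    def add(self, allele: Allele) -> None:
        key = str(allele.name)
        if key in self._alleles:
            raise ValueError(f"duplicate allele name: {key}")
        self._alleles[key] = allele

    def __len__(self) -> int:
        return len(self._alleles)

    def __iter__(self):
        return iter(self._alleles.values())

    def __contains__(self, name) -> bool:
        return str(name) in self._alleles

    def __eq__(self, other) -> bool:
        if not isinstance(other, AlleleReference):
            return NotImplemented
        return self._alleles == other._alleles

    def get(self, name) -> Allele:
        return self._alleles[str(name)]

    @property
    def loci(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for a in self._alleles.values():
            seen.setdefault(a.name.locus, None)
        return tuple(seen)

    def by_locus(self, locus: str, *, include_excluded: bool = False) -> list[Allele]:
        return [
            a
            for a in self._alleles.values()
            if a.name.locus == locus and (include_excluded or not a.excluded)
        ]

    def non_excluded(self) -> list[Allele]:
        return [a for a in self._alleles.values() if not a.excluded]

    def validate(self) -> None:
        """Check the cross-allele invariants (every locus has a usable allele)."""
        for locus in self.loci:
            if not self.by_locus(locus):
                raise ValueError(f"locus {locus}: every allele is excluded")

    def with_exclusions(self, names: TMapping[str, str]) -> "AlleleReference":
        """Return a copy with the given name -> reason exclusions applied."""
        out = AlleleReference()
        for a in self:
            if str(a.name) in names:
                a = replace(a, excluded=True, exclusion_reason=names[str(a.name)])
            out.add(a)
        return out


def _name_from_header(header: str) -> AlleleName:
    """Allele name from a FASTA header.

    IMGT headers look like ``HLA:HLA00001 A*01:01:01:01 1098 bp``; the allele
    name is then the second whitespace token. Plain headers carry the name as
    the first token.
    """
    tokens = header.split()
    if not tokens:
        raise ValueError("empty FASTA header")
    if len(tokens) >= 2 and AlleleName.is_valid(tokens[1]):
        return AlleleName.parse(tokens[1])
    return AlleleName.parse(tokens[0])


def read_allele_reference(
    fasta_source: str | Path,
    exon_annotation_source: str | Path,
    exclusion_source: str | Path | None = None,
) -> AlleleReference:
    """Load and validate a cDNA allele collection.

    Raises on duplicate allele names, non-ACGT bases and exon bounds that do
    not exactly partition the cDNA.
    """
    bounds: dict[str, list[tuple[int, int, int]]] = {}
    with open(exon_annotation_source, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            name, exon_index, start, end = row[0], int(row[1]), int(row[2]), int(row[3])
            bounds.setdefault(name, []).append((exon_index, start, end))

    exclusions: dict[str, str] = {}
    if exclusion_source is not None:
        for line in Path(exclusion_source).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            exclusions[parts[0]] = parts[1] if len(parts) > 1 else "excluded"

    ref = AlleleReference()
    for rec in SeqIO.parse(str(fasta_source), "fasta"):
        name = _name_from_header(rec.description)
        key = str(name)
        seq = check_dna(str(rec.seq), context=key)
        if key not in bounds:
            raise ValueError(f"{key}: no exon annotation found")
        ex = tuple((s, e) for _, s, e in sorted(bounds[key]))
        ref.add(
            Allele(
                name,
                seq,
                ex,
                excluded=key in exclusions,
                exclusion_reason=exclusions.get(key, ""),
            )
        )
    ref.validate()
    return ref


def write_allele_reference(
    reference: AlleleReference,
    fasta_path: str | Path,
    exon_annotation_path: str | Path,
    exclusion_path: str | Path | None = None,
) -> None:
    """Write *reference* in the package dialect (deterministic, round-trippable)."""
    with open(fasta_path, "w") as fa:
        for a in reference:
            fa.write(f">{a.name}\n")
            for i in range(0, len(a.cdna), 60):
                fa.write(a.cdna[i : i + 60] + "\n")
    with open(exon_annotation_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for a in reference:
            for i, (s, e) in enumerate(a.exon_bounds):
                w.writerow([str(a.name), i, s, e])
    if exclusion_path is not None:
        with open(exclusion_path, "w") as fh:
            for a in reference:
                if a.excluded:
                    fh.write(f"{a.name}\t{a.exclusion_reason}\n".rstrip() + "\n")


# ---------------------------------------------------------------------------
# Genotype tables and benchmark panel selection


class GenotypeTable:
    """Per sample, per locus: an unordered diploid allele-name pair."""

    def __init__(self):
        self._entries: dict[tuple[str, str], tuple[str, str]] = {}

    def set(self, sample: str, locus: str, allele1: str, allele2: str) -> None:
        a, b = sorted([str(AlleleName.parse(allele1)), str(AlleleName.parse(allele2))])
        self._entries[(sample, locus)] = (a, b)

    def get(self, sample: str, locus: str) -> tuple[str, str]:
        return self._entries[(sample, locus)]

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()

    @property
    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for sample, _ in self._entries:
            seen.setdefault(sample, None)
        return list(seen)

    def sample_alleles(self, sample: str) -> frozenset[str]:
        return frozenset(
            a
            for (s, _), pair in self._entries.items()
            if s == sample
            for a in pair
        )

    def all_alleles(self) -> frozenset[str]:
        return frozenset(a for pair in self._entries.values() for a in pair)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GenotypeTable":
        table = cls()
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                table.set(row[0], row[1], row[2], row[3])
        return table

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            for (sample, locus), (a, b) in self._entries.items():
                w.writerow([sample, locus, a, b])


def select_diverse_panel(
    table: GenotypeTable, n_restarts: int, seed: int
) -> list[str]:
    """Randomized greedy selection of a small sample panel covering all alleles.

    Each restart draws samples uniformly at random without replacement and
    keeps a sample iff it contributes at least one allele not yet in the pool,
    stopping once every distinct allele of the table is covered. The smallest
    pool over all restarts is returned (ties: first found). Restart ``r`` uses
    seed ``seed + r`` for reproducibility.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    samples = table.samples
    if not samples:
        return []
    alleles = {s: table.sample_alleles(s) for s in samples}
    target = table.all_alleles()
    best: list[str] | None = None
    for r in range(n_restarts):
        rng = random.Random(seed + r)
        order = samples[:]
        rng.shuffle(order)
        pool: list[str] = []
        covered: set[str] = set()
        for s in order:
            if alleles[s] - covered:
                pool.append(s)
                covered |= alleles[s]
                if len(covered) == len(target):
                    break
        if best is None or len(pool) < len(best):
            best = pool
    assert best is not None
    return best
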