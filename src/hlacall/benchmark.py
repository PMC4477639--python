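"""Simulation benchmarks: genotype-recovery and boundary-variant scenarios.

These drive the package end to end on synthetic data with known truth and
are shared by the test suite and the reproduction script.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from hlacall.calling import GenotypeCall, discriminate_boundary_variant
from hlacall.mapping import MappingIndex, reduce_start_points
from hlacall.pipeline import RunConfig, call_sample, map_records
from hlacall.reference import AlleleReference
from hlacall.simulate import (
    SimReadConfig,
    SimReferenceConfig,
    make_erroneous_reference_fixture,
    simulate_reads,
    simulate_reference,
)


@dataclass
class RecoveryResult:
    """Outcome of repeated simulate -> map -> call rounds."""

    n_total: int = 0
    n_exact: int = 0
    n_exact_per_locus: dict[str, int] = field(default_factory=dict)
    n_per_locus: dict[str, int] = field(default_factory=dict)
    n_alternatives: int = 0
    failures: list[tuple[tuple[str, str], tuple[str, str] | None]] = field(default_factory=list)

    @property
    def exact_rate(self) -> float:
        return self.n_exact / self.n_total if self.n_total else 0.0

    def exact_rate_for(self, locus: str) -> float:
        n = self.n_per_locus.get(locus, 0)
        return self.n_exact_per_locus.get(locus, 0) / n if n else 0.0

    @property
    def mean_alternatives(self) -> float:
        return self.n_alternatives / self.n_total if self.n_total else 0.0


def genotype_recovery(
    reference: AlleleReference | None = None,
    index: MappingIndex | None = None,
    n_per_locus: int = 100,
    depth: int = 50,
    error_rate: float = 0.0,
    seed: int = 0,
    loci: list[str] | None = None,
    run_config: RunConfig | None = None,
) -> RecoveryResult:
    """Draw random diploid genotypes per locus, simulate error-free capture
    reads at the given unique start-point depth, call them, and score how
    often the true pair ranks first."""
    if reference is None:
        reference, _ = simulate_reference(SimReferenceConfig(seed=seed))
    if index is None:
        index = MappingIndex(reference)
    config = run_config or RunConfig()
    rng = random.Random(seed + 1)
    result = RecoveryResult()
    for locus in loci if loci is not None else reference.loci:
        names = sorted(str(a.name) for a in reference.by_locus(locus))
        for i in range(n_per_locus):
            truth = tuple(sorted((rng.choice(names), rng.choice(names))))
            reads = simulate_reads(
                truth,
                reference,
                SimReadConfig(depth=depth, error_rate=error_rate, seed=rng.randrange(2**31)),
            )
            store = map_records(reads.records(), index)
            call = call_sample(reference, index, store, config, loci=[locus])[locus]
            result.n_total += 1
            result.n_per_locus[locus] = result.n_per_locus.get(locus, 0) + 1
            result.n_alternatives += len(call.alternatives)
            if call.best == truth:
                result.n_exact += 1
                result.n_exact_per_locus[locus] = result.n_exact_per_locus.get(locus, 0) + 1
            else:
                result.failures.append((truth, call.best))
    return result


def mini_mhc_fixture(
    seed: int = 0, n_loci: int = 3, alleles_per_locus: int = 10
) -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
    """A desk-scale stand-in for the MHC design inputs (synthetic): a few
    genomic haplotypes (one gDNA construct per locus, concatenated), one
    gDNA construct per allele, and every allele exon as a stand-alone
    record. Returns (haplotypes, gdnas, exon_records)."""
    from hlacall.baits import exon_records_from_reference
    from hlacall.simulate import genomic_construct

    reference, _ = simulate_reference(
        SimReferenceConfig(n_loci=n_loci, alleles_per_locus=alleles_per_locus, seed=seed)
    )
    gdnas = {
        f"gdna_{a.name}": genomic_construct(a, seed=seed * 1000 + i, flank_len=150)
        for i, a in enumerate(reference.non_excluded())
    }
    haplotypes = {}
    for h in range(3):
        parts = [
            genomic_construct(
                reference.by_locus(locus)[h], seed=seed * 77 + h * 10 + li, flank_len=150
            )
            for li, locus in enumerate(reference.loci)
        ]
        haplotypes[f"hap{h + 1}"] = "".join(parts)
    exon_records = exon_records_from_reference(reference)
    return haplotypes, gdnas, exon_records


@dataclass
class BoundaryVariantResult:
    decoy: str
    call: GenotypeCall
    decoy_is_candidate: bool
    decoy_outranked: bool
    gap_segments: list
    gap_in_3p_region: bool


def boundary_variant_scenario(
    offsets: tuple[int, ...] = (-34, -32),
    exon_index: int = 1,
    locus: str = "B",
    depth: int = 50,
    seed: int = 0,
) -> BoundaryVariantResult:
    """Stage the erroneous-reference scenario: a decoy allele differing from
    the sequenced one only a few bases upstream of an exon 3' boundary.

    Reads simulated from the true allele cannot cover the decoy's variant
    region — full-length placements mismatch and boundary-truncated ones are
    below the admissible minimum — so the decoy fails the full-coverage
    filter (or is out-ranked) and shows a gap segment in the 3' part of
    that exon.
    """
    reference, _ = simulate_reference(SimReferenceConfig(seed=seed))
    base = str(reference.by_locus(locus)[0].name)
    partner = str(reference.by_locus(locus)[5].name)
    reference, decoy = make_erroneous_reference_fixture(
        reference, base, offsets, exon_index=exon_index
    )
    index = MappingIndex(reference)
    reads = simulate_reads((base, partner), reference, SimReadConfig(depth=depth, seed=seed + 1))
    store = map_records(reads.records(), index)
    call = call_sample(reference, index, store, loci=[locus])[locus]

    decoy_allele = reference.get(decoy)
    profile = reduce_start_points(store.by_allele.get(decoy, ()), decoy_allele)
    gaps = discriminate_boundary_variant(profile, decoy_allele.exon_bounds)
    es, ee = decoy_allele.exon_bounds[exon_index]
    lo = ee + min(offsets)
    gap_in_3p = any(g.exon_index == exon_index and g.start <= lo and g.end > lo for g in gaps)
    is_candidate = any(decoy in sc.pair for sc in call.ranked)
    outranked = call.best is not None and decoy not in call.best
    return BoundaryVariantResult(decoy, call, is_candidate, outranked, gaps, gap_in_3p)
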