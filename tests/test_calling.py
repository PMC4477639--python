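"""Candidate filtering, pair parameters, harmonic-mean scoring and calling."""

import math
import random
from itertools import product

import numpy as np
import pytest

from hlacall.calling import (
    LocusData,
    Weights,
    call_genotype,
    central_read_ratio,
    discriminate_boundary_variant,
    harmonic_score,
    pair_raw_params,
    prefilter_candidates,
    scale_params,
    RawPairParams,
)
from hlacall.mapping import Mapping, MappingIndex, reduce_start_points
from hlacall.pipeline import call_sample, map_records
from hlacall.reference import Allele, AlleleName, AlleleReference
from hlacall.simulate import SimReadConfig, simulate_reads


# ---------------------------------------------------------------------------
# Harmonic mean


class TestHarmonicScore:
    def test_all_ones_is_exactly_one(self):
        assert harmonic_score((1.0, 1.0, 1.0, 1.0, 1.0)) == 1.0

    @pytest.mark.parametrize("k", range(5))
    def test_any_zero_annihilates(self, k):
        p = [0.8] * 5
        p[k] = 0.0
        assert harmonic_score(tuple(p)) == 0.0

    def test_all_zero_is_zero(self):
        assert harmonic_score((0.0,) * 5) == 0.0

    def test_half_vector_value(self):
        # 24 * 0.5^5 / (12) = 0.0625 with the default weights
        assert harmonic_score((0.5,) * 5) == pytest.approx(0.0625)

    def test_agrees_with_concrete_formula(self):
        """The general weighted form equals the expanded five-parameter
        formula for weights (0.5, 1, 0.1, 0.1, 1)."""
        rng = random.Random(0)
        for _ in range(200):
            asm, req, msl, mppr, auc = (rng.random() for _ in range(5))
            concrete = (
                (2 + 1 + 10 + 10 + 1) * asm * req * msl * mppr * auc
            ) / (2 * asm + 1 * req + 10 * msl + 10 * mppr + 1 * auc)
            general = harmonic_score((asm, req, msl, mppr, auc))
            assert general == pytest.approx(concrete, abs=1e-12)

    def test_strictly_monotone_in_each_parameter(self):
        grid = [0.2, 0.5, 0.8]
        for k in range(5):
            for others in product(grid, repeat=4):
                lo, hi = list(others), list(others)
                lo.insert(k, 0.3)
                hi.insert(k, 0.7)
                assert harmonic_score(tuple(lo)) < harmonic_score(tuple(hi))

    def test_bounded_by_one(self):
        rng = random.Random(1)
        for _ in range(200):
            p = tuple(rng.random() for _ in range(5))
            assert 0.0 <= harmonic_score(p) <= 1.0

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            Weights(asm=0.0)


# ---------------------------------------------------------------------------
# Central-read filter


def _toy_allele(length=2000):
    rng = random.Random(3)
    cdna = "".join(rng.choice("ACGT") for _ in range(length))
    return Allele(AlleleName.parse("A*01:01"), cdna, ((0, length),))


def _profile_with(allele, central_starts, noncentral_starts, read_len=100):
    maps = [
        Mapping(f"c{i}", 1, str(allele.name), s, read_len, False, False, "+")
        for i, s in enumerate(central_starts)
    ] + [
        Mapping(f"n{i}", 1, str(allele.name), s, read_len, False, False, "+")
        for i, s in enumerate(noncentral_starts)
    ]
    return reduce_start_points(maps, allele, read_len=read_len)


class TestCentralReadRatio:
    def test_all_central_gives_infinity(self):
        allele = _toy_allele()
        prof = _profile_with(allele, range(500, 520), [])
        assert central_read_ratio(prof) == math.inf

    def test_ratio_point_one_fails_threshold(self):
        allele = _toy_allele()
        prof = _profile_with(allele, [500], range(0, 10))
        assert central_read_ratio(prof) == pytest.approx(0.1)
        assert not central_read_ratio(prof) >= 0.2

    def test_ratio_exactly_point_two_passes(self):
        """The rule is 'dropped below 0.2': exactly 0.2 is kept."""
        allele = _toy_allele()
        prof = _profile_with(allele, [500, 600], range(0, 10))
        ratio = central_read_ratio(prof)
        assert ratio == 0.2
        assert ratio >= 0.2

    def test_just_below_point_two_fails(self):
        allele = _toy_allele(2000)
        central = [
            Mapping(f"c{i}", 1, str(allele.name), 500 + i, 100, False, False, "+")
            for i in range(19)
        ]
        noncentral = [
            Mapping(f"n{i}{st}", 1, str(allele.name), i, 100, False, False, st)
            for i in range(48)
            for st in "+-"
        ]
        prof = reduce_start_points(central + noncentral, allele)
        # 19 central / 96 noncentral is just below the threshold
        assert central_read_ratio(prof) == pytest.approx(19 / 96)
        assert not central_read_ratio(prof) >= 0.2

    def test_no_mappings_is_no_data(self):
        allele = _toy_allele()
        prof = reduce_start_points([], allele)
        assert math.isnan(central_read_ratio(prof))
        assert not central_read_ratio(prof) >= 0.2


# ---------------------------------------------------------------------------
# Pre-filtering


def _full_coverage_mappings(allele, read_len=100, prefix="f"):
    """Start points tiling the whole cDNA, truncated reads covering the ends."""
    maps = []
    n = len(allele.cdna)
    for i, s in enumerate(range(0, n - read_len + 1, 25)):
        maps.append(Mapping(f"{prefix}{i}", 1, str(allele.name), s, read_len, False, False, "+"))
    maps.append(Mapping(f"{prefix}e", 1, str(allele.name), n - read_len, read_len, False, False, "+"))
    return maps


class TestPrefilter:
    def test_fully_covered_allele_is_candidate(self):
        allele = _toy_allele(1000)
        prof = reduce_start_points(_full_coverage_mappings(allele), allele)
        assert prof.fully_covered
        res = prefilter_candidates({"A*01:01": prof})
        assert res.candidates == ["A*01:01"]
        assert res.qc.failed == []

    def test_one_uncovered_base_rejected_and_ranked_first(self):
        a1 = _toy_allele(1000)
        a2 = Allele(AlleleName.parse("A*02:01"), a1.cdna, ((0, 1000),))
        prof1 = reduce_start_points(_full_coverage_mappings(a1), a1)
        # drop the final reads: the last base(s) are uncovered
        maps2 = [
            Mapping(m.read_id, m.mate, "A*02:01", m.start, m.matched_len, False, False, "+")
            for m in _full_coverage_mappings(a2)[:-2]
        ]
        prof2 = reduce_start_points(maps2, a2)
        assert 0 < prof2.n_uncovered < 1000
        res = prefilter_candidates({"A*01:01": prof1, "A*02:01": prof2})
        assert res.candidates == ["A*01:01"]
        assert res.qc.failed[0][0] == "A*02:01"
        assert res.qc.undercovered[0] == ("A*02:01", prof2.n_uncovered)

    def test_undercovered_table_capped_at_50(self):
        profs = {}
        base = _toy_allele(1000)
        for i in range(60):
            name = f"A*{i + 1:02d}:01"
            allele = Allele(AlleleName.parse(name), base.cdna, ((0, 1000),))
            maps = _full_coverage_mappings(allele, prefix=f"x{i}_")[: 5 + i % 7]
            for_m = [
                Mapping(m.read_id, m.mate, name, m.start, m.matched_len, False, False, "+")
                for m in maps
            ]
            profs[name] = reduce_start_points(for_m, allele)
        res = prefilter_candidates(profs)
        assert len(res.qc.undercovered) == 50
        errors = [e for _, e in res.qc.undercovered]
        assert errors == sorted(errors)
        assert len(res.qc.failed) == 60

    def test_low_cov_mode_emits_review_list(self):
        allele = _toy_allele(1000)
        prof = reduce_start_points(_full_coverage_mappings(allele)[:-2], allele)
        res = prefilter_candidates({"A*01:01": prof}, low_cov_mode=True)
        assert res.candidates == []
        assert res.review and res.review[0][0] == "A*01:01"

    def test_force_include_and_exclude(self):
        allele = _toy_allele(1000)
        good = reduce_start_points(_full_coverage_mappings(allele), allele)
        bad_allele = Allele(AlleleName.parse("A*02:01"), allele.cdna, ((0, 1000),))
        bad = reduce_start_points([], bad_allele)
        res = prefilter_candidates(
            {"A*01:01": good, "A*02:01": bad},
            force_include=["A*02:01"],
            force_exclude=["A*01:01"],
        )
        assert res.candidates == ["A*02:01"]


# ---------------------------------------------------------------------------
# Pair parameters and scaling


def _locus_scenario(small_reference, small_index, locus="A", seed=21, depth=25):
    ref, _ = small_reference
    names = sorted(str(a.name) for a in ref.by_locus(locus))
    truth = (names[0], names[3])
    reads = simulate_reads(truth, ref, SimReadConfig(depth=depth, seed=seed))
    store = map_records(reads.records(), small_index)
    profiles = {
        str(a.name): reduce_start_points(store.by_allele.get(str(a.name), ()), a)
        for a in ref.by_locus(locus)
    }
    return ref, truth, store, profiles


class TestPairRawParams:
    def test_recount_oracle_heterozygous(self, small_reference, small_index):
        """asm/req/mppr recomputed by brute-force recount of the mapping table."""
        ref, truth, store, profiles = _locus_scenario(small_reference, small_index)
        a, b = truth
        data = LocusData.build(profiles, [a, b], store.by_allele)
        raw = pair_raw_params(a, b, data)

        reads_a = {(m.read_id, m.mate) for m in store.by_allele.get(a, ())}
        reads_b = {(m.read_id, m.mate) for m in store.by_allele.get(b, ())}
        asm_a, asm_b = len(reads_a - reads_b), len(reads_b - reads_a)
        assert (raw.asm_a, raw.asm_b) == (asm_a, asm_b)
        assert raw.asm == asm_a + asm_b
        assert raw.req == pytest.approx(min(asm_a, asm_b) / max(asm_a, asm_b))
        assert raw.req > 0.5  # balanced evidence at equal simulated depth

        def paired(reads):
            return sum(1 for rid, mate in reads if (rid, 3 - mate) in reads)

        expect_mppr = (paired(reads_a) + paired(reads_b)) / (len(reads_a) + len(reads_b))
        assert raw.mppr == pytest.approx(expect_mppr)
        assert raw.msl == pytest.approx(
            (len(ref.get(a).cdna) + len(ref.get(b).cdna)) / 2
        )
        assert 0.0 <= raw.auc <= 1.0

    def test_identical_sequence_alleles_have_no_exclusive_reads(self):
        allele = _toy_allele(1000)
        twin = Allele(AlleleName.parse("A*02:01"), allele.cdna, ((0, 1000),))
        maps1 = _full_coverage_mappings(allele)
        maps2 = [
            Mapping(m.read_id, m.mate, "A*02:01", m.start, m.matched_len, False, False, "+")
            for m in maps1
        ]
        profiles = {
            "A*01:01": reduce_start_points(maps1, allele),
            "A*02:01": reduce_start_points(maps2, twin),
        }
        data = LocusData.build(
            profiles, ["A*01:01", "A*02:01"], {"A*01:01": maps1, "A*02:01": maps2}
        )
        raw = pair_raw_params("A*01:01", "A*02:01", data)
        assert raw.asm_a == raw.asm_b == 0
        assert raw.req == 0.0

    def test_homozygous_req_is_one(self, small_reference, small_index):
        ref, truth, store, profiles = _locus_scenario(small_reference, small_index)
        a = truth[0]
        data = LocusData.build(profiles, list(truth), store.by_allele)
        raw = pair_raw_params(a, a, data)
        assert raw.req == 1.0
        # exclusive set counted once, not doubled
        assert raw.asm == raw.asm_a


class TestScaleParams:
    def test_single_pair_scales_to_ones(self):
        raw = [RawPairParams(3, 4, 7, 0.75, 1000.0, 0.9, 0.8)]
        (scaled,) = scale_params(raw)
        assert scaled == (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_divide_by_max(self):
        raw = [
            RawPairParams(5, 5, 10, 1.0, 1000.0, 0.5, 1.0),
            RawPairParams(3, 2, 5, 0.5, 1000.0, 0.25, 0.5),
        ]
        scaled = scale_params(raw)
        assert scaled[0][0] == 1.0 and scaled[1][0] == 0.5
        assert scaled[1][3] == 0.5

    def test_zero_column_stays_zero(self):
        raw = [RawPairParams(0, 0, 0, 0.0, 100.0, 0.0, 1.0)]
        (scaled,) = scale_params(raw)
        assert scaled[0] == 0.0 and scaled[2] == 1.0

    def test_idempotent_and_max_attained(self):
        rng = random.Random(2)
        raw = [
            RawPairParams(
                rng.randrange(50),
                rng.randrange(50),
                rng.randrange(100),
                rng.random(),
                rng.uniform(500, 1500),
                rng.random(),
                rng.random(),
            )
            for _ in range(20)
        ]
        scaled = scale_params(raw)
        cols = list(zip(*scaled))
        for col in cols:
            assert max(col) == pytest.approx(1.0)
        again = scale_params(
            [RawPairParams(0, 0, s[0], s[1], s[2], s[3], s[4]) for s in scaled]
        )
        for s1, s2 in zip(scaled, again):
            assert s1 == pytest.approx(s2)


# ---------------------------------------------------------------------------
# Genotype calling


class TestCallGenotype:
    def test_recovers_heterozygous_truth(self, small_reference, small_index):
        ref, truth, store, profiles = _locus_scenario(small_reference, small_index)
        call = call_sample(ref, small_index, store, loci=["A"])["A"]
        assert call.best == tuple(sorted(truth))
        assert "no_call" not in call.flags

    def test_truth_recovery_over_many_random_genotypes(self, small_reference, small_index):
        """True pair attains the maximum H across repeated random genotypes."""
        from hlacall.benchmark import genotype_recovery

        ref, _ = small_reference
        res = genotype_recovery(
            ref, small_index, n_per_locus=50, depth=50, seed=77, loci=["A", "B"]
        )
        assert res.n_total == 100
        assert res.exact_rate == 1.0

    def test_true_alleles_always_pass_prefilter(self, small_reference, small_index):
        ref, truth, store, profiles = _locus_scenario(small_reference, small_index, depth=50)
        res = prefilter_candidates(profiles)
        assert set(truth) <= set(res.candidates)

    def test_identical_cdna_alleles_reported_as_alternative(self, small_reference, small_index):
        ref, _ = small_reference
        # clone an allele under a new name: indistinguishable by construction
        orig = ref.by_locus("A")[0]
        clone = Allele(AlleleName.parse("A*77:01"), orig.cdna, orig.exon_bounds)
        ref2 = AlleleReference(list(ref))
        ref2.add(clone)
        idx2 = MappingIndex(ref2)
        truth = (str(orig.name), str(ref.by_locus("A")[2].name))
        reads = simulate_reads(truth, ref2, SimReadConfig(depth=50, seed=31))
        store = map_records(reads.records(), idx2)
        call = call_sample(ref2, idx2, store, loci=["A"])["A"]
        assert set(call.best) <= {*truth, "A*77:01"}
        assert len(call.alternatives) >= 1
        alt_names = {n for p in call.alternatives for n in p}
        assert "A*77:01" in alt_names or str(orig.name) in alt_names

    def test_homozygous_recovery(self, small_reference, small_index):
        ref, _ = small_reference
        a = str(ref.by_locus("B")[2].name)
        reads = simulate_reads((a, a), ref, SimReadConfig(depth=50, seed=41))
        store = map_records(reads.records(), small_index)
        call = call_sample(ref, small_index, store, loci=["B"])["B"]
        assert call.best == (a, a)
        # no heterozygous pair outranks the homozygote
        assert call.ranked[0].pair == (a, a)

    def test_no_candidates_is_no_call(self):
        allele = _toy_allele(1000)
        prof = reduce_start_points([], allele)
        call = call_genotype("A", {"A*01:01": prof}, [], {})
        assert call.no_call and "no_call" in call.flags

    def test_low_read_count_flag(self, small_reference, small_index):
        ref, truth, store, _ = _locus_scenario(small_reference, small_index)
        call = call_sample(ref, small_index, store, loci=["A"])["A"]
        assert "low_read_count" in call.flags  # simulated depth << 7 million reads


# ---------------------------------------------------------------------------
# Boundary-variant discrimination


class TestDiscriminateBoundaryVariant:
    def test_self_mapping_has_empty_report(self, small_reference, small_index):
        ref, truth, store, profiles = _locus_scenario(small_reference, small_index, depth=50)
        a = truth[0]
        prof = profiles[a]
        assert prof.fully_covered
        assert discriminate_boundary_variant(prof, ref.get(a).exon_bounds) == []

    def test_report_empty_iff_fully_covered(self, small_reference, small_index):
        ref, truth, store, profiles = _locus_scenario(small_reference, small_index, depth=10)
        for name, prof in profiles.items():
            report = discriminate_boundary_variant(prof, ref.get(name).exon_bounds)
            assert (report == []) == prof.fully_covered

    def test_decoy_near_exon_end_shows_3p_gap(self):
        from hlacall.benchmark import boundary_variant_scenario

        res = boundary_variant_scenario(offsets=(-34, -32), exon_index=1, seed=5)
        assert res.gap_in_3p_region
        assert (not res.decoy_is_candidate) or res.decoy_outranked
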