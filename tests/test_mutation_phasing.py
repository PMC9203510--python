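"""Haplotagging rules, somatic variant haplotype assignment and ordering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapcontext.phasing import HP1, HP2, UNTAGGED, blocks_from_read_connectivity
from hapcontext.reads import _label_from_counts, tag_read, tag_reads
from hapcontext.simulate import SimulationConfig, simulate_diploid_genome, \
    simulate_long_reads, inject_somatic_events, BiasRegionSpec, simulate_tumor
from hapcontext.somatic import (
    UNKNOWN,
    OrderedPair,
    SomaticVariant,
    StructuralVariant,
    assign_snv_haplotype,
    order_mutation_pairs,
    phase_sv,
    phase_snvs,
)

from conftest import make_block


def rule_tag(hp1, hp2):
    """Independent restatement of the phased-read rule: >=2 informative SNPs
    and majority ratio >= 0.7 (exact rational arithmetic)."""
    total = hp1 + hp2
    if total < 2 or hp1 == hp2:
        return UNTAGGED
    if 10 * max(hp1, hp2) >= 7 * total:
        return HP1 if hp1 > hp2 else HP2
    return UNTAGGED


class TestTagRead:
    def test_clean_hp1_read(self):
        blk = make_block([0] * 6)
        obs = [(s.pos, s.hp1_allele) for s in blk.snps[:5]]
        tag = tag_read(obs, blk, "r1")
        assert tag.label == HP1 and (tag.hp1_count, tag.hp2_count) == (5, 0)

    def test_two_to_one_is_below_ratio(self):
        blk = make_block([0] * 3)
        obs = [(blk.snps[0].pos, blk.snps[0].hp1_allele),
               (blk.snps[1].pos, blk.snps[1].hp1_allele),
               (blk.snps[2].pos, blk.snps[2].hp2_allele)]
        assert tag_read(obs, blk).label == UNTAGGED  # 2/3 < 0.7

    def test_seven_to_three_boundary_inclusive(self):
        blk = make_block([0] * 10)
        obs = [(s.pos, s.hp1_allele) for s in blk.snps[:7]] + [
            (s.pos, s.hp2_allele) for s in blk.snps[7:]
        ]
        assert tag_read(obs, blk).label == HP1  # ratio exactly 0.7

    def test_error_allele_is_non_informative(self):
        blk = make_block([0] * 4)  # alleles A/G
        obs = [(blk.snps[0].pos, "T"), (blk.snps[1].pos, "C")]
        tag = tag_read(obs, blk)
        assert tag.informative == 0 and tag.label == UNTAGGED

    def test_single_snp_untagged(self):
        blk = make_block([0] * 3)
        obs = [(blk.snps[0].pos, blk.snps[0].hp1_allele)]
        assert tag_read(obs, blk).label == UNTAGGED

    def test_rule_grid_up_to_ten_observations(self):
        for hp1 in range(11):
            for hp2 in range(11 - hp1):
                assert _label_from_counts(hp1, hp2) == rule_tag(hp1, hp2), \
                    (hp1, hp2)


class TestAssignSnv:
    @pytest.mark.parametrize(
        "hp1, hp2, expected",
        [
            (3, 1, HP1),   # boundary of the published rule
            (1, 3, HP2),
            (3, 2, UNKNOWN),
            (2, 0, UNKNOWN),
            (5, 0, HP1),
            (0, 0, UNKNOWN),
        ],
    )
    def test_rule_boundaries(self, hp1, hp2, expected):
        hap, _ = assign_snv_haplotype(hp1, hp2)
        assert hap == expected

    def test_zero_coverage_reason(self):
        assert assign_snv_haplotype(0, 0) == (UNKNOWN, "no_coverage")

    def test_rule_grid_up_to_ten_reads(self):
        for hp1 in range(11):
            for hp2 in range(11):
                hap, _ = assign_snv_haplotype(hp1, hp2)
                want = (
                    HP1 if hp1 >= 3 and hp2 <= 1
                    else HP2 if hp2 >= 3 and hp1 <= 1
                    else UNKNOWN
                )
                assert hap == want

    @given(st.integers(3, 30), st.integers(0, 1), st.integers(1, 20))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_majority_reads(self, major, minor, extra):
        """Adding mutant reads to the majority haplotype never flips the call."""
        before, _ = assign_snv_haplotype(major, minor)
        after, _ = assign_snv_haplotype(major + extra, minor)
        assert before == after == HP1


def _tagged(label, block_id=1):
    from hapcontext.reads import HaplotaggedRead

    return HaplotaggedRead("r", block_id, [], 3, 0, label)


class TestPhaseSV:
    def _sv(self, read_ids, chrom="chr1"):
        return StructuralVariant("sv1", "deletion", chrom, 1000, "+",
                                 chrom, 9000, "-",
                                 supporting_read_ids=list(read_ids))

    def test_three_reads_same_hap_is_phased(self):
        tags = {f"r{i}": _tagged(HP1) for i in range(3)}
        sv = phase_sv(self._sv(tags), tags)
        assert sv.hap == HP1

    def test_seven_three_boundary_ratio(self):
        tags = {f"a{i}": _tagged(HP1) for i in range(7)}
        tags.update({f"b{i}": _tagged(HP2) for i in range(3)})
        sv = phase_sv(self._sv(tags), tags)
        assert sv.hap == HP1  # exactly 0.7

    def test_two_reads_insufficient(self):
        tags = {f"r{i}": _tagged(HP1) for i in range(2)}
        sv = phase_sv(self._sv(tags), tags)
        assert sv.hap == UNKNOWN and sv.reason == "insufficient_phased_support"

    def test_non_autosomal_excluded(self):
        tags = {f"r{i}": _tagged(HP1) for i in range(5)}
        sv = phase_sv(self._sv(tags, chrom="chrX"), tags)
        assert sv.hap == UNKNOWN and sv.reason == "non_autosomal"

    def test_rule_grid_up_to_ten_supporting_reads(self):
        for n1 in range(11):
            for n2 in range(11 - n1):
                tags = {f"a{i}": _tagged(HP1) for i in range(n1)}
                tags.update({f"b{i}": _tagged(HP2) for i in range(n2)})
                sv = phase_sv(self._sv(tags), tags)
                total = n1 + n2
                want = UNKNOWN
                if total >= 3 and n1 != n2 and 10 * max(n1, n2) >= 7 * total:
                    want = HP1 if n1 > n2 else HP2
                assert sv.hap == want, (n1, n2)

    def test_duplicate_read_ids_count_once(self):
        tags = {"r0": _tagged(HP1), "r1": _tagged(HP1)}
        sv = self._sv(["r0", "r0", "r0", "r1"])
        assert phase_sv(sv, tags).hap == UNKNOWN  # only 2 distinct reads


class TestOrdering:
    def _pairs(self, neither=0, a_only=0, b_only=0, both=0):
        va = SomaticVariant("chr1", 100, "A", "T")
        vb = SomaticVariant("chr1", 200, "C", "G")
        read_alleles = {}
        k = 0
        for n, (has_a, has_b) in (
            (neither, (False, False)), (a_only, (True, False)),
            (b_only, (False, True)), (both, (True, True)),
        ):
            for _ in range(n):
                read_alleles[f"r{k}"] = {va.var_id: has_a, vb.var_id: has_b}
                k += 1
        return order_mutation_pairs([va, vb], read_alleles), va, vb

    def test_nested_pattern_orders_first_before_second(self):
        pairs, va, vb = self._pairs(neither=5, a_only=3, both=4)
        [p] = pairs
        assert p.relation == "ordered"
        assert (p.first, p.second) == (va.var_id, vb.var_id)

    def test_only_neither_and_both_is_co_occurring(self):
        pairs, *_ = self._pairs(neither=5, both=5)
        assert pairs[0].relation == "co_occurring"

    def test_exclusive_patterns_conflict(self):
        pairs, *_ = self._pairs(a_only=3, b_only=3)
        assert pairs[0].relation == "conflicting"

    def test_single_supporting_read_is_unresolved(self):
        pairs, *_ = self._pairs(neither=5, a_only=1, both=4)
        assert pairs[0].relation == "unresolved"

    def test_pairs_not_co_spanned_are_absent(self):
        va = SomaticVariant("chr1", 100, "A", "T")
        vb = SomaticVariant("chr1", 99_999_999, "C", "G")
        read_alleles = {"r0": {va.var_id: True}, "r1": {vb.var_id: True}}
        assert order_mutation_pairs([va, vb], read_alleles) == []

    def test_nested_clones_never_reverse_order(self, rng):
        """With B arising only on A-bearing molecules, no pair is ever
        ordered B before A."""
        va = SomaticVariant("chr1", 100, "A", "T")
        vb = SomaticVariant("chr1", 200, "C", "G")
        for _ in range(50):
            read_alleles = {}
            for k in range(30):
                has_a = rng.random() < 0.6
                has_b = bool(has_a and rng.random() < 0.5)
                read_alleles[f"r{k}"] = {va.var_id: bool(has_a),
                                         vb.var_id: has_b}
            for p in order_mutation_pairs([va, vb], read_alleles):
                if p.relation == "ordered":
                    assert (p.first, p.second) == (va.var_id, vb.var_id)


class TestRecoveryOnSyntheticReads:
    def _phase_case(self, per_base_error, seed, somatic_rate=40.0):
        cfg = SimulationConfig(genome_length=400_000, depth=30,
                               per_base_error=per_base_error,
                               somatic_rate=somatic_rate, seed=seed)
        genome, snps, truth = simulate_diploid_genome(cfg)
        callset = inject_somatic_events(genome, snps, cfg, truth)
        reads = simulate_long_reads(genome, snps, cfg, callset)
        blocks = blocks_from_read_connectivity(snps, reads)
        tagged = tag_reads(reads, blocks)
        snv_at = {(v.chrom, v.pos): v for v in callset.snvs}
        by_var = {}
        for r in reads:
            for pos, allele in r.somatic_observations:
                v = snv_at.get((r.chrom, pos))
                if v is not None and allele == v.alt:
                    by_var.setdefault(v.var_id, []).append(r.read_id)
        return phase_snvs(callset.snvs, tagged, by_var), callset.truth

    def test_error_free_variants_recover_truth_haplotype(self):
        """Every variant meeting the 3-vs-<=1 rule lands on its true
        haplotype when reads are error free."""
        variants, truth = self._phase_case(0.0, seed=21)
        assigned = [v for v in variants if v.hap != UNKNOWN]
        assert len(assigned) >= 0.8 * len(variants)
        for v in assigned:
            want = HP1 if truth.snv_hap[v.var_id] == 1 else HP2
            assert v.hap == want

    def test_misassignment_under_noise_below_one_percent(self):
        """At 10% per-base error and 30x depth, fewer than 1% of assigned
        variants land on the wrong haplotype."""
        wrong = assigned = 0
        for seed in (31, 32, 33):
            variants, truth = self._phase_case(0.10, seed=seed,
                                               somatic_rate=150.0)
            for v in variants:
                if v.hap == UNKNOWN:
                    continue
                assigned += 1
                want = HP1 if truth.snv_hap[v.var_id] == 1 else HP2
                wrong += v.hap != want
        assert assigned > 60
        assert wrong / assigned < 0.01

    def test_sv_haplotypes_recovered_from_supporting_reads(self, demo_case):
        blocks = blocks_from_read_connectivity(demo_case.snps, demo_case.reads)
        tagged = tag_reads(demo_case.reads, blocks)
        from hapcontext.somatic import phase_svs

        svs = phase_svs(demo_case.somatic.svs, tagged)
        phased = [s for s in svs if s.hap != UNKNOWN]
        assert len(phased) >= 0.9 * len(svs)
        for s in phased:
            want = HP1 if demo_case.truth.sv_hap[s.sv_id] == 1 else HP2
            assert s.hap == want
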