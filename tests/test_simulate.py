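"""Calibration, determinism and truth-consistency of the synthetic generator."""

import numpy as np
import pytest

from hapcontext.phasing import n50
from hapcontext.signatures import trinucleotide_spectrum, cosine_similarity, builtin_signatures
from hapcontext.simulate import (
    BiasRegionSpec,
    ConfigError,
    MethylationRegionSpec,
    SimulationConfig,
    SVClusterSpec,
    apply_truth_haplotypes,
    inject_somatic_events,
    simulate_diploid_genome,
    simulate_long_reads,
    simulate_tumor,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, fieldname",
        [
            (dict(genome_length=0), "genome_length"),
            (dict(depth=0), "depth"),
            (dict(per_base_error=1.5), "per_base_error"),
            (dict(snp_rate=-0.1), "snp_rate"),
            (dict(read_n50=0), "read_n50"),
        ],
    )
    def test_invalid_scalar_names_field(self, kwargs, fieldname):
        with pytest.raises(ConfigError, match=fieldname):
            SimulationConfig(**kwargs).validate()

    def test_out_of_bounds_interval_rejected(self):
        cfg = SimulationConfig(
            genome_length=1000,
            bias_regions=(BiasRegionSpec("chr1", 500, 2000, 1, 1.0, 5),),
        )
        with pytest.raises(ConfigError, match="bias_regions"):
            cfg.validate()

    def test_contradictory_overlapping_regions_rejected(self):
        cfg = SimulationConfig(
            genome_length=100_000,
            bias_regions=(
                BiasRegionSpec("chr1", 1000, 5000, 1, 1.0, 5),
                BiasRegionSpec("chr1", 3000, 8000, 2, 1.0, 5),
            ),
        )
        with pytest.raises(ConfigError, match="contradictory"):
            cfg.validate()


class TestGenome:
    def test_snp_count_near_expectation(self):
        cfg = SimulationConfig(genome_length=1_500_000, snp_rate=1 / 1500, seed=1)
        _, snps, _ = simulate_diploid_genome(cfg)
        # Poisson with mean 1000: 5 sigma band
        assert abs(len(snps) - 1000) < 5 * np.sqrt(1000)

    def test_zero_snp_rate_gives_empty_set(self):
        cfg = SimulationConfig(genome_length=100_000, snp_rate=0.0, seed=1)
        _, snps, truth = simulate_diploid_genome(cfg)
        assert snps == [] and truth.snp_count == 0

    def test_determinism_byte_identical(self, tmp_path):
        from hapcontext.io import write_fasta, write_phased_vcf, write_reads_tsv

        cfg = SimulationConfig(genome_length=120_000, depth=8, seed=42)
        outs = []
        for run in ("a", "b"):
            case = simulate_tumor(cfg)
            fa = tmp_path / f"{run}.fa"
            vcf = tmp_path / f"{run}.vcf"
            tsv = tmp_path / f"{run}.tsv"
            write_fasta(case.genome, str(fa))
            write_phased_vcf(case.snps, str(vcf))
            write_reads_tsv(case.reads, str(tsv))
            outs.append((fa.read_bytes(), vcf.read_bytes(), tsv.read_bytes()))
        assert outs[0] == outs[1]

    def test_snp_alleles_are_heterozygous_on_reference(self):
        cfg = SimulationConfig(genome_length=60_000, seed=3)
        genome, snps, _ = simulate_diploid_genome(cfg)
        for s in snps[:50]:
            assert genome.base(s.chrom, s.pos) == s.ref
            assert {s.hp1_allele, s.hp2_allele} == {s.ref, s.alt}


class TestReads:
    def test_error_free_reads_match_one_haplotype(self):
        cfg = SimulationConfig(genome_length=200_000, depth=5,
                               per_base_error=0.0, seed=5)
        genome, snps, _ = simulate_diploid_genome(cfg)
        allele = {
            (s.chrom, s.pos): (s.hp1_allele, s.hp2_allele) for s in snps
        }
        reads = simulate_long_reads(genome, snps, cfg)
        checked = 0
        for read in reads:
            for pos, obs in read.observations:
                hp1, hp2 = allele[(read.chrom, pos)]
                assert obs == (hp1 if read.hap_truth == 1 else hp2)
                checked += 1
        assert checked > 100

    def test_depth_calibration(self):
        cfg = SimulationConfig(genome_length=1_000_000, depth=30, seed=6)
        genome, snps, _ = simulate_diploid_genome(cfg)
        reads = simulate_long_reads(genome, snps, cfg)
        total = sum(r.end - r.start + 1 for r in reads)
        assert total == pytest.approx(3.0e7, rel=0.1)

    def test_read_n50_calibration(self):
        cfg = SimulationConfig(genome_length=2_000_000, read_n50=16_000, seed=7)
        genome, snps, _ = simulate_diploid_genome(cfg)
        reads = simulate_long_reads(genome, snps, cfg, n_reads=10_000)
        realized = n50([r.end - r.start + 1 for r in reads])
        assert realized == pytest.approx(16_000, rel=0.10)

    def test_error_rate_flips_expected_fraction(self):
        cfg = SimulationConfig(genome_length=300_000, depth=10,
                               per_base_error=0.10, seed=8)
        genome, snps, _ = simulate_diploid_genome(cfg)
        allele = {(s.chrom, s.pos): (s.hp1_allele, s.hp2_allele) for s in snps}
        reads = simulate_long_reads(genome, snps, cfg)
        flipped = total = 0
        for read in reads:
            for pos, obs in read.observations:
                hp1, hp2 = allele[(read.chrom, pos)]
                truth = hp1 if read.hap_truth == 1 else hp2
                total += 1
                flipped += obs != truth
        assert flipped / total == pytest.approx(0.10, abs=0.01)


class TestSomaticInjection:
    def test_full_bias_puts_all_snvs_on_one_haplotype(self):
        cfg = SimulationConfig(
            genome_length=400_000, somatic_rate=0.0, seed=9,
            bias_regions=(BiasRegionSpec("chr1", 100_001, 200_000, 2, 1.0, 20),),
        )
        genome, snps, truth = simulate_diploid_genome(cfg)
        callset = inject_somatic_events(genome, snps, cfg, truth)
        assert len(callset.snvs) == 20
        assert set(callset.truth.snv_hap.values()) == {2}

    def test_cn_oscillation_alternates_with_requested_transitions(self):
        cfg = SimulationConfig(
            genome_length=500_000, somatic_rate=0.0, seed=10,
            sv_clusters=(SVClusterSpec("chr1", 100_001, 400_000, 1, 10, 4),),
        )
        genome, snps, truth = simulate_diploid_genome(cfg)
        callset = inject_somatic_events(genome, snps, cfg, truth)
        in_cluster = [s for s in callset.cn_segments
                      if 100_001 <= s.start and s.end <= 400_000]
        states = [s.cn_state for s in in_cluster]
        assert states == [2, 1, 2, 1, 2]
        assert sum(1 for a, b in zip(states, states[1:]) if a != b) == 4

    def test_sv_cluster_intervals_mutually_interleave(self):
        cfg = SimulationConfig(
            genome_length=500_000, somatic_rate=0.0, seed=11,
            sv_clusters=(SVClusterSpec("chr1", 100_001, 400_000, 1, 8, 4),),
        )
        genome, snps, truth = simulate_diploid_genome(cfg)
        callset = inject_somatic_events(genome, snps, cfg, truth)
        ivals = [sv.interval()[1:] for sv in callset.svs]
        for (a1, a2) in ivals:
            for (b1, b2) in ivals:
                if (a1, a2) == (b1, b2):
                    continue
                lo, hi = ((a1, a2), (b1, b2)) if a1 < b1 else ((b1, b2), (a1, a2))
                # interleaved: lo.start < hi.start < lo.end < hi.end
                assert lo[0] < hi[0] < lo[1] < hi[1]

    def test_spectrum_of_injected_snvs_matches_generator_law(self):
        cfg = SimulationConfig(
            genome_length=3_000_000, somatic_rate=0.0, seed=12,
            bias_regions=(
                BiasRegionSpec("chr1", 1, 3_000_000, 1, 1.0, 500,
                               "apobec_like_synthetic"),
            ),
        )
        genome, snps, truth = simulate_diploid_genome(cfg)
        callset = inject_somatic_events(genome, snps, cfg, truth)
        spec = trinucleotide_spectrum(callset.snvs, genome.as_dict())
        assert spec.n_skipped == 0
        sig = builtin_signatures()["apobec_like_synthetic"]
        assert cosine_similarity(spec, sig) >= 0.95
        # exact agreement with the recorded truth categories
        from collections import Counter

        want = Counter(callset.truth.snv_category.values())
        got = spec.as_dict()
        for cat, n in want.items():
            assert got[cat] == n

    def test_apply_truth_haplotypes_round_trips(self):
        cfg = SimulationConfig(
            genome_length=200_000, somatic_rate=20.0, seed=13,
        )
        genome, snps, truth = simulate_diploid_genome(cfg)
        callset = apply_truth_haplotypes(
            inject_somatic_events(genome, snps, cfg, truth))
        for v in callset.snvs:
            assert v.hap == ("HP1" if callset.truth.snv_hap[v.var_id] == 1
                             else "HP2")


class TestCalibrationOverSeeds:
    def test_snp_count_depth_and_n50_within_three_mc_sigma(self):
        """Over 20 seeds the realized SNP count, depth and read N50 stay
        within three Monte-Carlo standard errors of their targets."""
        n_seeds = 20
        snp_counts, depths, n50s = [], [], []
        for seed in range(n_seeds):
            cfg = SimulationConfig(genome_length=400_000, depth=12, seed=seed)
            genome, snps, _ = simulate_diploid_genome(cfg)
            reads = simulate_long_reads(genome, snps, cfg)
            snp_counts.append(len(snps))
            depths.append(sum(r.end - r.start + 1 for r in reads) / 400_000)
            n50s.append(n50([r.end - r.start + 1 for r in reads]))
        for values, target in (
            (snp_counts, 400_000 / 1500),
            (depths, 12.0),
            (n50s, 16_000.0),
        ):
            mean = np.mean(values)
            se = np.std(values, ddof=1) / np.sqrt(n_seeds)
            assert abs(mean - target) < 3 * max(se, 0.02 * target)


class TestMethylationAndRna:
    def test_methylation_probabilities_respected(self, demo_case):
        df = demo_case.methylation_tumor
        hp1 = df[df.hap_truth == 1]["methylated"].mean()
        hp2 = df[df.hap_truth == 2]["methylated"].mean()
        assert hp1 == pytest.approx(0.9, abs=0.03)
        assert hp2 == pytest.approx(0.1, abs=0.03)

    def test_normal_tissue_has_no_haplotype_difference(self, demo_case):
        df = demo_case.methylation_normal
        hp1 = df[df.hap_truth == 1]["methylated"].mean()
        hp2 = df[df.hap_truth == 2]["methylated"].mean()
        assert abs(hp1 - hp2) < 0.05

    def test_rna_counts_skewed_as_configured(self, demo_case):
        n1 = sum(1 for r in demo_case.rna_tumor if r.hap_truth == 1)
        n2 = sum(1 for r in demo_case.rna_tumor if r.hap_truth == 2)
        assert n1 > 2 * n2  # configured 4:1 skew
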