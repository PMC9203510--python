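"""End-to-end orchestration of the haplotype-context analyses.

One flat-key YAML config drives: synthetic-data generation, phase-block
construction from read connectivity, read haplotagging, somatic SNV/SV
haplotype assignment, mutation-pair ordering, haplotype-bias regions,
chromothripsis calling with signature scoring, methylation DMR bias and
allele-specific expression.  Every stage is a thin call into the library
modules; the CLI layer adds no logic.  Output is a directory of TSV/VCF/BED
files plus a machine-readable ``summary.json`` with per-stage record counts
and headline calls, deterministic under the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, fields

import numpy as np

from . import bias as bias_mod
from . import expression as expr_mod
from . import io as io_mod
from . import methylation as meth_mod
from . import phasing as phasing_mod
from . import signatures as sig_mod
from . import somatic as somatic_mod
from .reads import tag_reads
from .simulate import (
    BiasRegionSpec,
    ConfigError,
    GeneSpec,
    MethylationRegionSpec,
    SimulationConfig,
    SVClusterSpec,
    simulate_tumor,
)

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_INPUT_ERROR = 3
EXIT_INTERNAL_ERROR = 4


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; unknown keys are rejected.

    Thresholds carry the published defaults: the 3-mutant-read rule, the
    0.7 read/SNP ratios, the 80% haplotype-bias threshold, 100-kb
    enrichment windows, the DMR-bias triple (>=3 same direction, ratio
    >=0.7, >=3/Mb) and the chromothripsis quadruple (>=10 SVs, 4/6
    oscillations, 0.2 SVs/Mb, 0.2 CN states/Mb).
    """

    out_dir: str = "hapcontext_out"
    seed: int = 0
    # synthetic input
    genome_length: int = 2_000_000
    n_chroms: int = 1
    snp_rate: float = 1.0 / 1500
    read_n50: int = 16_000
    read_length_sigma: float = 1.0
    depth: float = 30.0
    per_base_error: float = 0.10
    somatic_rate: float = 10.0
    clone_fraction: float = 1.0
    bias_regions: list = field(default_factory=list)
    sv_clusters: list = field(default_factory=list)
    methylation_regions: list = field(default_factory=list)
    genes: list = field(default_factory=list)
    # stage toggles
    run_simulate: bool = True
    run_phasing: bool = True
    run_mutation_phasing: bool = True
    run_bias: bool = True
    run_chromothripsis: bool = True
    run_methylation: bool = True
    run_expression: bool = True
    # thresholds
    tag_min_snps: int = 2
    tag_min_ratio: float = 0.7
    snv_min_major: int = 3
    snv_max_minor: int = 1
    sv_min_support: int = 3
    sv_min_ratio: float = 0.7
    order_min_reads: int = 2
    window: int = 100_000
    enrichment_alpha: float = 0.05
    bias_threshold: float = 0.8
    bias_min_phased: int = 5
    meth_min_reads: int = 3
    dmr_min_cpgs: int = 5
    dmr_min_diff: float = 0.3
    dmr_q_alpha: float = 0.05
    ase_alpha: float = 0.05
    ase_min_total: int = 10

    _VALID_RANGES = {
        "tag_min_ratio": (0.5, 1.0),
        "sv_min_ratio": (0.5, 1.0),
        "bias_threshold": (0.5, 1.0),
        "enrichment_alpha": (0.0, 1.0),
        "dmr_q_alpha": (0.0, 1.0),
        "ase_alpha": (0.0, 1.0),
        "per_base_error": (0.0, 1.0),
    }

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls) if not f.name.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key, (lo, hi) in cls._VALID_RANGES.items():
            val = getattr(cfg, key)
            if not lo <= val <= hi:
                raise ConfigError(f"{key} must be in [{lo}, {hi}], got {val}")
        return cfg

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            genome_length=self.genome_length,
            n_chroms=self.n_chroms,
            snp_rate=self.snp_rate,
            read_n50=self.read_n50,
            read_length_sigma=self.read_length_sigma,
            depth=self.depth,
            per_base_error=self.per_base_error,
            somatic_rate=self.somatic_rate,
            clone_fraction=self.clone_fraction,
            bias_regions=tuple(
                BiasRegionSpec(**r) if isinstance(r, dict) else r
                for r in self.bias_regions
            ),
            sv_clusters=tuple(
                SVClusterSpec(**{**r, "cn_states": tuple(r.get("cn_states", (2, 1)))})
                if isinstance(r, dict) else r
                for r in self.sv_clusters
            ),
            methylation_regions=tuple(
                MethylationRegionSpec(**r) if isinstance(r, dict) else r
                for r in self.methylation_regions
            ),
            genes=tuple(
                GeneSpec(**r) if isinstance(r, dict) else r for r in self.genes
            ),
            seed=self.seed,
        )


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages end to end; returns the summary dict.

    Fails fast with ``ConfigError``/``FileNotFoundError`` naming the stage
    when an enabled stage lacks its inputs.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}

    def _log(stage: str, **counts) -> None:
        summary["stages"][stage] = counts
        logger.info("stage=%s seed=%d %s", stage, config.seed,
                    " ".join(f"{k}={v}" for k, v in counts.items()))

    if not config.run_simulate:
        raise ConfigError(
            "stage simulate is disabled but downstream stages require its "
            "outputs; provide run_simulate=true"
        )
    sim_cfg = config.simulation_config()
    case = simulate_tumor(sim_cfg)
    contigs = sim_cfg.chrom_sizes()
    io_mod.write_fasta(case.genome, os.path.join(config.out_dir, "reference.fa"))
    io_mod.write_phased_vcf(case.snps,
                            os.path.join(config.out_dir, "germline_phased.vcf"),
                            contigs)
    io_mod.write_reads_tsv(case.reads, os.path.join(config.out_dir, "reads.tsv"))
    io_mod.write_cn_tsv(case.somatic.cn_segments,
                        os.path.join(config.out_dir, "cn_segments.tsv"))
    _log("simulate", n_snps=len(case.snps), n_reads=len(case.reads),
         n_somatic_snvs=len(case.somatic.snvs), n_svs=len(case.somatic.svs))

    blocks = []
    if config.run_phasing:
        blocks = phasing_mod.blocks_from_read_connectivity(case.snps, case.reads)
        het = {c: [s.pos for s in case.snps if s.chrom == c] for c in contigs}
        stats = phasing_mod.block_stats(blocks, het)
        io_mod.write_blocks_bed(blocks,
                                os.path.join(config.out_dir, "blocks.bed"))
        _log("phasing", n_blocks=stats.n_blocks, n50=stats.n50_length,
             n_phased_snps=stats.n_phased_snps)
        summary["block_stats"] = {
            "n_blocks": stats.n_blocks,
            "n50_length": stats.n50_length,
            "median_length": stats.median_length,
            "max_length": stats.max_length,
            "phased_fraction": stats.phased_fraction,
        }

    tagged = {}
    snvs = case.somatic.snvs
    svs = case.somatic.svs
    if config.run_mutation_phasing:
        if not blocks:
            raise ConfigError("stage mutation_phasing requires run_phasing")
        tagged = tag_reads(case.reads, blocks, config.tag_min_snps,
                           config.tag_min_ratio)
        snv_at: dict[tuple[str, int], somatic_mod.SomaticVariant] = {
            (v.chrom, v.pos): v for v in snvs
        }
        reads_by_variant: dict[str, list[str]] = {}
        for read in case.reads:
            for pos, allele in read.somatic_observations:
                v = snv_at.get((read.chrom, pos))
                if v is not None and allele == v.alt:
                    reads_by_variant.setdefault(v.var_id, []).append(
                        read.read_id)
        snvs = somatic_mod.phase_snvs(snvs, tagged, reads_by_variant,
                                      config.snv_min_major,
                                      config.snv_max_minor)
        svs = somatic_mod.phase_svs(svs, tagged,
                                    min_support=config.sv_min_support,
                                    min_ratio=config.sv_min_ratio)
        read_alleles: dict[str, dict[str, bool]] = {}
        for read in case.reads:
            cov = {}
            for pos, allele in read.somatic_observations:
                v = snv_at.get((read.chrom, pos))
                if v is not None:
                    cov[v.var_id] = allele == v.alt
            if cov:
                read_alleles[read.read_id] = cov
        pairs = somatic_mod.order_mutation_pairs(snvs, read_alleles,
                                                 config.order_min_reads)
        io_mod.write_somatic_vcf(
            snvs, os.path.join(config.out_dir, "somatic_phased.vcf"), contigs)
        io_mod.write_sv_tsv(svs, os.path.join(config.out_dir, "svs_phased.tsv"))
        n_tagged = sum(1 for t in tagged.values() if t.label != "untagged")
        _log("mutation_phasing",
             n_tagged_reads=n_tagged,
             n_snvs_phased=sum(1 for v in snvs if v.hap != "unknown"),
             n_svs_phased=sum(1 for s in svs if s.hap != "unknown"),
             n_ordered_pairs=sum(1 for p in pairs if p.relation == "ordered"))

    if config.run_bias:
        enriched, _table = bias_mod.find_enriched_windows(
            snvs, contigs, config.window, config.enrichment_alpha)
        regions = bias_mod.call_biased_regions(
            enriched, snvs, config.bias_min_phased, config.bias_threshold,
            blocks=blocks or None)
        sv_blocks = bias_mod.sv_concentrated_blocks(svs)
        _log("bias", n_enriched_windows=len(enriched),
             n_regions=len(regions),
             n_biased=sum(1 for r in regions if r.is_biased),
             n_sv_concentrated_blocks=len(sv_blocks))
        summary["biased_regions"] = [
            {"chrom": r.region.chrom, "start": r.region.start,
             "end": r.region.end, "hap": r.biased_hap,
             "fraction": r.bias_fraction}
            for r in regions if r.is_biased
        ]

    if config.run_chromothripsis:
        clusters = sig_mod.cluster_interleaved_svs(svs)
        calls = [sig_mod.call_chromothripsis(c, case.somatic.cn_segments)
                 for c in clusters]
        _log("chromothripsis", n_clusters=len(clusters),
             n_called=sum(1 for c in calls if c.passed))
        summary["chromothripsis"] = [
            {"chrom": c.cluster.chrom, "start": c.cluster.start,
             "end": c.cluster.end, "n_svs": c.cluster.n_svs,
             "passed": c.passed, "haplotype": c.cluster.major_haplotype,
             "criteria": c.criteria}
            for c in calls
        ]

    if config.run_methylation and case.methylation_tumor is not None:
        def _with_hap(df):
            df = df.copy()
            df["hap"] = [
                tagged[r].label if r in tagged else "untagged"
                for r in df["read_id"]
            ]
            return df

        meth_t = _with_hap(case.methylation_tumor)
        meth_n = _with_hap(case.methylation_normal)
        freq_t = meth_mod.haplotype_methylation_frequency(
            meth_t, config.meth_min_reads)
        freq_n = meth_mod.haplotype_methylation_frequency(
            meth_n, config.meth_min_reads)
        dmrs_t = meth_mod.call_dmrs(freq_t, config.dmr_min_cpgs,
                                    config.dmr_min_diff, config.dmr_q_alpha)
        dmrs_n = meth_mod.call_dmrs(freq_n, config.dmr_min_cpgs,
                                    config.dmr_min_diff, config.dmr_q_alpha)
        bias_blocks = meth_mod.dmr_bias_blocks(dmrs_t, dmrs_n, blocks)
        _log("methylation", n_tumor_dmrs=len(dmrs_t),
             n_normal_dmrs=len(dmrs_n), n_dmr_bias_blocks=len(bias_blocks))

    if config.run_expression and case.rna_tumor:
        counts = []
        gene_by_id = {g.gene_id: g for g in sim_cfg.genes}
        for tissue, rna in (("tumor", case.rna_tumor),
                            ("normal", case.rna_normal)):
            rna_tags = tag_reads(rna, blocks, config.tag_min_snps,
                                 config.tag_min_ratio)
            per_gene: dict[str, list[int]] = {}
            for read in rna:
                gene_id = read.read_id.split("_")[1]
                label = rna_tags[read.read_id].label
                if label in ("HP1", "HP2"):
                    per_gene.setdefault(gene_id, [0, 0])[
                        0 if label == "HP1" else 1] += 1
            for gene_id, (n1, n2) in per_gene.items():
                counts.append(expr_mod.AllelicCount(
                    f"{gene_id}_snp", gene_id, tissue, n1, n2))
        snp_table = expr_mod.allelic_expression_test(
            counts, config.ase_alpha, config.ase_min_total)
        verdicts = expr_mod.gene_level_verdicts(snp_table)
        _log("expression", n_snps_tested=len(snp_table),
             n_biased_genes=int((verdicts["biased_hap"].notna()).sum())
             if not verdicts.empty else 0)

    summary["input_digests"] = {
        name: _digest(os.path.join(config.out_dir, name))
        for name in ("germline_phased.vcf", "reads.tsv")
        if os.path.exists(os.path.join(config.out_dir, name))
    }
    with open(os.path.join(config.out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default)
    return summary


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
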