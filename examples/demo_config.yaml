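# Demo pipeline configuration: one 2-Mb chromosome at 20x with an
# APOBEC-context haplotype-biased region, an interleaved SV cluster with
# oscillating copy number, an allele-specific methylation region and
# haplotype-skewed genes.  Runs end to end in well under a minute:
#   hapcontext run --config examples/demo_config.yaml --seed 1 --out demo_out
seed: 1
genome_length: 2000000
n_chroms: 1
snp_rate: 0.000667        # ~1 het SNP per 1.5 kb
read_n50: 16000
depth: 20.0
per_base_error: 0.10
somatic_rate: 10.0

bias_regions:
  - chrom: chr1
    start: 400001
    end: 500000
    haplotype: 1
    fraction_on_hap: 0.95
    n_snvs: 30
    spectrum: apobec_like_synthetic

sv_clusters:
  - chrom: chr1
    start: 800001
    end: 1600000
    haplotype: 1
    n_svs: 12
    n_cn_oscillations: 6

methylation_regions:
  - chrom: chr1
    start: 100001
    end: 250000
    p_hp1: 0.9
    p_hp2: 0.15

genes:
  - gene_id: GENE1
    chrom: chr1
    start: 1700001
    end: 1760000
    tumor_rate_hp1: 40.0
    tumor_rate_hp2: 10.0
    normal_rate_hp1: 25.0
    normal_rate_hp2: 25.0
  - gene_id: GENE2
    chrom: chr1
    start: 1800001
    end: 1860000
    tumor_rate_hp1: 25.0
    tumor_rate_hp2: 25.0
    normal_rate_hp1: 25.0
    normal_rate_hp2: 25.0

# published thresholds (defaults shown explicitly)
tag_min_snps: 2
tag_min_ratio: 0.7
snv_min_major: 3
snv_max_minor: 1
sv_min_support: 3
sv_min_ratio: 0.7
window: 100000
bias_threshold: 0.8
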