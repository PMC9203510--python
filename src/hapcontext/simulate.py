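"""Synthetic diploid tumor/normal datasets with known haplotype structure.

Replaces restricted-access patient data with a generator whose truth is
fully known, so that every downstream stage (read haplotagging, somatic
variant phasing, bias-region calling, chromothripsis detection, methylation
and expression bias) can be tested as parameter recovery.

The generator emulates:

* a diploid genome of one or more chromosomes with heterozygous SNPs at a
  configurable rate (default one per 1.5 kb), each SNP's alleles assigned
  to haplotype 1 or 2;
* long reads with log-normal lengths calibrated so the realized N50 matches
  the target (default 16 kb), each read drawn from one haplotype, reporting
  the covered SNP alleles with a per-base error probability (default 10%)
  that flips the observed allele;
* somatic SNVs at a background rate plus *bias regions* in which a chosen
  number of SNVs fall on one designated haplotype with a given probability
  and draw trinucleotide contexts from a named signature;
* clusters of mutually interleaved SVs confined to one haplotype with
  oscillating copy-number segments across the cluster span;
* per-read CpG methylation calls with per-region per-haplotype methylation
  probabilities;
* haplotype-skewed transcript read counts per gene in tumor and normal.

A single integer seed fully determines every output; per-stage child seeds
are derived from it so stages are independently reproducible.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .phasing import HP1, HP2, PhasedSNP
from .signatures import CATEGORIES, builtin_signatures
from .somatic import SomaticVariant, StructuralVariant

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_LIST = ("A", "C", "G", "T")


class ConfigError(ValueError):
    """Invalid simulation configuration; the message names the field."""


@dataclass(frozen=True)
class BiasRegionSpec:
    """A mutation-enriched interval biased to one haplotype.

    ``fraction_on_hap`` of the region's ``n_snvs`` SNVs fall on
    ``haplotype`` (1 or 2); contexts are drawn from the named signature
    ("apobec_like_synthetic", "flat_synthetic") or uniformly when None.
    """

    chrom: str
    start: int  # 1-based inclusive
    end: int
    haplotype: int
    fraction_on_hap: float
    n_snvs: int
    spectrum: str | None = None


@dataclass(frozen=True)
class SVClusterSpec:
    """An interleaved SV cluster with oscillating CN on one haplotype."""

    chrom: str
    start: int
    end: int
    haplotype: int
    n_svs: int
    n_cn_oscillations: int
    cn_states: tuple[int, ...] = (2, 1)
    reads_per_sv: int = 6


@dataclass(frozen=True)
class MethylationRegionSpec:
    """Per-haplotype CpG methylation probabilities over an interval."""

    chrom: str
    start: int
    end: int
    p_hp1: float
    p_hp2: float


@dataclass(frozen=True)
class GeneSpec:
    """A gene interval with per-haplotype transcript read rates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    tumor_rate_hp1: float
    tumor_rate_hp2: float
    normal_rate_hp1: float
    normal_rate_hp2: float


@dataclass(frozen=True)
class SimulationConfig:
    genome_length: int = 2_000_000      # bp per chromosome
    n_chroms: int = 1
    snp_rate: float = 1.0 / 1500        # het SNPs per bp
    read_n50: int = 16_000              # target N50 read length, bp
    read_length_sigma: float = 1.0      # log-scale sd of read lengths
    depth: float = 30.0                 # fold coverage
    per_base_error: float = 0.10        # probability of flipping an observed allele
    somatic_rate: float = 10.0          # background somatic SNVs per Mb
    clone_fraction: float = 1.0         # fraction of tumor molecules carrying a somatic SNV
    bias_regions: tuple[BiasRegionSpec, ...] = ()
    sv_clusters: tuple[SVClusterSpec, ...] = ()
    methylation_regions: tuple[MethylationRegionSpec, ...] = ()
    genes: tuple[GeneSpec, ...] = ()
    seed: int = 0

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.genome_length for c in self.chrom_names()}

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise ConfigError("genome_length must be positive")
        if self.n_chroms <= 0:
            raise ConfigError("n_chroms must be positive")
        if not 0.0 <= self.snp_rate < 1.0:
            raise ConfigError("snp_rate must be in [0, 1)")
        if self.read_n50 <= 0:
            raise ConfigError("read_n50 must be positive")
        if self.read_length_sigma <= 0:
            raise ConfigError("read_length_sigma must be positive")
        if self.depth <= 0:
            raise ConfigError("depth must be positive")
        if not 0.0 <= self.per_base_error <= 1.0:
            raise ConfigError("per_base_error must be in [0, 1]")
        if self.somatic_rate < 0:
            raise ConfigError("somatic_rate must be non-negative")
        if not 0.0 <= self.clone_fraction <= 1.0:
            raise ConfigError("clone_fraction must be in [0, 1]")
        chroms = set(self.chrom_names())
        for name, spec_list in (
            ("bias_regions", self.bias_regions),
            ("sv_clusters", self.sv_clusters),
            ("methylation_regions", self.methylation_regions),
            ("genes", self.genes),
        ):
            for spec in spec_list:
                if spec.chrom not in chroms:
                    raise ConfigError(f"{name}: unknown chromosome {spec.chrom}")
                if not 1 <= spec.start <= spec.end <= self.genome_length:
                    raise ConfigError(f"{name}: interval outside genome bounds")
        for spec in self.bias_regions:
            if spec.haplotype not in (1, 2):
                raise ConfigError("bias_regions: haplotype must be 1 or 2")
            if not 0.0 <= spec.fraction_on_hap <= 1.0:
                raise ConfigError("bias_regions: fraction_on_hap must be in [0, 1]")
            if spec.n_snvs < 0:
                raise ConfigError("bias_regions: n_snvs must be non-negative")
        for a in self.bias_regions:
            for b in self.bias_regions:
                if a is not b and a.chrom == b.chrom and (
                    a.start <= b.end and b.start <= a.end
                ) and a.haplotype != b.haplotype:
                    raise ConfigError(
                        "bias_regions: overlapping regions with contradictory haplotypes"
                    )
        for spec in self.sv_clusters:
            if spec.haplotype not in (1, 2):
                raise ConfigError("sv_clusters: haplotype must be 1 or 2")
            if spec.n_svs < 2:
                raise ConfigError("sv_clusters: n_svs must be >= 2")
            if spec.n_cn_oscillations < 0:
                raise ConfigError("sv_clusters: n_cn_oscillations must be >= 0")
            if len(set(spec.cn_states)) not in (2, 3):
                raise ConfigError("sv_clusters: cn_states must hold 2 or 3 states")
        for spec in self.methylation_regions:
            if not (0.0 <= spec.p_hp1 <= 1.0 and 0.0 <= spec.p_hp2 <= 1.0):
                raise ConfigError(
                    "methylation_regions: probabilities must be in [0, 1]"
                )
        for spec in self.genes:
            for r in (spec.tumor_rate_hp1, spec.tumor_rate_hp2,
                      spec.normal_rate_hp1, spec.normal_rate_hp2):
                if r < 0:
                    raise ConfigError("genes: rates must be non-negative")

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Deterministic child generator for a named stage (stable across
        processes, unlike the built-in string hash)."""
        key = zlib.crc32(stage.encode("utf-8")) & 0x7FFFFFFF
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)


@dataclass
class Genome:
    """Reference sequences (uint8 arrays) with string accessors."""

    sequences: dict[str, np.ndarray]

    def seq(self, chrom: str) -> str:
        return self.sequences[chrom].tobytes().decode("ascii")

    def as_dict(self) -> dict[str, str]:
        return {c: self.seq(c) for c in self.sequences}

    def set_base(self, chrom: str, pos: int, base: str) -> None:
        self.sequences[chrom][pos - 1] = ord(base)

    def base(self, chrom: str, pos: int) -> str:
        return chr(self.sequences[chrom][pos - 1])

    def size(self, chrom: str) -> int:
        return self.sequences[chrom].size


@dataclass
class SimulatedRead:
    read_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    hap_truth: int  # 1 or 2
    observations: list[tuple[int, str]] = field(default_factory=list)
    somatic_observations: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class TruthSet:
    """Ground truth of every simulated event, keyed for recovery tests."""

    snp_count: int = 0
    snv_hap: dict[str, int] = field(default_factory=dict)
    snv_category: dict[str, str] = field(default_factory=dict)
    bias_regions: list[BiasRegionSpec] = field(default_factory=list)
    sv_hap: dict[str, int] = field(default_factory=dict)
    sv_cluster_of: dict[str, int] = field(default_factory=dict)
    chromothripsis_intervals: list[tuple[str, int, int]] = field(default_factory=list)
    dmr_regions: list[MethylationRegionSpec] = field(default_factory=list)
    expression_skews: dict[str, tuple[int, float]] = field(default_factory=dict)
    read_hap: dict[str, int] = field(default_factory=dict)


def _hap_label(h: int) -> str:
    return HP1 if h == 1 else HP2


def simulate_diploid_genome(
    config: SimulationConfig,
) -> tuple[Genome, list[PhasedSNP], TruthSet]:
    """Random diploid genome with phased heterozygous SNPs.

    SNP positions follow a Bernoulli process at ``snp_rate``; at each SNP the
    alternate allele differs from the reference and lands on HP1 or HP2 with
    equal probability.  Truth blocks span one chromosome each (block id =
    first SNP position).  Deterministic under the config seed.
    """
    config.validate()
    rng = config.stage_rng("genome")
    sequences: dict[str, np.ndarray] = {}
    snps: list[PhasedSNP] = []
    truth = TruthSet()
    for chrom in config.chrom_names():
        L = config.genome_length
        seq = _BASES[rng.integers(0, 4, L)]
        sequences[chrom] = seq.copy()
        if config.snp_rate > 0:
            positions = np.flatnonzero(rng.random(L) < config.snp_rate) + 1
        else:
            positions = np.array([], dtype=int)
        if positions.size == 0:
            continue
        block_id = int(positions[0])
        alt_offsets = rng.integers(1, 4, positions.size)
        alt_on_hp1 = rng.random(positions.size) < 0.5
        for pos, off, on1 in zip(positions, alt_offsets, alt_on_hp1):
            ref = chr(seq[pos - 1])
            alt = _BASE_LIST[(_BASE_LIST.index(ref) + off) % 4]
            hp1, hp2 = (alt, ref) if on1 else (ref, alt)
            snps.append(PhasedSNP(chrom, int(pos), ref, alt, block_id, hp1, hp2))
    truth.snp_count = len(snps)
    return Genome(sequences), snps, truth


@dataclass
class SomaticCallset:
    """Somatic events injected into the tumor genome, with their truth."""

    snvs: list[SomaticVariant]
    svs: list[StructuralVariant]
    cn_segments: list
    truth: TruthSet


_COMP = str.maketrans("ACGT", "TGCA")


def _draw_category_context(
    rng: np.random.Generator, spectrum: np.ndarray
) -> tuple[str, str, str, str]:
    """Sample a 96-category; return (reference trinucleotide, ref, alt,
    category label), emitted on a random strand."""
    idx = rng.choice(96, p=spectrum / spectrum.sum())
    cat = CATEGORIES[idx]
    five, ref, alt, three = cat[0], cat[2], cat[4], cat[6]
    tri = five + ref + three
    if rng.random() < 0.5:
        tri = tri.translate(_COMP)[::-1]
        ref = ref.translate(_COMP)
        alt = alt.translate(_COMP)
    return tri, ref, alt, cat


def inject_somatic_events(
    genome: Genome,
    snps: Sequence[PhasedSNP],
    config: SimulationConfig,
    truth: TruthSet | None = None,
) -> SomaticCallset:
    """Inject somatic SNVs, interleaved SV clusters and CN oscillation.

    Background SNVs are Poisson at ``somatic_rate``/Mb, uniform over the
    genome, on a random haplotype.  Bias-region SNVs fall on the designated
    haplotype with ``fraction_on_hap`` and, when a spectrum is named, the
    reference trinucleotide around each SNV is rewritten to a context drawn
    from that signature (so the emitted spectrum matches the generator law).
    SV clusters are a breakpoint "staircase": sorted breakpoints b_0..b_2n-1
    paired as (b_i, b_{i+n}), which makes every pair of member intervals
    mutually interleave; CN segments across the cluster span alternate
    between the configured states with the requested number of transitions.
    """
    config.validate()
    rng = config.stage_rng("somatic")
    truth = truth or TruthSet()
    snp_pos = {(s.chrom, s.pos) for s in snps}
    taken: set[tuple[str, int]] = set()
    snvs: list[SomaticVariant] = []
    sigs = builtin_signatures()

    def _free(chrom: str, pos: int, pad: int = 1) -> bool:
        return all(
            (chrom, p) not in snp_pos and (chrom, p) not in taken
            for p in range(pos - pad, pos + pad + 1)
        )

    # background somatic SNVs
    genome_mb = config.n_chroms * config.genome_length / 1e6
    n_background = rng.poisson(config.somatic_rate * genome_mb)
    chroms = config.chrom_names()
    for k in range(n_background):
        for _ in range(50):
            chrom = chroms[rng.integers(len(chroms))]
            pos = int(rng.integers(2, config.genome_length))
            if _free(chrom, pos):
                break
        else:
            continue
        taken.add((chrom, pos))
        ref = genome.base(chrom, pos)
        alt = _BASE_LIST[(_BASE_LIST.index(ref) + rng.integers(1, 4)) % 4]
        hap = int(rng.integers(1, 3))
        var = SomaticVariant(chrom, pos, ref, alt,
                             vaf=config.clone_fraction / 2)
        snvs.append(var)
        truth.snv_hap[var.var_id] = hap

    # bias-region SNVs with optional signature-driven contexts
    for spec in config.bias_regions:
        spectrum = sigs.get(spec.spectrum) if spec.spectrum else None
        if spec.spectrum and spectrum is None:
            raise ConfigError(f"bias_regions: unknown spectrum {spec.spectrum!r}")
        for _ in range(spec.n_snvs):
            for _ in range(200):
                pos = int(rng.integers(max(spec.start, 2),
                                       min(spec.end, config.genome_length - 1) + 1))
                # pad=2 keeps rewritten +-1 contexts disjoint between events
                if _free(spec.chrom, pos, pad=2):
                    break
            else:
                continue
            taken.add((spec.chrom, pos))
            category = None
            if spectrum is not None:
                tri, ref, alt, category = _draw_category_context(rng, spectrum)
                for off, base in zip((-1, 0, 1), tri):
                    genome.set_base(spec.chrom, pos + off, base)
            else:
                ref = genome.base(spec.chrom, pos)
                alt = _BASE_LIST[(_BASE_LIST.index(ref) + rng.integers(1, 4)) % 4]
            hap = (
                spec.haplotype
                if rng.random() < spec.fraction_on_hap
                else 3 - spec.haplotype
            )
            var = SomaticVariant(spec.chrom, pos, ref, alt,
                                 vaf=config.clone_fraction / 2)
            snvs.append(var)
            truth.snv_hap[var.var_id] = hap
            if category is not None:
                truth.snv_category[var.var_id] = category
        truth.bias_regions.append(spec)

    # SV clusters + CN oscillation
    svs: list[StructuralVariant] = []
    from .signatures import CNSegment

    cn_segments: list[CNSegment] = []
    cluster_spans: dict[str, list[tuple[int, int]]] = {}
    for ci, spec in enumerate(config.sv_clusters):
        n = spec.n_svs
        bps = np.sort(rng.choice(
            np.arange(spec.start, spec.end + 1), size=2 * n, replace=False
        ))
        sv_types = rng.choice(["deletion", "duplication", "inversion"], size=n)
        for i in range(n):
            sv_id = f"cluster{ci}_sv{i}"
            sv = StructuralVariant(
                sv_id, str(sv_types[i]), spec.chrom, int(bps[i]), "+",
                spec.chrom, int(bps[i + n]), "-",
            )
            svs.append(sv)
            truth.sv_hap[sv_id] = spec.haplotype
            truth.sv_cluster_of[sv_id] = ci
        cluster_spans.setdefault(spec.chrom, []).append((spec.start, spec.end))
        truth.chromothripsis_intervals.append((spec.chrom, spec.start, spec.end))
        # alternating CN segments: n_cn_oscillations transitions
        n_seg = spec.n_cn_oscillations + 1
        bounds = np.linspace(spec.start, spec.end, n_seg + 1).astype(int)
        states = [spec.cn_states[i % len(spec.cn_states)] for i in range(n_seg)]
        for i in range(n_seg):
            seg_start = int(bounds[i]) + (1 if i > 0 else 0)
            cn_segments.append(
                CNSegment(spec.chrom, seg_start, int(bounds[i + 1]), states[i])
            )

    # flat CN 2 elsewhere
    for chrom in chroms:
        spans = sorted(cluster_spans.get(chrom, []))
        cursor = 1
        for start, end in spans:
            if start > cursor:
                cn_segments.append(CNSegment(chrom, cursor, start - 1, 2))
            cursor = end + 1
        if cursor <= config.genome_length:
            cn_segments.append(CNSegment(chrom, cursor, config.genome_length, 2))
    cn_segments.sort(key=lambda s: (s.chrom, s.start))

    truth.dmr_regions = [
        m for m in config.methylation_regions if m.p_hp1 != m.p_hp2
    ]
    for g in config.genes:
        hi = 1 if g.tumor_rate_hp1 >= g.tumor_rate_hp2 else 2
        lo_rate = min(g.tumor_rate_hp1, g.tumor_rate_hp2)
        ratio = (max(g.tumor_rate_hp1, g.tumor_rate_hp2) / lo_rate
                 if lo_rate > 0 else math.inf)
        truth.expression_skews[g.gene_id] = (hi, ratio)

    return SomaticCallset(snvs, svs, cn_segments, truth)


def _read_length_params(config: SimulationConfig) -> tuple[float, float]:
    """Log-normal (mu, sigma) so the length-weighted median (N50) hits the
    target: the length-biased log-normal has median exp(mu + sigma^2)."""
    sigma = config.read_length_sigma
    mu = math.log(config.read_n50) - sigma * sigma
    return mu, sigma


def simulate_long_reads(
    genome: Genome,
    snps: Sequence[PhasedSNP],
    config: SimulationConfig,
    somatic: SomaticCallset | None = None,
    n_reads: int | None = None,
) -> list[SimulatedRead]:
    """Long reads with haplotype truth and noisy SNP observations.

    Read count is set so total bases match ``depth`` x genome size (unless
    ``n_reads`` is given).  Each read draws a haplotype uniformly, reports
    the true allele of every covered SNP flipped to the other allele with
    ``per_base_error``, and, when a somatic callset is supplied, reports
    somatic sites (alt on mutant molecules of the true haplotype with
    ``clone_fraction``) and appends the SV-supporting reads recorded in the
    callset's SV table.
    """
    config.validate()
    rng = config.stage_rng("reads")
    mu, sigma = _read_length_params(config)
    mean_len = math.exp(mu + sigma * sigma / 2.0)
    chroms = config.chrom_names()
    total_bases = config.depth * config.n_chroms * config.genome_length
    if n_reads is None:
        n_reads = max(int(round(total_bases / mean_len)), 1)

    by_chrom_pos: dict[str, np.ndarray] = {}
    by_chrom_alleles: dict[str, tuple[list[str], list[str]]] = {}
    for chrom in chroms:
        chrom_snps = sorted(
            (s for s in snps if s.chrom == chrom), key=lambda s: s.pos
        )
        by_chrom_pos[chrom] = np.array([s.pos for s in chrom_snps], dtype=int)
        by_chrom_alleles[chrom] = (
            [s.hp1_allele for s in chrom_snps],
            [s.hp2_allele for s in chrom_snps],
        )
    som_by_chrom: dict[str, list[SomaticVariant]] = {}
    som_hap: dict[str, int] = {}
    if somatic is not None:
        som_hap = somatic.truth.snv_hap
        for v in somatic.snvs:
            som_by_chrom.setdefault(v.chrom, []).append(v)
        for vs in som_by_chrom.values():
            vs.sort(key=lambda v: v.pos)

    lengths = np.maximum(rng.lognormal(mu, sigma, n_reads).astype(int), 200)
    chrom_idx = rng.integers(0, len(chroms), n_reads)
    haps = rng.integers(1, 3, n_reads)
    reads: list[SimulatedRead] = []
    truth = somatic.truth if somatic is not None else None

    def _observe(read: SimulatedRead) -> None:
        chrom = read.chrom
        pos_arr = by_chrom_pos[chrom]
        lo = int(np.searchsorted(pos_arr, read.start))
        hi = int(np.searchsorted(pos_arr, read.end, side="right"))
        hp1_al, hp2_al = by_chrom_alleles[chrom]
        err = rng.random(hi - lo) < config.per_base_error
        for k, idx in enumerate(range(lo, hi)):
            true_al = hp1_al[idx] if read.hap_truth == 1 else hp2_al[idx]
            other = hp2_al[idx] if read.hap_truth == 1 else hp1_al[idx]
            read.observations.append(
                (int(pos_arr[idx]), other if err[k] else true_al)
            )
        for v in som_by_chrom.get(chrom, ()):
            if v.pos < read.start or v.pos > read.end:
                continue
            carries = (
                som_hap.get(v.var_id) == read.hap_truth
                and rng.random() < config.clone_fraction
            )
            allele = v.alt if carries else v.ref
            if rng.random() < config.per_base_error:
                allele = v.ref if allele == v.alt else v.alt
            read.somatic_observations.append((v.pos, allele))

    for i in range(n_reads):
        chrom = chroms[chrom_idx[i]]
        L = genome.size(chrom)
        length = int(min(lengths[i], L))
        start = int(rng.integers(1, max(L - length + 1, 2)))
        read = SimulatedRead(f"read{i}", chrom, start, start + length - 1,
                             int(haps[i]))
        _observe(read)
        reads.append(read)
        if truth is not None:
            truth.read_hap[read.read_id] = read.hap_truth

    # SV-supporting reads, drawn from the SV's true haplotype around bp1
    if somatic is not None:
        for sv in somatic.svs:
            hap = somatic.truth.sv_hap.get(sv.sv_id)
            if hap is None:
                continue
            ci = somatic.truth.sv_cluster_of.get(sv.sv_id)
            n_sup = config.sv_clusters[ci].reads_per_sv if ci is not None else 6
            for j in range(n_sup):
                length = int(min(max(rng.lognormal(mu, sigma), 2000),
                                 genome.size(sv.chrom1)))
                offset = int(rng.integers(0, max(length - 100, 1)))
                start = max(1, sv.pos1 - offset)
                read = SimulatedRead(
                    f"{sv.sv_id}_sup{j}", sv.chrom1, start,
                    min(start + length - 1, genome.size(sv.chrom1)), hap,
                )
                _observe(read)
                reads.append(read)
                sv.supporting_read_ids.append(read.read_id)
                somatic.truth.read_hap[read.read_id] = hap
    return reads


def simulate_methylation_calls(
    reads: Sequence[SimulatedRead],
    genome: Genome,
    config: SimulationConfig,
    tissue: str = "tumor",
):
    """Per-read CpG methylation calls inside the configured regions.

    CpG sites are the actual CG dinucleotides of the reference within each
    ``methylation_regions`` interval; a read covering a site emits a binary
    call with the region's probability for the read's true haplotype.
    For ``tissue="normal"`` both haplotypes use the mean of the two
    probabilities (no allele-specific methylation in the matched normal).
    Returns a DataFrame: read_id, chrom, pos, methylated, hap_truth.
    """
    import pandas as pd

    rng = config.stage_rng(f"methylation_{tissue}")
    site_probs: dict[str, list[tuple[np.ndarray, float, float]]] = {}
    for spec in config.methylation_regions:
        seq = genome.sequences[spec.chrom]
        sub = seq[spec.start - 1 : spec.end]
        is_cg = (sub[:-1] == ord("C")) & (sub[1:] == ord("G"))
        sites = np.flatnonzero(is_cg) + spec.start  # 1-based C of each CpG
        if tissue == "normal":
            p = (spec.p_hp1 + spec.p_hp2) / 2.0
            site_probs.setdefault(spec.chrom, []).append((sites, p, p))
        else:
            site_probs.setdefault(spec.chrom, []).append(
                (sites, spec.p_hp1, spec.p_hp2)
            )
    rows = []
    for read in reads:
        for sites, p1, p2 in site_probs.get(read.chrom, ()):
            lo = int(np.searchsorted(sites, read.start))
            hi = int(np.searchsorted(sites, read.end, side="right"))
            if hi <= lo:
                continue
            p = p1 if read.hap_truth == 1 else p2
            states = (rng.random(hi - lo) < p).astype(int)
            for pos, st in zip(sites[lo:hi], states):
                rows.append((read.read_id, read.chrom, int(pos), int(st),
                             read.hap_truth))
    return pd.DataFrame(
        rows, columns=["read_id", "chrom", "pos", "methylated", "hap_truth"]
    )


def simulate_rna_reads(
    snps: Sequence[PhasedSNP],
    config: SimulationConfig,
    tissue: str = "tumor",
) -> list[SimulatedRead]:
    """Transcript reads per gene with haplotype-skewed counts.

    Per gene and haplotype the read count is Poisson at the configured rate;
    each read observes a consecutive run of 2-5 het SNPs inside the gene
    with ``per_base_error`` allele flips.  Genes with fewer than two SNPs
    yield untaggable reads (dropped).
    """
    config.validate()
    rng = config.stage_rng(f"rna_{tissue}")
    reads: list[SimulatedRead] = []
    for g in config.genes:
        gene_snps = sorted(
            (s for s in snps if s.chrom == g.chrom and g.start <= s.pos <= g.end),
            key=lambda s: s.pos,
        )
        if len(gene_snps) < 2:
            continue
        rates = (
            (g.tumor_rate_hp1, g.tumor_rate_hp2)
            if tissue == "tumor"
            else (g.normal_rate_hp1, g.normal_rate_hp2)
        )
        for hap, rate in zip((1, 2), rates):
            n = rng.poisson(rate)
            for j in range(n):
                k = int(min(rng.integers(2, 6), len(gene_snps)))
                i0 = int(rng.integers(0, len(gene_snps) - k + 1))
                chosen = gene_snps[i0 : i0 + k]
                obs = []
                for s in chosen:
                    true_al = s.hp1_allele if hap == 1 else s.hp2_allele
                    other = s.hp2_allele if hap == 1 else s.hp1_allele
                    obs.append(
                        (s.pos,
                         other if rng.random() < config.per_base_error else true_al)
                    )
                reads.append(
                    SimulatedRead(
                        f"{tissue}_{g.gene_id}_hp{hap}_r{j}", g.chrom,
                        chosen[0].pos, chosen[-1].pos, hap, obs,
                    )
                )
    return reads


@dataclass
class SyntheticTumor:
    """A complete synthetic case: genome, phasing truth, somatic events,
    DNA/RNA reads and methylation calls, plus the truth set."""

    config: SimulationConfig
    genome: Genome
    snps: list[PhasedSNP]
    somatic: SomaticCallset
    reads: list[SimulatedRead]
    methylation_tumor: "object"
    methylation_normal: "object"
    rna_tumor: list[SimulatedRead]
    rna_normal: list[SimulatedRead]

    @property
    def truth(self) -> TruthSet:
        return self.somatic.truth


def simulate_tumor(config: SimulationConfig,
                   with_reads: bool = True) -> SyntheticTumor:
    """Run the full generator: genome -> somatic injection -> reads ->
    methylation -> RNA.  ``with_reads=False`` skips read-level stages for
    lightweight region-level studies."""
    genome, snps, truth = simulate_diploid_genome(config)
    somatic = inject_somatic_events(genome, snps, config, truth)
    reads: list[SimulatedRead] = []
    meth_t = meth_n = None
    rna_t: list[SimulatedRead] = []
    rna_n: list[SimulatedRead] = []
    if with_reads:
        reads = simulate_long_reads(genome, snps, config, somatic)
        if config.methylation_regions:
            meth_t = simulate_methylation_calls(reads, genome, config, "tumor")
            meth_n = simulate_methylation_calls(reads, genome, config, "normal")
        if config.genes:
            rna_t = simulate_rna_reads(snps, config, "tumor")
            rna_n = simulate_rna_reads(snps, config, "normal")
    return SyntheticTumor(config, genome, snps, somatic, reads,
                          meth_t, meth_n, rna_t, rna_n)


def apply_truth_haplotypes(somatic: SomaticCallset) -> SomaticCallset:
    """Copy the truth haplotype of every somatic event onto its record, for
    region-level studies that bypass read-level haplotype assignment."""
    for v in somatic.snvs:
        hap = somatic.truth.snv_hap.get(v.var_id)
        if hap is not None:
            v.hap = _hap_label(hap)
    for sv in somatic.svs:
        hap = somatic.truth.sv_hap.get(sv.sv_id)
        if hap is not None:
            sv.hap = _hap_label(hap)
    return somatic


def scattered_svs(
    chrom: str,
    genome_length: int,
    n_svs: int,
    rng: np.random.Generator,
    sv_span: int = 2000,
) -> list[StructuralVariant]:
    """Negative control: short, well-separated (non-interleaving) SVs
    scattered uniformly, as produced by independent events rather than one
    shattering."""
    gap = genome_length // (n_svs + 1)
    svs = []
    for i in range(n_svs):
        anchor = gap * (i + 1) + int(rng.integers(0, max(gap // 4, 2)))
        svs.append(
            StructuralVariant(
                f"scattered_sv{i}", "deletion", chrom, anchor, "+",
                chrom, min(anchor + sv_span, genome_length), "-",
            )
        )
    return svs
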