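"""Phased-variant containers and phasing-accuracy metrics.

A diploid phasing partitions heterozygous SNPs into *phase blocks* (PS groups
in a VCF): within one block the assignment of every allele to haplotype 1
(HP1) or haplotype 2 (HP2) is jointly determined, while the labelling between
blocks is arbitrary.  This module parses phased VCFs, summarises block
statistics (N50, coverage of the genome by phase information) and implements
two concordance metrics between independent phasings of the same sample:

* switch/flip discrepancy — the minimal number of single-SNP reassignments
  (flips) and haplotype switch points (switches) explaining the disagreement
  between two phasings, evaluated per chromosome on the SNPs phased by both;
* consecutive-SNP panel concordance — the fraction of consecutive phased
  heterozygous SNP pairs whose cis/trans relation agrees with an external,
  chromosome-length panel haplotype (e.g. a statistically phased cohort).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

HP1 = "HP1"
HP2 = "HP2"
UNTAGGED = "untagged"


@dataclass(frozen=True)
class PhasedSNP:
    """One phased heterozygous SNP.

    ``hp1_allele``/``hp2_allele`` record which of ref/alt sits on each
    haplotype; heterozygosity (``hp1_allele != hp2_allele``) is an invariant.
    Positions are 1-based, VCF style.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    block_id: int
    hp1_allele: str
    hp2_allele: str

    def __post_init__(self) -> None:
        if self.hp1_allele == self.hp2_allele:
            raise ValueError(
                f"SNP {self.chrom}:{self.pos} is not heterozygous "
                f"({self.hp1_allele}|{self.hp2_allele})"
            )
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def alt_on_hp1(self) -> bool:
        return self.hp1_allele == self.alt


@dataclass
class PhasedBlock:
    """A phase block: >=2 SNPs sharing one PS identifier on one chromosome."""

    chrom: str
    block_id: int
    snps: list[PhasedSNP]

    def __post_init__(self) -> None:
        self.snps = sorted(self.snps, key=lambda s: s.pos)

    @property
    def start(self) -> int:
        return self.snps[0].pos

    @property
    def end(self) -> int:
        return self.snps[-1].pos

    @property
    def length(self) -> int:
        return self.end - self.start

    def __len__(self) -> int:
        return len(self.snps)

    def swapped(self) -> "PhasedBlock":
        """The same block with HP1 and HP2 exchanged (an equivalent phasing)."""
        return PhasedBlock(
            self.chrom,
            self.block_id,
            [
                PhasedSNP(s.chrom, s.pos, s.ref, s.alt, s.block_id,
                          s.hp2_allele, s.hp1_allele)
                for s in self.snps
            ],
        )


@dataclass
class BlockStats:
    n_blocks: int
    n50_length: int
    median_length: float
    max_length: int
    n_phased_snps: int
    phased_fraction: float | None
    genome_coverage: float | None
    n_windows_high: int = 0
    n_windows_low: int = 0
    n_windows: int = 0


@dataclass
class DiscrepancyReport:
    """Switch/flip discrepancies between two phasings, per chromosome and total.

    ``discrepancy_rate`` divides (switch+flip) by the number of compared SNPs;
    ``discrepancy_rate_pairs`` uses compared consecutive pairs as denominator.
    Both are reported because published "discrepancy rates" rarely state the
    denominator.  Rates are ``None`` when nothing was comparable.
    """

    per_chrom: dict[str, dict[str, int]] = field(default_factory=dict)
    n_compared_snps: int = 0
    n_compared_pairs: int = 0
    n_switch: int = 0
    n_flip: int = 0

    @property
    def discrepancy_rate(self) -> float | None:
        if self.n_compared_snps == 0:
            return None
        return (self.n_switch + self.n_flip) / self.n_compared_snps

    @property
    def discrepancy_rate_pairs(self) -> float | None:
        if self.n_compared_pairs == 0:
            return None
        return (self.n_switch + self.n_flip) / self.n_compared_pairs


def n50(lengths: Iterable[int]) -> int:
    """N50 of a set of lengths: the largest L such that elements of length >= L
    together cover at least half of the total length."""
    arr = np.sort(np.asarray(list(lengths), dtype=float))[::-1]
    if arr.size == 0 or arr.sum() <= 0:
        return 0
    half = arr.sum() / 2.0
    idx = int(np.searchsorted(np.cumsum(arr), half))
    return int(arr[idx])


def read_phased_vcf(path: str, sample: str | int = 0) -> list[PhasedBlock]:
    """Parse phased heterozygous SNPs from a VCF with GT|PS into phase blocks.

    Only phased, heterozygous, biallelic SNP records carrying a PS tag are
    retained; blocks are keyed by (chrom, PS).  A file with no phased records
    yields an empty list with a warning.  A malformed genotype raises a
    ``ValueError`` naming the record.
    """
    import pysam

    groups: dict[tuple[str, int], list[PhasedSNP]] = {}
    n_records = 0
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            n_records += 1
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                continue
            try:
                call = rec.samples[sample]
                gt = call["GT"]
            except (KeyError, IndexError) as exc:
                raise ValueError(
                    f"malformed genotype at {rec.chrom}:{rec.pos}"
                ) from exc
            if gt is None or len(gt) != 2 or None in gt:
                continue
            if not call.phased or gt[0] == gt[1]:
                continue
            ps = call.get("PS")
            if ps is None:
                continue
            alleles = (ref, alt)
            snp = PhasedSNP(rec.chrom, rec.pos, ref, alt, int(ps),
                            alleles[gt[0]], alleles[gt[1]])
            groups.setdefault((rec.chrom, int(ps)), []).append(snp)
    blocks = [
        PhasedBlock(chrom, ps, snps)
        for (chrom, ps), snps in sorted(groups.items())
        if len(snps) >= 2
    ]
    if not blocks:
        warnings.warn(f"no phased heterozygous SNPs found in {path}")
    return blocks


def block_stats(
    blocks: Sequence[PhasedBlock],
    het_snps: Mapping[str, Sequence[int]] | None = None,
    het_snp_total: int | None = None,
    window: int = 1_000_000,
    hi: float = 0.75,
    lo: float = 0.25,
) -> BlockStats:
    """Summary statistics of a set of phase blocks.

    ``het_snps`` (chrom -> positions of *all* heterozygous SNPs, phased or not)
    enables the phased fraction and the 1-Mb-window genome coverage: each
    window holding at least one het SNP is classified by the fraction of its
    het SNPs that are phased (> ``hi`` = high coverage, < ``lo`` = low);
    ``genome_coverage`` is the high-coverage fraction of windows.
    """
    n_phased = sum(len(b) for b in blocks)
    if not blocks:
        return BlockStats(0, 0, 0.0, 0, 0, None, None)
    lengths = [b.length for b in blocks]
    phased_fraction = None
    total = het_snp_total
    if total is None and het_snps is not None:
        total = sum(len(v) for v in het_snps.values())
    if total:
        phased_fraction = n_phased / total

    genome_coverage = None
    n_hi = n_lo = n_win = 0
    if het_snps is not None:
        phased_pos: dict[str, set[int]] = {}
        for b in blocks:
            phased_pos.setdefault(b.chrom, set()).update(s.pos for s in b.snps)
        for chrom, positions in het_snps.items():
            pos = np.asarray(sorted(positions))
            if pos.size == 0:
                continue
            ph = phased_pos.get(chrom, set())
            win_idx = (pos - 1) // window
            for w in np.unique(win_idx):
                in_w = pos[win_idx == w]
                frac = sum(1 for p in in_w if p in ph) / in_w.size
                n_win += 1
                if frac > hi:
                    n_hi += 1
                elif frac < lo:
                    n_lo += 1
        if n_win:
            genome_coverage = n_hi / n_win

    return BlockStats(
        n_blocks=len(blocks),
        n50_length=n50(lengths),
        median_length=float(np.median(lengths)),
        max_length=int(max(lengths)),
        n_phased_snps=n_phased,
        phased_fraction=phased_fraction,
        genome_coverage=genome_coverage,
        n_windows_high=n_hi,
        n_windows_low=n_lo,
        n_windows=n_win,
    )


def _switch_flip_counts(disagree: np.ndarray) -> tuple[int, int]:
    """Minimal switch/flip decomposition of a 0/1 disagreement vector.

    Works on the switch sequence s[i] = d[i] XOR d[i+1], which is invariant to
    the (arbitrary) global orientation of either phasing.  Each switch clears
    one s-position; a flip of a single SNP clears two adjacent s-positions, so
    the minimal-cost explanation pairs adjacent s-ones greedily as flips
    (maximum matching on a path) and counts the rest as switches.  Among
    minimal-cost explanations, isolated boundary disagreements are attributed
    to switches rather than flips.
    """
    if disagree.size < 2:
        return 0, 0
    s = np.flatnonzero(np.diff(disagree) != 0)
    switches = flips = 0
    i = 0
    while i < s.size:
        if i + 1 < s.size and s[i + 1] == s[i] + 1:
            flips += 1
            i += 2
        else:
            switches += 1
            i += 1
    return switches, flips


def compare_phasings(
    a: Sequence[PhasedBlock], b: Sequence[PhasedBlock]
) -> DiscrepancyReport:
    """Switch/flip discrepancy between two phasings of the same variants.

    Comparison is restricted to SNPs phased in both inputs (matching chrom,
    pos, ref, alt), performed independently per chromosome and per intersected
    block segment (a maximal run of shared SNPs lying in one block of *a* and
    one block of *b*).  Within each segment the minimal-cost switch/flip
    explanation is counted; identical phasings or globally swapped haplotypes
    yield zero errors.
    """
    report = DiscrepancyReport()
    a_idx: dict[str, dict[int, PhasedSNP]] = {}
    for blk in a:
        a_idx.setdefault(blk.chrom, {}).update({s.pos: s for s in blk.snps})
    b_idx: dict[str, dict[int, PhasedSNP]] = {}
    for blk in b:
        b_idx.setdefault(blk.chrom, {}).update({s.pos: s for s in blk.snps})

    for chrom in sorted(set(a_idx) & set(b_idx)):
        shared = sorted(set(a_idx[chrom]) & set(b_idx[chrom]))
        segments: list[list[tuple[PhasedSNP, PhasedSNP]]] = []
        prev_key = None
        for pos in shared:
            sa, sb = a_idx[chrom][pos], b_idx[chrom][pos]
            if (sa.ref, sa.alt) != (sb.ref, sb.alt):
                continue
            key = (sa.block_id, sb.block_id)
            if key != prev_key:
                segments.append([])
                prev_key = key
            segments[-1].append((sa, sb))

        c_snps = c_pairs = c_sw = c_fl = 0
        for seg in segments:
            d = np.array(
                [0 if sa.alt_on_hp1 == sb.alt_on_hp1 else 1 for sa, sb in seg],
                dtype=int,
            )
            sw, fl = _switch_flip_counts(d)
            c_snps += len(seg)
            c_pairs += max(len(seg) - 1, 0)
            c_sw += sw
            c_fl += fl
        if c_snps:
            report.per_chrom[chrom] = {
                "n_compared_snps": c_snps,
                "n_compared_pairs": c_pairs,
                "n_switch": c_sw,
                "n_flip": c_fl,
            }
            report.n_compared_snps += c_snps
            report.n_compared_pairs += c_pairs
            report.n_switch += c_sw
            report.n_flip += c_fl
    if report.n_compared_snps == 0:
        logger.warning("no shared phased SNPs between the two phasings")
    return report


def panel_concordance(
    blocks: Sequence[PhasedBlock],
    panel: Iterable[PhasedSNP],
) -> tuple[float | None, list[dict]]:
    """Concordance of consecutive-SNP phase relations against a panel.

    The panel provides one chromosome-length haplotype pair (e.g. cohort
    phasing), so only the *relative* phase (cis/trans of the alt alleles) of
    two consecutive phased het SNPs is comparable.  For every pair of
    consecutive SNPs inside one query block with both sites present in the
    panel (same ref/alt), the relation is compared; returns the consistent
    fraction (``None`` when no pair is comparable) and the mismatch list.
    """
    panel_idx: dict[tuple[str, int], PhasedSNP] = {
        (s.chrom, s.pos): s for s in panel
    }
    compared = consistent = 0
    mismatches: list[dict] = []
    for blk in blocks:
        for s1, s2 in zip(blk.snps, blk.snps[1:]):
            p1 = panel_idx.get((s1.chrom, s1.pos))
            p2 = panel_idx.get((s2.chrom, s2.pos))
            if p1 is None or p2 is None:
                continue
            if (p1.ref, p1.alt) != (s1.ref, s1.alt) or (p2.ref, p2.alt) != (
                s2.ref,
                s2.alt,
            ):
                continue
            rel_q = s1.alt_on_hp1 == s2.alt_on_hp1
            rel_p = p1.alt_on_hp1 == p2.alt_on_hp1
            compared += 1
            if rel_q == rel_p:
                consistent += 1
            else:
                mismatches.append(
                    {"chrom": blk.chrom, "pos1": s1.pos, "pos2": s2.pos,
                     "block_id": blk.block_id}
                )
    if compared == 0:
        logger.warning("no comparable consecutive SNP pairs against the panel")
        return None, mismatches
    return consistent / compared, mismatches


def blocks_from_read_connectivity(
    snps: Sequence[PhasedSNP],
    reads: Iterable,
) -> list[PhasedBlock]:
    """Partition SNPs into phase blocks by long-read connectivity.

    Two consecutive het SNPs can be phased jointly only if at least one read
    observes both; maximal runs of connected SNPs form blocks (the haplotype
    assignment within a block is taken from the input SNPs).  Reads must
    expose ``chrom`` and ``observations`` (list of (pos, allele)).  Runs of a
    single SNP are singletons and are not reported as blocks.
    """
    by_chrom: dict[str, list[PhasedSNP]] = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append(s)
    reads_by_chrom: dict[str, list] = {}
    for read in reads:
        reads_by_chrom.setdefault(read.chrom, []).append(read)
    blocks: list[PhasedBlock] = []
    for chrom, chrom_snps in sorted(by_chrom.items()):
        chrom_snps.sort(key=lambda s: s.pos)
        pos = np.array([s.pos for s in chrom_snps])
        linked = np.zeros(max(len(chrom_snps) - 1, 0), dtype=bool)
        for read in reads_by_chrom.get(chrom, ()):
            if len(read.observations) < 2:
                continue
            obs_pos = [p for p, _ in read.observations]
            i = int(np.searchsorted(pos, min(obs_pos)))
            j = int(np.searchsorted(pos, max(obs_pos), side="right"))
            if j - i >= 2:
                linked[i : j - 1] = True
        start = 0
        for gap in range(len(linked) + 1):
            if gap == len(linked) or not linked[gap]:
                run = chrom_snps[start : gap + 1]
                if len(run) >= 2:
                    block_id = run[0].pos
                    blocks.append(
                        PhasedBlock(
                            chrom,
                            block_id,
                            [
                                PhasedSNP(s.chrom, s.pos, s.ref, s.alt,
                                          block_id, s.hp1_allele, s.hp2_allele)
                                for s in run
                            ],
                        )
                    )
                start = gap + 1
    return blocks


def perturb_phasing(
    blocks: Sequence[PhasedBlock],
    flip_rate: float = 0.0,
    switch_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[list[PhasedBlock], int, int]:
    """Inject phasing errors for benchmarking the discrepancy metrics.

    Each SNP is flipped (alleles exchanged between haplotypes) independently
    with ``flip_rate``; a switch point (all downstream SNPs of the block
    exchanged) starts at each non-initial SNP with ``switch_rate``.  Returns
    the perturbed blocks and the number of injected flips and switches.
    """
    rng = rng or np.random.default_rng()
    out: list[PhasedBlock] = []
    n_flips = n_switches = 0
    for blk in blocks:
        orient = np.zeros(len(blk.snps), dtype=bool)
        sw = rng.random(len(blk.snps)) < switch_rate
        sw[0] = False
        state = False
        for i in range(len(blk.snps)):
            if sw[i]:
                state = not state
                n_switches += 1
            orient[i] = state
        fl = rng.random(len(blk.snps)) < flip_rate
        n_flips += int(fl.sum())
        orient ^= fl
        snps = [
            PhasedSNP(s.chrom, s.pos, s.ref, s.alt, s.block_id,
                      s.hp2_allele if o else s.hp1_allele,
                      s.hp1_allele if o else s.hp2_allele)
            for s, o in zip(blk.snps, orient)
        ]
        out.append(PhasedBlock(blk.chrom, blk.block_id, snps))
    return out, n_flips, n_switches
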