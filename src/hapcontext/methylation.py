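"""Allele-specific CpG methylation and haplotype DMR bias.

Per-read CpG methylation calls from nanopore data (nanopolish-style: one row
per read per CpG site) are split by the read's haplotype tag and aggregated
into per-site per-haplotype methylation frequencies (sites need >= 3 tagged
reads on a haplotype).  A minimal internal caller then finds differentially
methylated regions (DMRs) between haplotypes as maximal runs of consecutive
CpG sites with a consistent frequency difference; externally produced DMR
tables (e.g. metilene output) can be used as a drop-in replacement.  Phase
blocks whose DMRs point predominantly the same way are flagged as
"DMR-bias" blocks under three conditions: at least 3 DMRs in the major
direction, the major direction holding at least 70% of the block's DMRs,
and at least 3 major-direction DMRs per Mb of block span; tumor DMRs
overlapped more than 20% of their length by matched-normal DMRs are removed
beforehand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bias import bh_adjust
from .phasing import HP1, HP2, PhasedBlock

HP1_HYPO = "hp1_hypo"
HP2_HYPO = "hp2_hypo"

MIN_READS_PER_SITE = 3
DMR_MIN_CPGS = 5
DMR_MIN_DIFF = 0.3
BIAS_MIN_SAME_DIRECTION = 3
BIAS_MIN_RATIO = 0.7
BIAS_MIN_PER_MB = 3.0
NORMAL_OVERLAP_MAX = 0.2


@dataclass
class DMR:
    chrom: str
    start: int
    end: int
    mean_freq_hp1: float
    mean_freq_hp2: float
    direction: str
    n_cpgs: int
    q_value: float | None = None

    def __post_init__(self) -> None:
        expected = HP1_HYPO if self.mean_freq_hp1 < self.mean_freq_hp2 else HP2_HYPO
        if self.direction != expected:
            raise ValueError(
                f"direction {self.direction} inconsistent with mean difference"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class DMRBiasBlock:
    block_id: int
    block_length: int
    n_dmrs_total: int
    n_dmrs_major_direction: int
    major_direction: str
    dmrs_per_mb: float


def haplotype_methylation_frequency(
    calls: pd.DataFrame,
    min_reads: int = MIN_READS_PER_SITE,
) -> pd.DataFrame:
    """Per-site per-haplotype methylation frequencies.

    ``calls`` columns: read_id, chrom, pos, methylated (0/1), hap.  Calls on
    untagged reads are ignored; a haplotype's frequency at a site is emitted
    only when covered by >= ``min_reads`` tagged reads of that haplotype.
    Returns a table with columns chrom, pos, freq_hp1, freq_hp2, n_hp1,
    n_hp2 (frequencies NaN where suppressed).
    """
    tagged = calls[calls["hap"].isin([HP1, HP2])]
    if tagged.empty:
        return pd.DataFrame(
            columns=["chrom", "pos", "freq_hp1", "freq_hp2", "n_hp1", "n_hp2"]
        )
    g = tagged.groupby(["chrom", "pos", "hap"])["methylated"].agg(["sum", "count"])
    g = g.unstack("hap")
    out = pd.DataFrame(index=g.index)
    for hap, suffix in ((HP1, "hp1"), (HP2, "hp2")):
        n = g["count"].get(hap, pd.Series(0.0, index=g.index)).fillna(0)
        meth = g["sum"].get(hap, pd.Series(0.0, index=g.index)).fillna(0)
        freq = np.where(n >= min_reads, meth / np.maximum(n, 1), np.nan)
        out[f"freq_{suffix}"] = freq
        out[f"n_{suffix}"] = n.astype(int)
    return out.reset_index().sort_values(["chrom", "pos"]).reset_index(drop=True)


def call_dmrs(
    freq_table: pd.DataFrame,
    min_cpgs: int = DMR_MIN_CPGS,
    min_diff: float = DMR_MIN_DIFF,
    q_alpha: float = 0.05,
) -> list[DMR]:
    """Minimal between-haplotype DMR caller.

    Candidate regions are maximal runs of consecutive CpG sites (consecutive
    rows of the frequency table with both haplotype frequencies available)
    where |freq_hp1 - freq_hp2| >= ``min_diff`` with a consistent sign over
    >= ``min_cpgs`` sites.  Each candidate is tested with a two-sided
    Mann-Whitney U on the per-site frequencies of the two haplotypes and
    kept at BH-adjusted q < ``q_alpha``.
    """
    candidates: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]] = []
    usable = freq_table.dropna(subset=["freq_hp1", "freq_hp2"])
    for chrom, sub in usable.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        f1 = sub["freq_hp1"].to_numpy()
        f2 = sub["freq_hp2"].to_numpy()
        diff = f1 - f2
        sign = np.where(diff >= min_diff, 1, np.where(diff <= -min_diff, -1, 0))
        # runs are over consecutive usable rows, not genomic adjacency
        run_start: int | None = None
        run_sign = 0
        for i in range(len(sign) + 1):
            s = int(sign[i]) if i < len(sign) else 0
            if run_start is not None and s != run_sign:
                if i - run_start >= min_cpgs:
                    candidates.append(
                        (chrom, pos[run_start:i], f1[run_start:i], f2[run_start:i])
                    )
                run_start = None
            if run_start is None and s != 0:
                run_start, run_sign = i, s
    if not candidates:
        return []
    pvals = []
    for _, _, f1, f2 in candidates:
        if np.all(f1 == f1[0]) and np.all(f2 == f2[0]) and f1[0] == f2[0]:
            pvals.append(1.0)
        else:
            pvals.append(float(stats.mannwhitneyu(f1, f2).pvalue))
    qvals = bh_adjust(np.array(pvals))
    dmrs = []
    for (chrom, pos, f1, f2), q in zip(candidates, qvals):
        if q >= q_alpha:
            continue
        m1, m2 = float(f1.mean()), float(f2.mean())
        dmrs.append(
            DMR(chrom, int(pos[0]), int(pos[-1]), m1, m2,
                HP1_HYPO if m1 < m2 else HP2_HYPO, len(pos), float(q))
        )
    return dmrs


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def filter_normal_dmrs(
    tumor_dmrs: Sequence[DMR],
    normal_dmrs: Sequence[DMR],
    max_overlap: float = NORMAL_OVERLAP_MAX,
) -> list[DMR]:
    """Drop tumor DMRs overlapped by matched-normal DMRs over ``max_overlap``
    of the tumor DMR's length (constitutive allele-specific methylation)."""
    kept = []
    for t in tumor_dmrs:
        ov = sum(
            _overlap(t.start, t.end, n.start, n.end)
            for n in normal_dmrs
            if n.chrom == t.chrom
        )
        if ov / t.length <= max_overlap:
            kept.append(t)
    return kept


def dmr_bias_blocks(
    tumor_dmrs: Sequence[DMR],
    normal_dmrs: Sequence[DMR],
    blocks: Sequence[PhasedBlock],
    min_same_direction: int = BIAS_MIN_SAME_DIRECTION,
    min_ratio: float = BIAS_MIN_RATIO,
    min_per_mb: float = BIAS_MIN_PER_MB,
    max_normal_overlap: float = NORMAL_OVERLAP_MAX,
) -> list[DMRBiasBlock]:
    """Phase blocks with haplotype-directional DMR bias.

    After removing tumor DMRs explained by the matched normal, each DMR is
    assigned to the phase block it overlaps most.  A block is reported iff
    (i) the major hypomethylation direction holds >= ``min_same_direction``
    DMRs, (ii) that count is >= ``min_ratio`` of the block's DMRs, and
    (iii) the major-direction count per Mb of block span is >= ``min_per_mb``.
    """
    dmrs = filter_normal_dmrs(tumor_dmrs, normal_dmrs, max_normal_overlap)
    per_block: dict[int, list[str]] = {}
    block_by_id = {b.block_id: b for b in blocks}
    for d in dmrs:
        best, best_ov = None, 0
        for b in blocks:
            if b.chrom != d.chrom:
                continue
            ov = _overlap(d.start, d.end, b.start, b.end)
            if ov > best_ov:
                best, best_ov = b.block_id, ov
        if best is not None:
            per_block.setdefault(best, []).append(d.direction)
    out = []
    for bid, directions in sorted(per_block.items()):
        n1 = directions.count(HP1_HYPO)
        n2 = directions.count(HP2_HYPO)
        major = max(n1, n2)
        major_dir = HP1_HYPO if n1 >= n2 else HP2_HYPO
        block_len = max(block_by_id[bid].length, 1)
        per_mb = major / (block_len / 1e6)
        if (
            major >= min_same_direction
            and major / len(directions) >= min_ratio
            and per_mb >= min_per_mb
        ):
            out.append(
                DMRBiasBlock(bid, block_len, len(directions), major,
                             major_dir, per_mb)
            )
    return out
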