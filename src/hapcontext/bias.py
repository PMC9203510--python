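"""Mutation-enriched windows, haplotype-biased regions and SV-dense blocks.

The genome is partitioned into fixed non-overlapping windows (100 kb by
default).  Each window's somatic mutation count is tested against the
genome-wide rate with a one-sided Poisson upper-tail test, adjusted with
Benjamini-Hochberg across windows.  Adjacent significant windows are merged
into regions, and a region is called *haplotype biased* when more than 80%
of its haplotype-resolved mutations lie on one haplotype (with at least
``min_phased`` resolved mutations in the region).  Phase blocks dense in
phased SVs (three or more) are reported with the maximum per-haplotype
proportion of their SVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .phasing import HP1, HP2, PhasedBlock
from .somatic import UNKNOWN, SomaticVariant, StructuralVariant

DEFAULT_WINDOW = 100_000
BIAS_THRESHOLD = 0.8  # "more than 80%" -> strict inequality
DEFAULT_MIN_PHASED = 5


@dataclass
class EnrichedRegion:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # inclusive
    n_mutations: int
    expected_mutations: float
    p_raw: float
    p_adjusted: float
    block_ids: list[int] = field(default_factory=list)


@dataclass
class BiasedRegion:
    region: EnrichedRegion
    n_hp1: int
    n_hp2: int
    n_unknown: int
    biased_hap: str | None
    bias_fraction: float | None
    p_binomial: float | None
    reason: str | None = None

    @property
    def is_biased(self) -> bool:
        return self.biased_hap is not None


@dataclass
class SVConcentratedBlock:
    block_id: int
    n_phased_svs: int
    n_hp1: int
    n_hp2: int

    @property
    def max_hap_proportion(self) -> float:
        return max(self.n_hp1, self.n_hp2) / self.n_phased_svs


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone in raw-p rank)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return stats.false_discovery_control(p, method="bh")


def assign_windows(
    variants: Sequence[SomaticVariant],
    chrom_sizes: Mapping[str, int],
    window: int = DEFAULT_WINDOW,
) -> dict[tuple[str, int], list[SomaticVariant]]:
    """Partition variants onto the fixed window grid; every variant falls in
    exactly one window."""
    out: dict[tuple[str, int], list[SomaticVariant]] = {}
    for v in variants:
        if v.chrom not in chrom_sizes:
            raise KeyError(f"variant on unknown chromosome {v.chrom}")
        out.setdefault((v.chrom, (v.pos - 1) // window), []).append(v)
    return out


def find_enriched_windows(
    variants: Sequence[SomaticVariant],
    chrom_sizes: Mapping[str, int],
    window: int = DEFAULT_WINDOW,
    alpha: float = 0.05,
    callable_length: int | None = None,
    method: str = "poisson",
) -> tuple[list[EnrichedRegion], "object"]:
    """Windows where somatic mutations are enriched over the genome-wide rate.

    Every grid window of every chromosome is tested (count 0 gives p = 1).
    ``callable_length`` defaults to the total genome size; pass the phased
    block span when enrichment should be sought only within phase blocks.
    ``method`` is "poisson" (upper tail at lambda = total x window/callable)
    or "binomial" (count vs total with p = window/callable).  Returns the
    significant windows (BH-adjusted p < alpha) and a table of all windows.
    """
    import pandas as pd

    if method not in ("poisson", "binomial"):
        raise ValueError(f"unknown enrichment method {method!r}")
    total = len(variants)
    if total == 0:
        return [], pd.DataFrame(
            columns=["chrom", "start", "end", "n", "expected", "p", "p_adj"]
        )
    genome = sum(chrom_sizes.values())
    callable_length = callable_length or genome
    counts = assign_windows(variants, chrom_sizes, window)
    rows = []
    for chrom, size in chrom_sizes.items():
        n_win = (size + window - 1) // window
        for w in range(n_win):
            k = len(counts.get((chrom, w), ()))
            win_len = min(window, size - w * window)
            lam = total * win_len / callable_length
            if method == "poisson":
                p = float(stats.poisson.sf(k - 1, lam)) if k > 0 else 1.0
            else:
                p = float(stats.binom.sf(k - 1, total, win_len / callable_length)) if k > 0 else 1.0
            rows.append((chrom, w * window + 1, w * window + win_len, k, lam, p))
    table = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n", "expected", "p"]
    )
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    enriched = [
        EnrichedRegion(r.chrom, int(r.start), int(r.end), int(r.n),
                       float(r.expected), float(r.p), float(r.p_adj))
        for r in table.itertuples()
        if r.p_adj < alpha
    ]
    return enriched, table


def merge_adjacent_regions(
    regions: Sequence[EnrichedRegion],
) -> list[EnrichedRegion]:
    """Union adjacent/overlapping significant windows into single regions;
    the merged region keeps the smallest member p-values and summed counts."""
    merged: list[EnrichedRegion] = []
    for reg in sorted(regions, key=lambda r: (r.chrom, r.start)):
        if merged and merged[-1].chrom == reg.chrom and (
            reg.start <= merged[-1].end + 1
        ):
            prev = merged[-1]
            prev.end = max(prev.end, reg.end)
            prev.n_mutations += reg.n_mutations
            prev.expected_mutations += reg.expected_mutations
            prev.p_raw = min(prev.p_raw, reg.p_raw)
            prev.p_adjusted = min(prev.p_adjusted, reg.p_adjusted)
        else:
            merged.append(
                EnrichedRegion(reg.chrom, reg.start, reg.end, reg.n_mutations,
                               reg.expected_mutations, reg.p_raw,
                               reg.p_adjusted, list(reg.block_ids))
            )
    return merged


def call_biased_regions(
    enriched: Sequence[EnrichedRegion],
    variants: Sequence[SomaticVariant],
    min_phased: int = DEFAULT_MIN_PHASED,
    threshold: float = BIAS_THRESHOLD,
    merge: bool = True,
    blocks: Sequence[PhasedBlock] | None = None,
) -> list[BiasedRegion]:
    """Haplotype-bias calls on mutation-enriched regions.

    Only HP1/HP2-resolved mutations enter the bias fraction; a region is
    biased iff it holds >= ``min_phased`` resolved mutations and the major
    haplotype carries strictly more than ``threshold`` of them.  An exact
    two-sided binomial p-value against 0.5 is reported alongside.
    """
    regions = merge_adjacent_regions(enriched) if merge else list(enriched)
    out: list[BiasedRegion] = []
    for reg in regions:
        in_reg = [v for v in variants
                  if v.chrom == reg.chrom and reg.start <= v.pos <= reg.end]
        n1 = sum(1 for v in in_reg if v.hap == HP1)
        n2 = sum(1 for v in in_reg if v.hap == HP2)
        nu = sum(1 for v in in_reg if v.hap == UNKNOWN)
        if blocks is not None:
            reg.block_ids = sorted(
                b.block_id for b in blocks
                if b.chrom == reg.chrom
                and b.start <= reg.end and b.end >= reg.start
            )
        if n1 + n2 < min_phased:
            out.append(BiasedRegion(reg, n1, n2, nu, None, None, None,
                                    reason="insufficient_phased_mutations"))
            continue
        frac = max(n1, n2) / (n1 + n2)
        p = float(stats.binomtest(n1, n1 + n2, 0.5).pvalue)
        hap = (HP1 if n1 > n2 else HP2) if frac > threshold else None
        out.append(BiasedRegion(reg, n1, n2, nu, hap, frac, p,
                                None if hap else "below_bias_threshold"))
    return out


def sv_concentrated_blocks(
    svs: Iterable[StructuralVariant],
    min_svs: int = 3,
) -> list[SVConcentratedBlock]:
    """Phase blocks holding >= ``min_svs`` phased SVs, with the maximum
    proportion of the block's SVs lying on a single haplotype."""
    per_block: dict[int, list[str]] = {}
    for sv in svs:
        if sv.hap in (HP1, HP2):
            for bid in sv.block_ids or []:
                per_block.setdefault(bid, []).append(sv.hap)
    out = []
    for bid, haps in sorted(per_block.items()):
        if len(haps) >= min_svs:
            out.append(
                SVConcentratedBlock(bid, len(haps),
                                    haps.count(HP1), haps.count(HP2))
            )
    return out
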