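"""Haplotagging of long reads from their phased-SNP observations.

A read is assigned to a haplotype from the heterozygous SNP alleles it
carries: with at least two informative SNP observations inside one phase
block and at least 70% of them matching a single haplotype, the read is
labelled HP1 or HP2 ("phased read"); otherwise it stays untagged.  The same
rule is applied to genomic (DNA) and transcript (RNA) reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .phasing import HP1, HP2, UNTAGGED, PhasedBlock

MIN_INFORMATIVE_SNPS = 2
MIN_HAP_RATIO = 0.7
_RATIO_EPS = 1e-9


@dataclass
class HaplotaggedRead:
    """A read's SNP observations plus its derived haplotype label."""

    read_id: str
    block_id: int | None
    observations: list[tuple[int, str]] = field(default_factory=list)
    hp1_count: int = 0
    hp2_count: int = 0
    label: str = UNTAGGED

    @property
    def informative(self) -> int:
        return self.hp1_count + self.hp2_count


def _label_from_counts(
    hp1: int, hp2: int, min_snps: int = MIN_INFORMATIVE_SNPS,
    min_ratio: float = MIN_HAP_RATIO,
) -> str:
    total = hp1 + hp2
    if total < min_snps:
        return UNTAGGED
    major = max(hp1, hp2)
    # ratio >= 0.7 with the boundary inclusive (7:3 is tagged)
    if major < min_ratio * total - _RATIO_EPS:
        return UNTAGGED
    if hp1 == hp2:
        return UNTAGGED
    return HP1 if hp1 > hp2 else HP2


def tag_read(
    observations: Sequence[tuple[int, str]],
    block: PhasedBlock | Mapping[int, tuple[str, str]],
    read_id: str = "",
    min_snps: int = MIN_INFORMATIVE_SNPS,
    min_ratio: float = MIN_HAP_RATIO,
) -> HaplotaggedRead:
    """Tag one read against one phase block.

    ``observations`` are (pos, allele) pairs; alleles matching neither
    haplotype allele at a phased site (sequencing errors, somatic alleles)
    are non-informative.  The read is labelled HPk iff it has at least
    ``min_snps`` informative observations and the majority haplotype holds at
    least ``min_ratio`` of them (boundary inclusive).  Reads spanning two
    blocks are tagged per block by separate calls.
    """
    if isinstance(block, PhasedBlock):
        alleles = {s.pos: (s.hp1_allele, s.hp2_allele) for s in block.snps}
        block_id: int | None = block.block_id
    else:
        alleles = dict(block)
        block_id = None
    hp1 = hp2 = 0
    for pos, obs in observations:
        pair = alleles.get(pos)
        if pair is None:
            continue
        if obs == pair[0]:
            hp1 += 1
        elif obs == pair[1]:
            hp2 += 1
    return HaplotaggedRead(
        read_id=read_id,
        block_id=block_id,
        observations=list(observations),
        hp1_count=hp1,
        hp2_count=hp2,
        label=_label_from_counts(hp1, hp2, min_snps, min_ratio),
    )


def tag_reads(
    reads: Iterable,
    blocks: Sequence[PhasedBlock],
    min_snps: int = MIN_INFORMATIVE_SNPS,
    min_ratio: float = MIN_HAP_RATIO,
) -> dict[str, HaplotaggedRead]:
    """Tag many reads; each read is matched to the block covering most of its
    observations.  Reads must expose ``read_id``, ``chrom`` and
    ``observations``.  Returns read_id -> HaplotaggedRead.
    """
    site_to_block: dict[tuple[str, int], PhasedBlock] = {}
    for blk in blocks:
        for s in blk.snps:
            site_to_block[(blk.chrom, s.pos)] = blk
    out: dict[str, HaplotaggedRead] = {}
    for read in reads:
        hits: dict[int, list[tuple[int, str]]] = {}
        block_of: dict[int, PhasedBlock] = {}
        for pos, allele in read.observations:
            blk = site_to_block.get((read.chrom, pos))
            if blk is not None:
                hits.setdefault(blk.block_id, []).append((pos, allele))
                block_of[blk.block_id] = blk
        if not hits:
            out[read.read_id] = HaplotaggedRead(read.read_id, None,
                                                list(read.observations))
            continue
        best = max(hits, key=lambda b: len(hits[b]))
        tagged = tag_read(hits[best], block_of[best], read.read_id,
                          min_snps, min_ratio)
        out[read.read_id] = tagged
    return out
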