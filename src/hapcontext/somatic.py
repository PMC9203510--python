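"""Haplotype assignment of somatic variants from haplotagged long reads.

Somatic SNVs/indels are assigned to a haplotype when three or more mutant
reads (reads carrying the alternate allele) are tagged to one haplotype and
at most one to the other.  Structural variants are assigned when at least
three of their supporting reads are haplotagged and at least 70% of the
tagged supporters agree (boundary inclusive); SVs outside the autosomes are
excluded from phasing.  Mutation pairs co-spanned by individual reads are
ordered by the presence/absence pattern of the two alleles on each molecule.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .phasing import HP1, HP2, UNTAGGED
from .reads import HaplotaggedRead

UNKNOWN = "unknown"

# paper rule: >=3 mutant reads on one haplotype, <=1 on the other
MIN_MAJOR_MUTANT_READS = 3
MAX_MINOR_MUTANT_READS = 1
MIN_PHASED_SUPPORT = 3
MIN_SUPPORT_RATIO = 0.7
_RATIO_EPS = 1e-9

_AUTOSOME_RE = re.compile(r"^(chr)?([1-9]|1[0-9]|2[0-2])$")


@dataclass
class SomaticVariant:
    """A somatic SNV/MNV/indel with VAF and haplotype evidence."""

    chrom: str
    pos: int
    ref: str
    alt: str
    kind: str = "SNV"
    vaf: float | None = None
    hap: str = UNKNOWN
    block_id: int | None = None
    mut_read_ids: dict[str, list[str]] = field(default_factory=dict)
    annotation: str | None = None
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"VAF out of [0,1]: {self.vaf}")

    @property
    def var_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class StructuralVariant:
    """A somatic SV with two breakpoints and supporting-read evidence."""

    sv_id: str
    sv_type: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    supporting_read_ids: list[str] = field(default_factory=list)
    hap: str = UNKNOWN
    block_ids: list[int] = field(default_factory=list)
    n_hp1_support: int = 0
    n_hp2_support: int = 0
    reason: str | None = None

    def __post_init__(self) -> None:
        # canonical breakpoint order: (chrom1, pos1) <= (chrom2, pos2)
        if (self.chrom1, self.pos1) > (self.chrom2, self.pos2):
            self.chrom1, self.chrom2 = self.chrom2, self.chrom1
            self.pos1, self.pos2 = self.pos2, self.pos1
            self.strand1, self.strand2 = self.strand2, self.strand1

    @property
    def is_intrachromosomal(self) -> bool:
        return self.chrom1 == self.chrom2

    def interval(self) -> tuple[str, int, int]:
        if not self.is_intrachromosomal:
            raise ValueError(f"{self.sv_id} is interchromosomal")
        return self.chrom1, min(self.pos1, self.pos2), max(self.pos1, self.pos2)


def is_autosome(chrom: str) -> bool:
    return _AUTOSOME_RE.match(chrom) is not None


def assign_snv_haplotype(
    hp1_mut: int,
    hp2_mut: int,
    min_major: int = MIN_MAJOR_MUTANT_READS,
    max_minor: int = MAX_MINOR_MUTANT_READS,
) -> tuple[str, str | None]:
    """Haplotype call from mutant-read counts per haplotype.

    Returns (hap, reason); HPk iff that haplotype holds >= ``min_major``
    mutant reads and the other holds <= ``max_minor``.
    """
    if hp1_mut == 0 and hp2_mut == 0:
        return UNKNOWN, "no_coverage"
    if hp1_mut >= min_major and hp2_mut <= max_minor:
        return HP1, None
    if hp2_mut >= min_major and hp1_mut <= max_minor:
        return HP2, None
    return UNKNOWN, "ambiguous_support"


def phase_snvs(
    variants: Iterable[SomaticVariant],
    tagged_reads: Mapping[str, HaplotaggedRead],
    reads_by_variant: Mapping[str, Sequence[str]],
    min_major: int = MIN_MAJOR_MUTANT_READS,
    max_minor: int = MAX_MINOR_MUTANT_READS,
    min_vaf: float | None = None,
) -> list[SomaticVariant]:
    """Assign haplotypes to somatic point mutations.

    ``reads_by_variant`` maps a variant id to the ids of reads carrying its
    alternate allele; labels come from ``tagged_reads``.  An optional VAF
    floor (e.g. 0.2) restricts assignment to better-covered mutations.
    """
    out = []
    for var in variants:
        if min_vaf is not None and (var.vaf is None or var.vaf < min_vaf):
            var.hap, var.reason = UNKNOWN, "below_vaf_floor"
            out.append(var)
            continue
        by_hap: dict[str, list[str]] = {HP1: [], HP2: [], UNTAGGED: []}
        for rid in reads_by_variant.get(var.var_id, ()):
            tag = tagged_reads.get(rid)
            label = tag.label if tag is not None else UNTAGGED
            by_hap[label].append(rid)
        var.mut_read_ids = by_hap
        var.hap, var.reason = assign_snv_haplotype(
            len(by_hap[HP1]), len(by_hap[HP2]), min_major, max_minor
        )
        if var.hap != UNKNOWN:
            tags = [tagged_reads[r] for r in by_hap[var.hap]
                    if r in tagged_reads]
            block_ids = {t.block_id for t in tags if t.block_id is not None}
            var.block_id = min(block_ids) if block_ids else None
        out.append(var)
    return out


def phase_sv(
    sv: StructuralVariant,
    tagged_reads: Mapping[str, HaplotaggedRead],
    min_support: int = MIN_PHASED_SUPPORT,
    min_ratio: float = MIN_SUPPORT_RATIO,
    restrict_to_autosomes: bool = True,
) -> StructuralVariant:
    """Assign a haplotype to one SV from its tagged supporting reads.

    Observations from a read's primary and supplementary alignments are
    assumed pooled before tagging, and each read counts once.  Phased iff
    >= ``min_support`` supporting reads are tagged and the majority haplotype
    holds >= ``min_ratio`` of the tagged supporters (boundary inclusive).
    """
    if restrict_to_autosomes and not (
        is_autosome(sv.chrom1) and is_autosome(sv.chrom2)
    ):
        sv.hap, sv.reason = UNKNOWN, "non_autosomal"
        return sv
    labels = []
    block_ids = set()
    for rid in dict.fromkeys(sv.supporting_read_ids):
        tag = tagged_reads.get(rid)
        if tag is not None and tag.label in (HP1, HP2):
            labels.append(tag.label)
            if tag.block_id is not None:
                block_ids.add(tag.block_id)
    sv.n_hp1_support = labels.count(HP1)
    sv.n_hp2_support = labels.count(HP2)
    total = len(labels)
    if total < min_support:
        sv.hap, sv.reason = UNKNOWN, "insufficient_phased_support"
        return sv
    major = max(sv.n_hp1_support, sv.n_hp2_support)
    if major < min_ratio * total - _RATIO_EPS or (
        sv.n_hp1_support == sv.n_hp2_support
    ):
        sv.hap, sv.reason = UNKNOWN, "ambiguous_support"
        return sv
    sv.hap = HP1 if sv.n_hp1_support > sv.n_hp2_support else HP2
    sv.block_ids = sorted(block_ids)
    sv.reason = None
    return sv


def phase_svs(
    svs: Iterable[StructuralVariant],
    tagged_reads: Mapping[str, HaplotaggedRead],
    **kwargs,
) -> list[StructuralVariant]:
    return [phase_sv(sv, tagged_reads, **kwargs) for sv in svs]


@dataclass
class OrderedPair:
    first: str
    second: str
    relation: str  # ordered | co_occurring | conflicting | unresolved
    n_neither: int
    n_first_only: int
    n_second_only: int
    n_both: int


def order_mutation_pairs(
    variants: Sequence[SomaticVariant],
    read_alleles: Mapping[str, Mapping[str, bool]],
    min_reads: int = 2,
) -> list[OrderedPair]:
    """Temporal ordering of mutation pairs co-spanned by single molecules.

    ``read_alleles`` maps read_id -> {variant_id: carries_alt} for every
    variant position the read covers; pairs never co-covered by a read are
    not analysed (relationships beyond the read length cannot be inferred).
    "A before B" requires >= ``min_reads`` reads carrying both mutations,
    >= ``min_reads`` carrying A alone and none carrying B alone.  Reads with
    A-only and B-only patterns both supported indicate parallel clones
    (conflicting); only {neither, both} patterns leave the pair co-occurring
    but unordered.
    """
    ids = [v.var_id for v in variants]
    pair_counts: dict[tuple[str, str], list[int]] = {}
    for cov in read_alleles.values():
        present = [v for v in ids if v in cov]
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                a, b = sorted((present[i], present[j]))
                counts = pair_counts.setdefault((a, b), [0, 0, 0, 0])
                has_a, has_b = cov[a], cov[b]
                if has_a and has_b:
                    counts[3] += 1
                elif has_a:
                    counts[1] += 1
                elif has_b:
                    counts[2] += 1
                else:
                    counts[0] += 1
    out: list[OrderedPair] = []
    for (a, b), (n_neither, n_a, n_b, n_both) in sorted(pair_counts.items()):
        if n_a >= min_reads and n_b >= min_reads:
            relation, first, second = "conflicting", a, b
        elif n_both >= min_reads and n_a >= min_reads and n_b == 0:
            relation, first, second = "ordered", a, b
        elif n_both >= min_reads and n_b >= min_reads and n_a == 0:
            relation, first, second = "ordered", b, a
        elif n_a == 0 and n_b == 0 and n_both > 0:
            relation, first, second = "co_occurring", a, b
        else:
            relation, first, second = "unresolved", a, b
        if first == b:
            n_a, n_b = n_b, n_a
        out.append(OrderedPair(first, second, relation,
                               n_neither, n_a, n_b, n_both))
    return out
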