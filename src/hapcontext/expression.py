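"""Allele-specific expression and its link to regulatory aberrations.

Transcript reads are assigned to haplotypes with the same >=2-SNP, >=70%
rule used for genomic reads.  At each phased exonic SNP the HP1/HP2 read
counts are tested against a balanced 0.5 ratio with an exact binomial test
per tissue (BH-adjusted across SNPs); a SNP is *tumor-specific* biased when
significant in the tumor but not, in the same direction, in the matched
normal.  Genes aggregate their SNPs by majority direction.  Candidate
regulatory mutations are somatic variants in promoters (TSS +-1.5 kb) or
supplied enhancer intervals, excluding exonic/5'UTR/3'UTR annotations, and
are joined to biased genes on gene and haplotype, together with DMR-bias
evidence on the same phase block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .bias import bh_adjust
from .methylation import HP1_HYPO, DMRBiasBlock
from .phasing import HP1, HP2
from .reads import tag_read
from .somatic import SomaticVariant

tag_rna_read = tag_read  # identical labelling rule for transcript reads

PROMOTER_HALF_WIDTH = 1500
EXCLUDED_ANNOTATIONS = frozenset({"exonic", "5UTR", "3UTR"})


@dataclass
class AllelicCount:
    snp_id: str
    gene_id: str
    tissue: str  # tumor | normal
    hp1_reads: int
    hp2_reads: int

    def __post_init__(self) -> None:
        if self.hp1_reads < 0 or self.hp2_reads < 0:
            raise ValueError("read counts must be non-negative")


@dataclass
class RegulatoryCandidate:
    variant: SomaticVariant
    element: str  # promoter | enhancer
    gene_id: str
    hap: str


def allelic_expression_test(
    counts: Iterable[AllelicCount],
    alpha: float = 0.05,
    min_total: int = 10,
    test: str = "binomial",
) -> pd.DataFrame:
    """Per-SNP haplotype-bias verdicts in tumor and normal tissue.

    Each (snp, tissue) with >= ``min_total`` tagged reads is tested
    two-sided against a balanced ratio (exact binomial, default) with BH
    adjustment across SNPs within the tissue; ``test="fisher"`` instead
    contrasts tumor vs normal counts per SNP in a 2x2 exact test.  Returns a
    per-SNP frame with per-tissue p/q-values, bias directions, a
    ``tumor_specific`` flag, and a ``low_coverage`` flag per tissue.
    """
    df = pd.DataFrame(
        [
            (c.snp_id, c.gene_id, c.tissue, c.hp1_reads, c.hp2_reads)
            for c in counts
        ],
        columns=["snp_id", "gene_id", "tissue", "hp1", "hp2"],
    )
    if df.empty:
        return pd.DataFrame()
    wide = df.pivot_table(
        index=["snp_id", "gene_id"], columns="tissue",
        values=["hp1", "hp2"], aggfunc="sum", fill_value=0,
    )
    out = pd.DataFrame(index=wide.index).reset_index()
    for tissue in ("tumor", "normal"):
        hp1 = wide["hp1"].get(tissue, pd.Series(0, index=wide.index))
        hp2 = wide["hp2"].get(tissue, pd.Series(0, index=wide.index))
        total = hp1 + hp2
        tested = total >= min_total
        pvals = [
            float(stats.binomtest(int(a), int(n), 0.5).pvalue) if ok else float("nan")
            for a, n, ok in zip(hp1, total, tested)
        ]
        out[f"{tissue}_hp1"] = hp1.to_numpy()
        out[f"{tissue}_hp2"] = hp2.to_numpy()
        out[f"{tissue}_low_coverage"] = (~tested).to_numpy()
        out[f"{tissue}_p"] = pvals
        q = pd.Series(float("nan"), index=out.index)
        mask = out[f"{tissue}_p"].notna()
        if mask.any():
            q[mask] = bh_adjust(out.loc[mask, f"{tissue}_p"].to_numpy())
        out[f"{tissue}_q"] = q
        out[f"{tissue}_sig"] = (q < alpha).fillna(False)
        out[f"{tissue}_biased_hap"] = [
            (HP1 if a > b else HP2) if sig else None
            for a, b, sig in zip(out[f"{tissue}_hp1"], out[f"{tissue}_hp2"],
                                 out[f"{tissue}_sig"])
        ]
    if test == "fisher":
        fisher_p = [
            float(stats.fisher_exact(
                [[t1, t2], [n1, n2]]).pvalue)
            for t1, t2, n1, n2 in zip(out["tumor_hp1"], out["tumor_hp2"],
                                      out["normal_hp1"], out["normal_hp2"])
        ]
        out["tumor_vs_normal_p"] = fisher_p
        out["tumor_vs_normal_q"] = bh_adjust(pd.Series(fisher_p).to_numpy())
    elif test != "binomial":
        raise ValueError(f"unknown test {test!r}")
    out["tumor_specific"] = [
        bool(ts) and not (bool(ns) and th == nh)
        for ts, ns, th, nh in zip(out["tumor_sig"], out["normal_sig"],
                                  out["tumor_biased_hap"],
                                  out["normal_biased_hap"])
    ]
    return out


def gene_level_verdicts(snp_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-SNP verdicts to genes by majority tumor direction;
    genes whose significant SNPs disagree are flagged ``mixed``."""
    rows = []
    for gene, sub in snp_table.groupby("gene_id"):
        sig = sub[sub["tumor_sig"]]
        if sig.empty:
            rows.append((gene, None, False, False, 0))
            continue
        n1 = (sig["tumor_biased_hap"] == HP1).sum()
        n2 = (sig["tumor_biased_hap"] == HP2).sum()
        mixed = n1 > 0 and n2 > 0
        hap = HP1 if n1 >= n2 else HP2
        rows.append((gene, hap, bool(sig["tumor_specific"].any()), mixed,
                     len(sig)))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "biased_hap", "tumor_specific", "mixed", "n_sig_snps"],
    )


def annotate_regulatory(
    variants: Sequence[SomaticVariant],
    gene_models: pd.DataFrame,
    enhancers: Sequence[tuple[str, int, int, str]] = (),
    promoter_half_width: int = PROMOTER_HALF_WIDTH,
) -> list[RegulatoryCandidate]:
    """Candidate regulatory mutations in promoters or enhancers.

    ``gene_models`` needs columns gene_id, chrom, tss (1-based).  Promoter =
    TSS +- ``promoter_half_width``; ``enhancers`` are (chrom, start, end,
    gene_id) intervals.  Variants annotated exonic/5'UTR/3'UTR are excluded.
    """
    if gene_models is None or not {"gene_id", "chrom", "tss"} <= set(
        gene_models.columns
    ):
        raise ValueError("gene model with gene_id, chrom, tss columns required")
    out: list[RegulatoryCandidate] = []
    for v in variants:
        if v.annotation in EXCLUDED_ANNOTATIONS:
            continue
        placed = False
        for g in gene_models.itertuples():
            if g.chrom == v.chrom and abs(v.pos - g.tss) <= promoter_half_width:
                out.append(RegulatoryCandidate(v, "promoter", g.gene_id, v.hap))
                placed = True
                break
        if placed:
            continue
        for chrom, start, end, gene_id in enhancers:
            if chrom == v.chrom and start <= v.pos <= end:
                out.append(RegulatoryCandidate(v, "enhancer", gene_id, v.hap))
                break
    return out


def link_bias_to_regulation(
    gene_verdicts: pd.DataFrame,
    candidates: Sequence[RegulatoryCandidate],
    dmr_blocks: Sequence[DMRBiasBlock] = (),
    gene_blocks: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Join haplotype-biased genes to regulatory mutations and DMR bias.

    A row is concordant when the regulatory variant lies on the biased
    (over-expressed) haplotype; DMR concordance means the biased haplotype
    is the hypomethylated direction of a DMR-bias block containing the gene
    (``gene_blocks``: gene_id -> block_id).
    """
    cand_by_gene: dict[str, list[RegulatoryCandidate]] = {}
    for c in candidates:
        cand_by_gene.setdefault(c.gene_id, []).append(c)
    dmr_by_block = {b.block_id: b for b in dmr_blocks}
    rows = []
    for g in gene_verdicts.itertuples():
        if g.biased_hap is None:
            continue
        cands = cand_by_gene.get(g.gene_id, [])
        reg_hap = cands[0].hap if cands else None
        reg_element = cands[0].element if cands else None
        dmr_dir = None
        if gene_blocks is not None:
            blk = dmr_by_block.get(gene_blocks.get(g.gene_id))
            if blk is not None:
                dmr_dir = blk.major_direction
        dmr_hypo_hap = None
        if dmr_dir is not None:
            dmr_hypo_hap = HP1 if dmr_dir == HP1_HYPO else HP2
        rows.append(
            {
                "gene_id": g.gene_id,
                "biased_hap": g.biased_hap,
                "tumor_specific": g.tumor_specific,
                "regulatory_element": reg_element,
                "regulatory_hap": reg_hap,
                "regulatory_concordant": (
                    None if reg_hap is None else reg_hap == g.biased_hap
                ),
                "dmr_direction": dmr_dir,
                "dmr_concordant": (
                    None if dmr_hypo_hap is None
                    else dmr_hypo_hap == g.biased_hap
                ),
            }
        )
    return pd.DataFrame(rows)


def rna_editing_overlap(
    snps: Iterable,
    catalog: set[tuple[str, int]],
) -> float:
    """Fraction of A/G heterozygous phasing SNPs coinciding with known A-to-I
    RNA-editing sites (an upper bound on haplotype misassignment from
    editing).  Empty catalog or no A/G SNPs give 0.0 with a warning."""
    import warnings

    ag = [s for s in snps if {s.ref, s.alt} in ({"A", "G"}, {"T", "C"})]
    if not catalog or not ag:
        warnings.warn("empty RNA-editing catalog or no A/G SNPs; overlap 0")
        return 0.0
    hit = sum(1 for s in ag if (s.chrom, s.pos) in catalog)
    return hit / len(ag)
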