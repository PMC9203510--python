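"""Readers and writers for the interchange formats of the pipeline.

Internal coordinates are 1-based inclusive (VCF convention); BED emission is
0-based half-open.  Reads travel as a TSV with one row per read
(observations serialized as ``pos:allele`` pairs) so downstream stages can
be exercised without an aligner; a minimal SAM emission with HP/PS tags is
provided for interoperability.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .phasing import PhasedBlock, PhasedSNP
from .signatures import CATEGORIES, CNSegment, MutationSpectrum
from .simulate import Genome, SimulatedRead
from .somatic import SomaticVariant, StructuralVariant

_VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">
##INFO=<ID=HAP,Number=1,Type=String,Description="Assigned haplotype">
##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">
"""


def write_fasta(genome: Genome | Mapping[str, str], path: str,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        seqs = genome.as_dict() if isinstance(genome, Genome) else genome
        for chrom, seq in seqs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    from pyfaidx import Fasta

    with Fasta(path) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_phased_vcf(snps: Sequence[PhasedSNP], path: str,
                     contigs: Mapping[str, int] | None = None,
                     sample: str = "SAMPLE") -> None:
    """Phased germline het SNPs as VCF 4.2 with GT|PS (0|1 = ref on HP1)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom, size in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={size}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        for s in sorted(snps, key=lambda s: (s.chrom, s.pos)):
            gt = "1|0" if s.alt_on_hp1 else "0|1"
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\t"
                f"GT:PS\t{gt}:{s.block_id}\n"
            )


def write_somatic_vcf(variants: Sequence[SomaticVariant], path: str,
                      contigs: Mapping[str, int] | None = None) -> None:
    """Somatic variants with HAP/VAF INFO annotations."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom, size in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={size}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            info = f"HAP={v.hap}"
            if v.vaf is not None:
                info += f";VAF={v.vaf:.4f}"
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                     f"{info}\n")


def read_somatic_vcf(path: str) -> list[SomaticVariant]:
    import pysam

    out = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            kind = "SNV" if len(rec.ref) == 1 and len(rec.alts[0]) == 1 else "indel"
            vaf = rec.info.get("VAF")
            out.append(
                SomaticVariant(rec.chrom, rec.pos, rec.ref, rec.alts[0],
                               kind=kind,
                               vaf=float(vaf) if vaf is not None else None,
                               hap=rec.info.get("HAP", "unknown"))
            )
    return out


def _obs_to_str(obs: Iterable[tuple[int, str]]) -> str:
    return ";".join(f"{p}:{a}" for p, a in obs)


def _obs_from_str(s: str) -> list[tuple[int, str]]:
    if not s or pd.isna(s):
        return []
    out = []
    for item in str(s).split(";"):
        p, a = item.split(":")
        out.append((int(p), a))
    return out


def write_reads_tsv(reads: Sequence[SimulatedRead], path: str) -> None:
    rows = [
        (r.read_id, r.chrom, r.start, r.end, r.hap_truth,
         _obs_to_str(r.observations), _obs_to_str(r.somatic_observations))
        for r in reads
    ]
    pd.DataFrame(
        rows,
        columns=["read_id", "chrom", "start", "end", "hap_truth",
                 "observations", "somatic_observations"],
    ).to_csv(path, sep="\t", index=False)


def read_reads_tsv(path: str) -> list[SimulatedRead]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        SimulatedRead(
            str(r.read_id), str(r.chrom), int(r.start), int(r.end),
            int(r.hap_truth), _obs_from_str(r.observations),
            _obs_from_str(r.somatic_observations),
        )
        for r in df.itertuples()
    ]


def write_sam(reads: Sequence[SimulatedRead], genome: Genome, path: str,
              tags: Mapping[str, tuple[str, int]] | None = None) -> None:
    """Minimal unaligned-sequence SAM with HP/PS tags for tagged reads.

    ``tags`` maps read_id -> (label, block_id); the SEQ field is '*' because
    only SNP observations, not base-level sequences, are simulated.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom in genome.sequences:
            fh.write(f"@SQ\tSN:{chrom}\tLN:{genome.size(chrom)}\n")
        for r in sorted(reads, key=lambda r: (r.chrom, r.start)):
            cigar = f"{r.end - r.start + 1}M"
            fields = [r.read_id, "0", r.chrom, str(r.start), "60", cigar,
                      "*", "0", "0", "*", "*"]
            if tags and r.read_id in tags:
                label, ps = tags[r.read_id]
                hp = 1 if label == "HP1" else 2
                fields.append(f"HP:i:{hp}")
                fields.append(f"PS:i:{ps}")
            fh.write("\t".join(fields) + "\n")


def write_sv_tsv(svs: Sequence[StructuralVariant], path: str) -> None:
    """Nanomonsv-like SV table with supporting-read ids and haplotype."""
    rows = [
        (s.sv_id, s.chrom1, s.pos1, s.strand1, s.chrom2, s.pos2, s.strand2,
         s.sv_type, ";".join(s.supporting_read_ids), s.hap,
         ";".join(str(b) for b in s.block_ids))
        for s in svs
    ]
    pd.DataFrame(
        rows,
        columns=["sv_id", "chrom1", "pos1", "dir1", "chrom2", "pos2", "dir2",
                 "type", "read_ids", "hap", "block_ids"],
    ).to_csv(path, sep="\t", index=False)


def read_sv_tsv(path: str) -> list[StructuralVariant]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for r in df.itertuples():
        out.append(
            StructuralVariant(
                str(r.sv_id), str(r.type), str(r.chrom1), int(r.pos1),
                str(r.dir1), str(r.chrom2), int(r.pos2), str(r.dir2),
                supporting_read_ids=[x for x in str(r.read_ids).split(";") if x],
                hap=str(r.hap) if r.hap else "unknown",
                block_ids=[int(b) for b in str(r.block_ids).split(";") if b],
            )
        )
    return out


def write_cn_tsv(segments: Sequence[CNSegment], path: str) -> None:
    pd.DataFrame(
        [(s.chrom, s.start, s.end, s.cn_state) for s in segments],
        columns=["chrom", "start", "end", "cn"],
    ).to_csv(path, sep="\t", index=False)


def read_cn_tsv(path: str) -> list[CNSegment]:
    df = pd.read_csv(path, sep="\t")
    return [CNSegment(str(r.chrom), int(r.start), int(r.end), int(r.cn))
            for r in df.itertuples()]


def write_blocks_bed(blocks: Sequence[PhasedBlock], path: str) -> None:
    """Block extents as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for b in sorted(blocks, key=lambda b: (b.chrom, b.start)):
            fh.write(f"{b.chrom}\t{b.start - 1}\t{b.end}\tblock_{b.block_id}\n")


def write_spectrum_tsv(spectrum: MutationSpectrum, path: str) -> None:
    pd.DataFrame(
        {"category": CATEGORIES, "count": spectrum.counts.astype(int)}
    ).to_csv(path, sep="\t", index=False)


def read_metilene_dmrs(path: str):
    """Ingest a metilene-format DMR table (chr, start, stop, q-value,
    mean difference hp1-hp2, #CpGs, ...) as the fidelity path replacing the
    internal caller."""
    from .methylation import DMR, HP1_HYPO, HP2_HYPO

    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "q", "mean_diff",
                            "n_cpgs"],
                     usecols=range(6))
    out = []
    for r in df.itertuples():
        diff = float(r.mean_diff)
        f1, f2 = (0.5 + diff / 2, 0.5 - diff / 2)
        out.append(
            DMR(str(r.chrom), int(r.start), int(r.end), f1, f2,
                HP1_HYPO if diff < 0 else HP2_HYPO, int(r.n_cpgs),
                float(r.q))
        )
    return out
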