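"""Chromothripsis-like SV clusters and trinucleotide mutational signatures.

Chromothripsis — a single catastrophic shattering of one chromosome —
leaves two hallmarks: a cluster of mutually interleaved SVs (breakpoint
intervals intersecting one another in a chained fashion) and copy-number
states oscillating between a small number of levels across the cluster.
Clusters are built as connected components of the interval-intersection
graph of intrachromosomal SV spans, and a cluster is called chromothripsis
when all four of these hold:

  (i)   >= 10 SVs in the cluster;
  (ii)  >= 4 CN segments oscillating between two states, or >= 6 among
        three states;
  (iii) >= 0.2 SVs per Mb of cluster span;
  (iv)  >= 0.2 CN state changes per Mb of cluster span.

Local hypermutation (kataegis) is scored by the 96-category trinucleotide
substitution spectrum of mutation-enriched windows against an APOBEC-class
signature using cosine similarity (candidate when cosine > 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .phasing import HP1, HP2
from .somatic import SomaticVariant, StructuralVariant

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
CATEGORIES: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)
_CATEGORY_INDEX = {c: i for i, c in enumerate(CATEGORIES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

CHROMOTHRIPSIS_MIN_SVS = 10
CHROMOTHRIPSIS_MIN_OSC2 = 4
CHROMOTHRIPSIS_MIN_OSC3 = 6
CHROMOTHRIPSIS_MIN_SVS_PER_MB = 0.2
CHROMOTHRIPSIS_MIN_CN_STATES_PER_MB = 0.2
KATAEGIS_COSINE_THRESHOLD = 0.7


@dataclass
class CNSegment:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    cn_state: int


@dataclass
class SVCluster:
    chrom: str
    start: int
    end: int
    sv_ids: list[str]
    haplotypes: list[str] = field(default_factory=list)

    @property
    def n_svs(self) -> int:
        return len(self.sv_ids)

    @property
    def span_mb(self) -> float:
        return (self.end - self.start) / 1e6

    @property
    def svs_per_mb(self) -> float:
        return self.n_svs / self.span_mb if self.span_mb > 0 else float("inf")

    @property
    def major_haplotype(self) -> str | None:
        n1 = self.haplotypes.count(HP1)
        n2 = self.haplotypes.count(HP2)
        if n1 == n2 == 0 or n1 == n2:
            return None
        return HP1 if n1 > n2 else HP2


@dataclass
class ChromothripsisCall:
    cluster: SVCluster
    n_oscillations_2state: int       # oscillating segments (longest 2-state run)
    n_oscillations_3state: int       # oscillating segments (longest <=3-state run)
    n_transitions_2state: int
    n_transitions_3state: int
    cn_states_per_mb: float
    criteria: dict[str, bool] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.criteria.values())


@dataclass
class MutationSpectrum:
    counts: np.ndarray
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have 96 categories")
        if np.any(self.counts < 0):
            raise ValueError("spectrum counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_dict(self) -> dict[str, int]:
        return {c: int(n) for c, n in zip(CATEGORIES, self.counts)}


def cluster_interleaved_svs(
    svs: Sequence[StructuralVariant],
    max_gap: int = 0,
) -> list[SVCluster]:
    """Connected components of the SV interval-intersection graph.

    Intrachromosomal SVs span [min(bp1,bp2), max(bp1,bp2)]; interchromosomal
    SVs attach to each chromosome as a point at the local breakpoint.  Two
    SVs are linked when their intervals come within ``max_gap`` bp of each
    other (0 = strict overlap); singleton components are discarded.
    """
    items: dict[str, list[tuple[int, int, str, str]]] = {}
    for sv in svs:
        if sv.is_intrachromosomal:
            chrom, lo, hi = sv.interval()
            items.setdefault(chrom, []).append((lo, hi, sv.sv_id, sv.hap))
        else:
            items.setdefault(sv.chrom1, []).append(
                (sv.pos1, sv.pos1, sv.sv_id, sv.hap))
            items.setdefault(sv.chrom2, []).append(
                (sv.pos2, sv.pos2, sv.sv_id, sv.hap))
    clusters: list[SVCluster] = []
    for chrom, ivals in sorted(items.items()):
        ivals.sort()
        cur: list[tuple[int, int, str, str]] = []
        cur_end = -1
        for iv in ivals + [(int(2**62), int(2**62), "", "")]:
            if cur and iv[0] > cur_end + max_gap:
                if len(cur) >= 2:
                    clusters.append(
                        SVCluster(chrom, min(x[0] for x in cur),
                                  max(x[1] for x in cur),
                                  [x[2] for x in cur], [x[3] for x in cur])
                    )
                cur, cur_end = [], -1
            if iv[2] == "" and not cur:
                break
            cur.append(iv)
            cur_end = max(cur_end, iv[1])
    return clusters


def _longest_alternating_run(states: Sequence[int], max_states: int) -> int:
    """Length (in segments) of the longest run of consecutive segments where
    adjacent states differ and at most ``max_states`` distinct values recur."""
    best = 0
    n = len(states)
    for i in range(n):
        seen = {states[i]}
        j = i
        while j + 1 < n and states[j + 1] != states[j]:
            seen = seen | {states[j + 1]}
            if len(seen) > max_states:
                break
            j += 1
        best = max(best, j - i + 1)
    return best if best >= 2 else 0


def count_cn_oscillations(
    segments: Sequence[CNSegment],
    span: tuple[str, int, int] | None = None,
) -> tuple[int, int, float]:
    """Oscillating-CN statistics of the segments within a cluster span.

    Returns (n_2state, n_3state, cn_states_per_mb): the number of CN
    segments in the longest run alternating between exactly two (resp. at
    most three) recurring states, and the number of CN state changes per Mb
    of span.  Fewer than two segments give zeros.
    """
    segs = list(segments)
    if span is not None:
        chrom, lo, hi = span
        segs = [s for s in segs if s.chrom == chrom and s.end >= lo and s.start <= hi]
    segs.sort(key=lambda s: (s.chrom, s.start))
    states = [s.cn_state for s in segs]
    if len(states) < 2:
        return 0, 0, 0.0
    n2 = _longest_alternating_run(states, 2)
    n3 = _longest_alternating_run(states, 3)
    transitions = sum(1 for a, b in zip(states, states[1:]) if a != b)
    if span is not None:
        span_mb = (span[2] - span[1]) / 1e6
    else:
        span_mb = (segs[-1].end - segs[0].start) / 1e6
    per_mb = transitions / span_mb if span_mb > 0 else 0.0
    return n2, n3, per_mb


def call_chromothripsis(
    cluster: SVCluster,
    segments: Sequence[CNSegment],
    min_svs: int = CHROMOTHRIPSIS_MIN_SVS,
    min_osc2: int = CHROMOTHRIPSIS_MIN_OSC2,
    min_osc3: int = CHROMOTHRIPSIS_MIN_OSC3,
    min_svs_per_mb: float = CHROMOTHRIPSIS_MIN_SVS_PER_MB,
    min_cn_states_per_mb: float = CHROMOTHRIPSIS_MIN_CN_STATES_PER_MB,
    oscillation_measure: str = "segments",
) -> ChromothripsisCall:
    """Apply the four chromothripsis criteria to one SV cluster.

    ``oscillation_measure`` selects whether criterion (ii) counts oscillating
    CN *segments* (default) or state *transitions* within the longest
    alternating run.
    """
    span = (cluster.chrom, cluster.start, cluster.end)
    n2_seg, n3_seg, per_mb = count_cn_oscillations(segments, span)
    n2_tr = max(n2_seg - 1, 0)
    n3_tr = max(n3_seg - 1, 0)
    if oscillation_measure == "segments":
        o2, o3 = n2_seg, n3_seg
    elif oscillation_measure == "transitions":
        o2, o3 = n2_tr, n3_tr
    else:
        raise ValueError(f"unknown oscillation_measure {oscillation_measure!r}")
    criteria = {
        "i_n_svs": cluster.n_svs >= min_svs,
        "ii_cn_oscillation": o2 >= min_osc2 or o3 >= min_osc3,
        "iii_svs_per_mb": cluster.svs_per_mb >= min_svs_per_mb,
        "iv_cn_states_per_mb": per_mb >= min_cn_states_per_mb,
    }
    return ChromothripsisCall(cluster, n2_seg, n3_seg, n2_tr, n3_tr,
                              per_mb, criteria)


def classify_snv(chrom_seq: str, pos: int, ref: str, alt: str) -> str | None:
    """96-category label of one SNV given its chromosome sequence (1-based
    position); purine references are reverse-complemented to the
    pyrimidine-centric convention.  Returns None when no valid +-1 context
    exists."""
    if pos < 2 or pos > len(chrom_seq) - 1:
        return None
    tri = chrom_seq[pos - 2 : pos + 1].upper()
    if len(tri) != 3 or any(b not in _BASES for b in tri) or alt not in _BASES:
        return None
    if tri[1] != ref.upper():
        return None
    if ref in "GA":
        tri = tri.translate(_COMPLEMENT)[::-1]
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    cat = f"{tri[0]}[{ref}>{alt}]{tri[2]}"
    return cat if cat in _CATEGORY_INDEX else None


def trinucleotide_spectrum(
    snvs: Iterable[SomaticVariant],
    reference: Mapping[str, str],
) -> MutationSpectrum:
    """96-category substitution spectrum of a set of SNVs.

    SNVs without a valid trinucleotide context (contig edge, non-ACGT base,
    reference mismatch, non-SNV) are skipped and counted in ``n_skipped``.
    """
    counts = np.zeros(96)
    skipped = 0
    for v in snvs:
        seq = reference.get(v.chrom)
        cat = None
        if seq is not None and len(v.ref) == 1 and len(v.alt) == 1:
            cat = classify_snv(seq, v.pos, v.ref, v.alt)
        if cat is None:
            skipped += 1
        else:
            counts[_CATEGORY_INDEX[cat]] += 1
    return MutationSpectrum(counts, skipped)


def cosine_similarity(a: np.ndarray | MutationSpectrum,
                      b: np.ndarray | MutationSpectrum) -> float:
    """Cosine of two 96-dimensional non-negative vectors (counts or
    probabilities); scale-invariant, in [0, 1].  Zero vectors are undefined."""
    va = a.counts if isinstance(a, MutationSpectrum) else np.asarray(a, float)
    vb = b.counts if isinstance(b, MutationSpectrum) else np.asarray(b, float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(np.dot(va, vb) / (na * nb), 0.0, 1.0))


def best_matches(
    spectrum: MutationSpectrum,
    catalog: Mapping[str, np.ndarray],
    threshold: float = KATAEGIS_COSINE_THRESHOLD,
) -> list[tuple[str, float]]:
    """Catalog signatures with cosine > ``threshold``, best first."""
    scored = [(name, cosine_similarity(spectrum, sig))
              for name, sig in catalog.items()]
    return sorted([s for s in scored if s[1] > threshold],
                  key=lambda x: -x[1])


def builtin_signatures() -> dict[str, np.ndarray]:
    """Small synthetic signature pair for tests and the bundled pipeline.

    ``apobec_like_synthetic`` concentrates mass on C>T and C>G in the TpC
    context (the hallmark of APOBEC cytidine deaminase activity);
    ``flat_synthetic`` is uniform.  These are synthetic stand-ins, not COSMIC
    profiles; a COSMIC-format catalog can be supplied instead.
    """
    apobec = np.zeros(96)
    weights = {
        "T[C>T]A": 0.21, "T[C>T]G": 0.20, "T[C>T]T": 0.19,
        "T[C>G]A": 0.14, "T[C>G]G": 0.13, "T[C>G]T": 0.13,
    }
    for cat, w in weights.items():
        apobec[_CATEGORY_INDEX[cat]] = w
    apobec /= apobec.sum()
    flat = np.full(96, 1.0 / 96)
    return {"apobec_like_synthetic": apobec, "flat_synthetic": flat}


def read_signature_catalog(path: str) -> dict[str, np.ndarray]:
    """Read a COSMIC-format signature TSV (first column = 96 category labels
    like 'A[C>A]A', remaining columns = signatures)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    missing = set(CATEGORIES) - set(df.index)
    if missing:
        raise ValueError(f"catalog missing {len(missing)} categories")
    df = df.loc[list(CATEGORIES)]
    return {col: df[col].to_numpy(dtype=float) for col in df.columns}


@dataclass
class KataegisCandidate:
    chrom: str
    start: int
    end: int
    n_snvs: int
    cosine: float
    n_hp1: int
    n_hp2: int

    @property
    def dominant_hap(self) -> str | None:
        if self.n_hp1 == self.n_hp2:
            return None
        return HP1 if self.n_hp1 > self.n_hp2 else HP2


def kataegis_scan(
    snvs: Sequence[SomaticVariant],
    reference: Mapping[str, str],
    chrom_sizes: Mapping[str, int],
    window: int = 100_000,
    alpha: float = 0.05,
    signature: np.ndarray | None = None,
    cosine_threshold: float = KATAEGIS_COSINE_THRESHOLD,
    min_snvs: int = 5,
) -> list[KataegisCandidate]:
    """Mutation-enriched windows whose local spectrum is APOBEC-like.

    Reuses the window-enrichment test; an enriched (merged) region with at
    least ``min_snvs`` SNVs whose spectrum has cosine > ``cosine_threshold``
    to the APOBEC-class signature is flagged as a kataegis candidate,
    reporting its haplotype composition.
    """
    from .bias import find_enriched_windows, merge_adjacent_regions

    if signature is None:
        signature = builtin_signatures()["apobec_like_synthetic"]
    enriched, _ = find_enriched_windows(snvs, chrom_sizes, window, alpha)
    out = []
    for reg in merge_adjacent_regions(enriched):
        local = [v for v in snvs
                 if v.chrom == reg.chrom and reg.start <= v.pos <= reg.end]
        if len(local) < min_snvs:
            continue
        spec = trinucleotide_spectrum(local, reference)
        if spec.total == 0:
            continue
        cos = cosine_similarity(spec, signature)
        if cos > cosine_threshold:
            out.append(
                KataegisCandidate(
                    reg.chrom, reg.start, reg.end, len(local), cos,
                    sum(1 for v in local if v.hap == HP1),
                    sum(1 for v in local if v.hap == HP2),
                )
            )
    return out
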