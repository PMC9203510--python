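# Methods

## Scope and model

`hapcontext` analyses a diploid tumor genome whose germline heterozygous
SNPs have already been phased into blocks (a phased VCF with `GT|PS`); it
does not itself perform read-based phasing (WhatsHap-class MEC solving),
alignment, variant calling, CN segmentation or signal-level methylation
calling — those upstream outputs are consumed.  Within one phase block the
assignment of alleles to haplotype 1/2 is jointly determined; between
blocks the labelling is arbitrary, and every metric below is constructed to
respect that gauge freedom.

## Switch/flip discrepancy

Two phasings of the same sample are compared per chromosome on the SNPs
phased by both, within maximal runs of shared SNPs lying in a single block
of each input ("intersected block segments").  The disagreement vector is
reduced to its switch sequence `s[i] = d[i] XOR d[i+1]`, which is invariant
to each phasing's global orientation.  A *switch* (haplotype identity
inverts at a point) clears one `s`-position; a *flip* (one SNP on the wrong
haplotype) clears two adjacent `s`-positions.  Greedy left-to-right pairing
of adjacent `s`-ones is a maximum matching on a path graph, so the reported
counts are the minimal-cost explanation of the disagreement; among
minimal-cost explanations, isolated boundary disagreements are attributed
to switches rather than flips.  We use this orientation-free formulation
rather than "pick the orientation with fewest disagreements, then decompose
runs" because the latter is not always minimal (e.g. the pattern
`11011000`, where the best-disagreement orientation yields 3 switches but
the minimum is one flip plus one switch).  The discrepancy rate is reported
with two denominators — compared SNPs and compared consecutive pairs —
because published rates rarely state which is meant.

## Panel concordance

An external panel (e.g. a statistically phased cohort) provides one
chromosome-length haplotype pair, so only relative phase is comparable:
for every two *consecutive* phased het SNPs inside one query block and
present in the panel, the cis/trans relation of the alternate alleles is
compared.  Cross-block pairs are never compared.

## Read, SNV and SV haplotype assignment

A read is a "phased read" when it carries ≥2 informative SNP observations
within one block and the majority haplotype holds ≥70% of them; both
thresholds are boundary-inclusive (7:3 tags, 2:1 does not), and ratio
comparisons are done with an epsilon guard so the 0.7 boundary is exact.
Alleles matching neither haplotype (sequencing error, somatic alleles) are
non-informative.  A somatic SNV is assigned to the haplotype with ≥3
mutant reads when the other carries ≤1; an SV needs ≥3 tagged supporting
reads with the ≥0.7 majority, counts each distinct read once (primary and
supplementary observations assumed pooled), and is restricted to
autosomes.  An optional VAF floor (0.2) restricts assignment to
well-covered mutations.  Mutation pairs co-spanned by reads are ordered
"A before B" when both-mutant and A-only molecules each have ≥2 supporting
reads and no B-only molecule exists; A-only and B-only both supported is
reported as conflicting (parallel clones), and {neither, both} alone as
co-occurring.  Relationships beyond the read length are not inferred.

## Haplotype-biased regions

The genome is tiled with fixed 100-kb windows; each window's somatic count
is tested against λ = total·window/callable with a one-sided Poisson upper
tail (a binomial alternative is provided) and BH adjustment across all
windows.  The callable length defaults to the genome size; a phased-block
span can be passed instead when mutations are only sought inside blocks.
Adjacent significant windows are merged before bias calling.  A merged
region is *haplotype biased* when it holds ≥5 haplotype-resolved mutations
and strictly more than 80% lie on one haplotype; unknown-haplotype
mutations are excluded from the denominator (they carry no phase
information), and an exact two-sided binomial p against 0.5 is reported
alongside.  The `min_phased=5` guard exists because a one-mutation region
is trivially "100% biased".

## Chromothripsis and signatures

Interleaved-SV clusters are connected components of the
interval-intersection graph of intrachromosomal SV spans
(`[min(bp1,bp2), max(bp1,bp2)]`; interchromosomal SVs attach as points at
their local breakpoints).  The linking distance `max_gap` defaults to 0
(strict overlap) and is configurable; singleton components are discarded.
Copy-number oscillation is measured as the longest run of consecutive
segments whose adjacent states differ while recurring among ≤2 (resp. ≤3)
values; both the segment count of that run and its transition count are
reported, and the criteria are applied to the *segment* count (the
transition alternative is exposed as an option).  Criterion (iv), CN
states per Mb, counts state *changes* across the cluster span per Mb —
the wording is ambiguous between distinct states and changed segments, and
the change count is the scale-free choice.  A cluster is chromothripsis
when all four hold: ≥10 SVs; ≥4 two-state or ≥6 three-state oscillating
segments; ≥0.2 SVs/Mb; ≥0.2 CN state changes/Mb.

Trinucleotide spectra use the standard pyrimidine-centric 96-category
layout (6 substitutions × 16 contexts, COSMIC ordering); purine references
are reverse-complemented.  Signature similarity is the cosine of the count
vector with a signature profile (scale-invariant, in [0,1]).  The bundled
`apobec_like_synthetic` profile concentrates mass on C>T/C>G in TpC
contexts and is a clearly labelled synthetic stand-in, not a COSMIC
profile; COSMIC-format catalogs are read with `read_signature_catalog`.
Kataegis candidates are mutation-enriched regions (reusing the window
test) of ≥5 SNVs whose local spectrum has cosine >0.7 to the APOBEC-class
profile, reported with their haplotype composition.

## Methylation and DMR bias

Per-read CpG calls on haplotagged reads give per-site per-haplotype
frequencies; a site needs ≥3 tagged reads of a haplotype to report one.
The internal DMR caller takes maximal runs of ≥5 consecutive usable sites
(consecutive rows of the frequency table, not genomic adjacency) with
per-site |Δfreq| ≥ 0.3 of consistent sign, tests each run with a
two-sided Mann-Whitney U on the per-site frequencies and keeps BH-adjusted
q < 0.05.  These thresholds are pragmatic defaults; ingesting an external
metilene-format DMR table is the fidelity path.  Tumor DMRs overlapped
>20% of *their own* length by matched-normal DMRs are removed as
constitutive allele-specific methylation (the published rule does not name
which region's length; the tumor DMR is the conservative referent).  A
phase block has *DMR bias* when the major hypomethylation direction holds
≥3 DMRs, ≥70% of the block's DMRs, and ≥3 per Mb of block span
(end−start).  "Same direction" means hypomethylation of the same
haplotype.

## Allele-specific expression

Transcript reads are tagged with the same ≥2-SNP/≥0.7 rule.  Each
(SNP, tissue) with ≥10 tagged reads gets an exact two-sided binomial test
of the HP1 count against 0.5, BH-adjusted across SNPs within the tissue;
per-tissue testing (rather than a tumor-vs-normal contingency) matches how
per-tissue haplotype ratios are interpreted, and a Fisher tumor-vs-normal
option is provided.  A SNP is *tumor-specific* biased when significant in
tumor and not significant in the same direction in normal.  Genes
aggregate their significant SNPs by majority direction; disagreeing SNPs
flag the gene `mixed`.  Candidate regulatory mutations are non-exonic,
non-UTR somatic variants within ±1.5 kb of a TSS (promoter) or inside
supplied enhancer intervals; linkage joins biased genes to candidates on
gene and haplotype and to DMR-bias blocks on phase block, flagging
concordance (expression bias, regulatory mutation and hypomethylation on
the same haplotype).  Haplotype-specific CN is an annotation concern, not
a correction, and cohort-level differential expression is out of scope.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, with
one integer seed and stable per-stage child streams (CRC-keyed
`SeedSequence` spawns), so identical configurations are byte-identical:

* **Genome/SNPs** — i.i.d. uniform reference bases; het SNPs as a
  Bernoulli process at 1/1500 per bp (the ~1 per 1.5 kb density of human
  genomes), alternate allele on HP1 or HP2 with equal probability.
* **Reads** — log-normal lengths; because the length-biased version of a
  log-normal(μ, σ) has median `exp(μ+σ²)`, μ is set to `ln(N50) − σ²` so
  the realized N50 matches the target (default 16 kb, σ = 1.0, giving a
  mean of ~0.61·N50 as is typical for nanopore runs).  Read count is
  depth·genome/mean-length; each read draws a haplotype uniformly and
  reports every covered SNP's true allele, flipped to the other allele
  with the per-base error probability (default 10%, single-pass long-read
  scale).  Only SNP-site errors are modelled — no base-level sequence,
  indel profiles or squiggle simulation.
* **Somatic events** — background SNVs Poisson at a configurable rate
  (default 10/Mb, a typical lung-cancer burden; the per-case distribution
  is an order-of-magnitude choice exposed in config, not a claim); bias
  regions place a chosen number of SNVs on the designated haplotype with
  probability `fraction_on_hap`, drawing trinucleotide contexts from a
  named signature by rewriting the reference ±1 bp around the site
  (collisions padded so contexts never overlap, making the emitted
  spectrum match the drawn categories exactly); SV clusters sample 2n
  sorted breakpoints paired as (bᵢ, bᵢ₊ₙ), a staircase in which every two
  member intervals mutually interleave; CN segments across the cluster
  span alternate between two (configurable three) states with the
  requested number of transitions, flat CN 2 elsewhere.  Supporting reads
  for each SV are drawn from the SV's haplotype around its first
  breakpoint.
* **Methylation/RNA** — per-read binary CpG calls at the reference's CG
  positions inside configured regions with per-haplotype probabilities
  (the matched normal uses the mean of the two, i.e. no allele-specific
  methylation); transcript reads per gene/haplotype are Poisson at
  configured rates and observe consecutive runs of 2-5 gene SNPs.

What passing recovery tests does and does not show: the generator draws
reads uniformly with independent SNP-site errors and simulates clean CN
truth, so recovery results demonstrate the correctness of the decision
rules and statistics, not robustness to alignment artifacts, mappability
gaps, segmentation error, tumor impurity or subclonal structure, which
real data add.

Phase blocks for synthetic studies are built from *read connectivity*
(consecutive SNPs co-observed by at least one read), which models what is
phasable at a given depth without re-implementing an MEC solver; block
statistics under read subsampling therefore reflect connectivity, and
phasing errors for benchmarking the discrepancy metrics are injected
explicitly (`perturb_phasing`).

## Problem sizes and numerical choices

Tests and the acceptance script use 0.3-50 Mb single-chromosome genomes,
5-30× depth and 20-seed batches — sizes chosen so every stochastic check
has clear Monte-Carlo resolution while the whole suite runs in minutes.
Ratio thresholds are compared with a 1e-9 epsilon so the published 0.7
boundary is inclusive under floating point; "more than 80%" is strict;
BH adjustment is the standard step-up procedure; Mann-Whitney candidates
with identical constant frequencies short-circuit to p = 1; zero-vector
cosines raise rather than return a value; empty inputs return empty
results (or zero statistics) with warnings rather than errors wherever the
empty case is scientifically meaningful.

## Known limitations

Indels are matched by exact ref/alt at their position — ambiguously
aligned indels must be normalized (left-aligned) upstream — and MNVs are
treated as opaque; reads spanning a deletion on the deleted haplotype are
not given special missing-data handling; the internal DMR caller is
deliberately minimal; clonal inference, telomere length, single-cell
validation and plotting of published figure styles are out of scope.
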