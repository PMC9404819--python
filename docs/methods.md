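# Methods

This note records the models, conventions and numerical choices behind
locuskit, and what the synthetic test-bed does and does not establish.

## Coordinates, strand and the gene model

All user-facing coordinates are 1-based inclusive positions on the forward
assembly strand, the convention of VCF and genome browsers. A locus window
is the primary-transcript span (max exon end − min exon start + 1, introns
included) plus symmetric flanks (default 5,000 bp per side). Because the
reference use-case is a minus-strand gene whose published positions are
forward-strand, the window also carries a *gene-sense* view — the reverse
complement for minus-strand genes — and an exact bijection between forward
positions and 0-based gene-sense offsets. All motif scanning, codon
reconstruction and transcript assembly happen on the gene-sense sequence;
strand conversion lives exclusively in `locus_model`. Exons are numbered in
transcription order, so exon 1 of a minus-strand gene is the exon with the
greatest forward coordinates. Only single-transcript gene models are
supported; multi-isoform annotation is out of scope. Scan windows
containing N yield no score and are skipped (logged); a window that would
run past a chromosome end is an error, never a silent clip.

## Variant representation

Variants are reduced to biallelic records: multi-allelic VCF lines are
split per ALT (haplotypes carrying a different ALT become missing in the
split record) and alleles are trimmed to a minimal left-anchored
representation. Indels are localized by the first affected base after the
VCF anchor, so an insertion anchored on the last exonic base whose inserted
bases fall into the intron is intronic. Compartment classification
(upstream / 5′UTR / exon k / intron k / 3′UTR / downstream, with
upstream/downstream defined gene-sense) partitions the window: every
position maps to exactly one class. Missing genotypes are excluded from all
allele counts; no imputation. The cohort consensus allele is the
majority allele over called chromosomes, with ties resolved to the
reference allele (logged) — a convention required because intermediate
0.5 frequencies otherwise leave the choice undefined. SNP density is
reported as `floor(window length / SNP count)` with an explicit "no SNPs"
marker at zero.

## Coding effects and codon usage

The codon containing an exonic SNP is rebuilt from the spliced gene-sense
CDS; for minus-strand genes the VCF alleles are complemented before
substitution. Effects use translation table 1 (standard nuclear code):
silent iff the amino acid is unchanged, nonsense iff the alternate codon is
a stop, start-loss for a damaged initiator ATG. Codon-usage optimality is a
strict-inequality threshold on a per-mille usage table; the default cut-off
of 10‰ is configurable because the external tool the convention derives
from does not publish one. The packaged usage table is a synthetic
stand-in: generic mammalian per-mille values with the attested dromedary
entries (CCG 8.1‰, GTA 5.5‰, CAT 6.4‰ rare; CCA/GTC/CAC common) so the
documented rarity transitions are exact. For real analyses, supply a
species table in the two-column Kazusa-style layout.

## Tajima's D

π is computed from allele counts with the per-site unbiased form
`2k(n−k)/(n(n−1))` summed over segregating sites; S counts sites
segregating among called chromosomes; the constants a₁…e₂ are evaluated
exactly from their closed forms. An explicit pairwise double-loop
implementation is retained in the test suite as an independent oracle and
agrees to 1e−9 relative tolerance on 200 seeded random windows. With
missing data each site contributes with its own called-chromosome count;
the variance constants use the window-level n (maximum called count unless
given). S = 0 or a non-positive variance yields an explicit "undefined"
call, never a NaN. Windows are non-overlapping 2,000-bp tiles anchored at
position 1 (step configurable); the ±2 thresholds are rule-of-thumb labels
with no attached p-values.

## Differential TFBS

PWMs are read from TRANSFAC-style flat files (via Bio.motifs), given a
pseudocount of 0.01 per base before normalization (avoids log 0 in the
information weights), and scored with the information-weighted similarity
`Σᵢ Iᵢ fᵢ(obs) / Σᵢ Iᵢ maxᵦ fᵢ(b)`, where `Iᵢ = Σᵦ fᵢ(b) log₄(4 fᵢ(b))`.
Both strands are scanned; the default report threshold is 0.85
(per-matrix thresholds configurable). For each promoter variant (gene-sense
2,000 bp upstream of the transcript start by default) the two allele
sequences are built by in silico mutagenesis — the REF allele is first
checked against the window sequence to guard against FASTA/VCF
incoherence — and hits are diffed on a ±(motif length − 1) neighborhood of
the variant. Restricting to the neighborhood is exact: every motif window
overlapping the changed bases lies inside it and unchanged windows cancel.
Hits are keyed by matrix, strand and variant-anchored offset (left edge for
hits starting at or before the variant, right edge otherwise) so indel
length changes do not shift the comparison. A packaged list of ten
muscle-development/metabolism TFs (COMP1, C/EBP, MYOG, COUP, MEF2, SRF,
DELTAEF1, PBX1, MYOD, E2F) flags hits of interest. The packaged TRANSFAC
file contains six small consensus-derived synthetic matrices for
demonstration and testing; absolute differential-site *counts* depend
entirely on the matrix library and threshold supplied, and are therefore
not comparable across packs.

## Splice signals and intron retention

Donor and acceptor motifs are scored on the classic consensus-value scale
`CV = 100 (Σ fᵢ(obs) − Σmin)/(Σmax − Σmin)`, which is invariant to uniform
rescaling of a matrix and hits 100/0 exactly at the per-position max/min
motifs. The packaged matrices follow the donor 9-mer spanning [−3,+6] (GT
invariant at motif positions 4–5) and the acceptor 14-mer spanning
[−12,+2] (AG at positions 11–12), assembled from the classic primate
splice-site frequency compilations; the branch-point 7-mer (branch A at
position 5) is a synthetic consensus-derived stand-in. Report thresholds
default to CV 65 for donors/acceptors and 67 for branch points. Because
the matrices are assembled rather than exported from any external tool,
published consensus values for specific motifs reproduce in rank order but
not to two decimals; the analytically exact fixture checks (Σmax→100,
Σmin→0, brute-force scan equivalence) are the binding correctness
criterion, and the per-motif comparison is emitted as a calibration report.
ESE/ESS elements are handled as swappable motif *sets* (packaged defaults
are small synthetic purine-rich-enhancer and silencer-like hexamer sets);
an element is created/disrupted when the occurrence set in the variant
neighborhood changes between alleles. Splice diffing is restricted to
genic/UTR variants, matching the analysis it implements.

Intron retention: an alternative donor inside intron k retains the intron
prefix from the canonical exon-k boundary up to (excluding) the new donor's
first intron base; an alternative acceptor retains the prefix through its
AG. Splicing then resumes at the canonical downstream exon. The transcript
is reassembled gene-sense (with the variant's alternate allele applied when
given), translated from the canonical start, and reported with a truncated
flag and `stop_offset_aa` — residues translated past the peptide encoded by
exons 1..k. Frame arithmetic is exact: extending the retained prefix by
three bases before the first stop moves the stop by exactly one residue.

## Cross-species comparison

Alignment is consumed, not computed: per-species position maps (TSV) give
the comparator base or a gap at each focal position. Loci missing from a
map become gaps with a warning. Sharing counts report matches to the focal
reference, matches to the cohort consensus, and pairwise comparator
agreement both excluding gap loci and counting a shared gap as a shared
state — published tallies are ambiguous on that point, so both are emitted.
Indel loci compare by exact allele-string equality at the mapped anchor.

## Synthetic scenarios: what they show and what they cannot

The generator reproduces the study *design*: a minus-strand three-exon gene
spanning 6,757 bp with ±5,000-bp flanks (16,757-bp window) and a
183-diploid cohort, with spikes covering every compartment and functional
category — six silent exonic SNPs at frequency 0.5, an all-heterozygous
7-carrier insertion and an all-heterozygous 78-carrier acceptor-creating
SNP in intron 1, donor creation/disruption, TFBS gain/loss and ESE/ESS
changes. Functional spikes embed exact motif contexts (e.g. a donor
context at CV ≈ 70 whose reference allele breaks the +1 G to CV ≈ 52) so
threshold crossings are guaranteed by construction; the generator re-scores
every spike with the production scanners and refuses scenarios that do not
behave as declared. Background sequence is i.i.d. uniform with configurable
GC; there is no linkage disequilibrium, demography, mapping error or
read-level noise. Passing the end-to-end tests therefore demonstrates that
the *machinery* recovers known truths exactly under clean conditions — not
that any particular biological count from real cohorts will reproduce,
since those depend on the caller, matrix library and assembly versions.
SFS tiles ("neutral" ∝ 1/k, "balanced" k = n/2, "skewed-rare" singletons)
provide the neutrality-statistic test-bed; balanced tiles give D > 0 and
singleton tiles D < 0 in ≥95% of seeded replicates.

## Problem sizes

The test suite and the acceptance script run on the full-size window
(16,757 bp, 183 samples), 200 oracle-checked neutrality windows (up to 28
chromosomes × 14 sites) and 100 SFS replicates per shape — sizes chosen so
the whole reproduction completes in seconds while still exercising each
stage at the study's own geometry.
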