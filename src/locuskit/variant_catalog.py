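"""VCF ingestion, window filtering, variant typing and genic localization.

Variants are reduced to biallelic records (multi-allelic sites are split),
trimmed to a minimal left-anchored representation, and named with the
``<chrom>var<pos>`` convention used throughout the reports, e.g.
``5var58464910``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import (
    MalformedInputError,
    NoGenotypesError,
    OutsideRegionError,
)
from .locus_model import GeneModel, LocusWindow

logger = logging.getLogger(__name__)

MISSING = -1  # per-haplotype missing-allele code


def _trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Minimal representation: strip shared suffix, then shared prefix."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass
class Variant:
    """One biallelic variant with per-sample diploid genotypes.

    ``genotypes`` holds one ``(a1, a2)`` pair per sample with alleles coded
    0 (ref), 1 (alt) or :data:`MISSING`.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: tuple[tuple[int, int], ...] = ()
    samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.pos, self.ref, self.alt = _trim_alleles(self.pos, self.ref, self.alt)

    @property
    def vid(self) -> str:
        return f"{self.chrom}var{self.pos}"

    @property
    def vclass(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNP"
        if len(self.alt) > len(self.ref):
            return "insertion"
        if len(self.alt) < len(self.ref):
            return "deletion"
        return "MNP"

    @property
    def is_indel(self) -> bool:
        return self.vclass in {"insertion", "deletion"}

    @property
    def anchor_shared(self) -> bool:
        """True for the usual VCF indel encoding with a shared leading base."""
        return self.is_indel and self.ref[0] == self.alt[0]

    @property
    def effective_pos(self) -> int:
        """First base actually affected: anchor + 1 for anchored indels."""
        return self.pos + 1 if self.anchor_shared else self.pos

    # ---- genotype summaries ----------------------------------------------

    def allele_counts(self) -> tuple[int, int]:
        """(ref_chromosomes, alt_chromosomes) over non-missing haplotypes."""
        nref = nalt = 0
        for a1, a2 in self.genotypes:
            for a in (a1, a2):
                if a == 0:
                    nref += 1
                elif a == 1:
                    nalt += 1
        return nref, nalt


@dataclass(frozen=True)
class LocalizationClass:
    """Genic compartment of a variant: e.g. ``exon(1)``, ``intron(2)``.

    ``kind`` is one of upstream_intergenic / utr5 / exon / intron / utr3 /
    downstream_intergenic; ``index`` is the 1-based gene-sense exon or
    intron number (None otherwise).
    """

    kind: str
    index: int | None = None

    def __str__(self) -> str:
        return f"{self.kind}_{self.index}" if self.index is not None else self.kind

    @property
    def is_genic(self) -> bool:
        return self.kind in {"utr5", "exon", "intron", "utr3"}

    @property
    def is_exonic(self) -> bool:
        return self.kind == "exon"


def read_variants(
    vcf_source: str | Path,
    region: LocusWindow,
) -> list[Variant]:
    """Read a VCF and return normalized biallelic variants inside *region*.

    Both window bounds are inclusive.  Multi-allelic records are split: for
    each ALT a biallelic variant is produced in which haplotypes carrying a
    *different* ALT are coded missing.  Records lacking GT or files without
    samples raise :class:`MalformedInputError` / :class:`NoGenotypesError`.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(vcf_source), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError on bad files
        raise MalformedInputError(f"cannot open VCF {vcf_source}: {exc}") from exc
    samples = tuple(vcf.samples)
    if not samples:
        raise NoGenotypesError(f"VCF {vcf_source} has no sample columns")

    out: list[Variant] = []
    for i, rec in enumerate(vcf, start=1):
        if rec.CHROM != region.chrom:
            continue
        if not (region.start <= rec.POS <= region.end):
            continue
        gts = rec.genotypes  # [a1, a2, phased] per sample
        if gts is None:
            raise MalformedInputError(f"record {i} at {rec.POS} lacks GT")
        for alt_idx, alt in enumerate(rec.ALT, start=1):
            genos = []
            for g in gts:
                pair = []
                for a in g[:2]:
                    if a is None or a < 0:
                        pair.append(MISSING)
                    elif a == 0:
                        pair.append(0)
                    elif a == alt_idx:
                        pair.append(1)
                    else:  # carries one of the other split alleles
                        pair.append(MISSING)
                genos.append(tuple(pair))
            out.append(
                Variant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    genotypes=tuple(genos),
                    samples=samples,
                )
            )
    out.sort(key=lambda v: (v.pos, v.ref, v.alt))
    return out


def classify_variant(
    v: Variant, gene: GeneModel, window: LocusWindow
) -> LocalizationClass:
    """Assign the single genic compartment of a variant.

    Indels are localized by the first affected base after the VCF anchor, so
    an insertion anchored on the last exonic base with inserted sequence
    falling into the intron is intronic.  Upstream/downstream are defined in
    gene-sense orientation (for a minus-strand gene, forward positions above
    the gene span are *upstream*).
    """
    pos = v.effective_pos
    if not window.contains(pos):
        raise OutsideRegionError(f"{v.vid}: position {pos} outside window")

    if pos < gene.span_start or pos > gene.span_end:
        before_span = pos < gene.span_start
        upstream = before_span if gene.strand == "+" else not before_span
        return LocalizationClass("upstream_intergenic" if upstream else "downstream_intergenic")

    k = gene.exon_number_at(pos)
    if k is not None:
        for s, e in gene.utr5:
            if s <= pos <= e:
                return LocalizationClass("utr5")
        for s, e in gene.utr3:
            if s <= pos <= e:
                return LocalizationClass("utr3")
        return LocalizationClass("exon", k)
    k = gene.intron_number_at(pos)
    if k is None:  # cannot happen: span is exon ∪ intron
        raise OutsideRegionError(f"{v.vid}: position {pos} unclassifiable")
    return LocalizationClass("intron", k)


def snp_density(window_length: int, snp_count: int) -> int | None:
    """Average bases per SNP, floored; None when there are no SNPs."""
    if snp_count < 0:
        raise ValueError("snp_count must be >= 0")
    if snp_count == 0:
        logger.info("no SNPs: density undefined")
        return None
    return window_length // snp_count


def consensus_allele(v: Variant) -> str:
    """The most frequent allele in the cohort; ties resolve to REF (logged)."""
    nref, nalt = v.allele_counts()
    if nref + nalt == 0:
        raise NoGenotypesError(f"{v.vid}: all genotypes missing")
    if nalt > nref:
        return v.alt
    if nalt == nref:
        logger.info("%s: allele frequency tie (%d/%d); consensus set to REF",
                    v.vid, nalt, nref + nalt)
    return v.ref


@dataclass
class CatalogSummary:
    """Counts by variant class and compartment, plus the SNP density."""

    total: int
    by_vclass: dict[str, int]
    by_localization: dict[str, int]
    snp_density_denominator: int | None
    consensus: dict[str, str] = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return self.by_vclass.get("SNP", 0)

    @property
    def n_indels(self) -> int:
        return (self.by_vclass.get("insertion", 0)
                + self.by_vclass.get("deletion", 0))


def summarize_catalog(
    variants: Sequence[Variant], gene: GeneModel, window: LocusWindow
) -> CatalogSummary:
    by_class: Counter[str] = Counter()
    by_loc: Counter[str] = Counter()
    consensus: dict[str, str] = {}
    for v in variants:
        by_class[v.vclass] += 1
        by_loc[str(classify_variant(v, gene, window))] += 1
        try:
            consensus[v.vid] = consensus_allele(v)
        except NoGenotypesError:
            consensus[v.vid] = "."
    return CatalogSummary(
        total=len(variants),
        by_vclass=dict(by_class),
        by_localization=dict(by_loc),
        snp_density_denominator=snp_density(window.length, by_class.get("SNP", 0)),
        consensus=consensus,
    )


def catalog_table(
    variants: Sequence[Variant], gene: GeneModel, window: LocusWindow
) -> pd.DataFrame:
    """Per-variant report table (vid, pos, alleles, class, localization, counts)."""
    rows = []
    for v in variants:
        nref, nalt = v.allele_counts()
        rows.append(
            {
                "vid": v.vid,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "vclass": v.vclass,
                "localization": str(classify_variant(v, gene, window)),
                "ref_count": nref,
                "alt_count": nalt,
                "alt_frequency": nalt / (nref + nalt) if nref + nalt else float("nan"),
                "consensus": consensus_allele(v) if nref + nalt else ".",
            }
        )
    return pd.DataFrame(rows)
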