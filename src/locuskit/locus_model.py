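"""Gene model, locus window and coordinate bookkeeping.

All *external* coordinates in locuskit are 1-based inclusive positions on the
forward strand of the assembly, matching how genome browsers and VCF print
them.  For a minus-strand gene the biologically meaningful reading order is
the reverse complement, so :class:`LocusWindow` additionally exposes a
*gene-sense* view of the sequence together with an exact bijection between
forward positions and gene-sense offsets.  Gene-sense offsets are 0-based and
internal only; nothing downstream ever reports them to the user.

Exon numbering follows transcription order: for a minus-strand gene exon 1 is
the exon with the *greatest* forward coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from pyfaidx import Fasta

from .errors import (
    CdsFrameError,
    MissingGeneError,
    MixedStrandError,
    SequenceAlphabetError,
    WindowBoundsError,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID_BASES = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over the {A,C,G,T,N} alphabet.

    Involution: ``reverse_complement(reverse_complement(s)) == s``.
    Raises :class:`SequenceAlphabetError` on any other character.
    """
    bad = set(seq.upper()) - _VALID_BASES
    if bad:
        raise SequenceAlphabetError(
            f"non-IUPAC-core characters in sequence: {sorted(bad)!r}"
        )
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """Single-transcript gene model on forward-assembly coordinates.

    ``exons`` are ``(start, end)`` 1-based inclusive forward intervals ordered
    in gene-sense (transcription) order, so ``exons[0]`` is exon 1.
    ``cds_start``/``cds_end`` bound the translated region in *forward*
    coordinates (cds_start < cds_end regardless of strand).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        fw = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(fw, fw[1:]):
            if s2 <= e1:
                raise ValueError("exons overlap")
        expected = tuple(fw) if self.strand == "+" else tuple(fw[::-1])
        if tuple(self.exons) != expected:
            raise ValueError("exons not in gene-sense order for this strand")
        if not (self.span_start <= self.cds_start <= self.cds_end <= self.span_end):
            raise ValueError("CDS outside exon span")
        if self.cds_length % 3 != 0:
            raise CdsFrameError(
                f"CDS length {self.cds_length} of {self.gene_id} "
                "is not a multiple of 3"
            )

    # ---- derived geometry -------------------------------------------------

    @property
    def span_start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def span_end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def gene_length(self) -> int:
        """Primary-transcript span in bases, introns included."""
        return self.span_end - self.span_start + 1

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def cds_intervals(self) -> tuple[tuple[int, int], ...]:
        """Forward intervals of the CDS within each exon, gene-sense order."""
        out = []
        for s, e in self.exons:
            cs, ce = max(s, self.cds_start), min(e, self.cds_end)
            if cs <= ce:
                out.append((cs, ce))
        return tuple(out)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Forward intervals between consecutive exons, gene-sense order.

        ``introns[0]`` is intron 1 (between exon 1 and exon 2).
        """
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1 + 1, s2 - 1))
            else:
                out.append((e2 + 1, s1 - 1))
        return tuple(out)

    @property
    def utr5(self) -> tuple[tuple[int, int], ...]:
        """Forward intervals of exon sequence gene-sense-upstream of the CDS."""
        return self._utr(five_prime=True)

    @property
    def utr3(self) -> tuple[tuple[int, int], ...]:
        return self._utr(five_prime=False)

    def _utr(self, five_prime: bool) -> tuple[tuple[int, int], ...]:
        out = []
        for s, e in self.exons:
            if five_prime == (self.strand == "+"):
                # region with forward coordinate < cds_start
                cs, ce = s, min(e, self.cds_start - 1)
            else:
                cs, ce = max(s, self.cds_end + 1), e
            if cs <= ce:
                out.append((cs, ce))
        return tuple(out)

    def exon_number_at(self, pos: int) -> int | None:
        """1-based gene-sense exon number containing *pos*, or None."""
        for i, (s, e) in enumerate(self.exons, start=1):
            if s <= pos <= e:
                return i
        return None

    def intron_number_at(self, pos: int) -> int | None:
        for i, (s, e) in enumerate(self.introns, start=1):
            if s <= pos <= e:
                return i
        return None


@dataclass(frozen=True)
class LocusWindow:
    """The gene plus symmetric flanks, with both sequence orientations.

    ``fwd_seq`` is the forward-assembly sequence of ``[start, end]``;
    ``gene_sense_seq`` is its reverse complement when the gene is on the
    minus strand.  ``to_gene_sense``/``to_forward`` form an exact bijection
    between forward positions and 0-based gene-sense offsets.
    """

    chrom: str
    start: int
    end: int
    strand: str
    flank: int
    fwd_seq: str
    gene: GeneModel | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != self.length:
            raise ValueError(
                f"sequence length {len(self.fwd_seq)} != window length {self.length}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def gene_sense_seq(self) -> str:
        if self.strand == "-":
            return reverse_complement(self.fwd_seq)
        return self.fwd_seq

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def to_gene_sense(self, pos: int) -> int:
        """Forward 1-based position -> 0-based gene-sense offset."""
        if not self.contains(pos):
            raise ValueError(f"position {pos} outside window {self.start}-{self.end}")
        if self.strand == "-":
            return self.end - pos
        return pos - self.start

    def to_forward(self, offset: int) -> int:
        """0-based gene-sense offset -> forward 1-based position."""
        if not 0 <= offset < self.length:
            raise ValueError(f"offset {offset} outside window of length {self.length}")
        if self.strand == "-":
            return self.end - offset
        return self.start + offset

    def fwd_slice(self, start: int, end: int) -> str:
        """Forward-strand sequence of the 1-based inclusive interval."""
        if start < self.start or end > self.end or start > end:
            raise ValueError(f"bad interval {start}-{end} for window")
        return self.fwd_seq[start - self.start : end - self.start + 1]

    def gene_sense_slice(self, start: int, end: int) -> str:
        """Gene-sense sequence of the forward 1-based inclusive interval."""
        s = self.fwd_slice(start, end)
        return reverse_complement(s) if self.strand == "-" else s


# ---------------------------------------------------------------------------
# loaders


def load_gene_model(annotation_file: str, gene_id: str) -> GeneModel:
    """Build a :class:`GeneModel` for *gene_id* from a GFF3 file.

    The annotation may attach exons/CDS directly to the gene or through a
    single mRNA child; multi-isoform genes are out of scope and the first
    transcript encountered is used (logged).  Exons are renumbered in
    gene-sense order regardless of file order.
    """
    import gffutils

    db = gffutils.create_db(
        annotation_file,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    try:
        gene = db[gene_id]
    except gffutils.exceptions.FeatureNotFoundError:
        # fall back on Name=/gene_id= attributes
        gene = None
        for feat in db.features_of_type(("gene", "mRNA")):
            names = feat.attributes.get("Name", []) + feat.attributes.get("gene_id", [])
            if gene_id in names or feat.id == gene_id:
                gene = feat
                break
        if gene is None:
            raise MissingGeneError(f"gene {gene_id!r} not found in {annotation_file}")

    exon_feats = list(db.children(gene, featuretype="exon"))
    cds_feats = list(db.children(gene, featuretype="CDS"))
    if not exon_feats:
        raise MissingGeneError(f"gene {gene_id!r} has no exon records")
    strands = {f.strand for f in exon_feats}
    if len(strands) > 1:
        raise MixedStrandError(f"gene {gene_id!r} has exons on both strands")
    strand = strands.pop()
    if strand not in {"+", "-"}:
        raise MixedStrandError(f"gene {gene_id!r} has no usable strand ({strand!r})")

    fw = sorted((f.start, f.end) for f in exon_feats)
    exons = tuple(fw) if strand == "+" else tuple(fw[::-1])
    if cds_feats:
        cds_start = min(f.start for f in cds_feats)
        cds_end = max(f.end for f in cds_feats)
    else:
        logger.warning("gene %s has no CDS records; treating full span as CDS", gene_id)
        cds_start, cds_end = fw[0][0], fw[-1][1]

    return GeneModel(
        gene_id=gene_id,
        chrom=exon_feats[0].seqid,
        strand=strand,
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
    )


def build_window(
    genome: "str | Fasta | dict[str, str]",
    gene: GeneModel,
    flank: int = 5000,
) -> LocusWindow:
    """Extract the gene ± *flank* window from a reference sequence source.

    *genome* may be a FASTA path, an open :class:`pyfaidx.Fasta`, or a plain
    ``{chrom: sequence}`` dict (handy for toy constructs).  A window that
    would run off either chromosome end raises :class:`WindowBoundsError`;
    nothing is ever silently clipped.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    start = gene.span_start - flank
    end = gene.span_end + flank

    if isinstance(genome, str):
        genome = Fasta(genome)
    if isinstance(genome, dict):
        chrom_seq = genome[gene.chrom]
        chrom_len = len(chrom_seq)
        fetch = lambda s, e: chrom_seq[s - 1 : e]  # noqa: E731
    else:
        rec = genome[gene.chrom]
        chrom_len = len(rec)
        fetch = lambda s, e: str(rec[s - 1 : e])  # noqa: E731

    if start < 1 or end > chrom_len:
        raise WindowBoundsError(
            f"window {start}-{end} exceeds chromosome {gene.chrom} "
            f"bounds 1-{chrom_len}"
        )
    seq = fetch(start, end).upper()
    return LocusWindow(
        chrom=gene.chrom,
        start=start,
        end=end,
        strand=gene.strand,
        flank=flank,
        fwd_seq=seq,
        gene=gene,
    )
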