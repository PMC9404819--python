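"""Protein-level consequences of exonic SNPs and codon-usage rarity calls.

The codon holding a coding SNP is reconstructed on the gene-sense strand
(translation table 1, the standard nuclear code), the alternate base is
substituted — complemented first when the gene is on the minus strand — and
the substitution is typed silent / missense / nonsense / start_loss.
Synonymous changes can still swap an abundant codon for a rarely used one,
so each codon is also looked up in a per-mille codon-usage table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .errors import (
    MalformedInputError,
    OutsideRegionError,
    SequenceAlphabetError,
    UnsupportedVariantError,
)
from .locus_model import GeneModel, LocusWindow, reverse_complement
from .variant_catalog import Variant, classify_variant

_STOPS = frozenset(standard_dna_table.stop_codons)
_COMP = str.maketrans("ACGT", "TGCA")


def _translate_codon(codon: str) -> str:
    if set(codon) - set("ACGT"):
        raise SequenceAlphabetError(f"codon {codon!r} contains non-ACGT characters")
    if codon in _STOPS:
        return "*"
    return standard_dna_table.forward_table[codon]


@dataclass(frozen=True)
class CodonContext:
    """A coding SNP expressed in codon coordinates (gene-sense)."""

    vid: str
    codon_index: int  # 1-based codon number in the CDS
    codon_pos: int  # 1, 2 or 3 within the codon
    ref_codon: str
    alt_codon: str

    @property
    def ref_aa(self) -> str:
        return _translate_codon(self.ref_codon)

    @property
    def alt_aa(self) -> str:
        return _translate_codon(self.alt_codon)

    @property
    def effect(self) -> str:
        return substitution_effect(self)


def cds_gene_sense_sequence(gene: GeneModel, window: LocusWindow) -> str:
    """Spliced CDS in translation order."""
    return "".join(window.gene_sense_slice(s, e) for s, e in gene.cds_intervals)


def _cds_offset(gene: GeneModel, window: LocusWindow, pos: int) -> int | None:
    """0-based offset of forward position *pos* within the gene-sense CDS."""
    off = 0
    for s, e in gene.cds_intervals:
        if s <= pos <= e:
            return off + (e - pos if gene.strand == "-" else pos - s)
        off += e - s + 1
    return None


def codon_context(v: Variant, gene: GeneModel, window: LocusWindow) -> CodonContext:
    """Codon-level context of an exonic coding SNP.

    Raises :class:`UnsupportedVariantError` for indels (reported, never
    silently dropped) and :class:`OutsideRegionError` for variants outside
    the CDS (UTR, intron, intergenic).
    """
    if v.vclass != "SNP":
        raise UnsupportedVariantError(f"{v.vid}: codon context defined for SNPs only")
    loc = classify_variant(v, gene, window)
    if not loc.is_exonic:
        raise OutsideRegionError(f"{v.vid} is {loc}, not in the CDS")
    off = _cds_offset(gene, window, v.pos)
    if off is None:
        raise OutsideRegionError(f"{v.vid} is exonic but outside the CDS")
    cds = cds_gene_sense_sequence(gene, window)
    idx, cpos = divmod(off, 3)
    ref_codon = cds[idx * 3 : idx * 3 + 3]
    alt_base = v.alt if gene.strand == "+" else v.alt.translate(_COMP)
    ref_base = v.ref if gene.strand == "+" else v.ref.translate(_COMP)
    if ref_codon[cpos] != ref_base:
        raise MalformedInputError(
            f"{v.vid}: REF {v.ref} disagrees with CDS base {ref_codon[cpos]}"
        )
    alt_codon = ref_codon[:cpos] + alt_base + ref_codon[cpos + 1 :]
    return CodonContext(
        vid=v.vid,
        codon_index=idx + 1,
        codon_pos=cpos + 1,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
    )


def substitution_effect(ctx: CodonContext) -> str:
    """silent / missense / nonsense / start_loss for a codon substitution."""
    ref_aa = _translate_codon(ctx.ref_codon)
    alt_aa = _translate_codon(ctx.alt_codon)
    if ctx.codon_index == 1 and ctx.ref_codon == "ATG" and ctx.alt_codon != "ATG":
        return "start_loss"
    if ref_aa == alt_aa:
        return "silent"
    if alt_aa == "*":
        return "nonsense"
    return "missense"


# ---------------------------------------------------------------------------
# codon usage


@dataclass(frozen=True)
class CodonUsageTable:
    """Codon -> usage frequency in per-mille (‰), with a source label."""

    frequencies: dict[str, float]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.frequencies) != 64:
            raise MalformedInputError(
                f"codon usage table has {len(self.frequencies)} codons, expected 64"
            )
        if any(f < 0 for f in self.frequencies.values()):
            raise MalformedInputError("negative codon frequency")

    def __getitem__(self, codon: str) -> float:
        try:
            return self.frequencies[codon.upper()]
        except KeyError:
            raise MalformedInputError(f"codon {codon!r} absent from usage table")


@dataclass(frozen=True)
class RarityCall:
    codon: str
    frequency_permille: float
    threshold_permille: float

    @property
    def status(self) -> str:
        return "rare" if self.frequency_permille < self.threshold_permille else "common"


def load_codon_usage(path: str | Path | None = None, source: str = "") -> CodonUsageTable:
    """Read a two-column TSV (codon, per-mille frequency).

    With no path, the packaged synthetic stand-in table is used (see
    ``data/codon_usage_camelus_synthetic.tsv``).
    """
    if path is None:
        ref = resources.files("locuskit.data") / "codon_usage_camelus_synthetic.tsv"
        text = ref.read_text()
        source = source or "packaged synthetic stand-in"
    else:
        text = Path(path).read_text()
        source = source or str(path)
    freqs: dict[str, float] = {}
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise MalformedInputError(f"codon usage line {ln}: expected 2 columns")
        codon = parts[0].upper().replace("U", "T")
        try:
            freqs[codon] = float(parts[1])
        except ValueError:
            raise MalformedInputError(f"codon usage line {ln}: bad frequency {parts[1]!r}")
    return CodonUsageTable(frequencies=freqs, source=source)


def rarity_call(
    codon: str, table: CodonUsageTable, threshold_permille: float = 10.0
) -> RarityCall:
    """Rare iff usage frequency is strictly below the threshold (default 10‰)."""
    return RarityCall(
        codon=codon.upper(),
        frequency_permille=table[codon],
        threshold_permille=threshold_permille,
    )


def rarity_transition(
    ctx: CodonContext, table: CodonUsageTable, threshold_permille: float = 10.0
) -> str:
    """Describe the codon-optimality change of a substitution, e.g. 'rare→common'."""
    a = rarity_call(ctx.ref_codon, table, threshold_permille).status
    b = rarity_call(ctx.alt_codon, table, threshold_permille).status
    return f"{a}→{b}"
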