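"""Splice-signal scoring, allele diffing and intron-retention simulation.

Donor and acceptor sites are scored with per-position base-frequency
matrices on the classic consensus-value (CV) scale:

    CV = 100 · (Σ_i f_i(obs_i) − Σmin) / (Σmax − Σmin)

where Σmin/Σmax sum the per-position minimum/maximum frequencies, so the
per-position-max motif scores exactly 100 and the per-position-min motif
exactly 0.  By construction the CV is invariant to a uniform rescaling of
the matrix (percent vs. fraction).  The default matrices shipped with the
package follow the donor 9-mer spanning [−3,+6] around the exon|intron
boundary (GT at motif positions 4–5) and the acceptor 14-mer spanning
[−12,+2] (AG at motif positions 11–12); branch-point motifs are 7-mers
centred on the branch adenosine.

ESE/ESS auxiliary elements are handled as motif sets: an element is created
or disrupted when a motif's occurrence set in the variant neighborhood
changes between alleles.

Intron retention takes an alternative site inside an intron and rebuilds the
transcript with the corresponding intron prefix retained, then translates it
from the canonical start codon to find premature stops.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import (
    MalformedInputError,
    MatrixFormatError,
    OutsideRegionError,
    SequenceAlphabetError,
)
from .locus_model import GeneModel, LocusWindow
from .regulatory_diff import AlleleSequence, apply_allele
from .variant_catalog import Variant, classify_variant

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}

#: default report thresholds per signal kind (CV scale)
DEFAULT_THRESHOLDS = {"donor": 65.0, "acceptor": 65.0, "branch_point": 67.0}


@dataclass(frozen=True)
class SpliceMatrix:
    """Per-position base-frequency matrix for one splice-signal kind."""

    kind: str  # donor | acceptor | branch_point
    freqs: np.ndarray  # (L, 4) over A,C,G,T; any uniform scale
    #: motif position (0-based) of the first intron base, for donors/acceptors
    boundary_index: int | None = None

    def __post_init__(self) -> None:
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 4:
            raise MatrixFormatError(f"{self.kind}: matrix must be (L, 4)")

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    @property
    def sum_min(self) -> float:
        return float(self.freqs.min(axis=1).sum())

    @property
    def sum_max(self) -> float:
        return float(self.freqs.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self.freqs, axis=1))


def consensus_value(motif: str, m: SpliceMatrix) -> float:
    """CV of *motif* under matrix *m* on the 0–100 scale."""
    motif = motif.upper()
    if len(motif) != m.length:
        raise MalformedInputError(
            f"motif length {len(motif)} != matrix length {m.length}"
        )
    if set(motif) - set(_BASES):
        raise SequenceAlphabetError(f"motif {motif!r} contains non-ACGT characters")
    t = sum(m.freqs[i, _CODE[b]] for i, b in enumerate(motif))
    return 100.0 * (t - m.sum_min) / (m.sum_max - m.sum_min)


def load_splice_matrices(path: str | Path | None = None) -> dict[str, SpliceMatrix]:
    """Read splice matrices from a TSV with columns kind, pos, A, C, G, T.

    With no path the packaged default matrices are loaded: donor/acceptor
    tables assembled from the classic primate splice-site base-frequency
    compilations (approximate; see the data file header) and a synthetic
    branch-point matrix.
    """
    if path is None:
        text = (resources.files("locuskit.data") / "splice_matrices.tsv").read_text()
    else:
        text = Path(path).read_text()
    rows: dict[str, list[tuple[str, list[float]]]] = {}
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("kind\t"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise MatrixFormatError(f"splice matrix line {ln}: expected 6 columns")
        kind, pos = parts[0], parts[1]
        try:
            vals = [float(x) for x in parts[2:]]
        except ValueError:
            raise MatrixFormatError(f"splice matrix line {ln}: bad frequency")
        rows.setdefault(kind, []).append((pos, vals))
    out: dict[str, SpliceMatrix] = {}
    for kind, entries in rows.items():
        freqs = np.array([v for _, v in entries])
        positions = [p for p, _ in entries]
        boundary = None
        if "+1" in positions:
            boundary = positions.index("+1")
        out[kind] = SpliceMatrix(kind=kind, freqs=freqs, boundary_index=boundary)
    return out


@dataclass(frozen=True)
class SpliceSite:
    kind: str
    offset: int  # 0-based motif start on the scanned (gene-sense) sequence
    motif: str
    cv: float

    @property
    def position(self) -> int:
        return self.offset


def scan_splice_sites(
    seq: str,
    matrices: "dict[str, SpliceMatrix] | Sequence[SpliceMatrix]",
    threshold: float | dict[str, float] = 65.0,
) -> list[SpliceSite]:
    """Score every offset of *seq* with every matrix; report sites >= threshold.

    Windows containing N are skipped (logged once per scan).  *threshold*
    may be a single CV or a per-kind mapping.
    """
    if isinstance(matrices, dict):
        matrices = list(matrices.values())
    seq = seq.upper()
    codes = np.array([_CODE.get(b, 4) for b in seq], dtype=np.int8)
    sites: list[SpliceSite] = []
    skipped_n = False
    for m in matrices:
        thr = threshold.get(m.kind, 65.0) if isinstance(threshold, dict) else threshold
        L = m.length
        if len(codes) < L:
            continue
        win = np.lib.stride_tricks.sliding_window_view(codes, L)
        valid = np.all(win < 4, axis=1)
        if not valid.all():
            skipped_n = True
        padded = np.hstack([m.freqs, np.full((L, 1), np.nan)])
        t = padded[np.arange(L), win].sum(axis=1)
        cv = 100.0 * (t - m.sum_min) / (m.sum_max - m.sum_min)
        for j in np.flatnonzero(valid & (cv >= thr)):
            sites.append(
                SpliceSite(kind=m.kind, offset=int(j), motif=seq[j : j + L], cv=float(cv[j]))
            )
    if skipped_n:
        logger.info("scan windows containing N were skipped")
    sites.sort(key=lambda s: (s.offset, s.kind))
    return sites


# ---------------------------------------------------------------------------
# ESE / ESS motif sets


def load_motif_sets(path: str | Path | None = None) -> dict[str, frozenset[str]]:
    """Read ESE/ESS motif sets from a TSV (category, set_name, motif).

    The packaged defaults are small synthetic stand-in sets (enhancer-like
    purine-rich hexamers, silencer-like hexamers); both are swappable files.
    """
    if path is None:
        text = (resources.files("locuskit.data") / "ese_ess_motifs.tsv").read_text()
    else:
        text = Path(path).read_text()
    sets: dict[str, set[str]] = {"ESE": set(), "ESS": set()}
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("category"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise MalformedInputError(f"motif set line {ln}: expected 3 columns")
        cat, _set_name, motif = parts[0].upper(), parts[1], parts[2].upper()
        if cat not in sets:
            raise MalformedInputError(f"motif set line {ln}: category {cat!r}")
        sets[cat].add(motif)
    return {k: frozenset(v) for k, v in sets.items()}


def _motif_occurrences(seq: str, motifs: Iterable[str]) -> set[tuple[str, int]]:
    found = set()
    for motif in motifs:
        start = 0
        while True:
            i = seq.find(motif, start)
            if i < 0:
                break
            found.add((motif, i))
            start = i + 1
    return found


# ---------------------------------------------------------------------------
# allele diffing


@dataclass(frozen=True)
class SpliceElementDiff:
    """One created or disrupted splice element between the two alleles."""

    vid: str
    category: str  # donor | acceptor | branch_point | ESE | ESS
    event: str  # created | disrupted
    motif: str
    value: float | None  # CV for matrix-scored kinds, None for motif sets
    allele: str  # the allele under which the element is present


def _anchored(offset: int, seg_offset: int, seg_len: int) -> tuple:
    if offset <= seg_offset:
        return ("L", offset - seg_offset)
    return ("R", offset - (seg_offset + seg_len))


def diff_splice_elements(
    window: LocusWindow,
    v: Variant,
    matrices: dict[str, SpliceMatrix] | None = None,
    motif_sets: dict[str, frozenset[str]] | None = None,
    thresholds: dict[str, float] | None = None,
) -> list[SpliceElementDiff]:
    """Created/disrupted splice elements when swapping the variant's alleles.

    Restricted, like the analysis it implements, to variants in the gene
    body or UTRs; intergenic flank variants raise
    :class:`OutsideRegionError`.
    """
    gene = window.gene
    if gene is None:
        raise ValueError("window must carry its gene model")
    loc = classify_variant(v, gene, window)
    if not loc.is_genic:
        raise OutsideRegionError(f"{v.vid} is {loc}; splice diffing is genic/UTR only")
    if matrices is None:
        matrices = load_splice_matrices()
    if motif_sets is None:
        motif_sets = load_motif_sets()
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)

    ref_seq = apply_allele(window, v, "ref")
    alt_seq = apply_allele(window, v, "alt")
    max_l = max(
        [m.length for m in matrices.values()]
        + [len(x) for s in motif_sets.values() for x in s]
        or [1]
    )
    pad = max_l - 1

    def neighborhood(a: AlleleSequence) -> tuple[str, int]:
        start = max(0, a.seg_offset - pad)
        end = min(len(a.seq), a.seg_offset + a.seg_len + pad)
        return a.seq[start:end], a.seg_offset - start

    ref_sub, ref_seg = neighborhood(ref_seq)
    alt_sub, alt_seg = neighborhood(alt_seq)

    diffs: list[SpliceElementDiff] = []

    ref_sites = {
        (s.kind, _anchored(s.offset, ref_seg, ref_seq.seg_len)): s
        for s in scan_splice_sites(ref_sub, matrices, thr)
    }
    alt_sites = {
        (s.kind, _anchored(s.offset, alt_seg, alt_seq.seg_len)): s
        for s in scan_splice_sites(alt_sub, matrices, thr)
    }
    for key in sorted(set(alt_sites) - set(ref_sites)):
        s = alt_sites[key]
        diffs.append(SpliceElementDiff(v.vid, s.kind, "created", s.motif, s.cv, "alt"))
    for key in sorted(set(ref_sites) - set(alt_sites)):
        s = ref_sites[key]
        diffs.append(SpliceElementDiff(v.vid, s.kind, "disrupted", s.motif, s.cv, "ref"))

    for cat, motifs in motif_sets.items():
        ref_occ = {
            (m, _anchored(o, ref_seg, ref_seq.seg_len))
            for m, o in _motif_occurrences(ref_sub, motifs)
        }
        alt_occ = {
            (m, _anchored(o, alt_seg, alt_seq.seg_len))
            for m, o in _motif_occurrences(alt_sub, motifs)
        }
        for m, _ in sorted(alt_occ - ref_occ):
            diffs.append(SpliceElementDiff(v.vid, cat, "created", m, None, "alt"))
        for m, _ in sorted(ref_occ - alt_occ):
            diffs.append(SpliceElementDiff(v.vid, cat, "disrupted", m, None, "ref"))
    return diffs


# ---------------------------------------------------------------------------
# translation and intron retention


@dataclass(frozen=True)
class ProteinResult:
    seq: str
    has_stop: bool


def translate(transcript: str, start_offset: int = 0) -> ProteinResult:
    """Translate from an ATG at *start_offset* to the first stop (or the end).

    Standard nuclear code.  A missing start codon raises
    :class:`MalformedInputError`; running off the end without a stop is
    flagged, not an error.
    """
    transcript = transcript.upper()
    if transcript[start_offset : start_offset + 3] != "ATG":
        raise MalformedInputError(
            f"no ATG at offset {start_offset} "
            f"(found {transcript[start_offset:start_offset + 3]!r})"
        )
    coding = transcript[start_offset:]
    coding = coding[: len(coding) - len(coding) % 3]
    aa = str(Seq(coding).translate(table=1))
    stop = aa.find("*")
    if stop >= 0:
        return ProteinResult(seq=aa[:stop], has_stop=True)
    return ProteinResult(seq=aa, has_stop=False)


@dataclass(frozen=True)
class RetentionOutcome:
    """Consequence of retaining an intron prefix in the mature transcript."""

    retained_len: int
    transcript: str
    protein: str
    has_stop: bool
    canonical_protein_len: int
    exon_peptide_len: int  # residues fully encoded by exons 1..k (gene-sense)

    @property
    def truncated(self) -> bool:
        return self.has_stop and len(self.protein) < self.canonical_protein_len

    @property
    def stop_offset_aa(self) -> int | None:
        """Residues translated past the last canonical exon-k-encoded residue."""
        if not self.has_stop:
            return None
        return len(self.protein) - self.exon_peptide_len


def simulate_retention(
    gene: GeneModel,
    window: LocusWindow,
    alt_site: SpliceSite | int,
    which_intron: int,
    site_kind: str | None = None,
    variant: Variant | None = None,
) -> RetentionOutcome:
    """Rebuild and translate the transcript with part of intron *k* retained.

    Geometry: a new donor inside intron k keeps the intron prefix from the
    canonical exon-k boundary up to (excluding) the new donor's first intron
    base; a new acceptor keeps the prefix through the acceptor's AG.  In
    both cases splicing then resumes at the canonical downstream exon.

    *alt_site* is the alternative site either as a :class:`SpliceSite` or as
    the retained prefix length directly (int).  When *variant* is given its
    alternate allele is applied first — the variant must fall inside the
    retained intron — and site offsets refer to the mutated gene-sense
    window sequence (the sequence in which the site was found).
    """
    if not 1 <= which_intron <= gene.n_exons - 1:
        raise OutsideRegionError(f"gene has no intron {which_intron}")
    intron_fw = gene.introns[which_intron - 1]

    if variant is not None:
        loc = classify_variant(variant, gene, window)
        if not (loc.kind == "intron" and loc.index == which_intron):
            raise OutsideRegionError(
                f"{variant.vid} is {loc}, not inside intron {which_intron}"
            )
        aseq = apply_allele(window, variant, "alt")

        def off(pos: int) -> int:
            mapped = aseq.map_offset(window.to_gene_sense(pos))
            if mapped is None:
                raise OutsideRegionError(
                    f"{variant.vid}: boundary falls inside the replaced segment"
                )
            return mapped

        seq = aseq.seq
    else:
        seq = window.gene_sense_seq

        def off(pos: int) -> int:
            return window.to_gene_sense(pos)

    # gene-sense offsets of the intron on the (possibly mutated) sequence
    if gene.strand == "-":
        intron_start_off, intron_end_off = off(intron_fw[1]), off(intron_fw[0])
    else:
        intron_start_off, intron_end_off = off(intron_fw[0]), off(intron_fw[1])
    intron_len = intron_end_off - intron_start_off + 1

    if isinstance(alt_site, int):
        retained = alt_site
    else:
        kind = site_kind or alt_site.kind
        m_boundary = {"donor": 3, "acceptor": 12}.get(kind)
        if m_boundary is None:
            raise MalformedInputError(f"retention needs a donor/acceptor site, got {kind}")
        # donor: new exon|intron boundary at the motif's first intron base;
        # acceptor 14-mer: intron ends at motif position 12 (the G of AG)
        retained = alt_site.offset + m_boundary - intron_start_off
    if not 0 < retained <= intron_len:
        raise OutsideRegionError(
            f"retained length {retained} outside intron {which_intron} "
            f"(1..{intron_len})"
        )

    def gs_slice(s: int, e: int) -> str:
        if gene.strand == "-":
            return seq[off(e) : off(s) + 1]
        return seq[off(s) : off(e) + 1]

    parts = []
    for i, (s, e) in enumerate(gene.exons, start=1):
        parts.append(gs_slice(s, e))
        if i == which_intron:
            parts.append(seq[intron_start_off : intron_start_off + retained])
    transcript = "".join(parts)

    # canonical start: gene-sense offset of the CDS start within the transcript
    utr5_len = sum(e - s + 1 for s, e in gene.utr5)
    prot = translate(transcript, utr5_len)
    canonical = gene.cds_length // 3 - 1  # residues, stop codon excluded
    cds_upto = 0  # CDS bases carried by exons 1..k
    for i, (s, e) in enumerate(gene.exons, start=1):
        if i > which_intron:
            break
        cs, ce = max(s, gene.cds_start), min(e, gene.cds_end)
        if cs <= ce:
            cds_upto += ce - cs + 1
    return RetentionOutcome(
        retained_len=retained,
        transcript=transcript,
        protein=prot.seq,
        has_stop=prot.has_stop,
        canonical_protein_len=canonical,
        exon_peptide_len=cds_upto // 3,
    )
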