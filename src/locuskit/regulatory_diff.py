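"""Differential transcription-factor binding-site prediction between alleles.

For each promoter variant the two allele-specific sequences are built by in
silico mutagenesis and scanned, on both strands, with a library of position
weight matrices.  The similarity score is the information-weighted matrix
similarity used by MatInspector-style scanners:

    sim = Σ_i I_i · f_i(obs_i)  /  Σ_i I_i · max_b f_i(b)

with per-position information weights I_i = Σ_b f_i(b)·log4(4·f_i(b)).
A site is *gained* when it clears the threshold only with the alternate
allele and *lost* when only with the reference allele; hits are keyed by
matrix, strand and variant-anchored offset so indel length changes do not
spuriously shift the comparison.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import AlleleMismatchError, MatrixFormatError, OutsideRegionError
from .locus_model import LocusWindow, reverse_complement
from .variant_catalog import Variant

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}


def load_muscle_tf_list() -> tuple[str, ...]:
    """Curated muscle-development/metabolism TF names shipped with the package."""
    text = (resources.files("locuskit.data") / "muscle_tf_list.txt").read_text()
    return tuple(
        ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")
    )


def _norm_name(name: str) -> str:
    return re.sub(r"[^A-Z0-9]", "", name.upper())


@dataclass(frozen=True)
class PWM:
    """Position weight matrix with pseudocount-normalized frequencies.

    ``freqs`` is an (L, 4) array over A,C,G,T summing to 1 per row;
    ``info`` holds the per-position information weights I_i in [0, 1]
    (log base 4, so a single-base column scores ~1).
    """

    matrix_id: str
    tf_name: str
    freqs: np.ndarray
    muscle_flag: bool = False

    def __post_init__(self) -> None:
        if self.freqs.ndim != 2 or self.freqs.shape[1] != 4:
            raise MatrixFormatError(f"{self.matrix_id}: matrix must be (L, 4)")
        if self.length < 4:
            raise MatrixFormatError(f"{self.matrix_id}: motif length < 4")

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    @property
    def info(self) -> np.ndarray:
        f = self.freqs
        return np.sum(f * np.log(4.0 * f) / np.log(4.0), axis=1)

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self.freqs, axis=1))

    @property
    def max_score(self) -> float:
        return float(np.sum(self.info * self.freqs.max(axis=1)))


def pwm_from_counts(
    matrix_id: str,
    tf_name: str,
    counts: np.ndarray,
    pseudocount: float = 0.01,
    muscle_tfs: Sequence[str] = (),
) -> PWM:
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise MatrixFormatError(f"{matrix_id}: ragged or non 4-column count matrix")
    totals = counts.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        raise MatrixFormatError(f"{matrix_id}: empty count row")
    f = (counts / totals + pseudocount)
    f /= f.sum(axis=1, keepdims=True)
    norm = _norm_name(tf_name or matrix_id)
    flag = any(_norm_name(t) in norm for t in muscle_tfs)
    return PWM(matrix_id=matrix_id, tf_name=tf_name, freqs=f, muscle_flag=flag)


def load_pwms(
    matrix_file: str | Path | None = None, pseudocount: float = 0.01
) -> list[PWM]:
    """Read a TRANSFAC-style flat file of count matrices.

    Parsing is delegated to ``Bio.motifs`` (format "TRANSFAC"); counts are
    pseudocount-normalized into frequencies.  With no path, the packaged
    synthetic demonstration matrices are loaded.
    """
    import io

    from Bio import motifs as bio_motifs

    if matrix_file is None:
        text = (resources.files("locuskit.data") / "tf_matrices_synthetic.dat").read_text()
    else:
        text = Path(matrix_file).read_text()
    try:
        records = bio_motifs.parse(io.StringIO(text), "TRANSFAC")
    except Exception as exc:
        raise MatrixFormatError(f"cannot parse TRANSFAC file: {exc}") from exc
    muscle = load_muscle_tf_list()
    out = []
    for m in records:
        mid = m.get("ID") or m.get("AC") or f"M{len(out):03d}"
        bf = m.get("BF")
        tf = bf[0] if isinstance(bf, list) and bf else (bf or mid)
        counts = np.array([[m.counts[b][i] for b in _BASES] for i in range(m.length)])
        out.append(pwm_from_counts(mid, str(tf), counts, pseudocount, muscle))
    if not out:
        raise MatrixFormatError("no matrices found")
    return out


# ---------------------------------------------------------------------------
# scanning


@dataclass(frozen=True)
class TFBSHit:
    matrix_id: str
    tf_name: str
    offset: int  # 0-based offset of the motif start on the scanned sequence
    strand: str  # '+' scanned sequence as-is, '-' its reverse complement
    score: float
    muscle_flag: bool = False


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


_LUT = np.full(256, 4, dtype=np.int8)
for _b, _i in _CODE.items():
    _LUT[ord(_b)] = _i


def _scores_one_strand(codes: np.ndarray, pwm: PWM) -> np.ndarray:
    """Similarity score at every offset; NaN where the window contains N."""
    L = pwm.length
    if len(codes) < L:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = np.all(win < 4, axis=1)
    info = pwm.info
    padded = np.hstack([pwm.freqs, np.zeros((L, 1))])  # column for N
    per_pos = padded[np.arange(L), win]
    scores = (info * per_pos).sum(axis=1) / pwm.max_score
    scores[~valid] = np.nan
    return scores


def scan_pwms(
    seq: str, pwms: Sequence[PWM], threshold: float = 0.85
) -> list[TFBSHit]:
    """Scan both strands of *seq*; report offsets on the given sequence.

    Windows containing N are skipped.  A minus-strand hit at offset j means
    the reverse complement of ``seq[j:j+L]`` matches the motif.
    """
    codes = _LUT[_encode(seq)]
    rc_codes = _LUT[_encode(reverse_complement(seq))]
    n = len(seq)
    hits: list[TFBSHit] = []
    for pwm in pwms:
        for strand, c in (("+", codes), ("-", rc_codes)):
            scores = _scores_one_strand(c, pwm)
            for j in np.flatnonzero(scores >= threshold):
                off = int(j) if strand == "+" else n - pwm.length - int(j)
                hits.append(
                    TFBSHit(
                        matrix_id=pwm.matrix_id,
                        tf_name=pwm.tf_name,
                        offset=off,
                        strand=strand,
                        score=float(scores[j]),
                        muscle_flag=pwm.muscle_flag,
                    )
                )
    hits.sort(key=lambda h: (h.offset, h.matrix_id, h.strand))
    return hits


# ---------------------------------------------------------------------------
# allele application


@dataclass(frozen=True)
class AlleleSequence:
    """A gene-sense sequence with one allele substituted, plus its offset map.

    ``seg_offset`` is the gene-sense offset of the first base of the applied
    allele segment; ``seg_len``/``replaced_len`` give the segment length in
    this sequence and in the original window.  ``map_offset`` converts an
    original window gene-sense offset to an offset in this sequence (None
    inside the replaced segment for non-SNPs).
    """

    seq: str
    seg_offset: int
    seg_len: int
    replaced_len: int

    @property
    def shift(self) -> int:
        return self.seg_len - self.replaced_len

    def map_offset(self, orig: int) -> int | None:
        if orig < self.seg_offset:
            return orig
        if orig >= self.seg_offset + self.replaced_len:
            return orig + self.shift
        return orig if self.seg_len == self.replaced_len else None


def apply_allele(window: LocusWindow, v: Variant, allele: str) -> AlleleSequence:
    """Return the gene-sense window sequence carrying *allele* ('ref'|'alt').

    The REF allele is checked against the window sequence first; a mismatch
    raises :class:`AlleleMismatchError` (guards FASTA/VCF incoherence).
    """
    if allele not in {"ref", "alt"}:
        raise ValueError("allele must be 'ref' or 'alt'")
    if not (window.contains(v.pos) and window.contains(v.pos + len(v.ref) - 1)):
        raise OutsideRegionError(f"{v.vid} not fully inside the window")
    observed = window.fwd_slice(v.pos, v.pos + len(v.ref) - 1)
    if observed != v.ref:
        raise AlleleMismatchError(
            f"{v.vid}: REF {v.ref!r} but window has {observed!r} at {v.pos}"
        )
    applied = v.ref if allele == "ref" else v.alt
    i = v.pos - window.start
    fwd = window.fwd_seq[:i] + applied + window.fwd_seq[i + len(v.ref):]
    if window.strand == "-":
        seq = reverse_complement(fwd)
        seg_offset = window.end - (v.pos + len(v.ref) - 1)
    else:
        seq = fwd
        seg_offset = v.pos - window.start
    return AlleleSequence(
        seq=seq,
        seg_offset=seg_offset,
        seg_len=len(applied),
        replaced_len=len(v.ref),
    )


# ---------------------------------------------------------------------------
# differential sites


@dataclass
class DifferentialSiteReport:
    """Gained/lost TFBS hits when swapping the two alleles of one variant."""

    vid: str
    allele_ref: str
    allele_alt: str
    gained: list[TFBSHit] = field(default_factory=list)
    lost: list[TFBSHit] = field(default_factory=list)

    @property
    def n_differential(self) -> int:
        return len(self.gained) + len(self.lost)

    @property
    def unique_matrix_count(self) -> int:
        return len({h.matrix_id for h in self.gained + self.lost})

    @property
    def muscle_subset(self) -> list[TFBSHit]:
        return [h for h in self.gained + self.lost if h.muscle_flag]


def _hit_key(h: TFBSHit, seg_offset: int, seg_len: int) -> tuple:
    # anchor to the variant so indel length shifts cancel out
    if h.offset <= seg_offset:
        side, rel = "L", h.offset - seg_offset
    else:
        side, rel = "R", h.offset - (seg_offset + seg_len)
    return (h.matrix_id, h.strand, side, rel)


def promoter_interval(window: LocusWindow, promoter_span: int = 2000) -> tuple[int, int]:
    """Gene-sense offset interval [lo, hi] of the promoter upstream of the TSS."""
    tss = window.flank  # gene-sense offset of the first transcribed base
    lo = max(0, tss - promoter_span)
    return lo, tss - 1


def differential_tfbs(
    window: LocusWindow,
    v: Variant,
    pwms: Sequence[PWM],
    promoter_span: int = 2000,
    threshold: float = 0.85,
) -> DifferentialSiteReport:
    """Differential TFBS report for a promoter variant.

    Both allele sequences are built, a ±(max motif length − 1) neighborhood
    of the variant is scanned, and hits are diffed.  Restricting to the
    neighborhood is exact: any motif window overlapping the changed bases is
    contained in it, and unchanged windows diff away.
    """
    ref_seq = apply_allele(window, v, "ref")
    alt_seq = apply_allele(window, v, "alt")
    lo, hi = promoter_interval(window, promoter_span)
    seg_hi = ref_seq.seg_offset + ref_seq.seg_len - 1
    if seg_hi < lo or ref_seq.seg_offset > hi:
        raise OutsideRegionError(
            f"{v.vid} outside the {promoter_span} bp promoter span"
        )
    max_l = max(p.length for p in pwms)
    pad = max_l - 1

    def neighborhood(a: AlleleSequence) -> tuple[str, int]:
        start = max(0, a.seg_offset - pad)
        end = min(len(a.seq), a.seg_offset + a.seg_len + pad)
        return a.seq[start:end], start

    ref_sub, ref_start = neighborhood(ref_seq)
    alt_sub, alt_start = neighborhood(alt_seq)
    ref_hits = {
        _hit_key(h, ref_seq.seg_offset - ref_start, ref_seq.seg_len): h
        for h in scan_pwms(ref_sub, pwms, threshold)
    }
    alt_hits = {
        _hit_key(h, alt_seq.seg_offset - alt_start, alt_seq.seg_len): h
        for h in scan_pwms(alt_sub, pwms, threshold)
    }
    gained = [alt_hits[k] for k in sorted(set(alt_hits) - set(ref_hits))]
    lost = [ref_hits[k] for k in sorted(set(ref_hits) - set(alt_hits))]
    return DifferentialSiteReport(
        vid=v.vid, allele_ref=v.ref, allele_alt=v.alt, gained=gained, lost=lost
    )
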