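"""Cohort allele statistics and Tajima's D from its closed form.

Tajima's D contrasts two estimators of the scaled mutation rate θ: the mean
number of pairwise differences π and the segregating-site count S rescaled by
the harmonic number a1.  Under neutrality both estimate θ, so

    D = (π − S/a1) / sqrt(e1·S + e2·S·(S−1))

is centred near zero; an excess of intermediate-frequency sites pushes D
positive (balancing selection keeps alleles around 0.5), an excess of rare
variants pushes it negative (directional selection / expansion).  The ±2
bounds used for the calls are a rule-of-thumb label, not a formal test.

π is computed from allele counts with the unbiased per-site form
2·k·(n−k)/(n·(n−1)); an explicit pairwise double loop is kept in the test
suite as an independent oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import NoGenotypesError
from .variant_catalog import Variant

logger = logging.getLogger(__name__)


def allele_frequency(v: Variant) -> float:
    """Alternate-allele frequency over called chromosomes."""
    nref, nalt = v.allele_counts()
    n = nref + nalt
    if n == 0:
        raise NoGenotypesError(f"{v.vid}: no called genotypes")
    return nalt / n


@dataclass(frozen=True)
class ZygosityAudit:
    """Carrier/zygosity breakdown for one variant."""

    vid: str
    carriers: int
    het: int
    hom_alt: int

    @property
    def all_het(self) -> bool:
        return self.hom_alt == 0 and self.het >= 1


def zygosity_audit(v: Variant) -> ZygosityAudit:
    het = hom = 0
    for a1, a2 in v.genotypes:
        if a1 == 1 and a2 == 1:
            hom += 1
        elif 1 in (a1, a2):
            het += 1
    return ZygosityAudit(vid=v.vid, carriers=het + hom, het=het, hom_alt=hom)


# ---------------------------------------------------------------------------
# Tajima's D


@dataclass(frozen=True)
class TajimaConstants:
    """The a1…e2 constants of the D variance, for n sampled chromosomes."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """Exact evaluation of the closed-form constants; requires n ≥ 2."""
    if n < 2:
        raise ValueError(f"Tajima constants need n >= 2 chromosomes, got {n}")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


@dataclass(frozen=True)
class TajimaWindow:
    """Per-window summary: segregating sites, π, D and the rule-of-thumb call."""

    chrom: str
    win_start: int
    win_end: int
    S: int
    pi: float
    D: float | None

    @property
    def call(self) -> str:
        if self.D is None:
            return "undefined"
        if self.D > 2:
            return "balancing"
        if self.D < -2:
            return "directional"
        return "neutral"


def _site_counts(variants: Sequence[Variant]) -> list[tuple[int, int]]:
    """(alt_count, called_n) per site, sites with no calls dropped (logged)."""
    out = []
    for v in variants:
        nref, nalt = v.allele_counts()
        if nref + nalt == 0:
            logger.warning("%s: no called genotypes; site dropped from window", v.vid)
            continue
        out.append((nalt, nref + nalt))
    return out


def pairwise_pi(site_counts: Sequence[tuple[int, int]]) -> float:
    """Σ over sites of 2k(n−k)/(n(n−1)) — the unbiased mean pairwise diversity."""
    pi = 0.0
    for k, n in site_counts:
        if n >= 2:
            pi += 2.0 * k * (n - k) / (n * (n - 1))
    return pi


def tajima_D(
    variants: Sequence[Variant],
    n: int | None = None,
    *,
    win_start: int = 0,
    win_end: int = 0,
    chrom: str = "",
) -> TajimaWindow:
    """Tajima's D for one window of variants.

    *n* is the chromosome count used for the variance constants; when omitted
    it is the maximum called-chromosome count in the window.  S counts sites
    segregating among the called chromosomes.  With S = 0 (or a degenerate
    variance) D is None and the call is "undefined" — never a NaN.
    """
    counts = _site_counts(variants)
    seg = [(k, m) for k, m in counts if 0 < k < m]
    S = len(seg)
    pi = pairwise_pi(seg)
    if not chrom and variants:
        chrom = variants[0].chrom
    if S == 0:
        return TajimaWindow(chrom, win_start, win_end, 0, 0.0, None)
    if n is None:
        n = max(m for _, m in counts)
    const = tajima_constants(n)
    var = const.e1 * S + const.e2 * S * (S - 1)
    if var <= 0:
        return TajimaWindow(chrom, win_start, win_end, S, pi, None)
    D = (pi - S / const.a1) / np.sqrt(var)
    return TajimaWindow(chrom, win_start, win_end, S, pi, float(D))


def sliding_windows(
    variants: Sequence[Variant],
    window: int = 2000,
    n: int | None = None,
) -> list[TajimaWindow]:
    """Non-overlapping tiles anchored at position 1 along the chromosome.

    Tile t covers [t·w + 1, (t+1)·w]; each variant falls in exactly one tile.
    Unsorted input is sorted internally (logged).  Tiles with no variants are
    omitted.
    """
    if not variants:
        return []
    if any(b.pos < a.pos for a, b in zip(variants, variants[1:])):
        logger.info("unsorted variants; sorting by position")
        variants = sorted(variants, key=lambda v: v.pos)
    tiles: dict[int, list[Variant]] = {}
    for v in variants:
        tiles.setdefault((v.pos - 1) // window, []).append(v)
    out = []
    for t in sorted(tiles):
        vs = tiles[t]
        out.append(
            tajima_D(
                vs,
                n=n,
                win_start=t * window + 1,
                win_end=(t + 1) * window,
                chrom=vs[0].chrom,
            )
        )
    return out
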