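"""Cross-species allele sharing at the loci segregating in the focal cohort.

Alignment is consumed, not computed: the module takes per-species position
maps (focal forward position -> comparator base, or a gap) produced by an
external aligner, reads the comparator allele at every focal variant, and
tallies how often each comparator matches the focal reference allele, the
focal cohort consensus allele, and the other comparators.

Because published tallies are ambiguous about gap loci, pairwise sharing is
reported both ways: gaps excluded and gaps counted as mismatches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import MalformedInputError
from .variant_catalog import Variant, consensus_allele

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass
class OrthologAlleleTable:
    """Per-locus alleles: focal reference/consensus plus one per comparator."""

    table: pd.DataFrame  # columns: vid, pos, ref, consensus, <species...>
    species: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.table)


def load_position_maps(path: str | Path) -> dict[str, dict[int, str]]:
    """Read a position-map TSV (focal_pos, species, comparator_pos|GAP, base)."""
    maps: dict[str, dict[int, str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("focal_pos"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise MalformedInputError(f"position map line {ln}: expected 4 columns")
        pos, species, comp_pos, base = parts[:4]
        base = GAP if comp_pos.upper() == "GAP" or base == GAP else base.upper()
        maps.setdefault(species, {})[int(pos)] = base
    return maps


def build_allele_table(
    variants: Sequence[Variant],
    alignments: Mapping[str, Mapping[int, str]],
) -> OrthologAlleleTable:
    """Assemble the per-locus allele table from per-species position maps.

    A locus missing from a species' map becomes a gap with a warning, never
    an error: incomplete alignments are a fact of life for diverged taxa.
    """
    species = tuple(sorted(alignments))
    rows = []
    for v in variants:
        row = {
            "vid": v.vid,
            "pos": v.pos,
            "ref": v.ref,
            "consensus": consensus_allele(v),
        }
        for sp in species:
            base = alignments[sp].get(v.pos)
            if base is None:
                logger.warning("%s: no mapped position for %s; recorded as gap", v.vid, sp)
                base = GAP
            row[sp] = base
        rows.append(row)
    return OrthologAlleleTable(table=pd.DataFrame(rows), species=species)


@dataclass(frozen=True)
class SharingCounts:
    """Allele-sharing tallies for an :class:`OrthologAlleleTable`."""

    n_loci: int
    matches_reference: dict[str, int]
    matches_consensus: dict[str, int]
    gaps: dict[str, int]
    #: pairwise sharing counting only loci where both comparators have a base
    pairwise_excluding_gaps: dict[tuple[str, str], int]
    #: pairwise sharing also counting a gap shared by both as the same state
    pairwise_gap_shared: dict[tuple[str, str], int]


def sharing_counts(table: OrthologAlleleTable) -> SharingCounts:
    df = table.table
    ref_m: dict[str, int] = {}
    cons_m: dict[str, int] = {}
    gaps: dict[str, int] = {}
    for sp in table.species:
        col = df[sp]
        not_gap = col != GAP
        ref_m[sp] = int(((col == df["ref"]) & not_gap).sum())
        cons_m[sp] = int(((col == df["consensus"]) & not_gap).sum())
        gaps[sp] = int((~not_gap).sum())
    pair_ex: dict[tuple[str, str], int] = {}
    pair_gap: dict[tuple[str, str], int] = {}
    for i, a in enumerate(table.species):
        for b in table.species[i + 1 :]:
            both = (df[a] != GAP) & (df[b] != GAP)
            same = df[a] == df[b]
            pair_ex[(a, b)] = int((same & both).sum())
            pair_gap[(a, b)] = int(same.sum())  # gap==gap counts as shared
    return SharingCounts(
        n_loci=len(df),
        matches_reference=ref_m,
        matches_consensus=cons_m,
        gaps=gaps,
        pairwise_excluding_gaps=pair_ex,
        pairwise_gap_shared=pair_gap,
    )
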