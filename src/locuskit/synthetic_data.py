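"""Self-contained synthetic locus scenarios with known ground truth.

The generator emulates the study geometry the pipeline was built for: a toy
chromosome carrying a three-exon minus-strand gene (span 6,757 bases by
default) with ±5 kb flanks, a diploid cohort (183 samples by default), and a
list of *spikes* — variants placed in chosen compartments with chosen allele
frequencies, zygosity patterns and functional consequences.  Functional
spikes embed exact motif contexts into the background sequence so that the
intended threshold crossing is guaranteed by construction; the generator
re-scores every engineered context with the production scanners and refuses
to emit a scenario whose spikes do not behave as declared
(:class:`~locuskit.errors.SpikeError`).

Everything is deterministic under the scenario seed, and
:func:`make_locus` writes the standard formats the pipeline consumes
(FASTA, GFF3, VCF, matrix TSVs) next to a ``truth.json`` recording every
spike's expected classification, coding effect and diff events.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import coding_effects, popgen, splice_kit
from .errors import SpikeError
from .locus_model import GeneModel, LocusWindow, build_window, reverse_complement
from .regulatory_diff import differential_tfbs, load_pwms
from .splice_kit import diff_splice_elements, load_motif_sets, load_splice_matrices
from .variant_catalog import MISSING, Variant, classify_variant

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class Spike:
    """One planned variant: where it goes, what it is, and what it must do.

    ``offset`` is a gene-sense offset on the toy chromosome; ``functional``
    is one of none / tfbs_gain / tfbs_loss / donor_create / acceptor_create
    / donor_disrupt / ese_change / ess_change / silent / nonsense.
    """

    name: str
    offset: int
    vclass: str = "SNP"
    functional: str = "none"
    af: float | None = None
    carriers: int | None = None  # all-heterozygous carrier pattern
    indel_len: int = 5

    def __post_init__(self) -> None:
        if (self.af is None) == (self.carriers is None):
            raise SpikeError(f"spike {self.name}: give exactly one of af/carriers")


@dataclass
class ScenarioConfig:
    """Study-design parameters of a synthetic scenario.

    Defaults mirror the reference study geometry: 183 diploid samples, a
    minus-strand three-exon gene spanning 6,757 bases, ±5,000-base flanks.
    """

    seed: int = 0
    n_samples: int = 183
    chrom: str = "5"
    strand: str = "-"
    exon_lengths: tuple[int, int, int] = (506, 374, 1937)
    intron_lengths: tuple[int, int] = (1840, 2100)
    utr5_len: int = 119
    utr3_len: int = 1570
    flank: int = 5000
    margin: int = 600  # chromosome padding beyond each window edge
    gc: float = 0.5
    spikes: tuple[Spike, ...] = ()

    @property
    def gene_length(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)

    @property
    def cds_length(self) -> int:
        return self.gene_length - sum(self.intron_lengths) - self.utr5_len - self.utr3_len

    @property
    def chrom_length(self) -> int:
        return self.gene_length + 2 * self.flank + 2 * self.margin

    @property
    def gene_offset(self) -> int:
        """Gene-sense offset of the first transcribed base on the chromosome."""
        return self.margin + self.flank

    def compartment_offsets(self) -> dict[str, tuple[int, int]]:
        """Gene-sense offset ranges of every compartment (inclusive)."""
        g0 = self.gene_offset
        e1, e2, e3 = self.exon_lengths
        i1, i2 = self.intron_lengths
        out = {
            "upstream": (self.margin, g0 - 1),
            "promoter": (g0 - 2000, g0 - 1),
            "exon1": (g0, g0 + e1 - 1),
            "utr5": (g0, g0 + self.utr5_len - 1),
            "intron1": (g0 + e1, g0 + e1 + i1 - 1),
            "exon2": (g0 + e1 + i1, g0 + e1 + i1 + e2 - 1),
            "intron2": (g0 + e1 + i1 + e2, g0 + e1 + i1 + e2 + i2 - 1),
            "exon3": (g0 + e1 + i1 + e2 + i2, g0 + self.gene_length - 1),
            "downstream": (
                g0 + self.gene_length,
                g0 + self.gene_length + self.flank - 1,
            ),
        }
        out["utr3"] = (out["exon3"][1] - self.utr3_len + 1, out["exon3"][1])
        return out


def default_spikes(config: "ScenarioConfig") -> tuple[Spike, ...]:
    """The default spike list: every compartment and every functional kind.

    Mirrors the salient cohort patterns of the reference study design: six
    silent exonic SNPs at cohort frequency 0.5, an all-heterozygous
    7-carrier insertion in intron 1 next to an engineered donor-creating
    SNP, and an all-heterozygous 78-carrier acceptor-creating SNP.
    """
    comp = config.compartment_offsets()
    g0 = config.gene_offset
    cds1 = g0 + config.utr5_len  # gene-sense offset of the ATG
    e3 = comp["exon3"][0]
    return (
        Spike("up_snp", comp["upstream"][0] + 600, af=0.30),
        Spike("tfbs_gain", comp["promoter"][0] + 400, functional="tfbs_gain", af=0.25),
        Spike("tfbs_loss", comp["promoter"][0] + 900, functional="tfbs_loss", af=0.20),
        Spike("utr5_snp", g0 + 60, af=0.20),
        # codon 101, third base: CDS offsets 300..302
        Spike("exon1_silent", cds1 + 302, functional="silent", af=0.5),
        Spike("intron1_ins", comp["intron1"][0] + 700, vclass="insertion", carriers=7),
        Spike("intron1_donor_create", comp["intron1"][0] + 1000,
              functional="donor_create", af=0.30),
        Spike("intron1_acceptor_create", comp["intron1"][0] + 1500,
              functional="acceptor_create", carriers=78),
        # codon 150, third base: CDS offsets 447..449 (inside exon 2)
        Spike("exon2_silent", comp["exon2"][0] + (449 - 387), functional="silent", af=0.5),
        Spike("intron2_snp", comp["intron2"][0] + 300, af=0.10),
        Spike("intron2_donor_disrupt", comp["intron2"][0] + 800,
              functional="donor_disrupt", af=0.20),
        # third codon bases: exon 3 starts at CDS offset 761 ≡ 2 (mod 3)
        Spike("exon3_silent_1", e3 + 6, functional="silent", af=0.5),
        Spike("exon3_silent_2", e3 + 30, functional="silent", af=0.5),
        Spike("exon3_silent_3", e3 + 54, functional="silent", af=0.5),
        Spike("exon3_silent_4", e3 + 78, functional="silent", af=0.5),
        Spike("utr3_ese", comp["utr3"][0] + 200, functional="ese_change", af=0.30),
        Spike("utr3_ess", comp["utr3"][0] + 260, functional="ess_change", af=0.25),
        Spike("down_snp", comp["downstream"][0] + 800, af=0.35),
        Spike("down_del", comp["downstream"][0] + 1600, vclass="deletion", af=0.15),
    )


# ---------------------------------------------------------------------------
# engineered contexts
#
# Each functional spike embeds a fixed (ref-allele) context into the
# gene-sense background and declares the single base whose substitution
# flips the signal.  CVs quoted below are under the packaged default
# matrices and are re-verified at build time.

# donor 9-mer: alt "TCAGTAAGT"-style context scoring ~70, ref breaks the +1 G
_DONOR_ALT = "TCAGTAAGA"  # CV ≈ 69.8
_DONOR_REF = "TCAATAAGA"  # +1 G→A, CV ≈ 52.5
_DONOR_VAR = 3  # index of the varying base within the motif

# acceptor 14-mer: alt context scoring ~73, ref breaks the -2 A
_ACCEPTOR_ALT = "AAATTTGCTCAGGT"  # CV ≈ 72.7
_ACCEPTOR_REF = "AAATTTGCTCGGGT"  # -2 A→G, CV ≈ 57.7
_ACCEPTOR_VAR = 10

# MEF2-like synthetic matrix (consensus CTAAAAATAG): ref carries two
# high-information mismatches (similarity ≈ 0.80, below the 0.85 threshold),
# alt repairs one of them (similarity ≈ 0.90)
_MEF2_ALT = "CGAAAAATAG"  # one mismatch
_MEF2_REF = "CGAAAACTAG"  # two mismatches
_MEF2_VAR = 6

_ESE_ALT = "GAAGAA"
_ESE_REF = "GACGAA"
_ESE_VAR = 2

_ESS_ALT = "TAGGGT"
_ESS_REF = "TACGGT"
_ESS_VAR = 2


@dataclass
class Scenario:
    """A realized scenario: sequences, gene model, variants and truth."""

    config: ScenarioConfig
    genome: dict[str, str]  # forward-strand chromosome
    gene: GeneModel
    window: LocusWindow
    variants: list[Variant]
    truth: dict


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(_BASES))[rng.choice(4, size=n, p=p)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + TAA."""
    codons = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
    ok = [c for c in codons if c not in {"TAA", "TAG", "TGA", "ATG"}]
    body = [ok[i] for i in rng.integers(0, len(ok), size=n_codons - 2)]
    return "ATG" + "".join(body) + "TAA"


def _alt_counts_for(spike: Spike, n_chrom: int) -> int:
    if spike.carriers is not None:
        return spike.carriers
    m = round(spike.af * n_chrom)
    if not 0 < m <= n_chrom:
        raise SpikeError(f"spike {spike.name}: frequency {spike.af} unrealizable")
    return m


def _genotypes_for(
    spike: Spike, n_samples: int, rng: np.random.Generator
) -> tuple[tuple[int, int], ...]:
    if spike.carriers is not None:
        if spike.carriers > n_samples:
            raise SpikeError(f"spike {spike.name}: more carriers than samples")
        carrier_idx = set(rng.choice(n_samples, size=spike.carriers, replace=False))
        return tuple((0, 1) if i in carrier_idx else (0, 0) for i in range(n_samples))
    m = _alt_counts_for(spike, 2 * n_samples)
    hap = np.zeros(2 * n_samples, dtype=int)
    hap[rng.choice(2 * n_samples, size=m, replace=False)] = 1
    return tuple((int(hap[2 * i]), int(hap[2 * i + 1])) for i in range(n_samples))


def generate(config: ScenarioConfig | None = None) -> Scenario:
    """Build a scenario in memory; deterministic under ``config.seed``."""
    if config is None:
        config = ScenarioConfig()
    if not config.spikes:
        config = dataclasses.replace(config, spikes=default_spikes(config))
    rng = np.random.default_rng(config.seed)
    comp = config.compartment_offsets()

    # ---- gene-sense chromosome -------------------------------------------
    n_codons = config.cds_length // 3
    cds = _random_cds(rng, n_codons)
    e1, e2, e3 = config.exon_lengths
    i1, i2 = config.intron_lengths
    cds1_len = e1 - config.utr5_len
    cds3_len = e3 - config.utr3_len
    exon1 = _random_seq(rng, config.utr5_len, config.gc) + cds[:cds1_len]
    exon2 = cds[cds1_len : cds1_len + e2]
    exon3 = cds[cds1_len + e2 :] + _random_seq(rng, config.utr3_len, config.gc)
    intron1 = "GT" + _random_seq(rng, i1 - 4, config.gc) + "AG"
    intron2 = "GT" + _random_seq(rng, i2 - 4, config.gc) + "AG"
    gs = list(
        _random_seq(rng, config.margin + config.flank, config.gc)
        + exon1 + intron1 + exon2 + intron2 + exon3
        + _random_seq(rng, config.flank + config.margin, config.gc)
    )
    assert len(gs) == config.chrom_length

    # ---- embed spike contexts and collect variant plans ------------------
    plans: list[dict] = []
    for spike in config.spikes:
        plan = {"spike": spike}
        off = spike.offset
        if spike.functional in {"donor_create", "donor_disrupt"}:
            alt_m, ref_m = _DONOR_ALT, _DONOR_REF
            if spike.functional == "donor_disrupt":
                alt_m, ref_m = ref_m, alt_m
            start = off - _DONOR_VAR
            gs[start : start + 9] = list(ref_m)
            plan.update(gs_ref=ref_m[_DONOR_VAR], gs_alt=alt_m[_DONOR_VAR])
            plan["event"] = (
                ("donor", "created")
                if spike.functional == "donor_create"
                else ("donor", "disrupted")
            )
        elif spike.functional == "acceptor_create":
            start = off - _ACCEPTOR_VAR
            gs[start : start + 14] = list(_ACCEPTOR_REF)
            plan.update(gs_ref=_ACCEPTOR_REF[_ACCEPTOR_VAR], gs_alt=_ACCEPTOR_ALT[_ACCEPTOR_VAR])
            plan["event"] = ("acceptor", "created")
        elif spike.functional in {"tfbs_gain", "tfbs_loss"}:
            alt_m, ref_m = _MEF2_ALT, _MEF2_REF
            if spike.functional == "tfbs_loss":
                alt_m, ref_m = ref_m, alt_m
            start = off - _MEF2_VAR
            gs[start : start + 10] = list(ref_m)
            plan.update(gs_ref=ref_m[_MEF2_VAR], gs_alt=alt_m[_MEF2_VAR])
            plan["event"] = (
                ("tfbs", "gained") if spike.functional == "tfbs_gain" else ("tfbs", "lost")
            )
        elif spike.functional == "ese_change":
            start = off - _ESE_VAR
            gs[start : start + 6] = list(_ESE_REF)
            plan.update(gs_ref=_ESE_REF[_ESE_VAR], gs_alt=_ESE_ALT[_ESE_VAR])
            plan["event"] = ("ESE", "created")
        elif spike.functional == "ess_change":
            start = off - _ESS_VAR
            gs[start : start + 6] = list(_ESS_REF)
            plan.update(gs_ref=_ESS_REF[_ESS_VAR], gs_alt=_ESS_ALT[_ESS_VAR])
            plan["event"] = ("ESS", "created")
        elif spike.functional == "silent":
            # third codon base: engineer a 4-fold degenerate codon (GGx)
            codon_start = off - 2
            gs[codon_start : codon_start + 3] = list("GGC")
            alts = "T"
            plan.update(gs_ref="C", gs_alt=alts, coding_effect="silent")
        elif spike.functional == "nonsense":
            codon_start = off - 2  # TAC -> TAA at the third base
            gs[codon_start : codon_start + 3] = list("TAC")
            plan.update(gs_ref="C", gs_alt="A", coding_effect="nonsense")
        elif spike.vclass == "SNP":
            ref = gs[off]
            plan.update(gs_ref=ref, gs_alt=_BASES[(_BASES.index(ref) + 1) % 4])
        plans.append(plan)

    gs_seq = "".join(gs)
    fwd = reverse_complement(gs_seq) if config.strand == "-" else gs_seq
    genome = {config.chrom: fwd}

    # ---- gene model on forward coordinates --------------------------------
    def to_fwd(offset: int) -> int:
        if config.strand == "-":
            return config.chrom_length - offset
        return offset + 1

    def interval(lo: int, hi: int) -> tuple[int, int]:
        a, b = to_fwd(lo), to_fwd(hi)
        return (min(a, b), max(a, b))

    exon_ivs = [interval(*comp["exon1"]), interval(*comp["exon2"]), interval(*comp["exon3"])]
    cds_lo = comp["exon1"][0] + config.utr5_len
    cds_hi = comp["exon3"][1] - config.utr3_len
    cds_iv = interval(cds_lo, cds_hi)
    gene = GeneModel(
        gene_id="MSTN_toy",
        chrom=config.chrom,
        strand=config.strand,
        exons=tuple(exon_ivs),
        cds_start=cds_iv[0],
        cds_end=cds_iv[1],
    )
    window = build_window(genome, gene, flank=config.flank)

    # ---- variants ----------------------------------------------------------
    variants: list[Variant] = []
    truth_spikes: list[dict] = []
    for plan in plans:
        spike: Spike = plan["spike"]
        if spike.vclass == "SNP":
            gs_ref, gs_alt = plan["gs_ref"], plan["gs_alt"]
            if config.strand == "-":
                pos = to_fwd(spike.offset)
                ref, alt = gs_ref.translate(_COMP), gs_alt.translate(_COMP)
            else:
                pos = spike.offset + 1
                ref, alt = gs_ref, gs_alt
        elif spike.vclass == "insertion":
            pos = to_fwd(spike.offset)
            ref = fwd[pos - 1]
            alt = ref + _random_seq(rng, spike.indel_len, config.gc)
        else:  # deletion
            pos = to_fwd(spike.offset)
            ref = fwd[pos - 1 : pos - 1 + spike.indel_len + 1]
            alt = ref[0]
        v = Variant(
            chrom=config.chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            genotypes=_genotypes_for(spike, config.n_samples, rng),
            samples=tuple(f"S{i:03d}" for i in range(config.n_samples)),
        )
        variants.append(v)
        audit = popgen.zygosity_audit(v)
        entry = {
            "name": spike.name,
            "vid": v.vid,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "vclass": v.vclass,
            "localization": str(classify_variant(v, gene, window)),
            "alt_count": v.allele_counts()[1],
            "carriers": audit.carriers,
            "all_het": audit.all_het,
            "functional": spike.functional,
        }
        if "event" in plan:
            entry["event"] = {"category": plan["event"][0], "kind": plan["event"][1]}
        if "coding_effect" in plan:
            entry["coding_effect"] = plan["coding_effect"]
        truth_spikes.append(entry)

    variants.sort(key=lambda v: v.pos)
    truth = {
        "chrom": config.chrom,
        "n_samples": config.n_samples,
        "window": {"start": window.start, "end": window.end, "length": window.length},
        "gene": {
            "gene_id": gene.gene_id,
            "strand": gene.strand,
            "exons": list(gene.exons),
            "cds_start": gene.cds_start,
            "cds_end": gene.cds_end,
        },
        "spikes": sorted(truth_spikes, key=lambda e: e["pos"]),
    }
    scenario = Scenario(
        config=config, genome=genome, gene=gene, window=window,
        variants=variants, truth=truth,
    )
    _verify_spikes(scenario)
    return scenario


def _verify_spikes(sc: Scenario) -> None:
    """Re-score every functional spike with the production code.

    Construction validation, not calibration: a failure means the embedded
    context collided with something and the scenario is refused.
    """
    matrices = load_splice_matrices()
    motif_sets = load_motif_sets()
    pwms = load_pwms()
    by_vid = {v.vid: v for v in sc.variants}
    for entry in sc.truth["spikes"]:
        event = entry.get("event")
        if event is None:
            if entry.get("coding_effect"):
                v = by_vid[entry["vid"]]
                ctx = coding_effects.codon_context(v, sc.gene, sc.window)
                if ctx.effect != entry["coding_effect"]:
                    raise SpikeError(
                        f"{entry['name']}: expected {entry['coding_effect']}, "
                        f"got {ctx.effect}"
                    )
            continue
        v = by_vid[entry["vid"]]
        cat, kind = event["category"], event["kind"]
        if cat == "tfbs":
            rep = differential_tfbs(sc.window, v, pwms)
            hits = rep.gained if kind == "gained" else rep.lost
            if not hits:
                raise SpikeError(f"{entry['name']}: no {kind} TFBS recovered")
        else:
            diffs = diff_splice_elements(sc.window, v, matrices, motif_sets)
            want = "created" if kind == "created" else "disrupted"
            if not any(d.category == cat and d.event == want for d in diffs):
                raise SpikeError(f"{entry['name']}: no {want} {cat} recovered")


# ---------------------------------------------------------------------------
# writers


def write_fasta(path: Path, genome: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(path: Path, gene: GeneModel) -> None:
    lines = ["##gff-version 3"]
    s, e = gene.span_start, gene.span_end
    st = gene.strand
    lines.append(
        f"{gene.chrom}\tlocuskit\tgene\t{s}\t{e}\t.\t{st}\t.\t"
        f"ID={gene.gene_id};Name={gene.gene_id}"
    )
    mrna = f"{gene.gene_id}.t1"
    lines.append(
        f"{gene.chrom}\tlocuskit\tmRNA\t{s}\t{e}\t.\t{st}\t.\t"
        f"ID={mrna};Parent={gene.gene_id}"
    )
    for i, (es, ee) in enumerate(sorted(gene.exons), start=1):
        lines.append(
            f"{gene.chrom}\tlocuskit\texon\t{es}\t{ee}\t.\t{st}\t.\t"
            f"ID={mrna}.exon{i};Parent={mrna}"
        )
    phase = 0
    for cs, ce in gene.cds_intervals:  # gene-sense order: phases accumulate
        lines.append(
            f"{gene.chrom}\tlocuskit\tCDS\t{cs}\t{ce}\t.\t{st}\t{phase}\t"
            f"ID={mrna}.cds;Parent={mrna}"
        )
        phase = (3 - ((ce - cs + 1 - phase) % 3)) % 3
    Path(path).write_text("\n".join(lines) + "\n")


def write_vcf(path: Path, variants: Sequence[Variant], chrom_len: int) -> None:
    if not variants:
        raise ValueError("no variants to write")
    samples = variants[0].samples
    head = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={variants[0].chrom},length={chrom_len}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    body = []
    for v in sorted(variants, key=lambda x: x.pos):
        gts = []
        for a1, a2 in v.genotypes:
            f1 = "." if a1 == MISSING else str(a1)
            f2 = "." if a2 == MISSING else str(a2)
            gts.append(f"{f1}/{f2}")
        body.append(
            f"{v.chrom}\t{v.pos}\t{v.vid}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(head + body) + "\n")


def make_locus(config: ScenarioConfig | None = None, out_dir: str | Path = ".") -> dict:
    """Generate a scenario and write FASTA/GFF3/VCF/truth JSON to *out_dir*.

    Returns a dict of the written paths plus the truth dict; byte-identical
    across runs with the same config.
    """
    sc = generate(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "toy_genome.fa",
        "gff3": out / "toy_gene.gff3",
        "vcf": out / "cohort.vcf",
        "truth": out / "truth.json",
    }
    write_fasta(paths["fasta"], sc.genome)
    write_gff3(paths["gff3"], sc.gene)
    write_vcf(paths["vcf"], sc.variants, len(sc.genome[sc.config.chrom]))
    paths["truth"].write_text(json.dumps(sc.truth, indent=1, sort_keys=True) + "\n")
    return {"scenario": sc, **{k: str(v) for k, v in paths.items()}}


# ---------------------------------------------------------------------------
# site-frequency-spectrum tiles for the neutrality-test stage


def make_sfs_tile(
    n_chrom: int,
    S: int,
    shape: str = "neutral",
    seed: int = 0,
    *,
    chrom: str = "5",
    tile_start: int = 1,
    tile_len: int = 2000,
) -> list[Variant]:
    """A block of biallelic SNPs with a chosen site-frequency spectrum.

    ``shape``: "neutral" draws derived counts k ∝ 1/k (the standard neutral
    expectation), "balanced" forces k = n/2 at every site, "skewed-rare"
    makes every site a singleton.  Positions are distinct and uniform in
    the tile.  ``n_chrom`` must be even (diploid samples).
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if S > tile_len:
        raise ValueError(f"S={S} exceeds tile capacity {tile_len}")
    if n_chrom % 2 or n_chrom < 4:
        raise ValueError("n_chrom must be even and >= 4")
    rng = np.random.default_rng(seed)
    if shape == "neutral":
        ks = np.arange(1, n_chrom)
        p = (1.0 / ks) / np.sum(1.0 / ks)
        counts = rng.choice(ks, size=S, p=p)
    elif shape == "balanced":
        counts = np.full(S, n_chrom // 2)
    elif shape == "skewed-rare":
        counts = np.ones(S, dtype=int)
    else:
        raise ValueError(f"unknown SFS shape {shape!r}")
    positions = np.sort(rng.choice(np.arange(tile_start, tile_start + tile_len),
                                   size=S, replace=False))
    n_samples = n_chrom // 2
    samples = tuple(f"S{i:03d}" for i in range(n_samples))
    out = []
    for pos, k in zip(positions, counts):
        hap = np.zeros(n_chrom, dtype=int)
        hap[rng.choice(n_chrom, size=int(k), replace=False)] = 1
        genos = tuple((int(hap[2 * i]), int(hap[2 * i + 1])) for i in range(n_samples))
        out.append(Variant(chrom=chrom, pos=int(pos), ref="A", alt="G",
                           genotypes=genos, samples=samples))
    return out
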