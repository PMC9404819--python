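"""Consensus values, splice-site scanning, element diffing and retention."""

import numpy as np
import pytest
from Bio.Data.CodonTable import standard_dna_table

from locuskit.errors import MalformedInputError, OutsideRegionError
from locuskit.splice_kit import (
    DEFAULT_THRESHOLDS,
    SpliceMatrix,
    consensus_value,
    diff_splice_elements,
    load_motif_sets,
    load_splice_matrices,
    scan_splice_sites,
    simulate_retention,
    translate,
)
from locuskit.variant_catalog import Variant

# independent translation oracle from the code table
_CODE = dict(standard_dna_table.forward_table)
_CODE.update({c: "*" for c in standard_dna_table.stop_codons})


def oracle_translate(seq):
    aa = []
    for i in range(0, len(seq) - 2, 3):
        a = _CODE[seq[i : i + 3]]
        if a == "*":
            return "".join(aa), True
        aa.append(a)
    return "".join(aa), False


def naive_cv_scan(seq, m, thr):
    out = set()
    for j in range(len(seq) - m.length + 1):
        win = seq[j : j + m.length]
        if "N" in win:
            continue
        t = sum(m.freqs[i, "ACGT".index(b)] for i, b in enumerate(win))
        cv = 100.0 * (t - m.sum_min) / (m.sum_max - m.sum_min)
        if cv >= thr:
            out.add((j, round(cv, 9)))
    return out


@pytest.fixture(scope="module")
def matrices():
    return load_splice_matrices()


class TestConsensusValue:
    def test_per_position_max_scores_100(self, matrices):
        for m in matrices.values():
            assert consensus_value(m.consensus, m) == pytest.approx(100.0)

    def test_per_position_min_scores_0(self, matrices):
        for m in matrices.values():
            worst = "".join("ACGT"[i] for i in np.argmin(m.freqs, axis=1))
            assert consensus_value(worst, m) == pytest.approx(0.0)

    def test_invariant_under_uniform_scaling(self, matrices):
        m = matrices["donor"]
        scaled = SpliceMatrix(kind="donor", freqs=m.freqs / 100.0,
                              boundary_index=m.boundary_index)
        for motif in ("CAGGTAAGT", "TATGTTATT", "GGTGTTAAT"):
            assert consensus_value(motif, scaled) == pytest.approx(
                consensus_value(motif, m), rel=1e-12)

    def test_length_mismatch_rejected(self, matrices):
        with pytest.raises(MalformedInputError):
            consensus_value("ACGT", matrices["donor"])

    def test_matrix_geometry(self, matrices):
        assert matrices["donor"].length == 9
        assert matrices["acceptor"].length == 14
        assert matrices["branch_point"].length == 7
        # invariant dinucleotides sit at the documented motif positions
        assert matrices["donor"].consensus[3:5] == "GT"
        assert matrices["acceptor"].consensus[10:12] == "AG"


class TestScanning:
    def test_embedded_consensus_found(self, matrices):
        m = matrices["donor"]
        seq = "G" * 30 + m.consensus + "G" * 30
        sites = scan_splice_sites(seq, {"donor": m}, threshold=65)
        assert any(s.offset == 30 and s.cv == pytest.approx(100.0) for s in sites)

    def test_homopolymer_background_below_threshold(self, matrices):
        # all-G sequence scores below 65 for every default matrix
        assert scan_splice_sites("G" * 120, matrices, DEFAULT_THRESHOLDS) == []

    def test_matches_naive_rescan(self, matrices):
        rng = np.random.default_rng(2)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        for kind, m in matrices.items():
            got = {
                (s.offset, round(s.cv, 9))
                for s in scan_splice_sites(seq, {kind: m}, threshold=50)
            }
            assert got == naive_cv_scan(seq, m, 50)


class TestDiffing:
    def _spike_variant(self, scenario, name):
        e = next(x for x in scenario.truth["spikes"] if x["name"] == name)
        return next(v for v in scenario.variants if v.vid == e["vid"])

    @pytest.mark.parametrize(
        "name,category,event",
        [
            ("intron1_donor_create", "donor", "created"),
            ("intron1_acceptor_create", "acceptor", "created"),
            ("intron2_donor_disrupt", "donor", "disrupted"),
            ("utr3_ese", "ESE", "created"),
            ("utr3_ess", "ESS", "created"),
        ],
    )
    def test_spiked_elements_recovered(self, scenario, name, category, event):
        v = self._spike_variant(scenario, name)
        diffs = diff_splice_elements(scenario.window, v)
        assert any(d.category == category and d.event == event for d in diffs)

    def test_allele_swap_involution(self, scenario):
        """Swapping alleles (on a window carrying the alt base) mirrors events."""
        from locuskit.locus_model import LocusWindow
        from locuskit.regulatory_diff import apply_allele

        v = self._spike_variant(scenario, "intron1_donor_create")
        w = scenario.window
        # rebuild the window with the alternate base as its reference
        i = v.pos - w.start
        alt_fwd = w.fwd_seq[:i] + v.alt + w.fwd_seq[i + len(v.ref):]
        w_alt = LocusWindow(chrom=w.chrom, start=w.start, end=w.end,
                            strand=w.strand, flank=w.flank, fwd_seq=alt_fwd,
                            gene=w.gene)
        swapped = Variant(chrom=v.chrom, pos=v.pos, ref=v.alt, alt=v.ref,
                          genotypes=v.genotypes, samples=v.samples)
        fwd = diff_splice_elements(scenario.window, v)
        rev = diff_splice_elements(w_alt, swapped)
        flip = {"created": "disrupted", "disrupted": "created"}
        assert {(d.category, flip[d.event], d.motif) for d in fwd} == {
            (d.category, d.event, d.motif) for d in rev}

    def test_identity_alleles_empty_diff(self, scenario):
        v = self._spike_variant(scenario, "intron1_donor_create")
        same = Variant(chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.ref,
                       genotypes=v.genotypes, samples=v.samples)
        assert diff_splice_elements(scenario.window, same) == []

    def test_intergenic_variant_rejected(self, scenario):
        v = self._spike_variant(scenario, "up_snp")
        with pytest.raises(OutsideRegionError):
            diff_splice_elements(scenario.window, v)


class TestTranslate:
    @pytest.mark.parametrize(
        "seq,protein,has_stop",
        [("ATGTAA", "M", True), ("ATGGCCGCC", "MAA", False)],
    )
    def test_known(self, seq, protein, has_stop):
        r = translate(seq)
        assert (r.seq, r.has_stop) == (protein, has_stop)

    def test_requires_start_codon(self):
        with pytest.raises(MalformedInputError):
            translate("TTGGCC")

    def test_matches_independent_oracle_on_random_orfs(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            body = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3 * 40)])
            seq = "ATG" + body
            r = translate(seq)
            o_seq, o_stop = oracle_translate(seq)
            assert (r.seq, r.has_stop) == (o_seq, o_stop)


class TestRetention:
    def test_toy_in_frame_stop_truncates(self):
        """Intron starting TAATAA in frame stops translation immediately."""
        from locuskit.locus_model import GeneModel, build_window

        # plus-strand toy: exon1 = ATG AAA (CDS), intron = TAATAA...,
        # exon2 = GGG TGA equivalent
        exon1, intron, exon2 = "ATGAAA", "TAATAACCCGGG", "GGGTAA"
        chrom = "T" * 10 + exon1 + intron + exon2 + "T" * 10
        g = GeneModel("toy", "t", "+", ((11, 16), (29, 34)), 11, 34)
        w = build_window({"t": chrom}, g, flank=5)
        out = simulate_retention(g, w, 6, which_intron=1)
        assert out.truncated
        assert out.protein == "MK"  # stop right at the retained TAA
        assert out.stop_offset_aa == 0  # no residues past the exon-1 peptide

    def test_retention_without_stop_extends_protein(self):
        from locuskit.locus_model import GeneModel, build_window

        exon1, intron, exon2 = "ATGAAA", "GGCGGCGGCGGC", "GGGTAA"
        chrom = "T" * 10 + exon1 + intron + exon2 + "T" * 10
        g = GeneModel("toy", "t", "+", ((11, 16), (29, 34)), 11, 34)
        w = build_window({"t": chrom}, g, flank=5)
        out = simulate_retention(g, w, 12, which_intron=1)
        assert not out.truncated
        assert len(out.protein) > out.canonical_protein_len

    def test_frame_arithmetic_shifts_by_one_per_codon(self):
        """Extending the retained prefix by 3 bases pre-stop adds one residue."""
        from locuskit.locus_model import GeneModel, build_window

        exon1, intron, exon2 = "ATGAAA", "GGCGGCGGTAAC", "GGGTAA"
        chrom = "T" * 10 + exon1 + intron + exon2 + "T" * 10
        g = GeneModel("toy", "t", "+", ((11, 16), (29, 34)), 11, 34)
        w = build_window({"t": chrom}, g, flank=5)
        r3 = simulate_retention(g, w, 3, which_intron=1)
        r6 = simulate_retention(g, w, 6, which_intron=1)
        assert r6.stop_offset_aa == r3.stop_offset_aa + 1

    def test_scenario_donor_site_geometry(self, scenario):
        """The spiked alt donor maps to the engineered retained length."""
        e = next(x for x in scenario.truth["spikes"]
                 if x["name"] == "intron1_donor_create")
        v = next(x for x in scenario.variants if x.vid == e["vid"])
        from locuskit.regulatory_diff import apply_allele

        matrices = load_splice_matrices()
        aseq = apply_allele(scenario.window, v, "alt")
        pad = 13
        lo = aseq.seg_offset - pad
        sites = scan_splice_sites(
            aseq.seq[lo : aseq.seg_offset + aseq.seg_len + pad],
            {"donor": matrices["donor"]}, DEFAULT_THRESHOLDS)
        assert sites
        from locuskit.splice_kit import SpliceSite

        s = max(sites, key=lambda x: x.cv)
        s = SpliceSite(kind=s.kind, offset=s.offset + lo, motif=s.motif, cv=s.cv)
        out = simulate_retention(scenario.gene, scenario.window, s, 1, variant=v)
        # spike sits 1000 bases into intron 1 and marks the motif's +1 base,
        # so the retained prefix is exactly the first 1000 intron bases
        assert out.retained_len == 1000
        assert isinstance(out.truncated, bool)

    def test_site_outside_intron_rejected(self, scenario):
        with pytest.raises(OutsideRegionError):
            simulate_retention(scenario.gene, scenario.window, 10 ** 6, 1)
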