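"""PWM loading, information weights, scanning oracle and allele diffing."""

import numpy as np
import pytest

from locuskit.errors import AlleleMismatchError, MatrixFormatError, OutsideRegionError
from locuskit.locus_model import reverse_complement
from locuskit.regulatory_diff import (
    PWM,
    apply_allele,
    differential_tfbs,
    load_muscle_tf_list,
    load_pwms,
    pwm_from_counts,
    scan_pwms,
)
from locuskit.variant_catalog import Variant

# ---------------------------------------------------------------------------
# naive full-scan oracle


def naive_scan(seq, pwms, threshold):
    """Rescore every offset on both strands with explicit Python loops."""
    hits = set()
    for pwm in pwms:
        L = pwm.length
        denom = sum(pwm.info[i] * pwm.freqs[i].max() for i in range(L))
        for target, strand in ((seq, "+"), (reverse_complement(seq), "-")):
            for j in range(len(target) - L + 1):
                win = target[j : j + L]
                if "N" in win:
                    continue
                s = sum(
                    pwm.info[i] * pwm.freqs[i, "ACGT".index(b)]
                    for i, b in enumerate(win)
                )
                if s / denom >= threshold:
                    off = j if strand == "+" else len(seq) - L - j
                    hits.add((pwm.matrix_id, strand, off, round(s / denom, 10)))
    return hits


class TestPWMConstruction:
    def test_uniform_column_zero_information(self):
        p = pwm_from_counts("m", "tf", np.array([[25, 25, 25, 25]] * 4))
        assert p.info == pytest.approx(np.zeros(4), abs=1e-12)

    def test_single_base_column_maximal_information(self):
        counts = np.array([[100, 0, 0, 0]] * 4)
        p = pwm_from_counts("m", "tf", counts, pseudocount=0.0001)
        assert p.info == pytest.approx(np.ones(4), abs=1e-2)

    def test_packaged_fixture_file_loads(self):
        pwms = load_pwms()
        assert len(pwms) == 6
        by_id = {p.matrix_id: p for p in pwms}
        assert by_id["M_MEF2_SYN"].length == 10
        assert by_id["M_MYOD_SYN"].length == 6
        assert all(
            np.allclose(p.freqs.sum(axis=1), 1.0) for p in pwms
        )

    def test_muscle_flagging_from_curated_list(self):
        muscle = load_muscle_tf_list()
        assert "MEF2" in muscle and len(muscle) == 10
        pwms = load_pwms()
        assert all(p.muscle_flag for p in pwms)  # demo pack is all-muscle

    def test_ragged_matrix_rejected(self):
        with pytest.raises(MatrixFormatError):
            pwm_from_counts("m", "tf", np.array([[1, 2, 3]]))


class TestScanning:
    def test_consensus_scores_one(self):
        pwms = load_pwms()
        mef2 = next(p for p in pwms if p.matrix_id == "M_MEF2_SYN")
        hits = scan_pwms("TT" + mef2.consensus + "TT", [mef2], threshold=0.999)
        plus = [h for h in hits if h.strand == "+"]
        assert len(plus) == 1
        assert plus[0].offset == 2
        assert plus[0].score == pytest.approx(1.0)

    def test_poly_a_vs_gc_matrix_no_hit(self):
        gc = pwm_from_counts("gc", "tf", np.array([[0, 50, 50, 0]] * 6))
        assert scan_pwms("A" * 50, [gc], threshold=0.85) == []

    def test_matches_naive_full_rescan(self):
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        pwms = load_pwms()
        got = {
            (h.matrix_id, h.strand, h.offset, round(h.score, 10))
            for h in scan_pwms(seq, pwms, threshold=0.8)
        }
        assert got == naive_scan(seq, pwms, 0.8)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(1)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        pwms = load_pwms()
        fwd = scan_pwms(seq, pwms, threshold=0.8)
        rev = scan_pwms(reverse_complement(seq), pwms, threshold=0.8)
        as_set = lambda hits, n: {
            (h.matrix_id, h.strand, h.offset, round(h.score, 9)) for h in hits
        }
        mirrored = {
            (m, "+-"[s == "+"], len(seq) - next(
                p.length for p in pwms if p.matrix_id == m) - o, sc)
            for m, s, o, sc in as_set(rev, len(seq))
        }
        assert as_set(fwd, len(seq)) == mirrored

    def test_windows_with_N_skipped(self):
        pwms = load_pwms()
        mef2 = next(p for p in pwms if p.matrix_id == "M_MEF2_SYN")
        # every scannable window of this 14-mer covers the N, so none scores
        seq = "TT" + mef2.consensus[:5] + "N" + mef2.consensus[6:] + "TT"
        assert scan_pwms(seq, [mef2], threshold=0.5) == []


class TestApplyAllele:
    def test_ref_identity(self, scenario):
        v = scenario.variants[0]
        a = apply_allele(scenario.window, v, "ref")
        assert a.seq == scenario.window.gene_sense_seq

    def test_snp_single_base_change(self, scenario):
        v = next(x for x in scenario.variants if x.vclass == "SNP")
        ref = apply_allele(scenario.window, v, "ref")
        alt = apply_allele(scenario.window, v, "alt")
        assert len(alt.seq) == len(ref.seq)
        diff = [i for i, (a, b) in enumerate(zip(ref.seq, alt.seq)) if a != b]
        assert diff == [alt.seg_offset]

    def test_insertion_lengthens_by_alt_minus_ref(self, scenario):
        v = next(x for x in scenario.variants if x.vclass == "insertion")
        alt = apply_allele(scenario.window, v, "alt")
        assert len(alt.seq) == scenario.window.length + len(v.alt) - len(v.ref)

    def test_offset_map_shifts_after_segment(self, scenario):
        v = next(x for x in scenario.variants if x.vclass == "insertion")
        alt = apply_allele(scenario.window, v, "alt")
        before = alt.seg_offset - 10
        after = alt.seg_offset + alt.replaced_len + 10
        assert alt.map_offset(before) == before
        assert alt.map_offset(after) == after + alt.shift

    def test_ref_mismatch_guard(self, scenario):
        v = scenario.variants[0]
        bad_ref = "A" if v.ref != "A" else "C"
        bad = Variant(chrom=v.chrom, pos=v.pos, ref=bad_ref, alt="G",
                      genotypes=v.genotypes, samples=v.samples)
        with pytest.raises(AlleleMismatchError):
            apply_allele(scenario.window, bad, "ref")


class TestDifferentialTFBS:
    def test_spiked_gain_recovered(self, scenario):
        e = next(x for x in scenario.truth["spikes"] if x["name"] == "tfbs_gain")
        v = next(x for x in scenario.variants if x.vid == e["vid"])
        rep = differential_tfbs(scenario.window, v, load_pwms())
        assert any(h.matrix_id == "M_MEF2_SYN" for h in rep.gained)
        assert rep.unique_matrix_count <= rep.n_differential

    def test_spiked_loss_recovered_with_muscle_flag(self, scenario):
        e = next(x for x in scenario.truth["spikes"] if x["name"] == "tfbs_loss")
        v = next(x for x in scenario.variants if x.vid == e["vid"])
        rep = differential_tfbs(scenario.window, v, load_pwms())
        assert any(h.matrix_id == "M_MEF2_SYN" for h in rep.lost)
        assert len(rep.muscle_subset) >= 1  # MEF2 is on the curated list

    def test_identity_variant_yields_empty_report(self, scenario):
        v = next(x for x in scenario.truth["spikes"] if x["name"] == "tfbs_gain")
        var = next(x for x in scenario.variants if x.vid == v["vid"])
        same = Variant(chrom=var.chrom, pos=var.pos, ref=var.ref, alt=var.ref,
                       genotypes=var.genotypes, samples=var.samples)
        rep = differential_tfbs(scenario.window, same, load_pwms())
        assert rep.gained == [] and rep.lost == []

    def test_variant_outside_promoter_rejected(self, scenario):
        e = next(x for x in scenario.truth["spikes"] if x["name"] == "down_snp")
        v = next(x for x in scenario.variants if x.vid == e["vid"])
        with pytest.raises(OutsideRegionError):
            differential_tfbs(scenario.window, v, load_pwms())

    def test_neighborhood_equals_full_scan_diff(self, scenario):
        """Diffing the variant neighborhood equals diffing full scans."""
        e = next(x for x in scenario.truth["spikes"] if x["name"] == "tfbs_gain")
        v = next(x for x in scenario.variants if x.vid == e["vid"])
        pwms = load_pwms()
        rep = differential_tfbs(scenario.window, v, pwms)
        # oracle: scan a 3 kb slab around the variant in both full sequences
        ref = apply_allele(scenario.window, v, "ref")
        alt = apply_allele(scenario.window, v, "alt")
        lo, hi = ref.seg_offset - 1500, ref.seg_offset + 1500
        full_ref = naive_scan(ref.seq[lo:hi], pwms, 0.85)
        full_alt = naive_scan(alt.seq[lo:hi], pwms, 0.85)
        gained = full_alt - full_ref
        lost = full_ref - full_alt
        assert len(gained) == len(rep.gained)
        assert len(lost) == len(rep.lost)
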