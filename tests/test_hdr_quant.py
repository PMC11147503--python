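import math

import numpy as np
import pytest

import ampedit as ae
from ampedit.hdr_quant import ReadLabel, classify_read, donor_edits_on_amplicon
from ampedit.synthetic_reads import FastqRead


def _aln(read_seq, amp, quals=None):
    r = FastqRead("r", "", read_seq, quals or tuple([30] * len(read_seq)))
    return ae.assign_amplicon(r, [amp])


@pytest.fixture(scope="module")
def hdr_setup(locus, designed_donor):
    amp, guide, _ = locus
    hdr_seq = ae.allele_from_donor(amp, designed_donor).sequence
    return amp, guide, designed_donor, hdr_seq


class TestClassifyRead:
    def test_hdr_allele_read_complete(self, hdr_setup):
        amp, guide, donor, hdr_seq = hdr_setup
        c = classify_read(_aln(hdr_seq, amp), guide, donor)
        assert c.label is ReadLabel.HDR_COMPLETE
        assert c.donor_matched == c.donor_total == 3

    def test_wt_read(self, hdr_setup):
        amp, guide, donor, _ = hdr_setup
        c = classify_read(_aln(amp.sequence, amp), guide, donor)
        assert c.label is ReadLabel.WT

    def test_cut_site_deletion_is_nhej(self, hdr_setup):
        amp, guide, donor, _ = hdr_setup
        cut = guide.cut_index
        read = amp.sequence[: cut - 2] + amp.sequence[cut + 3 :]
        c = classify_read(_aln(read, amp), guide, donor)
        assert c.label is ReadLabel.NHEJ_INDEL

    def test_partial_hdr(self, hdr_setup):
        # revert one donor base: 2 of 3 donor positions matched, no indel
        amp, guide, donor, hdr_seq = hdr_setup
        pos, _, ref = donor_edits_on_amplicon(donor)[0]
        read = hdr_seq[:pos] + amp.sequence[pos] + hdr_seq[pos + 1 :]
        c = classify_read(_aln(read, amp), guide, donor)
        assert c.label is ReadLabel.HDR_PARTIAL
        assert c.donor_matched == 2

    def test_low_quality_edit_position_forces_ambiguous(self, hdr_setup):
        amp, guide, donor, hdr_seq = hdr_setup
        pos, _, _ = donor_edits_on_amplicon(donor)[0]
        quals = [30] * len(hdr_seq)
        quals[pos] = 10
        c = classify_read(_aln(hdr_seq, amp, tuple(quals)), guide, donor)
        assert c.label is ReadLabel.AMBIGUOUS

    def test_non_covering_read_ambiguous(self, hdr_setup):
        amp, guide, donor, hdr_seq = hdr_setup
        c = classify_read(_aln(hdr_seq[:40], amp), guide, donor)
        assert c.label is ReadLabel.AMBIGUOUS

    def test_nhej_precedence_over_hdr(self, hdr_setup):
        # donor bases present AND a 5-nt deletion at the cut: NHEJ wins
        amp, guide, donor, hdr_seq = hdr_setup
        cut = guide.cut_index
        read = hdr_seq[: cut - 1] + hdr_seq[cut + 4 :]
        c = classify_read(_aln(read, amp), guide, donor)
        assert c.label is ReadLabel.NHEJ_INDEL

    def test_small_indel_below_threshold_ignored(self, hdr_setup):
        amp, guide, donor, _ = hdr_setup
        cut = guide.cut_index
        read = amp.sequence[:cut] + amp.sequence[cut + 1 :]  # 1-nt del
        assert classify_read(_aln(read, amp), guide, donor).label is ReadLabel.WT
        assert (
            classify_read(_aln(read, amp), guide, donor, min_indel_len=1).label
            is ReadLabel.NHEJ_INDEL
        )


class TestQuantifyEditing:
    def test_zero_error_recovers_realized_split(self, hdr_setup, clean_errors):
        amp, guide, donor, hdr_seq = hdr_setup
        hdr = ae.AlleleSpec("hdr", amp.id, hdr_seq, 0.94)
        wt = ae.AlleleSpec("wt", amp.id, amp.sequence, 0.06)
        reads = ae.simulate_reads([hdr, wt], 1000, clean_errors, seed=12)
        aligned = [ae.assign_amplicon(r, [amp]) for r in reads]
        q = ae.quantify_editing(aligned, guide, donor)
        truth = sum(1 for r in reads if "allele=hdr" in r.comment) / 1000
        assert q.n_ambiguous == 0
        assert q.fractions["HDR_complete"] == pytest.approx(truth)
        assert q.fractions["NHEJ_indel"] == 0.0

    def test_all_wt(self, hdr_setup, clean_errors):
        amp, guide, donor, _ = hdr_setup
        wt = ae.AlleleSpec("wt", amp.id, amp.sequence, 1.0)
        reads = ae.simulate_reads([wt], 200, clean_errors, seed=1)
        q = ae.quantify_editing([ae.assign_amplicon(r, [amp]) for r in reads], guide, donor)
        assert q.fractions["HDR_complete"] == 0.0
        assert q.fractions["NHEJ_indel"] == 0.0
        assert q.fractions["WT"] == 1.0

    def test_hdr_nhej_mixture_with_sub_errors(self, hdr_setup):
        # 80% HDR / 20% NHEJ (3-nt del) with 1% substitution error
        amp, guide, donor, hdr_seq = hdr_setup
        cut = guide.cut_index
        hdr = ae.AlleleSpec("hdr", amp.id, hdr_seq, 0.8)
        nhej = ae.make_allele(amp, [("del", cut - 1, cut + 2)], "nhej", 0.2)
        err = ae.ErrorModel(sub_rate=0.01, quality_mean=40, quality_sd=0)
        reads = ae.simulate_reads([hdr, nhej], 2000, err, seed=14)
        aligned = [a for a in (ae.assign_amplicon(r, [amp]) for r in reads) if a]
        q = ae.quantify_editing(aligned, guide, donor)
        truth_nhej = sum(1 for r in reads if "allele=nhej" in r.comment) / 2000
        sigma = math.sqrt(truth_nhej * (1 - truth_nhej) / q.n_total)
        assert abs(q.fractions["NHEJ_indel"] - truth_nhej) <= 3 * sigma
        hdr_est = q.fractions["HDR_complete"] + q.fractions["HDR_partial"]
        truth_hdr = 1 - truth_nhej
        assert abs(hdr_est - truth_hdr) <= 3 * math.sqrt(truth_hdr * (1 - truth_hdr) / q.n_total)

    def test_read_order_and_rc_invariance(self, hdr_setup, clean_errors):
        amp, guide, donor, hdr_seq = hdr_setup
        hdr = ae.AlleleSpec("hdr", amp.id, hdr_seq, 0.5)
        wt = ae.AlleleSpec("wt", amp.id, amp.sequence, 0.5)
        reads = ae.simulate_reads([hdr, wt], 300, clean_errors, seed=15, rc_fraction=0.0)
        aligned = [ae.assign_amplicon(r, [amp]) for r in reads]
        q1 = ae.quantify_editing(aligned, guide, donor)
        q2 = ae.quantify_editing(aligned[::-1], guide, donor)
        rc_reads = [
            FastqRead(r.read_id, r.comment, ae.reverse_complement(r.sequence), r.qualities[::-1])
            for r in reads
        ]
        q3 = ae.quantify_editing(
            [ae.assign_amplicon(r, [amp]) for r in rc_reads], guide, donor
        )
        assert q1.counts == q2.counts == q3.counts

    def test_no_classifiable_reads_raises(self, hdr_setup):
        amp, guide, donor, hdr_seq = hdr_setup
        short = _aln(hdr_seq[:30], amp)
        with pytest.raises(ValueError):
            ae.quantify_editing([short], guide, donor)


class TestDigestQuantify:
    def test_band_mass_modes(self):
        # only cut fragments with mass -> fraction 1
        assert ae.digest_quantify(band_masses=[(90, 0.0), (50, 3.0), (40, 2.0)], uncut_length=90) == 1.0
        assert ae.digest_quantify(band_masses=[(90, 5.0), (50, 3.0), (40, 2.0)], uncut_length=90) == 0.5

    def test_read_mode_mixture(self, clean_errors):
        rng = np.random.default_rng(6)
        wt_seq = "".join(rng.choice(list("ACGT"), 90))
        while "TCCGGA" in wt_seq or "TCCGGA" in ae.reverse_complement(wt_seq):
            wt_seq = "".join(rng.choice(list("ACGT"), 90))
        edited = wt_seq[:42] + "TCCGGA" + wt_seq[48:]
        amp = ae.AmpliconReference("a", wt_seq)
        mix = [
            ae.AlleleSpec("edited", "a", edited, 0.5),
            ae.AlleleSpec("wt", "a", wt_seq, 0.5),
        ]
        reads = ae.simulate_reads(mix, 4000, clean_errors, seed=16)
        frac = ae.digest_quantify(
            reads=[r.sequence for r in reads], wt_sequence=wt_seq, edited_sequence=edited
        )
        truth = sum(1 for r in reads if "allele=edited" in r.comment) / 4000
        assert frac == pytest.approx(truth)
        assert abs(frac - 0.5) <= 3 * math.sqrt(0.25 / 4000)

    def test_site_in_wt_invalidates_assay(self):
        with pytest.raises(ValueError, match="WT"):
            ae.digest_quantify(reads=["TCCGGA"], wt_sequence="AATCCGGAAT")

    def test_sequence_and_digest_modes_agree(self, locus, clean_errors):
        # the edited allele both carries donor bases and gains the site:
        # the two assays measure the same molecules
        amp, guide, _ = locus
        from ampedit.donor_design import DesignRequest, design_ssodn

        cut = guide.cut_index
        template = "TCCGGA"
        payload = tuple(
            (cut + 10 + k, template[k])
            for k in range(6)
            if amp.sequence[cut + 10 + k] != template[k]
        )
        donor = design_ssodn(DesignRequest(guide=guide, payload_edits=payload, mutate_pam=False), amp)
        edited = ae.allele_from_donor(amp, donor, "ed", 0.3)
        wt = ae.AlleleSpec("wt", amp.id, amp.sequence, 0.7)
        reads = ae.simulate_reads([edited, wt], 2000, clean_errors, seed=18)
        aligned = [ae.assign_amplicon(r, [amp]) for r in reads]
        q = ae.quantify_editing(aligned, guide, donor)
        seq_frac = q.fractions["HDR_complete"]
        dig_frac = ae.digest_quantify(
            reads=[a.seq for a in aligned], wt_sequence=amp.sequence,
        )
        sigma = math.sqrt(0.3 * 0.7 / 2000)
        assert abs(seq_frac - dig_frac) <= 3 * sigma


class TestSizeShift:
    def test_all_intron_reads(self, locus, clean_errors):
        amp, guide, _ = locus
        rng = np.random.default_rng(9)
        intron = "".join(rng.choice(list("ACGT"), 143))
        allele = ae.make_allele(amp, [("ins", guide.cut_index, intron)], "intron")
        reads = ae.simulate_reads([allele], 100, clean_errors, seed=3)
        aligned = [ae.assign_amplicon(r, [amp]) for r in reads]
        frac, ci, n = ae.size_shift_quantify(aligned, guide)
        assert frac == 1.0 and n == 100

    def test_wrong_insert_length_not_counted(self, locus, clean_errors):
        amp, guide, _ = locus
        rng = np.random.default_rng(9)
        allele = ae.make_allele(
            amp, [("ins", guide.cut_index, "".join(rng.choice(list("ACGT"), 100)))], "ins100"
        )
        reads = ae.simulate_reads([allele], 50, clean_errors, seed=3)
        aligned = [ae.assign_amplicon(r, [amp]) for r in reads]
        frac, _, n = ae.size_shift_quantify(aligned, guide, expected_insert_len=143, tol=0.1)
        assert frac == 0.0 and n == 50

    def test_mixture_with_ont_errors(self, locus):
        amp, guide, _ = locus
        rng = np.random.default_rng(9)
        intron = "".join(rng.choice(list("ACGT"), 143))
        allele = ae.make_allele(amp, [("ins", guide.cut_index, intron)], "intron", 0.2)
        wt = ae.AlleleSpec("wt", amp.id, amp.sequence, 0.8)
        reads = ae.simulate_reads([allele, wt], 2000, ae.ONT_LIKE, seed=20)
        aligned = [a for a in (ae.assign_amplicon(r, [amp]) for r in reads) if a]
        frac, _, n = ae.size_shift_quantify(aligned, guide)
        truth = sum(1 for r in reads if "allele=intron" in r.comment) / 2000
        assert abs(frac - truth) <= 3 * math.sqrt(truth * (1 - truth) / n)
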