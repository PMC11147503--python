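import numpy as np
import pytest

import ampedit as ae
from ampedit.donor_design import (
    AnchorError,
    CodingContext,
    DesignError,
    DesignRequest,
    anchor_donor,
    apply_donor,
    design_ssodn,
    enumerate_silent_substitutions,
    load_human_codon_usage,
    validate_donor,
)
from ampedit.sequence_model import EditClass

from oracles import find_all, translate

SPACER = "CGGCTGTGGTGTGAGTCCGG"


def _edited_allele_has_protospacer(edited: str, spacer: str, pam: str = "TGG") -> bool:
    target = spacer + pam
    return bool(find_all(edited, target) or find_all(ae.reverse_complement(edited), target))


class TestCodonUsage:
    def test_families_sum_to_one(self):
        usage = load_human_codon_usage()
        from ampedit.donor_design import GENETIC_CODE

        totals = {}
        for codon, f in usage.items():
            totals[GENETIC_CODE[codon]] = totals.get(GENETIC_CODE[codon], 0.0) + f
        assert all(abs(t - 1.0) < 1e-9 for t in totals.values())
        assert len(usage) == 64


class TestEnumerateSilent:
    def test_leucine_codon_offers_synonym(self):
        # CTG (Leu) at codon 2; CTC is a synonymous single-nt change
        amp = ae.AmpliconReference("a", "ATGCTGGCATAA")
        ctx = CodingContext("a", ((0, 12),), "+", 0)
        cands = enumerate_silent_substitutions(ctx, amp, (3, 6))
        alt_codons = {c.alt_codon for c in cands}
        assert "CTC" in alt_codons
        for c in cands:
            edited = amp.sequence[: c.edit.donor_pos] + c.edit.donor_base + amp.sequence[c.edit.donor_pos + 1 :]
            assert translate(edited) == translate(amp.sequence)

    def test_met_codon_has_no_candidates(self):
        amp = ae.AmpliconReference("a", "ATGCTGGCATAA")
        ctx = CodingContext("a", ((0, 12),), "+", 0)
        assert enumerate_silent_substitutions(ctx, amp, (0, 3)) == []

    def test_noncoding_region_empty(self):
        amp = ae.AmpliconReference("a", "ATGCTGGCATAAACGTACGT")
        ctx = CodingContext("a", ((0, 12),), "+", 0)
        assert enumerate_silent_substitutions(ctx, amp, (12, 20)) == []

    def test_sorted_by_usage_distance(self, locus):
        amp, guide, ctx = locus
        cands = enumerate_silent_substitutions(ctx, amp, guide.spacer_interval)
        dists = [c.usage_distance for c in cands]
        assert dists == sorted(dists)

    def test_minus_strand_coding(self):
        # same CDS read on the minus strand: candidates stay synonymous
        amp = ae.AmpliconReference("a", ae.reverse_complement("ATGCTGGCATAA"))
        ctx = CodingContext("a", ((0, 12),), "-", 0)
        cands = enumerate_silent_substitutions(ctx, amp, (0, 12))
        assert cands
        for c in cands:
            edited = amp.sequence[: c.edit.donor_pos] + c.edit.donor_base + amp.sequence[c.edit.donor_pos + 1 :]
            assert translate(ae.reverse_complement(edited)) == translate(
                ae.reverse_complement(amp.sequence)
            )


class TestDesignSsodn:
    def test_identity_design(self, locus):
        amp, guide, _ = locus
        req = DesignRequest(guide=guide, mutate_pam=False, n_spacer_silent=0)
        donor = design_ssodn(req, amp)
        span = (guide.cut_index - 45, guide.cut_index + 45)
        assert donor.full_sequence == amp.sequence[span[0] : span[1]]
        assert donor.edits == ()

    def test_silent_only_design(self, locus):
        # donor mutating only the spacer, not the PAM: all edits silent,
        # translation preserved (oracle: translate both alleles)
        amp, guide, ctx = locus
        req = DesignRequest(guide=guide, mutate_pam=False, n_spacer_silent=3)
        donor = design_ssodn(req, amp, ctx)
        assert len(donor.edits) == 3
        assert all(e.edit_class == EditClass.SPACER_SILENT for e in donor.edits)
        edited = apply_donor(amp, donor)
        assert translate(edited[1:142]) == translate(amp.sequence[1:142])
        assert not _edited_allele_has_protospacer(edited, SPACER)

    def test_full_design_mismatch_arithmetic(self, locus):
        amp, guide, ctx = locus
        payload_pos = guide.cut_index + 20
        alt = "A" if amp.sequence[payload_pos] != "A" else "C"
        req = DesignRequest(
            guide=guide, payload_edits=((payload_pos, alt),),
            mutate_pam=True, n_spacer_silent=2,
        )
        donor = design_ssodn(req, amp, ctx)
        edited = apply_donor(amp, donor)
        mismatches = sum(1 for a, b in zip(amp.sequence, edited) if a != b)
        assert mismatches == 1 + 1 + 2  # payload + PAM + silent, exactly
        assert not _edited_allele_has_protospacer(edited, SPACER)

    @pytest.mark.parametrize("n_silent,mutate_pam", [(0, True), (1, False), (2, True), (3, False)])
    def test_rescan_never_finds_protospacer(self, locus, n_silent, mutate_pam):
        amp, guide, ctx = locus
        if n_silent == 0 and not mutate_pam:
            pytest.skip("identity design retains the protospacer by definition")
        req = DesignRequest(guide=guide, mutate_pam=mutate_pam, n_spacer_silent=n_silent)
        donor = design_ssodn(req, amp, ctx)
        assert not _edited_allele_has_protospacer(apply_donor(amp, donor), SPACER)
        assert len(donor.edits) == n_silent + (1 if mutate_pam else 0)

    def test_silent_pam_impossible_raises(self):
        # frame 0 puts the PAM GG at the start of a Gly codon: GGx -> any
        # change of either G is non-synonymous, so silent disruption fails
        rng = np.random.default_rng(7)
        left = "".join(rng.choice(list("ACGT"), 60))
        amp = ae.AmpliconReference("a", left + SPACER + "TGG" + "A" * 61)
        guide = ae.locate_guide(amp, SPACER, "NGG")
        ctx = CodingContext("a", ((0, 144),), "+", 0)
        req = DesignRequest(guide=guide, mutate_pam=True)
        with pytest.raises(DesignError):
            design_ssodn(req, amp, ctx)
        donor = design_ssodn(
            DesignRequest(guide=guide, mutate_pam=True, allow_nonsilent_pam=True), amp, ctx
        )
        assert len(donor.edits) == 1

    def test_payload_outside_span_raises(self, locus):
        amp, guide, _ = locus
        with pytest.raises(DesignError):
            design_ssodn(
                DesignRequest(guide=guide, payload_edits=((0, "A"),), mutate_pam=False),
                amp,
            )

    def test_minus_strand_donor(self, locus):
        amp, guide, ctx = locus
        req = DesignRequest(guide=guide, mutate_pam=False, n_spacer_silent=2, donor_strand="-")
        donor = design_ssodn(req, amp, ctx)
        assert donor.strand == "-"
        plus = design_ssodn(
            DesignRequest(guide=guide, mutate_pam=False, n_spacer_silent=2), amp, ctx
        )
        assert donor.full_sequence == ae.reverse_complement(plus.full_sequence)


class TestAnchorDonor:
    def test_exact_substring_zero_edits(self, locus):
        amp, _, _ = locus
        donor = ae.parse_donor_notation(amp.sequence[20:80].lower(), "sub")
        anchored = anchor_donor(donor, amp)
        assert anchored.amplicon_start == 20
        assert anchored.edits == ()

    def test_reversion_round_trip(self, printed_donors):
        # build a WT amplicon by reverting the silent donor's uppercase
        # positions to arbitrary different bases, then re-anchor
        silent = ae.parse_donor_notation(printed_donors["SRSF2_silent_ssODN"], "silent")
        wt = list(silent.full_sequence)
        for e in silent.edits:
            wt[e.donor_pos] = "G" if e.donor_base != "G" else "C"
        amp = ae.AmpliconReference("wt", "".join(wt))
        anchored = anchor_donor(silent, amp)
        assert len(anchored.edits) == 3
        assert all(e.ref_base is not None and e.ref_base != e.donor_base for e in anchored.edits)

    def test_rc_amplicon_anchors_minus(self, printed_donors):
        silent = ae.parse_donor_notation(printed_donors["SRSF2_silent_ssODN"], "silent")
        wt = list(silent.full_sequence)
        for e in silent.edits:
            wt[e.donor_pos] = "G" if e.donor_base != "G" else "C"
        amp_rc = ae.AmpliconReference("wt_rc", ae.reverse_complement("".join(wt)))
        anchored = anchor_donor(silent, amp_rc)
        assert anchored.strand == "-"
        assert len(anchored.edits) == 3

    def test_no_anchor_raises(self, printed_donors):
        silent = ae.parse_donor_notation(printed_donors["SRSF2_silent_ssODN"], "silent")
        amp = ae.AmpliconReference("x", "ACGT" * 40)
        with pytest.raises(AnchorError):
            anchor_donor(silent, amp)


class TestValidateDonor:
    def test_bspei_gained_on_payload(self, locus):
        amp, guide, ctx = locus
        # find a donor-span position where a single substitution creates TCCGGA
        assert not find_all(amp.sequence, "TCCGGA")
        cut = guide.cut_index
        pos = cut + 10
        template = "TCCGGA"
        payload = [
            (pos + k, template[k])
            for k in range(6)
            if amp.sequence[pos + k] != template[k]
        ]
        req = DesignRequest(guide=guide, payload_edits=tuple(payload), mutate_pam=False)
        donor = design_ssodn(req, amp)
        report = validate_donor(donor, guide, amp, ctx, enzymes={"BspEI": "TCCGGA"})
        assert report.sites_gained["BspEI"] == 1
        assert report.sites_lost["BspEI"] == 0
        assert report.mismatches == len(payload)

    def test_printed_p95h_contains_one_bspei_site(self, printed_donors):
        # string-search oracle on the printed donors: the site the digest
        # assay relies on exists once in the P95H donor, never in the silent
        p95h = ae.parse_donor_notation(printed_donors["SRSF2_P95H_ssODN"])
        silent = ae.parse_donor_notation(printed_donors["SRSF2_silent_ssODN"])
        assert len(find_all(p95h.full_sequence, "TCCGGA")) == 1
        assert len(find_all(silent.full_sequence, "TCCGGA")) == 0

    def test_zero_edit_donor(self, locus):
        amp, guide, ctx = locus
        donor = design_ssodn(DesignRequest(guide=guide, mutate_pam=False), amp)
        report = validate_donor(donor, guide, amp, ctx, enzymes={"BspEI": "TCCGGA"})
        assert report.residual_protospacer is True
        assert report.translation_preserved is True
        assert report.mismatches == 0
        assert report.sites_gained["BspEI"] == 0 and report.sites_lost["BspEI"] == 0

    def test_designed_donor_report(self, locus, designed_donor):
        amp, guide, ctx = locus
        report = validate_donor(designed_donor, guide, amp, ctx, enzymes={"BspEI": "TCCGGA"})
        assert report.residual_protospacer is False
        assert report.translation_preserved is True
        assert report.mismatches == 3
        assert report.nonsilent_edits == ()
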