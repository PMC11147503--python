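"""ssODN donor design: payload edits, PAM disruption, and codon-usage-aware
silent spacer-breaking mutations.

The design goal is to prevent re-cutting of the repaired (HDR) allele: the
donor carries, beyond the desired payload substitutions, a PAM-disrupting
change and/or several synonymous ("silent") substitutions in the PAM-proximal
bases of the spacer. Silent candidates are ranked by how closely the
alternative codon's relative usage matches the wild-type codon's
("equivalent frequency"), so that designed donors perturb translation
kinetics as little as possible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources

from .sequence_model import (
    AmpliconReference,
    DonorSpec,
    EditClass,
    GuideTarget,
    PointEdit,
    iupac_match,
    locate_guide,
    reverse_complement,
)

__all__ = [
    "CodingContext",
    "DesignRequest",
    "SilentCandidate",
    "DonorReport",
    "load_human_codon_usage",
    "load_printed_donors",
    "enumerate_silent_substitutions",
    "design_ssodn",
    "validate_donor",
    "anchor_donor",
    "apply_donor",
    "AnchorError",
    "DesignError",
]

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class AnchorError(ValueError):
    pass


class DesignError(ValueError):
    pass


def load_human_codon_usage() -> dict[str, float]:
    """Bundled human codon usage, normalized so each synonymous family sums to 1."""
    raw: dict[str, float] = {}
    path = resources.files("ampedit.data") / "codon_usage_human.tsv"
    with path.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            raw[row["codon"]] = float(row["fraction"])
    totals: dict[str, float] = {}
    for codon, frac in raw.items():
        totals[GENETIC_CODE[codon]] = totals.get(GENETIC_CODE[codon], 0.0) + frac
    return {c: f / totals[GENETIC_CODE[c]] for c, f in raw.items()}


def load_printed_donors() -> dict[str, str]:
    """The four bundled SRSF2 ssODN donor strings (annotated notation)."""
    path = resources.files("ampedit.data") / "srsf2_donors.tsv"
    out: dict[str, str] = {}
    with path.open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["donor_id"]] = row["donor_string"]
    return out


def translate(seq: str) -> str:
    if len(seq) % 3:
        raise ValueError("CDS length not a multiple of 3")
    return "".join(GENETIC_CODE[seq[i : i + 3]] for i in range(0, len(seq), 3))


@dataclass(frozen=True)
class CodingContext:
    """Reading-frame annotation of an amplicon.

    ``cds_intervals`` are ordered plus-strand intervals; ``frame_offset`` is
    the number of bases of the first interval (in coding orientation) that
    complete an upstream codon. ``codon_usage`` maps codon to relative
    frequency within its synonymous family.
    """

    amplicon_id: str
    cds_intervals: tuple[tuple[int, int], ...]
    coding_strand: str = "+"
    frame_offset: int = 0
    codon_usage: dict[str, float] = field(default_factory=load_human_codon_usage)

    def __post_init__(self):
        if self.coding_strand not in "+-":
            raise ValueError("coding_strand must be '+' or '-'")
        if not 0 <= self.frame_offset <= 2:
            raise ValueError("frame_offset must be 0..2")
        # per-amino-acid frequencies must sum to 1
        totals: dict[str, float] = {}
        for codon, f in self.codon_usage.items():
            totals[GENETIC_CODE[codon]] = totals.get(GENETIC_CODE[codon], 0.0) + f
        for aa, t in totals.items():
            if abs(t - 1.0) > 1e-9:
                raise ValueError(f"codon usage for {aa!r} sums to {t}, not 1")

    def coding_positions(self) -> list[int]:
        """Amplicon positions in coding order (5'→3' of the coding strand)."""
        pos = [i for (a, b) in self.cds_intervals for i in range(a, b)]
        return pos if self.coding_strand == "+" else pos[::-1]

    def codon_map(self, amplicon_seq: str):
        """Map amplicon position -> (codon_index, offset, codon string).

        Codon strings are in coding orientation. Positions completing a
        partial upstream codon (frame_offset) and a trailing partial codon
        are omitted.
        """
        if self.cds_intervals and max(b for _, b in self.cds_intervals) > len(amplicon_seq):
            raise ValueError("CDS interval extends past the amplicon")
        order = self.coding_positions()[self.frame_offset :]
        order = order[: len(order) - len(order) % 3]
        mapping: dict[int, tuple[int, int, str]] = {}
        for ci in range(len(order) // 3):
            trip = order[3 * ci : 3 * ci + 3]
            codon = "".join(
                amplicon_seq[p] if self.coding_strand == "+"
                else reverse_complement(amplicon_seq[p])
                for p in trip
            )
            for off, p in enumerate(trip):
                mapping[p] = (ci, off, codon)
        return mapping


@dataclass(frozen=True)
class SilentCandidate:
    edit: PointEdit  # donor_pos holds the *amplicon* position here
    wt_codon: str
    alt_codon: str
    usage_distance: float


@dataclass(frozen=True)
class DesignRequest:
    guide: GuideTarget
    payload_edits: tuple[tuple[int, str], ...] = ()  # (amplicon pos, new base)
    mutate_pam: bool = True
    n_spacer_silent: int = 0
    spacer_region: int = 10  # PAM-proximal nt of the spacer considered for silent edits
    arm_len5: int = 45
    arm_len3: int = 45
    pt_bonds_per_end: int = 2
    donor_strand: str = "+"
    allow_nonsilent_pam: bool = False

    def __post_init__(self):
        if self.arm_len5 < 20 or self.arm_len3 < 20:
            raise ValueError("homology arms must be at least 20 nt")
        if self.n_spacer_silent < 0:
            raise ValueError("n_spacer_silent must be >= 0")


def enumerate_silent_substitutions(
    ctx: CodingContext,
    amplicon: AmpliconReference,
    region: tuple[int, int],
    pam_boundary: int | None = None,
) -> list[SilentCandidate]:
    """All synonymous single-nt substitutions inside ``region``.

    Sorted by |usage(WT codon) − usage(alt codon)| ascending; ties broken by
    proximity to ``pam_boundary`` (closest first) or, absent that, by
    position descending. A region with no coding overlap returns [].
    """
    cmap = ctx.codon_map(amplicon.sequence)
    out: list[SilentCandidate] = []
    for pos in range(*region):
        if pos not in cmap:
            continue
        _, off, codon = cmap[pos]
        aa = GENETIC_CODE[codon]
        ref_plus = amplicon.sequence[pos]
        for alt_plus in "ACGT":
            if alt_plus == ref_plus:
                continue
            alt_coding = alt_plus if ctx.coding_strand == "+" else reverse_complement(alt_plus)
            alt_codon = codon[:off] + alt_coding + codon[off + 1 :]
            if GENETIC_CODE[alt_codon] != aa:
                continue
            dist = abs(ctx.codon_usage.get(codon, 0.0) - ctx.codon_usage.get(alt_codon, 0.0))
            out.append(
                SilentCandidate(
                    edit=PointEdit(pos, alt_plus, ref_base=ref_plus,
                                   edit_class=EditClass.SPACER_SILENT),
                    wt_codon=codon,
                    alt_codon=alt_codon,
                    usage_distance=dist,
                )
            )
    if pam_boundary is not None:
        key = lambda c: (c.usage_distance, abs(c.edit.donor_pos - pam_boundary))
    else:
        key = lambda c: (c.usage_distance, -c.edit.donor_pos)
    return sorted(out, key=key)


def _spacer_proximal_region(guide: GuideTarget, length: int) -> tuple[int, int]:
    """The PAM-proximal ``length`` nt of the spacer, as a plus-strand interval."""
    s0, s1 = guide.spacer_interval
    length = min(length, s1 - s0)
    return (s1 - length, s1) if guide.strand == "+" else (s0, s0 + length)


def _pam_boundary(guide: GuideTarget) -> int:
    return guide.spacer_interval[1] if guide.strand == "+" else guide.spacer_interval[0]


def apply_donor(amplicon: AmpliconReference, donor: DonorSpec) -> str:
    """The HDR allele: the amplicon with the donor's edits substituted in."""
    if not donor.anchored:
        raise AnchorError("donor must be anchored to the amplicon first")
    seq = list(amplicon.sequence)
    for e in donor.edits:
        apos = donor.amplicon_start + e.donor_pos
        base = e.donor_base if donor.strand == "+" else reverse_complement(e.donor_base)
        if donor.strand == "-":
            apos = donor.amplicon_start + (len(donor.full_sequence) - 1 - e.donor_pos)
        seq[apos] = base
    return "".join(seq)


def anchor_donor(
    donor: DonorSpec,
    amplicon: AmpliconReference,
    guide: GuideTarget | None = None,
    ctx: CodingContext | None = None,
) -> DonorSpec:
    """Place a donor on an amplicon by its non-edit (lowercase-derived) positions.

    The placement must be unique over both strands. Each edit gains its
    ``ref_base``; classes are auto-assigned when a guide (PAM/spacer
    intervals) and coding context are available: PAM overlap →
    ``pam_disrupting``; inside the spacer and synonymous → ``spacer_silent``;
    otherwise ``payload``.
    """
    edit_pos = set(donor.edit_positions())
    n = len(donor.full_sequence)

    def matches_at(seq: str, start: int, dseq: str) -> bool:
        if start < 0 or start + n > len(seq):
            return False
        return all(
            seq[start + i] == dseq[i] for i in range(n) if i not in edit_pos
        )

    hits: list[tuple[str, int]] = []
    for strand in "+-":
        dseq = donor.full_sequence
        epos = edit_pos
        if strand == "-":
            dseq = reverse_complement(donor.full_sequence)
            epos = {n - 1 - p for p in edit_pos}
        for start in range(len(amplicon.sequence) - n + 1):
            if all(
                amplicon.sequence[start + i] == dseq[i]
                for i in range(n)
                if i not in epos
            ):
                hits.append((strand, start))
    if len(hits) != 1:
        raise AnchorError(
            f"donor {donor.donor_id!r}: {len(hits)} anchor sites (need exactly 1)"
        )
    strand, start = hits[0]

    cmap = ctx.codon_map(amplicon.sequence) if ctx is not None else {}
    new_edits = []
    for e in donor.edits:
        if strand == "+":
            apos = start + e.donor_pos
            alt_plus = e.donor_base
        else:
            apos = start + (n - 1 - e.donor_pos)
            alt_plus = reverse_complement(e.donor_base)
        ref_plus = amplicon.sequence[apos]
        ref_donor = ref_plus if strand == "+" else reverse_complement(ref_plus)
        cls = e.edit_class
        if guide is not None or ctx is not None:
            cls = EditClass.PAYLOAD
            if guide is not None and guide.pam_interval[0] <= apos < guide.pam_interval[1]:
                cls = EditClass.PAM_DISRUPTING
            elif (
                guide is not None
                and guide.spacer_interval[0] <= apos < guide.spacer_interval[1]
                and apos in cmap
            ):
                _, off, codon = cmap[apos]
                alt_coding = alt_plus if ctx.coding_strand == "+" else reverse_complement(alt_plus)
                alt_codon = codon[:off] + alt_coding + codon[off + 1 :]
                if GENETIC_CODE[alt_codon] == GENETIC_CODE[codon]:
                    cls = EditClass.SPACER_SILENT
        new_edits.append(
            PointEdit(e.donor_pos, e.donor_base,
                      ref_base=ref_donor if ref_donor != e.donor_base else None,
                      edit_class=cls)
        )
    return replace(
        donor,
        edits=tuple(new_edits),
        strand=strand,
        amplicon_id=amplicon.id,
        amplicon_start=start,
    )


def _count_sites(seq: str, site: str) -> int:
    """Occurrences of a recognition site on either strand (palindromes once)."""
    def count(s: str, pat: str) -> int:
        c = i = 0
        while (i := s.find(pat, i)) != -1:
            c += 1
            i += 1
        return c

    total = count(seq, site)
    rc = reverse_complement(site)
    if rc != site:
        total += count(seq, rc)
    return total


@dataclass(frozen=True)
class DonorReport:
    residual_protospacer: bool
    translation_preserved: bool | None
    sites_gained: dict[str, int]
    sites_lost: dict[str, int]
    mismatches: int
    nonsilent_edits: tuple[int, ...]  # amplicon positions of non-synonymous edits


def validate_donor(
    donor: DonorSpec,
    guide: GuideTarget,
    amplicon: AmpliconReference,
    ctx: CodingContext | None = None,
    enzymes: dict[str, str] | None = None,
) -> DonorReport:
    """Check a donor against re-cutting, translation, and restriction sites.

    ``residual_protospacer`` is True iff a perfect spacer+PAM match survives
    on either strand of the edited allele. ``enzymes`` maps name →
    recognition sequence (e.g. ``{"BspEI": "TCCGGA"}``).
    """
    if not donor.anchored:
        donor = anchor_donor(donor, amplicon, guide=guide, ctx=ctx)
    edited = apply_donor(amplicon, donor)
    edited_amp = AmpliconReference(id=amplicon.id + "_edited", sequence=edited)
    try:
        hit = locate_guide(
            edited_amp, guide.spacer, guide.pam_pattern, require_pam=True,
            guide_id=guide.guide_id,
        )
    except Exception:
        hit = object()  # multiple hits still count as residual
    residual = hit is not None

    translation_ok: bool | None = None
    nonsilent: list[int] = []
    if ctx is not None:
        cmap = ctx.codon_map(amplicon.sequence)
        emap = ctx.codon_map(edited)
        changed = {p for p in cmap if amplicon.sequence[p] != edited[p]}
        for p in sorted(changed):
            if GENETIC_CODE[emap[p][2]] != GENETIC_CODE[cmap[p][2]]:
                nonsilent.append(p)
        silent_classed = [
            e for e in donor.edits if e.edit_class == EditClass.SPACER_SILENT
        ]
        translation_ok = not any(
            (donor.amplicon_start + (e.donor_pos if donor.strand == "+"
             else len(donor.full_sequence) - 1 - e.donor_pos)) in nonsilent
            for e in silent_classed
        )

    gained: dict[str, int] = {}
    lost: dict[str, int] = {}
    for name, site in (enzymes or {}).items():
        before = _count_sites(amplicon.sequence, site.upper())
        after = _count_sites(edited, site.upper())
        gained[name] = max(0, after - before)
        lost[name] = max(0, before - after)

    mismatches = sum(
        1 for a, b in zip(amplicon.sequence, edited) if a != b
    )
    return DonorReport(
        residual_protospacer=residual,
        translation_preserved=translation_ok,
        sites_gained=gained,
        sites_lost=lost,
        mismatches=mismatches,
        nonsilent_edits=tuple(nonsilent),
    )


def _pam_disruption_candidates(
    guide: GuideTarget,
    amplicon: AmpliconReference,
    ctx: CodingContext | None,
) -> list[SilentCandidate]:
    """Substitutions in the PAM that break the pattern, silent ones first."""
    p0, p1 = guide.pam_interval
    pam_plus = amplicon.sequence[p0:p1]
    pattern = guide.pam_pattern if guide.strand == "+" else reverse_complement(guide.pam_pattern)
    cmap = ctx.codon_map(amplicon.sequence) if ctx is not None else {}
    cands: list[SilentCandidate] = []
    for i, pos in enumerate(range(p0, p1)):
        for alt in "ACGT":
            if alt == amplicon.sequence[pos]:
                continue
            mutated = pam_plus[:i] + alt + pam_plus[i + 1 :]
            if iupac_match(pattern, mutated):
                continue  # does not break the PAM
            silent = False
            dist = float("inf")
            if pos in cmap:
                _, off, codon = cmap[pos]
                alt_coding = alt if ctx.coding_strand == "+" else reverse_complement(alt)
                alt_codon = codon[:off] + alt_coding + codon[off + 1 :]
                if GENETIC_CODE[alt_codon] == GENETIC_CODE[codon]:
                    silent = True
                    dist = abs(
                        ctx.codon_usage.get(codon, 0.0)
                        - ctx.codon_usage.get(alt_codon, 0.0)
                    )
            cands.append(
                SilentCandidate(
                    edit=PointEdit(pos, alt, ref_base=amplicon.sequence[pos],
                                   edit_class=EditClass.PAM_DISRUPTING),
                    wt_codon="", alt_codon="",
                    usage_distance=0.0 if not silent and ctx is None else dist,
                )
            )
    # silent (finite distance) candidates first, then by distance
    return sorted(cands, key=lambda c: (c.usage_distance == float("inf"), c.usage_distance))


def design_ssodn(
    req: DesignRequest,
    amplicon: AmpliconReference,
    ctx: CodingContext | None = None,
) -> DonorSpec:
    """Design an ssODN donor around the guide's cut site.

    The donor spans ``[cut − arm_len5, cut + arm_len3)`` on the amplicon plus
    strand and carries, exactly: the payload edits, one PAM-disrupting edit
    when ``mutate_pam``, and ``n_spacer_silent`` synonymous substitutions in
    the PAM-proximal spacer region. Raises :class:`DesignError` when a silent
    PAM disruption is required but impossible (unless
    ``allow_nonsilent_pam``), or when silent candidates run out.
    """
    guide = req.guide
    cut = guide.cut_index
    span = (cut - req.arm_len5, cut + req.arm_len3)
    if span[0] < 0 or span[1] > len(amplicon.sequence):
        raise DesignError("donor span extends past the amplicon")

    edits_by_pos: dict[int, PointEdit] = {}
    for pos, base in req.payload_edits:
        if not (span[0] <= pos < span[1]):
            raise DesignError(f"payload edit at {pos} outside donor span {span}")
        if base == amplicon.sequence[pos]:
            raise DesignError(f"payload edit at {pos} equals the reference base")
        edits_by_pos[pos] = PointEdit(pos, base, ref_base=amplicon.sequence[pos],
                                      edit_class=EditClass.PAYLOAD)

    if req.mutate_pam:
        cands = [
            c for c in _pam_disruption_candidates(guide, amplicon, ctx)
            if c.edit.donor_pos not in edits_by_pos
            and span[0] <= c.edit.donor_pos < span[1]
        ]
        silent_cands = [c for c in cands if c.usage_distance != float("inf")]
        if ctx is not None and not silent_cands and not req.allow_nonsilent_pam:
            if not cands:
                raise DesignError("no substitution can disrupt the PAM inside the donor span")
            raise DesignError(
                "PAM overlaps coding sequence and no synonymous disruption exists; "
                "pass allow_nonsilent_pam=True to accept a non-silent change"
            )
        chosen = (silent_cands or cands)[0]
        edits_by_pos[chosen.edit.donor_pos] = chosen.edit

    if req.n_spacer_silent:
        if ctx is None:
            raise DesignError("silent spacer mutations require a CodingContext")
        region = _spacer_proximal_region(guide, req.spacer_region)
        cands = enumerate_silent_substitutions(
            ctx, amplicon, region, pam_boundary=_pam_boundary(guide)
        )
        placed = 0
        used_codons = {
            ctx.codon_map(amplicon.sequence).get(p, (None,))[0] for p in edits_by_pos
        }
        cmap = ctx.codon_map(amplicon.sequence)
        for c in cands:
            if placed == req.n_spacer_silent:
                break
            pos = c.edit.donor_pos
            ci = cmap[pos][0]
            if pos in edits_by_pos or ci in used_codons:
                continue  # one edit per codon keeps every silent call truly silent
            edits_by_pos[pos] = c.edit
            used_codons.add(ci)
            placed += 1
        if placed < req.n_spacer_silent:
            raise DesignError(
                f"only {placed} silent spacer substitutions available in the "
                f"PAM-proximal region (requested {req.n_spacer_silent})"
            )

    core = list(amplicon.sequence[span[0] : span[1]])
    donor_edits = []
    for pos in sorted(edits_by_pos):
        e = edits_by_pos[pos]
        dpos = pos - span[0]
        core[dpos] = e.donor_base
        donor_edits.append(replace(e, donor_pos=dpos))
    full = "".join(core)
    n = len(full)
    bonds = tuple(range(1, req.pt_bonds_per_end + 1)) + tuple(
        range(n - req.pt_bonds_per_end, n)
    ) if req.pt_bonds_per_end else ()

    donor = DonorSpec(
        donor_id=f"{guide.guide_id}_ssodn",
        full_sequence=full,
        edits=tuple(donor_edits),
        pt_bonds=bonds,
        strand="+",
        amplicon_id=amplicon.id,
        amplicon_start=span[0],
    )
    if req.donor_strand == "-":
        donor = _flip_donor(donor)
    return donor


def _flip_donor(donor: DonorSpec) -> DonorSpec:
    """Re-express an anchored donor on the opposite strand."""
    n = len(donor.full_sequence)
    new_edits = tuple(
        PointEdit(
            n - 1 - e.donor_pos,
            reverse_complement(e.donor_base),
            ref_base=None if e.ref_base is None else reverse_complement(e.ref_base),
            edit_class=e.edit_class,
        )
        for e in donor.edits
    )
    new_bonds = tuple(sorted(n - b for b in donor.pt_bonds))
    return replace(
        donor,
        full_sequence=reverse_complement(donor.full_sequence),
        edits=tuple(sorted(new_edits, key=lambda e: e.donor_pos)),
        pt_bonds=new_bonds,
        strand="-" if donor.strand == "+" else "+",
    )
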