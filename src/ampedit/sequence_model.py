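"""Core DNA data model: amplicons, guides, HDR donors, and coordinate conventions.

All coordinates are 0-based with half-open intervals ``[start, end)``.
1-based inclusive coordinates appear only in rendered TSV reports.

Donor notation
--------------
ssODN donors are written in a compact annotated string form:

* lowercase letter — base matches the reference,
* UPPERCASE letter — edited base (a substitution relative to reference),
* ``*`` — phosphorothioate bond between the two flanking bases.

``parse_donor_notation`` and ``render_donor_notation`` round-trip this form
byte-identically.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AmpliconReference",
    "GuideTarget",
    "PointEdit",
    "EditClass",
    "DonorSpec",
    "DonorParseError",
    "GuideLocateError",
    "reverse_complement",
    "parse_donor_notation",
    "render_donor_notation",
    "locate_guide",
    "cut_site",
    "iupac_match",
    "read_fasta",
    "write_fasta",
]

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes allowed); an involution."""
    bad = set(seq) - set("ACGTRYSWKMBDHVNacgtryswkmbdhvn")
    if bad:
        raise ValueError(f"non-IUPAC character(s) in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(pattern: str, seq: str) -> bool:
    """True if ``seq`` matches the same-length IUPAC ``pattern``."""
    if len(pattern) != len(seq):
        return False
    return all(s in IUPAC_SETS.get(p.upper(), "") for p, s in zip(pattern, seq.upper()))


class EditClass(str, enum.Enum):
    PAYLOAD = "payload"
    PAM_DISRUPTING = "pam_disrupting"
    SPACER_SILENT = "spacer_silent"
    OTHER = "other"


@dataclass(frozen=True)
class AmpliconReference:
    """A reference amplicon: the amplified locus reads are mapped back to."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"amplicon {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"amplicon {self.id!r}: illegal characters {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    @property
    def has_n(self) -> bool:
        return "N" in self.sequence

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GuideTarget:
    """A guide (spacer + PAM) located on an amplicon.

    ``cut_index`` is a between-base index on the plus strand of the amplicon:
    the SpCas9 blunt cut 3 nt 5' of the PAM. ``target_window`` defaults to
    spacer ∪ PAM.
    """

    guide_id: str
    spacer: str
    pam_pattern: str
    amplicon_id: str
    strand: str
    spacer_interval: tuple[int, int]
    pam_interval: tuple[int, int]
    cut_index: int
    target_window: tuple[int, int]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        s0, s1 = self.spacer_interval
        if not (s0 < self.cut_index < s1):
            raise ValueError("cut_index must lie strictly inside spacer_interval")


@dataclass(frozen=True)
class PointEdit:
    """A single-nucleotide substitution carried by a donor.

    ``ref_base`` is None until the donor is anchored to an amplicon.
    """

    donor_pos: int
    donor_base: str
    ref_base: str | None = None
    edit_class: EditClass = EditClass.OTHER

    def __post_init__(self):
        if self.donor_base not in "ACGT":
            raise ValueError(f"edit base must be A/C/G/T, got {self.donor_base!r}")
        if self.ref_base is not None and self.ref_base == self.donor_base:
            raise ValueError("donor_base must differ from known ref_base")


@dataclass(frozen=True)
class DonorSpec:
    """An ssODN HDR donor: full sequence, classified point edits, PT bonds.

    ``pt_bonds`` are inter-base bond indices: bond ``b`` sits between bases
    ``b-1`` and ``b`` of ``full_sequence``. When anchored to an amplicon
    (:func:`ampedit.donor_design.anchor_donor`), ``amplicon_id``,
    ``amplicon_start`` and ``strand`` describe the placement of the donor on
    the plus strand of that amplicon and every edit gains its ``ref_base``.
    """

    donor_id: str
    full_sequence: str
    edits: tuple[PointEdit, ...] = ()
    pt_bonds: tuple[int, ...] = ()
    strand: str = "+"
    amplicon_id: str | None = None
    amplicon_start: int | None = None

    def __post_init__(self):
        n = len(self.full_sequence)
        for b in self.pt_bonds:
            if not (1 <= b <= n - 1):
                raise ValueError(f"pt bond index {b} outside [1, {n - 1}]")
        for e in self.edits:
            if not (0 <= e.donor_pos < n):
                raise ValueError(f"edit position {e.donor_pos} outside donor")

    @property
    def anchored(self) -> bool:
        return self.amplicon_start is not None

    def edit_positions(self) -> tuple[int, ...]:
        return tuple(e.donor_pos for e in self.edits)

    def with_edits(self, edits) -> "DonorSpec":
        return replace(self, edits=tuple(edits))


class DonorParseError(ValueError):
    pass


class GuideLocateError(ValueError):
    pass


def parse_donor_notation(donor_string: str, donor_id: str = "donor") -> DonorSpec:
    """Parse the annotated donor string form into a :class:`DonorSpec`.

    Raises :class:`DonorParseError` naming the offending offset on illegal
    characters or misplaced ``*``.
    """
    s = donor_string.strip()
    if not s:
        raise DonorParseError("empty donor string")
    bases: list[str] = []
    edits: list[PointEdit] = []
    bonds: list[int] = []
    prev_star = False
    for off, ch in enumerate(s):
        if ch == "*":
            if not bases:
                raise DonorParseError(f"offset {off}: '*' before any base")
            if prev_star:
                raise DonorParseError(f"offset {off}: adjacent '*'")
            bonds.append(len(bases))  # bond between bases[-1] and the next base
            prev_star = True
            continue
        if ch.upper() not in "ACGT":
            raise DonorParseError(f"offset {off}: illegal character {ch!r}")
        if ch.isupper():
            edits.append(PointEdit(donor_pos=len(bases), donor_base=ch))
        bases.append(ch.upper())
        prev_star = False
    if prev_star:
        raise DonorParseError("'*' may not be the last character")
    return DonorSpec(
        donor_id=donor_id,
        full_sequence="".join(bases),
        edits=tuple(edits),
        pt_bonds=tuple(bonds),
    )


def render_donor_notation(donor: DonorSpec) -> str:
    """Inverse of :func:`parse_donor_notation` (byte-identical round trip)."""
    edit_pos = set(donor.edit_positions())
    bond_set = set(donor.pt_bonds)
    out: list[str] = []
    for i, base in enumerate(donor.full_sequence):
        if i in bond_set:
            out.append("*")
        out.append(base if i in edit_pos else base.lower())
    return "".join(out)


def _pam_ok(amplicon_seq: str, pam_pattern: str, start: int, end: int) -> bool:
    if start < 0 or end > len(amplicon_seq):
        return False
    return iupac_match(pam_pattern, amplicon_seq[start:end])


def locate_guide(
    amplicon: AmpliconReference,
    spacer: str,
    pam_pattern: str = "NGG",
    require_pam: bool = True,
    guide_id: str = "guide",
    window_pad: int = 0,
) -> GuideTarget | None:
    """Exact search for the spacer (optionally followed by PAM) on both strands.

    Returns the unique :class:`GuideTarget` or ``None`` when absent; multiple
    hits raise :class:`GuideLocateError` listing positions. Intervals are
    always reported on the plus strand of the amplicon.
    """
    spacer = spacer.upper()
    if len(spacer) < 10:
        raise ValueError("spacer must be at least 10 nt")
    for ch in pam_pattern.upper():
        if ch not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC code in PAM pattern: {ch!r}")
    seq = amplicon.sequence
    if not seq:
        raise GuideLocateError("empty amplicon")
    plen = len(pam_pattern)
    hits: list[tuple[str, int]] = []  # (strand, spacer start on + strand)

    # plus strand: spacer then PAM immediately 3'
    i = seq.find(spacer)
    while i != -1:
        if not require_pam or _pam_ok(seq, pam_pattern, i + len(spacer), i + len(spacer) + plen):
            hits.append(("+", i))
        i = seq.find(spacer, i + 1)
    # minus strand: rc(spacer) on +, PAM (as rc of pattern) immediately 5'
    rcs = reverse_complement(spacer)
    rc_pam = reverse_complement(pam_pattern)
    i = seq.find(rcs)
    while i != -1:
        if not require_pam or _pam_ok(seq, rc_pam, i - plen, i):
            hits.append(("-", i))
        i = seq.find(rcs, i + 1)

    if not hits:
        return None
    if len(hits) > 1:
        raise GuideLocateError(f"ambiguous guide target, hits at {hits}")
    strand, start = hits[0]
    s_iv = (start, start + len(spacer))
    if strand == "+":
        p_iv = (s_iv[1], s_iv[1] + plen)
        cut = s_iv[1] - 3
    else:
        p_iv = (s_iv[0] - plen, s_iv[0])
        cut = s_iv[0] + 3
    lo = min(s_iv[0], p_iv[0]) - window_pad
    hi = max(s_iv[1], p_iv[1]) + window_pad
    window = (max(0, lo), min(len(seq), hi))
    return GuideTarget(
        guide_id=guide_id,
        spacer=spacer,
        pam_pattern=pam_pattern.upper(),
        amplicon_id=amplicon.id,
        strand=strand,
        spacer_interval=s_iv,
        pam_interval=p_iv,
        cut_index=cut,
        target_window=window,
    )


def cut_site(target: GuideTarget) -> int:
    """Between-base cut index: SpCas9 blunt cut 3 nt 5' of the PAM boundary."""
    s0, s1 = target.spacer_interval
    return s1 - 3 if target.strand == "+" else s0 + 3


def read_fasta(path) -> list[AmpliconReference]:
    """Read amplicon references from FASTA; IDs must be unique."""
    refs = [
        AmpliconReference(id=rec.id, sequence=str(rec.seq), description=rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    ids = [r.id for r in refs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate amplicon IDs in FASTA")
    return refs


def write_fasta(refs, path) -> None:
    records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description) for r in refs
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
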