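"""On-target editing-outcome quantification in three assay modes.

* **sequence** — per-read classification into WT / complete HDR / partial
  HDR / NHEJ indel / ambiguous, from donor-edit positions and an indel window
  around the cut site;
* **digest** — the RFLP fraction from reads carrying an introduced
  restriction site, or from gel band masses (mass-weighting equals the molar
  fraction because cutting conserves mass);
* **size_shift** — the fraction of reads carrying a single insertion of the
  expected length (e.g. a 143 bp synthetic intron; some descriptions round
  this to ~100 bp, so the length stays configurable) overlapping the cut.

Precedence for per-read labels is NHEJ > HDR_complete > HDR_partial > WT:
a read with both donor bases and a cut-site indel is NHEJ-contaminated.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from statsmodels.stats.proportion import proportion_confint

from .alignment_io import AlignedRead
from .sequence_model import (
    AmpliconReference,
    DonorSpec,
    GuideTarget,
    reverse_complement,
)

__all__ = [
    "ReadLabel",
    "ReadClassification",
    "EditingQuant",
    "classify_read",
    "quantify_editing",
    "digest_quantify",
    "digest_limit_of_detection",
    "size_shift_quantify",
    "donor_edits_on_amplicon",
]


class ReadLabel(str, enum.Enum):
    WT = "WT"
    HDR_COMPLETE = "HDR_complete"
    HDR_PARTIAL = "HDR_partial"
    NHEJ_INDEL = "NHEJ_indel"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    label: ReadLabel
    donor_matched: int
    donor_total: int
    indel_in_window: bool


@dataclass(frozen=True)
class EditingQuant:
    mode: str
    n_total: int  # classifiable (non-ambiguous) reads
    n_ambiguous: int
    counts: dict[str, int]
    fractions: dict[str, float]
    ci95: dict[str, tuple[float, float]]  # Wilson intervals


def donor_edits_on_amplicon(donor: DonorSpec) -> list[tuple[int, str, str | None]]:
    """(amplicon position, expected donor base on +, ref base on +) per edit."""
    if not donor.anchored:
        raise ValueError("donor must be anchored to an amplicon")
    n = len(donor.full_sequence)
    out = []
    for e in donor.edits:
        if donor.strand == "+":
            pos = donor.amplicon_start + e.donor_pos
            base = e.donor_base
            ref = e.ref_base
        else:
            pos = donor.amplicon_start + (n - 1 - e.donor_pos)
            base = reverse_complement(e.donor_base)
            ref = None if e.ref_base is None else reverse_complement(e.ref_base)
        out.append((pos, base, ref))
    return sorted(out)


def _read_base_at(aln: AlignedRead, pos: int) -> tuple[str | None, int | None]:
    """(base, quality) the read places at reference position ``pos``;
    (None, None) if not covered, ("-", None) if deleted."""
    qi = 0
    rj = aln.ref_start
    for op, n in aln.ops:
        if op == "S":
            qi += n
        elif op == "M":
            if rj <= pos < rj + n:
                k = pos - rj
                return aln.seq[qi + k], aln.base_qualities[qi + k]
            qi += n
            rj += n
        elif op == "D":
            if rj <= pos < rj + n:
                return "-", None
            rj += n
        elif op == "I":
            qi += n
    return None, None


def _indels_overlapping(aln: AlignedRead, w0: int, w1: int, min_len: int = 1) -> bool:
    qi = 0
    rj = aln.ref_start
    for op, n in aln.ops:
        if op == "S":
            qi += n
        elif op == "M":
            qi += n
            rj += n
        elif op == "D":
            if n >= min_len and rj < w1 and rj + n > w0:
                return True
            rj += n
        elif op == "I":
            # insertion anchored between rj-1 and rj
            if n >= min_len and w0 <= rj <= w1:
                return True
            qi += n
    return False


def _covers(aln: AlignedRead, w0: int, w1: int) -> bool:
    return aln.ref_start <= w0 and aln.ref_end >= w1


def classify_read(
    aln: AlignedRead,
    guide: GuideTarget,
    donor: DonorSpec,
    window_pad: int = 4,
    min_base_quality: int = 16,
    min_indel_len: int = 3,
) -> ReadClassification:
    """Label one aligned read by its editing outcome.

    The NHEJ window is ``[cut - window_pad, cut + window_pad)``; only indels
    of at least ``min_indel_len`` nt count as NHEJ evidence (1–2 nt indels
    are the dominant nanopore error mode; set 1 for error-free data). Reads
    not fully covering the window and every donor-edit position are
    ambiguous, as are reads where any donor position has base quality below
    ``min_base_quality`` (that position is uncounted, so HDR completeness
    cannot be established).
    """
    edits = donor_edits_on_amplicon(donor)
    cut = guide.cut_index
    w0, w1 = cut - window_pad, cut + window_pad
    span = (min(w0, edits[0][0]), max(w1, edits[-1][0] + 1)) if edits else (w0, w1)
    if not _covers(aln, *span):
        return ReadClassification(aln.read_id, ReadLabel.AMBIGUOUS, 0, len(edits), False)

    indel = _indels_overlapping(aln, w0, w1, min_indel_len)
    matched = 0
    counted = 0
    for pos, donor_base, _ in edits:
        base, qual = _read_base_at(aln, pos)
        if base == "-":
            continue  # deletion over an edit position: indel logic governs
        if base is None or (qual is not None and qual < min_base_quality):
            counted = -1  # uncounted position: completeness undecidable
            break
        counted += 1
        if base == donor_base:
            matched += 1

    if indel:
        label = ReadLabel.NHEJ_INDEL
    elif counted < 0 or (counted == 0 and edits):
        label = ReadLabel.AMBIGUOUS
    elif matched == counted and counted == len(edits):
        label = ReadLabel.HDR_COMPLETE
    elif matched > 0:
        label = ReadLabel.HDR_PARTIAL
    else:
        label = ReadLabel.WT
    return ReadClassification(aln.read_id, label, max(0, matched), len(edits), indel)


_LABELS = [l.value for l in ReadLabel if l is not ReadLabel.AMBIGUOUS]


def quantify_editing(
    alignments: list[AlignedRead],
    guide: GuideTarget,
    donor: DonorSpec,
    window_pad: int = 4,
    min_base_quality: int = 16,
    min_indel_len: int = 3,
) -> EditingQuant:
    """Sequence-mode editing fractions over non-ambiguous reads, Wilson 95% CIs."""
    counts = dict.fromkeys(_LABELS, 0)
    n_amb = 0
    for aln in alignments:
        c = classify_read(aln, guide, donor, window_pad, min_base_quality, min_indel_len)
        if c.label is ReadLabel.AMBIGUOUS:
            n_amb += 1
        else:
            counts[c.label.value] += 1
    n = sum(counts.values())
    if n == 0:
        raise ValueError("no classifiable reads")
    fractions = {k: v / n for k, v in counts.items()}
    ci = {
        k: tuple(proportion_confint(v, n, alpha=0.05, method="wilson"))
        for k, v in counts.items()
    }
    return EditingQuant("sequence", n, n_amb, counts, fractions, ci)


def digest_quantify(
    reads: list[str] | None = None,
    enzyme_site: str = "TCCGGA",
    wt_sequence: str | None = None,
    edited_sequence: str | None = None,
    band_masses: list[tuple[float, float]] | None = None,
    uncut_length: float | None = None,
    length_tol: float = 0.05,
) -> float:
    """RFLP cut fraction.

    Read mode: the fraction of reads containing the intact recognition site
    (checked on both strands); requires that the site is absent from the WT
    allele and present in the edited allele when those are supplied.
    Band-mass mode: ``sum(mass of cut bands) / sum(all masses)`` where bands
    within ``length_tol`` of ``uncut_length`` are uncut; mass-weighting makes
    this the molar fraction since cutting conserves mass.
    """
    site = enzyme_site.upper()
    rc = reverse_complement(site)

    def has_site(seq: str) -> bool:
        s = seq.upper()
        return site in s or (rc != site and rc in s)

    if band_masses is not None:
        if uncut_length is None:
            raise ValueError("band-mass mode needs the expected uncut length")
        total = sum(m for _, m in band_masses)
        if total <= 0:
            raise ValueError("total band mass must be positive")
        cut = sum(
            m for length, m in band_masses
            if abs(length - uncut_length) > length_tol * uncut_length
        )
        return cut / total

    if reads is None:
        raise ValueError("supply reads or band_masses")
    if wt_sequence is not None and has_site(wt_sequence):
        raise ValueError("recognition site present in the WT allele: assay invalid")
    if edited_sequence is not None and not has_site(edited_sequence):
        raise ValueError("recognition site absent from the edited allele")
    if not reads:
        raise ValueError("no reads supplied")
    return sum(1 for r in reads if has_site(r)) / len(reads)


def digest_limit_of_detection(
    wt_sequence: str,
    edited_sequence: str,
    fractions: tuple[float, ...] = (0.0, 0.005, 0.01, 0.02, 0.05),
    n_molecules: int = 10000,
    seeds: tuple[int, ...] = tuple(range(1, 11)),
    enzyme_site: str = "TCCGGA",
    tolerance_pp: float = 0.5,
    alpha: float = 0.05,
    min_seed_successes: int | None = None,
):
    """Assay-validation dilution series for the restriction-digest readout.

    For each nonzero mixture fraction and each seed, ``n_molecules`` are
    drawn from the WT/edited mixture (no sequencing error), quantified with
    :func:`digest_quantify`, and compared against the matched 0% mixture: a
    seed *succeeds* when the estimate is within ``tolerance_pp`` percentage
    points of the true fraction AND Fisher's exact test separates the
    site-carrying counts from the 0% run at ``alpha``. Returns
    ``(limit_of_detection_percent, per_fraction_table)`` where the limit is
    the smallest fraction succeeding in at least ``min_seed_successes`` seeds
    (default: all but one).
    """
    from scipy.stats import fisher_exact

    from .sequence_model import AmpliconReference
    from .synthetic_reads import AlleleSpec, ErrorModel, simulate_reads

    if min_seed_successes is None:
        min_seed_successes = len(seeds) - 1
    amp_id = "lod_amplicon"
    AmpliconReference(amp_id, wt_sequence)  # validates the sequence
    clean = ErrorModel(quality_mean=40, quality_sd=0)
    table: dict[float, dict] = {}
    zero_counts: dict[int, int] = {}
    for frac in sorted(fractions):
        successes = 0
        estimates = []
        for seed in seeds:
            mix = [
                AlleleSpec("edited", amp_id, edited_sequence, frac),
                AlleleSpec("wt", amp_id, wt_sequence, 1.0 - frac),
            ]
            reads = [
                r.sequence
                for r in simulate_reads(mix, n_molecules, clean, seed=seed, rc_fraction=0.0)
            ]
            est = digest_quantify(
                reads=reads, enzyme_site=enzyme_site,
                wt_sequence=wt_sequence, edited_sequence=edited_sequence,
            )
            estimates.append(est)
            k = round(est * n_molecules)
            if frac == 0.0:
                zero_counts[seed] = k
                continue
            k0 = zero_counts.get(seed, 0)
            _, p = fisher_exact(
                [[k, n_molecules - k], [k0, n_molecules - k0]], alternative="greater"
            )
            recovered = abs(est - frac) * 100.0 <= tolerance_pp
            if recovered and p < alpha:
                successes += 1
        table[frac] = {
            "estimates": estimates,
            "mean_estimate": sum(estimates) / len(estimates),
            "successes": successes,
        }
    lod = next(
        (
            f * 100.0
            for f in sorted(table)
            if f > 0.0 and table[f]["successes"] >= min_seed_successes
        ),
        float("nan"),
    )
    return lod, table


def size_shift_quantify(
    alignments: list[AlignedRead],
    guide: GuideTarget,
    expected_insert_len: int = 143,
    tol: float = 0.1,
    window_pad: int = 4,
) -> tuple[float, tuple[float, float], int]:
    """Fraction of cut-window-covering reads with a single insertion of the
    expected length (within ``±tol``) overlapping the cut window.

    Returns (fraction, Wilson 95% CI, n covering reads).
    """
    if expected_insert_len <= 0:
        raise ValueError("expected_insert_len must be positive")
    cut = guide.cut_index
    w0, w1 = cut - window_pad, cut + window_pad
    lo = expected_insert_len * (1 - tol)
    hi = expected_insert_len * (1 + tol)
    n_cover = 0
    n_integrated = 0
    for aln in alignments:
        if not _covers(aln, w0, w1):
            continue
        n_cover += 1
        rj = aln.ref_start
        hits = 0
        ok_len = 0
        for op, n in aln.ops:
            if op == "M" or op == "D":
                rj += n
            if op == "I" and w0 <= rj <= w1:
                hits += 1
                if lo <= n <= hi:
                    ok_len += 1
        if hits == 1 and ok_len == 1:
            n_integrated += 1
    if n_cover == 0:
        return float("nan"), (float("nan"), float("nan")), 0
    frac = n_integrated / n_cover
    ci = tuple(proportion_confint(n_integrated, n_cover, alpha=0.05, method="wilson"))
    return frac, ci, n_cover
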