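"""Seeded simulators: amplicon reads from allele mixtures under a
nanopore-like error model, diploid clone genotypes under the donor-mixture
model, and limiting-dilution wells under the single-hit Poisson model.

These generators define the study conditions for the whole pipeline's tests:
every simulation takes an explicit seed (or ``numpy.random.Generator``) and is
byte-reproducible. True allele labels ride in the FASTQ comment (after the
first whitespace) so downstream tools ignore them but tests can recover them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence_model import AmpliconReference, DonorSpec, reverse_complement
from .donor_design import apply_donor

__all__ = [
    "AlleleSpec",
    "ErrorModel",
    "FastqRead",
    "GENOTYPE_CLASSES",
    "make_allele",
    "allele_from_donor",
    "simulate_reads",
    "simulate_clones",
    "simulate_ld_wells",
    "write_fastq",
    "read_fastq",
]

GENOTYPE_CLASSES = (
    "hom_mut", "het_mut_silent", "hom_silent", "mut_wt", "silent_wt", "unedited",
)


@dataclass(frozen=True)
class AlleleSpec:
    """One allele of a mixture: a base amplicon plus modifications.

    Modifications are tuples on the *unmodified* amplicon coordinates:
    ``("sub", pos, base)``, ``("ins", pos, seq)`` (inserted before ``pos``),
    ``("del", start, end)``.
    """

    allele_id: str
    base_amplicon_id: str
    sequence: str
    fraction: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must be in [0, 1]")


@dataclass(frozen=True)
class ErrorModel:
    """Per-base independent error model caricaturing nanopore (R10-like) reads.

    ``sub_rate``/``ins_rate``/``del_rate`` are per-base event probabilities;
    indel lengths are geometric with success parameter ``indel_length_p``;
    the deletion rate is multiplied by ``homopolymer_del_multiplier`` inside
    homopolymer runs of length >= 3. Base qualities are drawn from a clipped
    normal and emitted as Phred+33.
    """

    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    indel_length_p: float = 0.75
    homopolymer_del_multiplier: float = 3.0
    quality_mean: float = 25.0
    quality_sd: float = 6.0

    def __post_init__(self):
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("rates must be in [0, 1)")
        if self.homopolymer_del_multiplier < 1.0:
            raise ValueError("homopolymer multiplier must be >= 1")


#: A plausible default for R10-class nanopore amplicon reads.
ONT_LIKE = ErrorModel(sub_rate=0.01, ins_rate=0.003, del_rate=0.005)


@dataclass(frozen=True)
class FastqRead:
    read_id: str
    comment: str
    sequence: str
    qualities: tuple[int, ...]


def make_allele(
    amplicon: AmpliconReference,
    modifications,
    allele_id: str = "allele",
    fraction: float = 1.0,
) -> AlleleSpec:
    """Apply substitutions/insertions/deletions (coordinates on the unmodified
    amplicon) to build an allele sequence. Overlapping modifications error."""
    spans = []
    for m in modifications:
        kind = m[0]
        if kind == "sub":
            spans.append((m[1], m[1] + 1))
        elif kind == "ins":
            spans.append((m[1], m[1]))
        elif kind == "del":
            spans.append((m[1], m[2]))
        else:
            raise ValueError(f"unknown modification kind {kind!r}")
        if spans[-1][0] < 0 or spans[-1][1] > len(amplicon.sequence):
            raise ValueError(f"modification {m} out of bounds")
    for (a0, a1), (b0, b1) in zip(sorted(spans), sorted(spans)[1:]):
        if b0 < a1:
            raise ValueError("overlapping modifications")

    seq = amplicon.sequence
    out = []
    cursor = 0
    for m in sorted(modifications, key=lambda m: m[1]):
        if m[0] == "sub":
            out.append(seq[cursor : m[1]])
            out.append(m[2].upper())
            cursor = m[1] + 1
        elif m[0] == "ins":
            out.append(seq[cursor : m[1]])
            out.append(m[2].upper())
            cursor = m[1]
        else:  # del
            out.append(seq[cursor : m[1]])
            cursor = m[2]
    out.append(seq[cursor:])
    return AlleleSpec(allele_id, amplicon.id, "".join(out), fraction)


def allele_from_donor(
    amplicon: AmpliconReference,
    donor: DonorSpec,
    allele_id: str | None = None,
    fraction: float = 1.0,
) -> AlleleSpec:
    """The HDR allele: reference with the (anchored) donor edits substituted."""
    return AlleleSpec(
        allele_id or f"{donor.donor_id}_hdr",
        amplicon.id,
        apply_donor(amplicon, donor),
        fraction,
    )


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _homopolymer_mask(seq: str) -> np.ndarray:
    """True at positions inside a homopolymer run of length >= 3."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    mask = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        j = i
        while j < n and arr[j] == arr[i]:
            j += 1
        if j - i >= 3:
            mask[i:j] = True
        i = j
    return mask


# for each base byte, its three possible substitution targets
_SUB_TARGETS = {
    ord("A"): b"CGT", ord("C"): b"AGT", ord("G"): b"ACT", ord("T"): b"ACG",
}


def _mutate(seq: str, err: ErrorModel, rng: np.random.Generator) -> str:
    """Apply the error model to one molecule: deletions, then substitutions on
    surviving bases, then insertions at junction points."""
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    keep = np.ones(n, dtype=bool)

    if err.del_rate:
        rate = np.where(
            _homopolymer_mask(seq),
            err.del_rate * err.homopolymer_del_multiplier,
            err.del_rate,
        )
        for s in np.nonzero(rng.random(n) < rate)[0]:
            if keep[s]:
                length = int(rng.geometric(err.indel_length_p))
                keep[s : s + length] = False

    if err.sub_rate:
        for s in np.nonzero((rng.random(n) < err.sub_rate) & keep)[0]:
            arr[s] = _SUB_TARGETS[arr[s]][int(rng.integers(0, 3))]

    inserts: dict[int, str] = {}
    if err.ins_rate:
        for p in np.nonzero(rng.random(n + 1) < err.ins_rate)[0]:
            length = int(rng.geometric(err.indel_length_p))
            inserts[int(p)] = "".join(
                "ACGT"[j] for j in rng.integers(0, 4, size=length)
            )

    if not inserts and keep.all():
        return arr.tobytes().decode()
    pieces = []
    last = 0
    for p in sorted(inserts):
        pieces.append(arr[last:p][keep[last:p]].tobytes().decode())
        pieces.append(inserts[p])
        last = p
    pieces.append(arr[last:][keep[last:]].tobytes().decode())
    return "".join(pieces)


def simulate_reads(
    mixture: list[AlleleSpec],
    n_reads: int,
    err: ErrorModel = ErrorModel(),
    seed=0,
    rc_fraction: float = 0.5,
    read_prefix: str = "read",
) -> list[FastqRead]:
    """Simulate full-span amplicon reads from an allele mixture.

    Allele counts are Multinomial(n_reads, fractions); ``rc_fraction`` of the
    reads are emitted reverse-complemented (nanopore amplicons arrive in both
    orientations). Reproducible: identical (mixture, n_reads, err, seed)
    give identical output.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    fracs = np.array([a.fraction for a in mixture], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"mixture fractions sum to {fracs.sum()}, not 1")
    rng = _as_rng(seed)
    reads: list[FastqRead] = []
    if n_reads == 0:
        return reads
    choice = rng.choice(len(mixture), size=n_reads, p=fracs)
    for k in range(n_reads):
        allele = mixture[choice[k]]
        seq = _mutate(allele.sequence, err, rng) if (
            err.sub_rate or err.ins_rate or err.del_rate
        ) else allele.sequence
        strand = "-" if rng.random() < rc_fraction else "+"
        if strand == "-":
            seq = reverse_complement(seq)
        if err.quality_sd == 0:
            q = int(min(41, max(2, round(err.quality_mean))))
            quals = (q,) * len(seq)
        else:
            quals = tuple(
                np.clip(
                    np.rint(rng.normal(err.quality_mean, err.quality_sd, size=len(seq))),
                    2, 41,
                ).astype(int).tolist()
            )
        reads.append(
            FastqRead(
                read_id=f"{read_prefix}_{k:06d}",
                comment=f"allele={allele.allele_id} strand={strand}",
                sequence=seq,
                qualities=quals,
            )
        )
    return reads


def write_fastq(reads: list[FastqRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id} {r.comment}\n{r.sequence}\n+\n{qual}\n")


def read_fastq(path) -> list[FastqRead]:
    reads = []
    with open(path) as fh:
        while True:
            header = fh.readline().rstrip("\n")
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            name, _, comment = header[1:].partition(" ")
            reads.append(
                FastqRead(name, comment, seq, tuple(ord(c) - 33 for c in qual))
            )
    return reads


def simulate_clones(
    p_mutant: float,
    h: float,
    n_clones: int,
    seed=0,
) -> dict[str, int]:
    """Diploid clone genotypes under the donor-mixture model.

    Each of the two alleles is independently HDR-edited with probability
    ``h``; an edited allele takes the mutant donor identity with probability
    ``p_mutant``, else the silent donor. Returns counts over
    :data:`GENOTYPE_CLASSES`.
    """
    if not (0.0 <= p_mutant <= 1.0 and 0.0 <= h <= 1.0):
        raise ValueError("p_mutant and h must be in [0, 1]")
    rng = _as_rng(seed)
    edited = rng.random((n_clones, 2)) < h
    mutant = (rng.random((n_clones, 2)) < p_mutant) & edited
    n_edit = edited.sum(axis=1)
    n_mut = mutant.sum(axis=1)
    counts = dict.fromkeys(GENOTYPE_CLASSES, 0)
    for ne, nm in zip(n_edit, n_mut):
        if ne == 2:
            key = ("hom_silent", "het_mut_silent", "hom_mut")[nm]
        elif ne == 1:
            key = "mut_wt" if nm == 1 else "silent_wt"
        else:
            key = "unedited"
        counts[key] += 1
    return counts


def simulate_ld_wells(
    frequency_per_cell: float,
    doses: list[tuple[float, int]],
    seed=0,
) -> list[tuple[float, int, int]]:
    """Positive/negative wells under the single-hit Poisson model.

    ``P(well negative | dose d) = exp(-f * d)``. ``doses`` is a list of
    ``(cells_per_well, n_wells)``; returns ``(dose, n_wells, n_negative)``.
    """
    if frequency_per_cell < 0:
        raise ValueError("frequency must be >= 0")
    rng = _as_rng(seed)
    out = []
    for dose, n_wells in doses:
        p_neg = float(np.exp(-frequency_per_cell * dose))
        n_neg = int(rng.binomial(n_wells, p_neg))
        out.append((dose, n_wells, n_neg))
    return out
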