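"""Read-to-amplicon assignment and pairwise alignment.

The native aligner is an affine-gap "glocal" dynamic program: reference
flanks are free and read ends are soft-clipped only when the score favors
it (local in both sequences, which is exactly that behavior under positive
match score). It is banded around the main diagonal with automatic band
widening when the optimal path touches the band edge, and falls back to the
full matrix for small problems. Indels are left-aligned post hoc so pileup
and window-overlap logic see canonical coordinates. Pre-aligned reads in SAM
(e.g. from an external long-read mapper) can substitute via :func:`read_sam`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .sequence_model import AmpliconReference, reverse_complement
from .synthetic_reads import FastqRead

__all__ = [
    "AlignParams",
    "AlignedRead",
    "align_read",
    "assign_amplicon",
    "write_sam",
    "read_sam",
]

log = logging.getLogger(__name__)

_NEG = -(2**30)
_FULL_THRESHOLD = 4096  # m*n at or below this: use the full matrix outright


_SCALE = 4  # internal integer scale so quarter-point gap extends stay exact


@dataclass(frozen=True)
class AlignParams:
    """Two-piece affine scoring: a gap of length L costs
    ``min(gap_open + L*gap_extend, long_gap_open + L*long_gap_extend)``
    (all penalties positive-cost, stored negative). The long-gap class keeps
    large insertions (e.g. a 143 bp intron) cheaper than soft-clipping."""

    match: float = 2
    mismatch: float = -4
    gap_open: float = -4
    gap_extend: float = -2
    long_gap_open: float = -20
    long_gap_extend: float = -0.25
    band: int | None = None  # None: 2*|len(q)-len(r)| + 32, then widen on demand
    min_score: float = 30  # assignment floor; below it a read is unassigned

    def scaled(self) -> tuple[int, int, int, int, int, int]:
        vals = (self.match, self.mismatch, self.gap_open, self.gap_extend,
                self.long_gap_open, self.long_gap_extend)
        out = tuple(round(v * _SCALE) for v in vals)
        for v, s in zip(vals, out):
            if abs(v * _SCALE - s) > 1e-9:
                raise ValueError("alignment scores must be multiples of 0.25")
        return out


@dataclass(frozen=True)
class AlignedRead:
    """A read aligned to the plus strand of one amplicon.

    ``seq`` and ``base_qualities`` are stored in reference (plus-strand)
    orientation. ``ops`` is the ordered CIGAR-like operation list over
    ``{"M", "I", "D", "S"}``; after normalization it never begins or ends
    with I or D.
    """

    read_id: str
    amplicon_id: str
    ref_start: int
    ops: tuple[tuple[str, int], ...]
    map_conf: int
    seq: str
    base_qualities: tuple[int, ...]
    strand: str = "+"
    score: int = 0

    def __post_init__(self):
        q_len = sum(n for op, n in self.ops if op in "MIS")
        if q_len != len(self.seq):
            raise ValueError(
                f"{self.read_id}: ops consume {q_len} query bases, read has {len(self.seq)}"
            )

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.ops if op in "MD")

    def cigar(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.ops)


@njit(cache=True)
def _affine_fill(q, r, match, mismatch, go1, ge1, go2, ge2, band):
    """Fill banded two-piece affine local DP matrices.

    Returns (H, E1, E2, F1, F2, best, bi, bj). E = gaps consuming reference
    (deletions in the read), F = gaps consuming query (insertions); classes
    1/2 are the short/long gap cost pieces.
    """
    m, n = q.shape[0], r.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E1 = np.full((m + 1, n + 1), _NEG, dtype=np.int32)
    E2 = np.full((m + 1, n + 1), _NEG, dtype=np.int32)
    F1 = np.full((m + 1, n + 1), _NEG, dtype=np.int32)
    F2 = np.full((m + 1, n + 1), _NEG, dtype=np.int32)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        lo = 1 if band >= m + n else max(1, i - band)
        hi = n if band >= m + n else min(n, i + band)
        for j in range(lo, hi + 1):
            e1 = max(E1[i, j - 1] + ge1, H[i, j - 1] + go1 + ge1)
            e2 = max(E2[i, j - 1] + ge2, H[i, j - 1] + go2 + ge2)
            f1 = max(F1[i - 1, j] + ge1, H[i - 1, j] + go1 + ge1)
            f2 = max(F2[i - 1, j] + ge2, H[i - 1, j] + go2 + ge2)
            s = match if q[i - 1] == r[j - 1] else mismatch
            h = H[i - 1, j - 1] + s
            if e1 > h:
                h = e1
            if e2 > h:
                h = e2
            if f1 > h:
                h = f1
            if f2 > h:
                h = f2
            if h < 0:
                h = 0
            E1[i, j] = e1
            E2[i, j] = e2
            F1[i, j] = f1
            F2[i, j] = f2
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E1, E2, F1, F2, int(best), bi, bj


@njit(cache=True)
def _affine_score(q, r, match, mismatch, go1, ge1, go2, ge2, band):
    """Score-only two-piece affine DP with rolling rows (for assignment)."""
    m, n = q.shape[0], r.shape[0]
    Hp = np.zeros(n + 1, dtype=np.int32)
    E1p = np.full(n + 1, _NEG, dtype=np.int32)
    E2p = np.full(n + 1, _NEG, dtype=np.int32)
    F1p = np.full(n + 1, _NEG, dtype=np.int32)
    F2p = np.full(n + 1, _NEG, dtype=np.int32)
    Hc = np.zeros(n + 1, dtype=np.int32)
    E1c = np.full(n + 1, _NEG, dtype=np.int32)
    E2c = np.full(n + 1, _NEG, dtype=np.int32)
    F1c = np.full(n + 1, _NEG, dtype=np.int32)
    F2c = np.full(n + 1, _NEG, dtype=np.int32)
    best = np.int32(0)
    for i in range(1, m + 1):
        lo = 1 if band >= m + n else max(1, i - band)
        hi = n if band >= m + n else min(n, i + band)
        for j in range(n + 1):
            Hc[j] = 0
            E1c[j] = _NEG
            E2c[j] = _NEG
            F1c[j] = _NEG
            F2c[j] = _NEG
        for j in range(lo, hi + 1):
            e1 = max(E1c[j - 1] + ge1, Hc[j - 1] + go1 + ge1)
            e2 = max(E2c[j - 1] + ge2, Hc[j - 1] + go2 + ge2)
            f1 = max(F1p[j] + ge1, Hp[j] + go1 + ge1)
            f2 = max(F2p[j] + ge2, Hp[j] + go2 + ge2)
            s = match if q[i - 1] == r[j - 1] else mismatch
            h = Hp[j - 1] + s
            if e1 > h:
                h = e1
            if e2 > h:
                h = e2
            if f1 > h:
                h = f1
            if f2 > h:
                h = f2
            if h < 0:
                h = 0
            E1c[j] = e1
            E2c[j] = e2
            F1c[j] = f1
            F2c[j] = f2
            Hc[j] = h
            if h > best:
                best = h
        Hp, Hc = Hc, Hp
        E1p, E1c = E1c, E1p
        E2p, E2c = E2c, E2p
        F1p, F1c = F1c, F1p
        F2p, F2c = F2c, F2p
    return int(best)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def _default_band(m: int, n: int) -> int:
    return 2 * abs(m - n) + 32


def _traceback(mats, bi, bj, q, r, scaled):
    """Recover ops from filled matrices; tie preference M, then D, then I.

    Returns (ops chronological, query start, ref start, visited path cells).
    """
    H, E1, E2, F1, F2 = mats
    match, mismatch, go1, ge1, go2, ge2 = scaled
    ops: list[str] = []
    i, j = bi, bj
    state = "H"
    path: list[tuple[int, int]] = []
    while True:
        path.append((i, j))
        if state == "H":
            v = H[i, j]
            if v == 0:
                break
            s = match if q[i - 1] == r[j - 1] else mismatch
            if i > 0 and j > 0 and v == H[i - 1, j - 1] + s:
                ops.append("M")
                i -= 1
                j -= 1
            elif v == E1[i, j]:
                state = "E1"
            elif v == E2[i, j]:
                state = "E2"
            elif v == F1[i, j]:
                state = "F1"
            elif v == F2[i, j]:
                state = "F2"
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback inconsistency")
        elif state == "E1":
            ops.append("D")
            if E1[i, j] == H[i, j - 1] + go1 + ge1:
                state = "H"
            j -= 1
        elif state == "E2":
            ops.append("D")
            if E2[i, j] == H[i, j - 1] + go2 + ge2:
                state = "H"
            j -= 1
        elif state == "F1":
            ops.append("I")
            if F1[i, j] == H[i - 1, j] + go1 + ge1:
                state = "H"
            i -= 1
        else:
            ops.append("I")
            if F2[i, j] == H[i - 1, j] + go2 + ge2:
                state = "H"
            i -= 1
    ops.reverse()
    return ops, i, j, path


def _merge_ops(ops: list[str]) -> list[tuple[str, int]]:
    merged: list[tuple[str, int]] = []
    for op in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + 1)
        else:
            merged.append((op, 1))
    return merged


def _clip_ops(
    merged: list[tuple[str, int]], qstart: int, qlen: int
) -> list[tuple[str, int]]:
    """Add soft-clip ops for the unaligned query ends.

    A positive-match local optimum never begins or ends with I/D (a boundary
    gap strictly lowers the score), so only clips need adding.
    """
    out: list[tuple[str, int]] = []
    if qstart:
        out.append(("S", qstart))
    out.extend(merged)
    consumed = qstart + sum(n for op, n in merged if op in "MI")
    if qlen - consumed:
        out.append(("S", qlen - consumed))
    return out


def _left_align_indels(
    ops: list[tuple[str, int]], seq: str, ref: str, ref_start: int
) -> tuple[tuple[str, int], ...]:
    """Shift each I/D run to its leftmost equivalent placement.

    An insertion at query offset ``qi`` shifts left while
    ``seq[qi-1-s] == seq[qi+n-1-s]`` (repeat context in the read); a deletion
    at ref offset ``rj`` shifts while ``ref[rj-1-s] == ref[rj+n-1-s]``. Both
    preserve the implied aligned sequence exactly.
    """
    ops = list(ops)
    k = 0
    while k < len(ops):
        op, n = ops[k]
        if op in "ID" and k > 0 and ops[k - 1][0] == "M":
            qi = sum(x for o, x in ops[:k] if o in "MIS")
            rj = ref_start + sum(x for o, x in ops[:k] if o in "MD")
            prev_n = ops[k - 1][1]
            shift = 0
            if op == "I":
                while (
                    shift < prev_n
                    and seq[qi - 1 - shift] == seq[qi + n - 1 - shift]
                ):
                    shift += 1
            else:
                while (
                    shift < prev_n
                    and ref[rj - 1 - shift] == ref[rj + n - 1 - shift]
                ):
                    shift += 1
            if shift:
                ops[k - 1] = ("M", prev_n - shift)
                if k + 1 < len(ops) and ops[k + 1][0] == "M":
                    ops[k + 1] = ("M", ops[k + 1][1] + shift)
                else:
                    ops.insert(k + 1, ("M", shift))
                if ops[k - 1][1] == 0:
                    ops.pop(k - 1)
                    continue  # re-examine this indel at its new index
        k += 1
    return tuple(o for o in ops if o[1] > 0)


def _strip_boundary_indels(
    ops: list[tuple[str, int]], ref_start: int
) -> tuple[list[tuple[str, int]], int]:
    """Remove I/D runs abutting the clipped ends (left-alignment can create
    them): a boundary D just moves ``ref_start``; a boundary I folds into the
    soft clip."""
    ops = list(ops)
    changed = True
    while changed:
        changed = False
        i0 = 1 if ops and ops[0][0] == "S" else 0
        if len(ops) > i0 and ops[i0][0] in "ID":
            op, n = ops.pop(i0)
            if op == "D":
                ref_start += n
            elif i0 == 1:
                ops[0] = ("S", ops[0][1] + n)
            else:
                ops.insert(0, ("S", n))
            changed = True
        i1 = len(ops) - 2 if ops and ops[-1][0] == "S" else len(ops) - 1
        if i1 >= 0 and ops[i1][0] in "ID":
            op, n = ops.pop(i1)
            if op == "I":
                if i1 == len(ops) - 1 and ops and ops[-1][0] == "S":
                    ops[-1] = ("S", ops[-1][1] + n)
                else:
                    ops.append(("S", n))
            changed = True
    return ops, ref_start


def align_read(
    read_seq: str,
    amplicon: AmpliconReference,
    params: AlignParams = AlignParams(),
    read_id: str = "read",
    base_qualities: tuple[int, ...] | None = None,
) -> AlignedRead | None:
    """Glocal affine alignment of one read to one amplicon (plus strand only).

    Returns ``None`` when no positive-scoring alignment exists. The band is
    widened automatically (doubling) whenever the optimal path touches the
    band edge; small problems use the full matrix outright.
    """
    if not read_seq or not amplicon.sequence:
        raise ValueError("read and amplicon must be non-empty")
    q = _encode(read_seq)
    r = _encode(amplicon.sequence)
    m, n = len(q), len(r)
    scaled = params.scaled()
    band = params.band if params.band is not None else _default_band(m, n)
    if m * n <= _FULL_THRESHOLD:
        band = m + n
    while True:
        H, E1, E2, F1, F2, best, bi, bj = _affine_fill(q, r, *scaled, band)
        if best <= 0:
            return None
        ops_raw, qstart, ref_start, path = _traceback(
            (H, E1, E2, F1, F2), bi, bj, q, r, scaled
        )
        if band >= m + n:
            break
        touched = any(abs(j - i) >= band for i, j in path if 0 < i <= m)
        if not touched:
            break
        band = min(2 * band, m + n)
    merged = _merge_ops(ops_raw)
    ops = _clip_ops(merged, qstart, m)
    ops = _left_align_indels(ops, read_seq, amplicon.sequence, ref_start)
    ops, ref_start = _strip_boundary_indels(list(ops), ref_start)
    quals = base_qualities if base_qualities is not None else tuple([40] * m)
    return AlignedRead(
        read_id=read_id,
        amplicon_id=amplicon.id,
        ref_start=ref_start,
        ops=tuple(ops),
        map_conf=60,
        seq=read_seq,
        base_qualities=tuple(quals),
        strand="+",
        score=best / _SCALE,
    )


_MAPQ_SCALE = 6  # map_conf = min(60, 6 * (best - second best)), in score units


def assign_amplicon(
    read: FastqRead,
    amplicons: list[AmpliconReference],
    params: AlignParams = AlignParams(),
) -> AlignedRead | None:
    """Align a read against every amplicon (both strands) and keep the best.

    ``map_conf`` is ``min(60, 6 * (best − second-best amplicon))``, 60 when
    only one amplicon is supplied; returns ``None`` (unassigned) when the
    best score falls below ``params.min_score``. Permutation-invariant in the
    amplicon list (ties broken by amplicon id, then strand).
    """
    if not amplicons:
        raise ValueError("need at least one amplicon")
    rc_seq = reverse_complement(read.sequence)
    q_fwd = _encode(read.sequence)
    q_rev = _encode(rc_seq)
    scaled = params.scaled()
    scored: list[tuple[int, str, str]] = []  # (scaled score, amplicon_id, strand)
    by_id = {a.id: a for a in amplicons}
    for amp in amplicons:
        r = _encode(amp.sequence)
        m, n = len(q_fwd), len(r)
        band = params.band if params.band is not None else _default_band(m, n)
        if m * n <= _FULL_THRESHOLD:
            band = m + n
        for strand, q in (("+", q_fwd), ("-", q_rev)):
            s = _affine_score(q, r, *scaled, band)
            scored.append((s, amp.id, strand))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    best_score, best_id, best_strand = scored[0]
    if best_score < params.min_score * _SCALE:
        return None
    second = next((s for s, aid, _ in scored if aid != best_id), None)
    if second is None:
        map_conf = 60
    else:
        margin = (best_score - second) / _SCALE
        map_conf = int(max(0, min(60, round(_MAPQ_SCALE * margin))))
    seq = read.sequence if best_strand == "+" else rc_seq
    quals = read.qualities if best_strand == "+" else read.qualities[::-1]
    aln = align_read(
        seq, by_id[best_id], params, read_id=read.read_id, base_qualities=quals
    )
    if aln is None or aln.score < params.min_score:
        return None
    return replace(aln, strand=best_strand, map_conf=map_conf)


_OP_TO_CODE = {"M": 0, "I": 1, "D": 2, "S": 4}
_CODE_TO_OP = {0: "M", 1: "I", 2: "D", 4: "S", 7: "M", 8: "M"}


def write_sam(aligned: list[AlignedRead], amplicons: list[AmpliconReference], path) -> None:
    """Write alignments as SAM text (with @SQ headers from the amplicons)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": a.id, "LN": len(a.sequence)} for a in amplicons],
    }
    idx = {a.id: i for i, a in enumerate(amplicons)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for ar in aligned:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = ar.read_id
            seg.query_sequence = ar.seq
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in ar.base_qualities)
            )
            seg.flag = 16 if ar.strand == "-" else 0
            seg.reference_id = idx[ar.amplicon_id]
            seg.reference_start = ar.ref_start
            seg.mapping_quality = ar.map_conf
            seg.cigartuples = [(_OP_TO_CODE[op], n) for op, n in ar.ops]
            fh.write(seg)


def read_sam(path) -> list[AlignedRead]:
    """Import SAM records as :class:`AlignedRead`; MAPQ becomes ``map_conf``.

    Unmapped records are skipped with a logged count; an unsupported CIGAR
    operation raises.
    """
    import pysam

    out: list[AlignedRead] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.reference_id < 0:
                skipped += 1
                continue
            ops = []
            for code, n in seg.cigartuples or []:
                if code == 5:  # hard clip: no query bases present
                    continue
                if code not in _CODE_TO_OP:
                    raise ValueError(
                        f"unsupported CIGAR op code {code} in read {seg.query_name}"
                    )
                op = _CODE_TO_OP[code]
                if ops and ops[-1][0] == op:
                    ops[-1] = (op, ops[-1][1] + n)
                else:
                    ops.append((op, n))
            quals = (
                tuple(int(q) for q in seg.query_qualities)
                if seg.query_qualities is not None
                else tuple([40] * len(seg.query_sequence or ""))
            )
            out.append(
                AlignedRead(
                    read_id=seg.query_name,
                    amplicon_id=seg.reference_name,
                    ref_start=seg.reference_start,
                    ops=tuple(ops),
                    map_conf=seg.mapping_quality,
                    seq=seg.query_sequence or "",
                    base_qualities=quals,
                    strand="-" if seg.is_reverse else "+",
                )
            )
    if skipped:
        log.info("skipped %d unmapped SAM records", skipped)
    return out
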