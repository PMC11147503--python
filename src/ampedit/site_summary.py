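"""Per-site pileup counting of high-quality reference bases, substitutions,
deletions, and insertions, with TSV round trip.

Counting semantics mirror amplicon variant-calling practice: reads below the
mapping-quality floor are excluded entirely; base calls below the base-quality
floor are excluded at that site only; deletions are recorded once at their
left-aligned anchor (with their span) while span coverage is tracked at every
deleted position; insertions are keyed by inserted sequence and anchored
after the preceding reference base. Depth is capped deterministically by
input order. Adjacent mismatches are counted as independent single-nt
substitutions.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field

from .alignment_io import AlignedRead
from .sequence_model import AmpliconReference

__all__ = ["QualityThresholds", "SitePileupRow", "pileup", "write_site_tsv", "read_site_tsv"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QualityThresholds:
    """Calling criteria: base quality >= 16, mapping quality >= 10, depth cap
    10000 — the thresholds the per-site summary counts under."""

    min_base_quality: int = 16
    min_map_quality: int = 10
    max_depth: int = 10000


@dataclass
class SitePileupRow:
    amplicon_id: str
    pos: int  # 0-based
    depth_hq: int = 0
    ref_count: int = 0
    subs: dict[str, int] = field(default_factory=dict)
    dels: dict[int, int] = field(default_factory=dict)  # span -> count, anchored here
    del_span_cover: int = 0
    ins: dict[str, int] = field(default_factory=dict)  # inserted seq -> count

    def check(self) -> None:
        if self.ref_count + sum(self.subs.values()) > self.depth_hq:
            raise AssertionError("calls exceed high-quality depth")


def pileup(
    alignments: list[AlignedRead],
    amplicon: AmpliconReference,
    thresholds: QualityThresholds = QualityThresholds(),
) -> list[SitePileupRow]:
    """Tally per-position counts for one amplicon from aligned reads."""
    ref = amplicon.sequence
    rows = [SitePileupRow(amplicon.id, p) for p in range(len(ref))]
    n_used = 0
    n_dropped_depth = 0
    for aln in alignments:
        if aln.amplicon_id != amplicon.id:
            raise ValueError(f"alignment {aln.read_id} is not on amplicon {amplicon.id}")
        if aln.map_conf < thresholds.min_map_quality:
            continue
        if n_used >= thresholds.max_depth:
            n_dropped_depth += 1
            continue
        n_used += 1
        qi = 0
        rj = aln.ref_start
        for op, n in aln.ops:
            if op == "S":
                qi += n
            elif op == "M":
                if rj + n > len(ref):
                    raise ValueError(f"alignment {aln.read_id} extends past reference end")
                for k in range(n):
                    if aln.base_qualities[qi + k] >= thresholds.min_base_quality:
                        row = rows[rj + k]
                        row.depth_hq += 1
                        base = aln.seq[qi + k]
                        if base == ref[rj + k]:
                            row.ref_count += 1
                        else:
                            row.subs[base] = row.subs.get(base, 0) + 1
                qi += n
                rj += n
            elif op == "D":
                if rj + n > len(ref):
                    raise ValueError(f"alignment {aln.read_id} extends past reference end")
                rows[rj].dels[n] = rows[rj].dels.get(n, 0) + 1
                for k in range(n):
                    rows[rj + k].del_span_cover += 1
                rj += n
            elif op == "I":
                anchor = max(0, rj - 1)
                seq = aln.seq[qi : qi + n]
                rows[anchor].ins[seq] = rows[anchor].ins.get(seq, 0) + 1
                qi += n
            else:  # pragma: no cover
                raise ValueError(f"unknown op {op!r}")
    if n_dropped_depth:
        log.info(
            "depth cap %d reached on %s: dropped %d reads",
            thresholds.max_depth, amplicon.id, n_dropped_depth,
        )
    return rows


_COLUMNS = [
    "amplicon", "pos_1based", "depth_hq", "ref_count",
    "sub_A", "sub_C", "sub_G", "sub_T",
    "del_events", "del_span_cover", "ins_events",
]


def _events_str(d: dict, keyfmt=str) -> str:
    return ";".join(f"{keyfmt(k)}:{d[k]}" for k in sorted(d)) if d else "."


def write_site_tsv(rows: list[SitePileupRow], path=None) -> str:
    """Serialize rows (sorted by amplicon, position) as TSV; 1-based positions."""
    rows = sorted(rows, key=lambda r: (r.amplicon_id, r.pos))
    buf = io.StringIO()
    w = csv.writer(buf, delimiter="\t", lineterminator="\n")
    w.writerow(_COLUMNS)
    for r in rows:
        w.writerow([
            r.amplicon_id, r.pos + 1, r.depth_hq, r.ref_count,
            r.subs.get("A", 0), r.subs.get("C", 0), r.subs.get("G", 0), r.subs.get("T", 0),
            _events_str(r.dels), r.del_span_cover, _events_str(r.ins),
        ])
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _parse_events(s: str, keytype):
    if s in (".", ""):
        return {}
    out = {}
    for item in s.split(";"):
        k, _, v = item.rpartition(":")
        out[keytype(k)] = int(v)
    return out


def read_site_tsv(source) -> list[SitePileupRow]:
    """Inverse of :func:`write_site_tsv` (accepts a path or TSV text)."""
    if isinstance(source, str) and "\t" in source:
        fh = io.StringIO(source)
    else:
        fh = open(source)
    with fh:
        reader = csv.DictReader(fh, delimiter="\t")
        rows = []
        for rec in reader:
            subs = {
                b: int(rec[f"sub_{b}"]) for b in "ACGT" if int(rec[f"sub_{b}"]) > 0
            }
            rows.append(
                SitePileupRow(
                    amplicon_id=rec["amplicon"],
                    pos=int(rec["pos_1based"]) - 1,
                    depth_hq=int(rec["depth_hq"]),
                    ref_count=int(rec["ref_count"]),
                    subs=subs,
                    dels=_parse_events(rec["del_events"], int),
                    del_span_cover=int(rec["del_span_cover"]),
                    ins=_parse_events(rec["ins_events"], str),
                )
            )
    return rows
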