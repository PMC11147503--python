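"""Per-target filtered variant percentages and paired condition comparison.

For each (off-)target window, the summary counts substitution and insertion
alleles whose site lies in the window and deletion events whose span starts
in or extends into the window. A variant passes the filters when it is
supported by at least ``min_reads`` reads AND makes up at least ``min_frac``
of the reads at its site. Under the single-variant-per-read assumption the
fully-reference percentage is 100 minus the sum of all passing variant
percentages (clipped at 0 with a warning when multi-variant reads break the
assumption).

Condition comparisons use two-sided paired t-tests per target with
Benjamini–Hochberg FDR correction across the family tested in one call.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .site_summary import SitePileupRow

__all__ = [
    "TargetWindow",
    "PassingVariant",
    "TargetSiteSummary",
    "summarize_target",
    "compare_conditions",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetWindow:
    """A predicted cut-site window on an amplicon (default: spacer ∪ PAM)."""

    target_id: str
    amplicon_id: str
    window: tuple[int, int]
    cut_index: int | None = None

    def __post_init__(self):
        if self.window[0] >= self.window[1]:
            raise ValueError("window must be non-empty")


@dataclass(frozen=True)
class PassingVariant:
    kind: str  # "sub" | "del" | "ins"
    site: int  # 0-based anchor position
    allele: str  # base, deleted span ("del<n>"), or inserted sequence
    reads: int
    pct: float


@dataclass(frozen=True)
class TargetSiteSummary:
    target_id: str
    total_reads: int
    pct_sub: float
    pct_del: float
    pct_ins: float
    pct_ref: float
    passing_variants: tuple[PassingVariant, ...]
    empty: bool = False
    clipped: bool = False


def _site_total(row: SitePileupRow) -> int:
    # reads contributing information at this site: high-quality base calls
    # plus reads whose deletion spans it
    return row.depth_hq + row.del_span_cover


def summarize_target(
    rows: list[SitePileupRow],
    window: TargetWindow,
    min_reads: int = 3,
    min_frac: float = 0.001,
) -> TargetSiteSummary:
    """Filtered percent substitution/deletion/insertion and fully-reference
    percent for one target window."""
    by_pos = {r.pos: r for r in rows if r.amplicon_id == window.amplicon_id}
    w0, w1 = window.window
    totals = [_site_total(by_pos[p]) for p in range(w0, w1) if p in by_pos]
    total_reads = max(totals, default=0)
    if total_reads == 0:
        return TargetSiteSummary(
            window.target_id, 0,
            float("nan"), float("nan"), float("nan"), float("nan"),
            (), empty=True,
        )

    passing: list[PassingVariant] = []

    def consider(kind, site, allele, reads):
        site_total = _site_total(by_pos[site])
        if site_total == 0:
            return
        if reads >= min_reads and reads / site_total >= min_frac:
            passing.append(
                PassingVariant(kind, site, allele, reads, 100.0 * reads / site_total)
            )

    for p in range(w0, w1):
        row = by_pos.get(p)
        if row is None:
            continue
        for base, cnt in sorted(row.subs.items()):
            consider("sub", p, base, cnt)
        for seq, cnt in sorted(row.ins.items()):
            consider("ins", p, seq, cnt)
    # deletions: span intersects the window, anchors possibly upstream
    for p, row in sorted(by_pos.items()):
        for span, cnt in sorted(row.dels.items()):
            if p < w1 and p + span > w0:  # starts in or extends into the window
                consider("del", p, f"del{span}", cnt)

    pct_sub = sum(v.pct for v in passing if v.kind == "sub")
    pct_del = sum(v.pct for v in passing if v.kind == "del")
    pct_ins = sum(v.pct for v in passing if v.kind == "ins")
    pct_ref = 100.0 - (pct_sub + pct_del + pct_ins)
    clipped = False
    if pct_ref < 0:
        log.warning(
            "target %s: variant percentages exceed 100 (multi-variant reads); "
            "clipping pct_ref to 0", window.target_id,
        )
        pct_ref = 0.0
        clipped = True
    return TargetSiteSummary(
        window.target_id, total_reads, pct_sub, pct_del, pct_ins, pct_ref,
        tuple(passing), clipped=clipped,
    )


def compare_conditions(
    data: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    metric: str = "pct_ref",
) -> pd.DataFrame:
    """Two-sided paired t-tests per target between two conditions, BH-corrected.

    ``data`` needs columns ``target``, ``sample``, ``condition`` and the
    metric column; samples must be paired (every sample present in both
    conditions for each target). Zero-variance zero-difference pairs give
    p = 1 by convention. Returns a DataFrame (target, n_pairs, t, p, q).
    """
    required = {"target", "sample", "condition", metric}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = []
    for target, grp in data.groupby("target", sort=True):
        a = grp[grp["condition"] == condition_a].set_index("sample")[metric]
        b = grp[grp["condition"] == condition_b].set_index("sample")[metric]
        unpaired = set(a.index) ^ set(b.index)
        if unpaired:
            raise ValueError(f"target {target}: unpaired samples {sorted(unpaired)}")
        if len(a) < 2:
            raise ValueError(f"target {target}: need >=2 complete pairs, got {len(a)}")
        diffs = (a - b.reindex(a.index)).to_numpy(dtype=float)
        if np.allclose(diffs, 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(a.to_numpy(dtype=float),
                                   b.reindex(a.index).to_numpy(dtype=float))
            if math.isnan(p):  # identical nonzero-variance degenerate case
                t, p = 0.0, 1.0
        out.append({"target": target, "n_pairs": len(a), "t": float(t), "p": float(p)})
    df = pd.DataFrame(out)
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df
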