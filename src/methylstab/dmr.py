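"""DMR calling: core-threshold seeding, edge extension, and CpG annotation.

A window with p < alpha_core (default 1e-5, strict) is a core window; runs of
adjacent core windows seed DMRs.  Edges extend until no window with
p < alpha_edge (default 0.1) remains within extension_distance (default
1,000 bp) of the growing DMR boundary; windows lying between an absorbed
window and the DMR are absorbed too, so DMRs stay contiguous intervals.
Extension iterates to a fixed point, and extended DMRs that overlap or touch
are merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisThresholds

__all__ = [
    "DMR",
    "DMRSet",
    "call_core_windows",
    "extend_and_merge",
    "annotate_cpg_class",
    "dmr_summary",
]


@dataclass
class DMR:
    contig: str
    start: int
    end: int
    window_ids: tuple[int, ...]       # tested member windows
    core_window_ids: tuple[int, ...]  # members with p < alpha_core
    edge_window_ids: tuple[int, ...]  # members with alpha_core <= p < alpha_edge
    min_p: float
    min_q: float
    cpg_per_100bp: float | None = None
    cpg_class: str | None = None

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def n_windows(self) -> int:
        return len(self.window_ids)

    @property
    def name(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"


@dataclass
class DMRSet:
    comparison: str
    thresholds: AnalysisThresholds
    dmrs: list[DMR] = field(default_factory=list)
    grid_signature: tuple[int, int, int] = (0, 0, 0)  # (n windows, min id, max id)

    def __len__(self) -> int:
        return len(self.dmrs)

    @property
    def member_window_ids(self) -> frozenset[int]:
        return frozenset(w for d in self.dmrs for w in d.window_ids)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "contig": d.contig,
                "start": d.start,
                "end": d.end,
                "name": d.name,
                "length_bp": d.length_bp,
                "n_windows": d.n_windows,
                "n_core_windows": len(d.core_window_ids),
                "min_p": d.min_p,
                "min_q": d.min_q,
                "cpg_per_100bp": d.cpg_per_100bp,
                "cpg_class": d.cpg_class,
            }
            for d in self.dmrs
        ]
        cols = ["contig", "start", "end", "name", "length_bp", "n_windows",
                "n_core_windows", "min_p", "min_q", "cpg_per_100bp",
                "cpg_class"]
        return pd.DataFrame(rows, columns=cols)

    def to_bed(self) -> pd.DataFrame:
        """BED5: name is the comparison, score is -log10 of the best p."""
        return pd.DataFrame(
            {
                "contig": [d.contig for d in self.dmrs],
                "start": [d.start for d in self.dmrs],
                "end": [d.end for d in self.dmrs],
                "name": [self.comparison] * len(self.dmrs),
                "score": [
                    round(-np.log10(max(d.min_p, 1e-300)), 3) for d in self.dmrs
                ],
            }
        )


def _grid_signature(results: pd.DataFrame) -> tuple[int, int, int]:
    if results.empty:
        return (0, 0, 0)
    ids = results["window_id"]
    return (len(results), int(ids.min()), int(ids.max()))


def call_core_windows(
    results: pd.DataFrame, thresholds: AnalysisThresholds
) -> set[int]:
    """Window ids with p strictly below alpha_core."""
    if results["p_value"].isna().any():
        raise ValueError("missing p-values in results table")
    mask = results["p_value"] < thresholds.alpha_core
    return set(results.loc[mask, "window_id"].astype(int))


def extend_and_merge(
    results: pd.DataFrame,
    thresholds: AnalysisThresholds,
    comparison: str = "",
) -> DMRSet:
    """Seed DMRs from adjacent core runs, extend edges to a fixed point, merge.

    The candidate rule: a tested window with p < alpha_edge qualifies when the
    gap between it and the current DMR boundary is <= extension_distance bp;
    absorbing it extends the DMR hull (gap windows included).  Distances are
    measured on the window grid, so untested (coverage-filtered) windows can
    be spanned but never themselves qualify.
    """
    ws = thresholds.window_size
    reach = thresholds.extension_distance // ws + 1  # max index step absorbable
    out = DMRSet(
        comparison=comparison,
        thresholds=thresholds,
        grid_signature=_grid_signature(results),
    )
    if results.empty:
        return out
    if results["p_value"].isna().any():
        raise ValueError("missing p-values in results table")

    for contig, grp in results.groupby("contig", sort=False):
        grp = grp.sort_values("start")
        idx = (grp["start"].to_numpy() // ws).astype(np.int64)
        p = grp["p_value"].to_numpy()
        q = grp["q_value"].to_numpy() if "q_value" in grp else np.full(len(grp), np.nan)
        wid = grp["window_id"].to_numpy()
        pos_of = {int(i): j for j, i in enumerate(idx)}

        core = idx[p < thresholds.alpha_core]
        if core.size == 0:
            continue
        edge_idx = np.sort(idx[p < thresholds.alpha_edge])

        # seed intervals: maximal runs of adjacent core windows
        intervals: list[list[int]] = []
        run_start = prev = int(core[0])
        for i in core[1:]:
            i = int(i)
            if i == prev + 1:
                prev = i
            else:
                intervals.append([run_start, prev])
                run_start = prev = i
        intervals.append([run_start, prev])

        # extend each interval to a fixed point
        changed = True
        while changed:
            changed = False
            for iv in intervals:
                lo, hi = iv
                left = edge_idx[(edge_idx < lo) & (edge_idx >= lo - reach)]
                if left.size:
                    iv[0] = int(left.min())
                    changed = True
                right = edge_idx[(edge_idx > hi) & (edge_idx <= hi + reach)]
                if right.size:
                    iv[1] = int(right.max())
                    changed = True
            # merge overlapping or touching intervals
            intervals.sort()
            merged: list[list[int]] = []
            for iv in intervals:
                if merged and iv[0] <= merged[-1][1] + 1:
                    merged[-1][1] = max(merged[-1][1], iv[1])
                else:
                    merged.append(iv)
            intervals = merged

        for lo, hi in intervals:
            members = [pos_of[i] for i in range(lo, hi + 1) if i in pos_of]
            mp = p[members]
            member_ids = tuple(int(wid[j]) for j in members)
            core_ids = tuple(
                int(wid[j]) for j in members if p[j] < thresholds.alpha_core
            )
            edge_ids = tuple(
                int(wid[j])
                for j in members
                if thresholds.alpha_core <= p[j] < thresholds.alpha_edge
            )
            out.dmrs.append(
                DMR(
                    contig=contig,
                    start=lo * ws,
                    end=(hi + 1) * ws,
                    window_ids=member_ids,
                    core_window_ids=core_ids,
                    edge_window_ids=edge_ids,
                    min_p=float(mp.min()),
                    min_q=float(np.nanmin(q[members])),
                )
            )
    out.dmrs.sort(key=lambda d: (d.contig, d.start))
    return out


def annotate_cpg_class(dmrs: DMRSet, windows: pd.DataFrame) -> DMRSet:
    """Mean member CpG count per 100 bp; desert iff strictly below the cutoff."""
    ws = dmrs.thresholds.window_size
    cpg = windows.set_index("window_id")["cpg_count"]
    for d in dmrs.dmrs:
        try:
            counts = cpg.loc[list(d.window_ids)]
        except KeyError as exc:
            raise IndexError(
                f"DMR {d.name} references windows absent from the grid"
            ) from exc
        d.cpg_per_100bp = float(counts.mean()) * (100.0 / ws)
        d.cpg_class = (
            "desert" if d.cpg_per_100bp < dmrs.thresholds.cpg_desert_cutoff
            else "island"
        )
    return dmrs


def dmr_summary(dmrs: DMRSet) -> dict:
    """Counts by length and CpG class, plus p-value summaries."""
    lengths = [d.length_bp for d in dmrs.dmrs]
    hist: dict[int, int] = {}
    for ln in lengths:
        hist[ln] = hist.get(ln, 0) + 1
    classes = {"desert": 0, "island": 0, "unannotated": 0}
    for d in dmrs.dmrs:
        classes[d.cpg_class or "unannotated"] += 1
    pvals = [d.min_p for d in dmrs.dmrs]
    return {
        "comparison": dmrs.comparison,
        "n_dmrs": len(dmrs.dmrs),
        "n_windows": sum(d.n_windows for d in dmrs.dmrs),
        "length_histogram": {int(k): hist[k] for k in sorted(hist)},
        "cpg_class_counts": classes,
        "min_p": float(min(pvals)) if pvals else None,
        "median_min_p": float(np.median(pvals)) if pvals else None,
    }
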