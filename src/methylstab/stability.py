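"""Between-generation stability of methylation via DMR-set overlap.

Two DMRs overlap iff they share at least one member 100-bp window — the
analysis is window-native, so this is the only criterion stable under the
grid.  The habitat-stability funnel: tier 1 holds DMRs found between the F1
generation and both lakes; tier 2, those also found in at least one of the
four lake-vs-river comparisons; tier 3, those found in all four (each set
matched independently).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .dmr import DMR, DMRSet

__all__ = [
    "OverlapReport",
    "StabilityTiers",
    "overlap_dmr_sets",
    "relaxed_overlap_fraction",
    "habitat_stability_tiers",
]


class GridMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class OverlapReport:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    n_overlap_a: int  # DMRs of A sharing >=1 window with any DMR of B
    n_overlap_b: int
    jaccard: float    # over member window ids

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class StabilityTiers:
    tier1: list[DMR] = field(default_factory=list)
    tier2: list[DMR] = field(default_factory=list)
    tier3: list[DMR] = field(default_factory=list)
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.tier1), len(self.tier2), len(self.tier3))


def _check_grids(*sets: DMRSet) -> None:
    sigs = {s.grid_signature for s in sets}
    if len(sigs) > 1:
        raise GridMismatchError(
            f"DMR sets computed on different window grids: {sorted(sigs)}"
        )


def overlap_dmr_sets(a: DMRSet, b: DMRSet) -> OverlapReport:
    """Shared-window overlap between two DMR sets, both orientations."""
    _check_grids(a, b)
    windows_a = a.member_window_ids
    windows_b = b.member_window_ids
    n_over_a = sum(1 for d in a.dmrs if set(d.window_ids) & windows_b)
    n_over_b = sum(1 for d in b.dmrs if set(d.window_ids) & windows_a)
    union = windows_a | windows_b
    jac = len(windows_a & windows_b) / len(union) if union else 0.0
    return OverlapReport(
        label_a=a.comparison,
        label_b=b.comparison,
        n_a=len(a),
        n_b=len(b),
        n_overlap_a=n_over_a,
        n_overlap_b=n_over_b,
        jaccard=jac,
    )


def relaxed_overlap_fraction(
    core_set: DMRSet, other_results: pd.DataFrame, alpha_relaxed: float | None = None
) -> float:
    """Fraction of core DMRs supported at a relaxed threshold elsewhere.

    A core-set DMR counts as supported when at least one of its member
    windows has p < alpha_relaxed (default from the set's thresholds) in the
    other comparison's window results.
    """
    if alpha_relaxed is None:
        alpha_relaxed = core_set.thresholds.alpha_relaxed
    if not core_set.dmrs:
        return 0.0
    p = other_results.set_index("window_id")["p_value"]
    needed = set(core_set.member_window_ids)
    missing = needed - set(p.index)
    if missing:
        raise GridMismatchError(
            f"{len(missing)} member windows missing from other_results"
        )
    supported = sum(
        1
        for d in core_set.dmrs
        if (p.loc[list(d.window_ids)] < alpha_relaxed).any()
    )
    return supported / len(core_set.dmrs)


def habitat_stability_tiers(
    f1_vs_l1: DMRSet,
    f1_vs_l2: DMRSet,
    lake_river_sets: list[DMRSet],
) -> StabilityTiers:
    """The stability funnel, anchored on the F1-vs-first-lake DMR list.

    tier1: f1_vs_l1 DMRs sharing >=1 window with f1_vs_l2.
    tier2: tier1 members matching >=1 of the four lake-vs-river sets.
    tier3: tier1 members matching all four, each set independently.
    """
    if len(lake_river_sets) != 4:
        raise ValueError(
            f"expected exactly 4 lake-vs-river sets, got {len(lake_river_sets)}"
        )
    _check_grids(f1_vs_l1, f1_vs_l2, *lake_river_sets)
    windows_l2 = f1_vs_l2.member_window_ids
    lr_windows = [s.member_window_ids for s in lake_river_sets]
    lr_labels = [s.comparison for s in lake_river_sets]

    tiers = StabilityTiers()
    rows = []
    for d in f1_vs_l1.dmrs:
        mw = set(d.window_ids)
        if not (mw & windows_l2):
            continue
        tiers.tier1.append(d)
        matched = [lab for lab, w in zip(lr_labels, lr_windows) if mw & w]
        tier = 1
        if matched:
            tiers.tier2.append(d)
            tier = 2
        if len(matched) == len(lr_labels):
            tiers.tier3.append(d)
            tier = 3
        rows.append(
            {
                "dmr": d.name,
                "contig": d.contig,
                "start": d.start,
                "end": d.end,
                "tier": tier,
                "matched_comparisons": ",".join(matched),
            }
        )
    tiers.provenance = pd.DataFrame(
        rows,
        columns=["dmr", "contig", "start", "end", "tier",
                 "matched_comparisons"],
    )
    return tiers
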