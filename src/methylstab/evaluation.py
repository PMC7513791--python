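"""Truth-table evaluation of DMR calls on synthetic studies.

A planted region counts as recovered when a DMR's *core* windows (the
windows individually significant at alpha_core) intersect it.  Matching on
core windows rather than full DMR spans keeps the bookkeeping honest: edge
extension absorbs nonsignificant gap windows by design, so a sprawling DMR
can touch a neighboring planted region without any differential signal
there.
"""

from __future__ import annotations

import pandas as pd

from .config import NULL
from .dmr import DMRSet

__all__ = ["region_recovery", "false_positive_dmrs"]


def _planted_regions(truth: pd.DataFrame) -> pd.DataFrame:
    planted = truth[truth["truth_class"] != NULL]
    return planted.groupby(["region_id", "truth_class"])["window_id"].agg(set)


def region_recovery(
    truth: pd.DataFrame, dmrs: DMRSet | list[DMRSet]
) -> pd.DataFrame:
    """Per planted region: was it hit by a core window of (each of) the sets?

    Returns a frame indexed by region_id with the truth class and one boolean
    column per DMR set (recovered = some DMR core window lies in the region).
    """
    sets = dmrs if isinstance(dmrs, list) else [dmrs]
    regions = _planted_regions(truth)
    out = pd.DataFrame(
        {
            "truth_class": [cls for (_, cls) in regions.index],
        },
        index=[rid for (rid, _) in regions.index],
    )
    out.index.name = "region_id"
    for s in sets:
        cores = set().union(*[set(d.core_window_ids) for d in s.dmrs]) \
            if s.dmrs else set()
        out[s.comparison or "dmrs"] = [
            bool(windows & cores) for windows in regions.to_numpy()
        ]
    return out


def false_positive_dmrs(truth: pd.DataFrame, dmrs: DMRSet) -> list:
    """DMRs whose core windows all lie outside planted regions."""
    planted = set(truth.loc[truth["truth_class"] != NULL, "window_id"])
    return [
        d for d in dmrs.dmrs if not (set(d.core_window_ids) & planted)
    ]
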