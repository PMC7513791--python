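"""Brute-force oracles used by the acceptance script (independent of the
package's implementation paths)."""

from __future__ import annotations

import numpy as np
import pandas as pd

import methylstab as ms


def results_frame(pvals, contig="c", window_size=100):
    n = len(pvals)
    starts = np.arange(n) * window_size
    return pd.DataFrame(
        {
            "window_id": np.arange(n),
            "contig": contig,
            "start": starts,
            "end": starts + window_size,
            "p_value": pvals,
            "q_value": ms.bh_adjust(pvals),
        }
    )


def oracle_extend(pvals, thresholds):
    """Naive fixed-point DMR extension over one contig (index pairs)."""
    ws = thresholds.window_size
    core = [i for i, p in enumerate(pvals) if p < thresholds.alpha_core]
    if not core:
        return []
    intervals = [[i, i] for i in core]
    changed = True
    while changed:
        changed = False
        for iv in intervals:
            for w, p in enumerate(pvals):
                if p >= thresholds.alpha_edge or iv[0] <= w <= iv[1]:
                    continue
                gap = (iv[0] - w - 1) * ws if w < iv[0] else (w - iv[1] - 1) * ws
                if gap <= thresholds.extension_distance:
                    iv[0] = min(iv[0], w)
                    iv[1] = max(iv[1], w)
                    changed = True
        intervals.sort()
        merged = []
        for iv in intervals:
            if merged and iv[0] <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], iv[1])
            else:
                merged.append(iv)
        intervals = merged
    return [tuple(iv) for iv in intervals]


def called_intervals(dmrset, window_size=100):
    return [(d.start // window_size, d.end // window_size - 1)
            for d in dmrset.dmrs]
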