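"""DMR calling: core thresholding, edge extension to fixed point, CpG class."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import methylstab as ms
from methylstab.config import AnalysisThresholds

THR = AnalysisThresholds()


def results_frame(pvals, contig="c", window_size=100, start_index=0):
    n = len(pvals)
    starts = (np.arange(n) + start_index) * window_size
    return pd.DataFrame(
        {
            "window_id": np.arange(n) + start_index,
            "contig": contig,
            "start": starts,
            "end": starts + window_size,
            "p_value": pvals,
            "q_value": ms.bh_adjust(pvals),
        }
    )


def oracle_extend(pvals, thresholds=THR):
    """Independent fixed-point oracle over one contig.

    Maintains intervals in window-index space; repeatedly absorbs any
    qualifying window (p < alpha_edge) whose bp gap to an interval boundary
    is <= extension_distance; merges touching intervals; iterates until
    stable.  Returns sorted (lo, hi) index pairs.
    """
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
                if w < iv[0]:
                    gap = (iv[0] - w - 1) * ws
                else:
                    gap = (w - iv[1] - 1) * ws
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


class TestCallCoreWindows:
    def test_strict_inequality_at_threshold(self):
        res = results_frame([1e-5, 5e-6, 0.5])
        core = ms.call_core_windows(res, THR)
        assert core == {1}

    def test_matches_brute_force_filter(self, rng):
        pvals = 10 ** (-rng.uniform(0, 8, size=200))
        res = results_frame(pvals)
        core = ms.call_core_windows(res, THR)
        assert core == set(np.flatnonzero(pvals < 1e-5))

    def test_missing_pvalues_rejected(self):
        res = results_frame([0.5, 0.5])
        res.loc[0, "p_value"] = np.nan
        with pytest.raises(ValueError):
            ms.call_core_windows(res, THR)


class TestExtendAndMerge:
    def test_absorbs_sub_edge_neighbor(self):
        res = results_frame([1e-6, 0.05, 0.5])
        dmrs = ms.extend_and_merge(res, THR)
        assert len(dmrs) == 1
        d = dmrs.dmrs[0]
        assert (d.start, d.end) == (0, 200)
        assert d.n_windows == 2
        assert d.core_window_ids == (0,)
        assert d.edge_window_ids == (1,)

    def test_isolated_core_stays_single_window(self):
        pvals = [0.5] * 5 + [1e-6] + [0.5] * 5
        dmrs = ms.extend_and_merge(results_frame(pvals), THR)
        assert len(dmrs) == 1
        assert dmrs.dmrs[0].length_bp == 100

    def test_chained_absorption_reaches_fixed_point(self):
        # core at window 0; edge windows at 9 and 18: the second only comes
        # within 1,000 bp after the first is absorbed
        pvals = [1e-6] + [0.5] * 8 + [0.09] + [0.5] * 8 + [0.09] + [0.5] * 3
        dmrs = ms.extend_and_merge(results_frame(pvals), THR)
        assert called_intervals(dmrs) == oracle_extend(pvals) == [(0, 18)]

    def test_empty_core_empty_set(self):
        dmrs = ms.extend_and_merge(results_frame([0.5] * 10), THR)
        assert len(dmrs) == 0

    def test_gap_windows_absorbed_for_contiguity(self):
        pvals = [1e-6, 0.5, 0.05, 0.9]
        dmrs = ms.extend_and_merge(results_frame(pvals), THR)
        d = dmrs.dmrs[0]
        assert (d.start, d.end) == (0, 300)
        # the p=0.5 gap window is a member but neither core nor edge
        assert d.n_windows == 3
        assert set(d.window_ids) == {0, 1, 2}
        assert d.edge_window_ids == (2,)

    @given(st.data())
    @settings(max_examples=60)
    def test_matches_fixed_point_oracle(self, data):
        n = data.draw(st.integers(10, 60))
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        # p-landscape with plenty of core and edge windows
        pvals = 10 ** (-rng.uniform(0, 7, size=n))
        dmrs = ms.extend_and_merge(results_frame(pvals), THR)
        assert called_intervals(dmrs) == oracle_extend(list(pvals))

    def test_idempotent_on_own_output(self, rng):
        for _ in range(20):
            pvals = 10 ** (-rng.uniform(0, 7, size=50))
            d1 = ms.extend_and_merge(results_frame(pvals), THR)
            # feeding member windows' p-values back in changes nothing
            iv1 = called_intervals(d1)
            assert iv1 == oracle_extend(list(pvals))
            d2 = ms.extend_and_merge(results_frame(pvals), THR)
            assert called_intervals(d2) == iv1

    def test_every_core_window_in_exactly_one_dmr(self, rng):
        pvals = 10 ** (-rng.uniform(0, 7, size=300))
        res = results_frame(pvals)
        dmrs = ms.extend_and_merge(res, THR)
        core = ms.call_core_windows(res, THR)
        covered = [d.core_window_ids for d in dmrs.dmrs]
        flat = [w for ids in covered for w in ids]
        assert set(flat) == core
        assert len(flat) == len(set(flat))
        assert all(d.core_window_ids for d in dmrs.dmrs)

    def test_threshold_monotonicity(self, rng):
        pvals = 10 ** (-rng.uniform(0, 7, size=200))
        res = results_frame(pvals)
        strict = ms.call_core_windows(res, THR)
        relaxed = ms.call_core_windows(
            res, AnalysisThresholds(alpha_core=0.05, alpha_edge=0.1)
        )
        assert strict <= relaxed

    def test_dmrs_disjoint_and_sorted(self, rng):
        pvals = 10 ** (-rng.uniform(0, 7, size=400))
        dmrs = ms.extend_and_merge(results_frame(pvals), THR)
        spans = [(d.start, d.end) for d in dmrs.dmrs]
        assert spans == sorted(spans)
        assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))


class TestAnnotateAndSummarize:
    def _annotated(self, pvals, cpg_counts):
        res = results_frame(pvals)
        dmrs = ms.extend_and_merge(res, THR)
        windows = res[["contig", "start", "end", "window_id"]].copy()
        windows["cpg_count"] = cpg_counts
        return ms.annotate_cpg_class(dmrs, windows)

    def test_desert_below_cutoff(self):
        out = self._annotated([1e-6, 0.05, 0.5], [2, 4, 30])
        d = out.dmrs[0]
        assert d.cpg_per_100bp == pytest.approx(3.0)
        assert d.cpg_class == "desert"

    def test_island_at_cutoff_boundary(self):
        # mean exactly 10 -> island (strict "<" for desert)
        out = self._annotated([1e-6, 0.05, 0.5], [8, 12, 0])
        assert out.dmrs[0].cpg_per_100bp == pytest.approx(10.0)
        assert out.dmrs[0].cpg_class == "island"

    def test_high_density_is_island(self):
        out = self._annotated([1e-6, 0.05, 0.5], [12, 14, 0])
        assert out.dmrs[0].cpg_per_100bp == pytest.approx(13.0)
        assert out.dmrs[0].cpg_class == "island"

    def test_summary_empty_set(self):
        dmrs = ms.extend_and_merge(results_frame([0.5] * 5), THR)
        s = ms.dmr_summary(dmrs)
        assert s["n_dmrs"] == 0
        assert s["length_histogram"] == {}

    def test_summary_histogram_matches_tally(self, rng):
        pvals = 10 ** (-rng.uniform(0, 7, size=300))
        dmrs = ms.extend_and_merge(results_frame(pvals), THR)
        s = ms.dmr_summary(dmrs)
        lengths = [d.length_bp for d in dmrs.dmrs]
        assert s["n_dmrs"] == len(lengths)
        for length, count in s["length_histogram"].items():
            assert lengths.count(length) == count
        assert sum(s["length_histogram"].values()) == len(lengths)
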