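"""Shell-shape arm: aperture index, ANOVA, Tukey letters, classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import studentized_range

import methylstab as ms
from methylstab.phenotype import (
    DEVELOPMENTAL_PLASTICITY,
    HERITABLE,
    INDETERMINATE,
    TRANSGENERATIONAL_PLASTICITY,
    MeasurementError,
    compact_letter_display,
)


def anova_f_oracle(groups):
    """Textbook sum-of-squares decomposition."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((g - np.mean(g)) ** 2).sum() for g in groups)
    k, n = len(groups), len(all_vals)
    return (ssb / (k - 1)) / (ssw / (n - k))


def frame(groups: dict[str, list[float]]) -> pd.DataFrame:
    rows = [
        {"population": g, "aperture_index": v}
        for g, vals in groups.items()
        for v in vals
    ]
    return pd.DataFrame(rows)


class TestApertureIndex:
    def test_scalar_examples(self):
        assert ms.aperture_index(2.0, 4.0) == pytest.approx(0.5)
        assert ms.aperture_index(3.0, 3.0) == pytest.approx(1.0)

    def test_batch_matches_elementwise_division(self, rng):
        w = rng.uniform(1, 5, size=50)
        h = rng.uniform(2, 8, size=50)
        np.testing.assert_allclose(ms.aperture_index(w, h), w / h)

    def test_nonpositive_rejected(self):
        with pytest.raises(MeasurementError):
            ms.aperture_index(0.0, 2.0)
        with pytest.raises(MeasurementError):
            ms.aperture_index(1.0, -2.0)


class TestOneWayAnova:
    def test_identical_groups_give_f_zero(self):
        res = ms.one_way_anova(frame({"a": [1, 2, 3], "b": [1, 2, 3]}))
        assert res.f_statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # SSB = 13.5 on 1 df, SSW = 4 on 4 df -> F = 13.5 / 1 = 13.5
        res = ms.one_way_anova(frame({"a": [1, 2, 3], "b": [4, 5, 6]}))
        assert res.f_statistic == pytest.approx(13.5, abs=1e-10)
        assert (res.df_between, res.df_within) == (1, 4)

    def test_matches_sum_of_squares_oracle(self, rng):
        groups = {
            f"g{i}": list(rng.normal(i * 0.1, 1.0, size=rng.integers(5, 15)))
            for i in range(4)
        }
        res = ms.one_way_anova(frame(groups))
        oracle = anova_f_oracle([np.array(v) for v in groups.values()])
        assert res.f_statistic == pytest.approx(oracle, rel=1e-10)

    def test_null_pvalues_are_uniform(self, rng):
        pvals = []
        for _ in range(400):
            groups = {f"g{i}": list(rng.normal(0, 1, 10)) for i in range(3)}
            pvals.append(ms.one_way_anova(frame(groups)).p_value)
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 0.001

    def test_small_group_rejected(self):
        with pytest.raises(ms.ConfigurationError):
            ms.one_way_anova(frame({"a": [1.0], "b": [1, 2]}))


class TestTukeyHsd:
    def test_identical_groups_share_a_letter(self, rng):
        vals = list(rng.normal(0, 1, 20))
        res = ms.tukey_hsd(frame({"a": vals, "b": vals, "c": vals}))
        assert len(set(res.letters.values())) == 1
        assert not res.pairs["reject"].any()

    def test_separated_groups_get_distinct_letters(self, rng):
        res = ms.tukey_hsd(
            frame(
                {"lo": list(rng.normal(0, 0.01, 10)),
                 "hi": list(rng.normal(5, 0.01, 10))}
            )
        )
        assert res.letters["lo"] != res.letters["hi"]
        assert res.differs("lo", "hi")

    def test_adjusted_p_matches_studentized_range(self, rng):
        groups = {
            "a": list(rng.normal(0.0, 1, 8)),
            "b": list(rng.normal(0.5, 1, 8)),
            "c": list(rng.normal(1.0, 1, 8)),
        }
        res = ms.tukey_hsd(frame(groups))
        arrs = {k: np.array(v) for k, v in groups.items()}
        n = sum(len(v) for v in arrs.values())
        k = len(arrs)
        df = n - k
        mse = sum(((v - v.mean()) ** 2).sum() for v in arrs.values()) / df
        for row in res.pairs.itertuples():
            va, vb = arrs[row.group_a], arrs[row.group_b]
            se = np.sqrt(mse / 2 * (1 / len(va) + 1 / len(vb)))
            q = abs(vb.mean() - va.mean()) / se
            expected = studentized_range.sf(q, k, df)
            assert row.p_adj == pytest.approx(expected, abs=1e-6)

    def test_tukey_p_dominates_pairwise_t(self, rng):
        from scipy.stats import ttest_ind

        groups = {
            f"g{i}": list(rng.normal(i * 0.3, 1, 10)) for i in range(4)
        }
        res = ms.tukey_hsd(frame(groups))
        for row in res.pairs.itertuples():
            t_p = ttest_ind(groups[row.group_a], groups[row.group_b]).pvalue
            assert row.p_adj >= t_p - 1e-12


class TestCompactLetterDisplay:
    def test_no_significance_single_letter(self):
        letters = compact_letter_display(("a", "b", "c"), set())
        assert set(letters.values()) == {"a"}

    def test_chain_structure(self):
        # a != c, but b bridges both
        letters = compact_letter_display(
            ("a", "b", "c"), {frozenset(("a", "c"))}
        )
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])

    def test_all_pairs_significant_all_distinct(self):
        groups = ("a", "b", "c", "d")
        sig = {frozenset(p) for p in itertools.combinations(groups, 2)}
        letters = compact_letter_display(groups, sig)
        assert len(set(letters.values())) == 4

    def test_letters_encode_exactly_the_nonsignificance_graph(self, rng):
        # random significance patterns stay consistent with shared letters
        groups = ("a", "b", "c", "d", "e")
        pairs = list(itertools.combinations(groups, 2))
        for _ in range(30):
            sig = {frozenset(p) for p in pairs if rng.random() < 0.4}
            letters = compact_letter_display(groups, sig)
            for x, y in pairs:
                shared = bool(set(letters[x]) & set(letters[y]))
                assert shared == (frozenset((x, y)) not in sig)


class TestClassifyPattern:
    def test_exhaustive_flag_patterns_have_unique_labels(self):
        for flags in itertools.product([False, True], repeat=5):
            pat = ms.classify_from_flags(*flags)
            f1, f2, f3, f1_lake, f3_lake = flags
            if not (f1 or f2 or f3):
                assert pat.label == HERITABLE
            elif f1 and not f1_lake:
                assert pat.label == DEVELOPMENTAL_PLASTICITY
            elif not f1 and (f2 or f3):
                assert pat.label == TRANSGENERATIONAL_PLASTICITY
                assert pat.heritable_component == f3_lake
            else:
                assert pat.label == INDETERMINATE

    def test_observed_study_pattern_maps_to_washout_with_flag(self):
        pat = ms.classify_from_flags(
            f1_differs_f0=False, f2_differs_f0=True, f3_differs_f0=True,
            f1_differs_lake=True, f3_differs_lake=True,
        )
        assert pat.label == TRANSGENERATIONAL_PLASTICITY
        assert pat.heritable_component

    @pytest.mark.parametrize(
        "scenario,expected",
        [
            ("heritable", HERITABLE),
            ("developmental", DEVELOPMENTAL_PLASTICITY),
            ("transgenerational_washout", TRANSGENERATIONAL_PLASTICITY),
        ],
    )
    def test_recovers_generating_scenario(self, scenario, expected):
        sc = ms.PhenotypeScenario(scenario=scenario)
        shells = ms.with_aperture_index(ms.simulate_phenotypes(sc, seed=42))
        pattern = ms.classify_pattern(ms.tukey_hsd(shells))
        assert pattern.label == expected

    def test_missing_group_rejected(self, rng):
        res = ms.tukey_hsd(
            frame({"a": list(rng.normal(0, 1, 5)),
                   "b": list(rng.normal(0, 1, 5))})
        )
        with pytest.raises(ms.ConfigurationError):
            ms.classify_pattern(res)


class TestLineageSubset:
    def test_keeping_all_lineages_matches_unfiltered(self):
        sc = ms.PhenotypeScenario()
        shells = ms.with_aperture_index(ms.simulate_phenotypes(sc, seed=3))
        full = ms.one_way_anova(shells)
        anova, _, _ = ms.lineage_subset_analysis(shells, [1, 2, 3, 4, 5])
        assert anova.f_statistic == pytest.approx(full.f_statistic)

    def test_filter_tally_matches_brute_force(self):
        sc = ms.PhenotypeScenario()
        shells = ms.with_aperture_index(ms.simulate_phenotypes(sc, seed=3))
        keep = [2, 3, 5]
        anova, _, _ = ms.lineage_subset_analysis(shells, keep)
        expected = (
            shells["lineage"].isna() | shells["lineage"].isin(keep)
        ).sum()
        n = anova.df_within + anova.df_between + 1
        assert n == expected

    def test_classification_stable_under_subsetting(self):
        sc = ms.PhenotypeScenario(scenario="transgenerational_washout")
        shells = ms.with_aperture_index(ms.simulate_phenotypes(sc, seed=4))
        full_pattern = ms.classify_pattern(ms.tukey_hsd(shells))
        _, _, sub_pattern = ms.lineage_subset_analysis(shells, [2, 3, 5])
        assert sub_pattern.label == full_pattern.label

    def test_emptying_a_generation_rejected(self):
        sc = ms.PhenotypeScenario(n_lineages=2)
        shells = ms.with_aperture_index(ms.simulate_phenotypes(sc, seed=5))
        with pytest.raises(ms.ConfigurationError):
            ms.lineage_subset_analysis(shells, [99])
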