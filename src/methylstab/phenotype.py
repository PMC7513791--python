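"""Shell-shape arm: aperture index, ANOVA, Tukey HSD with compact letters,
and classification of the transgenerational pattern.

The aperture index (aperture width / shell height) summarizes current-
adaptation of the shell: river snails carry wider apertures for their height.
Group structure across populations is tested with one-way ANOVA and a
Tukey(-Kramer) post-hoc; groups sharing a compact-display letter are not
significantly different.  The generation pattern is then a pure function of
which groups differ: if the first lab generation already matches the lakes
the divergence was developmental plasticity; if it matches its river parents
and later generations drift, transgenerational plasticity; if nothing moves
across three lab generations, heritable (epi)genetic divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .config import ConfigurationError

__all__ = [
    "AnovaResult",
    "TukeyResult",
    "GenerationPattern",
    "aperture_index",
    "one_way_anova",
    "tukey_hsd",
    "compact_letter_display",
    "classify_pattern",
    "classify_from_flags",
    "lineage_subset_analysis",
]

DEVELOPMENTAL_PLASTICITY = "developmental_plasticity"
TRANSGENERATIONAL_PLASTICITY = "transgenerational_plasticity"
HERITABLE = "heritable"
INDETERMINATE = "mixed/indeterminate"


class MeasurementError(ValueError):
    pass


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: pd.Series
    group_se: pd.Series


@dataclass
class TukeyResult:
    pairs: pd.DataFrame  # group_a, group_b, mean_diff, p_adj, reject
    letters: dict[str, str]
    alpha: float
    group_order: tuple[str, ...]

    def differs(self, a: str, b: str) -> bool:
        """True when the two groups share no compact-display letter."""
        return not (set(self.letters[a]) & set(self.letters[b]))


@dataclass
class GenerationPattern:
    label: str
    heritable_component: bool
    flags: dict[str, bool] = field(default_factory=dict)
    supporting: pd.DataFrame | None = None


def aperture_index(width, height):
    """Aperture width over shell height; both must be positive."""
    w = np.asarray(width, dtype=float)
    h = np.asarray(height, dtype=float)
    if np.any(w <= 0) or np.any(h <= 0):
        raise MeasurementError("widths and heights must be positive")
    out = w / h
    return float(out) if out.ndim == 0 else out


def with_aperture_index(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    out["aperture_index"] = aperture_index(
        out["aperture_width"], out["shell_height"]
    )
    return out


def _grouped(records: pd.DataFrame, group_col: str, value_col: str):
    order = list(dict.fromkeys(records[group_col]))
    groups = [records.loc[records[group_col] == g, value_col].to_numpy()
              for g in order]
    return order, groups


def one_way_anova(
    records: pd.DataFrame,
    group_col: str = "population",
    value_col: str = "aperture_index",
) -> AnovaResult:
    """Classical between/within decomposition; p from the F distribution."""
    order, groups = _grouped(records, group_col, value_col)
    if len(order) < 2:
        raise ConfigurationError("ANOVA needs at least two groups")
    for g, vals in zip(order, groups):
        if len(vals) < 2:
            raise ConfigurationError(f"group {g!r} has fewer than 2 records")
    f, p = stats.f_oneway(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    means = pd.Series({g: float(np.mean(v)) for g, v in zip(order, groups)})
    se = pd.Series(
        {g: float(np.std(v, ddof=1) / np.sqrt(len(v)))
         for g, v in zip(order, groups)}
    )
    return AnovaResult(
        f_statistic=float(f),
        df_between=k - 1,
        df_within=n - k,
        p_value=float(p),
        group_means=means,
        group_se=se,
    )


def compact_letter_display(
    groups: tuple[str, ...], significant_pairs: set[frozenset[str]]
) -> dict[str, str]:
    """Insert-and-absorb letter assignment over the nonsignificance graph.

    Starts from one letter covering everything; every significant pair splits
    each letter containing both; letters that become subsets of another are
    absorbed.  Ties in letter naming are resolved by group order.
    """
    rank0 = {g: i for i, g in enumerate(groups)}
    ordered_pairs = sorted(
        (tuple(sorted(p, key=rank0.get)) for p in significant_pairs),
        key=lambda ab: (rank0[ab[0]], rank0[ab[1]]),
    )
    letters: list[set[str]] = [set(groups)]
    for a, b in ordered_pairs:
        new: list[set[str]] = []
        for ls in letters:
            if a in ls and b in ls:
                new.append(ls - {a})
                new.append(ls - {b})
            else:
                new.append(ls)
        # drop empties/duplicates, absorb strict subsets
        uniq: list[set[str]] = []
        for ls in new:
            if ls and ls not in uniq:
                uniq.append(ls)
        letters = [ls for ls in uniq if not any(ls < other for other in uniq)]
    # deterministic letter order: by earliest member in group order
    rank = {g: i for i, g in enumerate(groups)}
    letters.sort(key=lambda ls: sorted(rank[g] for g in ls))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, ls in enumerate(letters):
        ch = alphabet[i % len(alphabet)]
        for g in groups:
            if g in ls:
                out[g] += ch
    return out


def tukey_hsd(
    records: pd.DataFrame,
    group_col: str = "population",
    value_col: str = "aperture_index",
    alpha: float = 0.05,
) -> TukeyResult:
    """All pairwise comparisons via the studentized-range distribution.

    Unbalanced designs use the Tukey-Kramer standard error.  Compact letters
    are derived from the rejection pattern at ``alpha``.
    """
    order, groups = _grouped(records, group_col, value_col)
    for g, vals in zip(order, groups):
        if len(vals) < 2:
            raise ConfigurationError(f"group {g!r} has fewer than 2 records")
    res = pairwise_tukeyhsd(
        records[value_col].to_numpy(),
        records[group_col].to_numpy(),
        alpha=alpha,
    )
    tbl = pd.DataFrame(
        res.summary().data[1:],
        columns=[c.strip() for c in res.summary().data[0]],
    )
    pairs = pd.DataFrame(
        {
            "group_a": tbl["group1"].astype(str),
            "group_b": tbl["group2"].astype(str),
            "mean_diff": tbl["meandiff"].astype(float),
            "p_adj": np.asarray(res.pvalues, dtype=float),
            "reject": np.asarray(res.reject, dtype=bool),
        }
    )
    sig = {
        frozenset((r.group_a, r.group_b))
        for r in pairs.itertuples()
        if r.reject
    }
    letters = compact_letter_display(tuple(order), sig)
    return TukeyResult(
        pairs=pairs, letters=letters, alpha=alpha, group_order=tuple(order)
    )


def classify_from_flags(
    f1_differs_f0: bool,
    f2_differs_f0: bool,
    f3_differs_f0: bool,
    f1_differs_lake: bool,
    f3_differs_lake: bool,
) -> GenerationPattern:
    """Pure significance-pattern classifier (exhaustively testable).

    heritable: no lab generation differs from the river parents.
    developmental_plasticity: F1 already differs from F0 and matches lakes.
    transgenerational_plasticity: F1 matches F0 but a later generation moved;
    a heritable component is flagged when F3 still differs from the lakes.
    Everything else is mixed/indeterminate.
    """
    flags = {
        "f1_differs_f0": f1_differs_f0,
        "f2_differs_f0": f2_differs_f0,
        "f3_differs_f0": f3_differs_f0,
        "f1_differs_lake": f1_differs_lake,
        "f3_differs_lake": f3_differs_lake,
    }
    if not (f1_differs_f0 or f2_differs_f0 or f3_differs_f0):
        return GenerationPattern(HERITABLE, heritable_component=True, flags=flags)
    if f1_differs_f0 and not f1_differs_lake:
        return GenerationPattern(
            DEVELOPMENTAL_PLASTICITY, heritable_component=False, flags=flags
        )
    if not f1_differs_f0 and (f2_differs_f0 or f3_differs_f0):
        return GenerationPattern(
            TRANSGENERATIONAL_PLASTICITY,
            heritable_component=f3_differs_lake,
            flags=flags,
        )
    return GenerationPattern(INDETERMINATE, heritable_component=False, flags=flags)


def classify_pattern(
    tukey: TukeyResult,
    river_f0: str = "R2-F0",
    f1: str = "R2-F1",
    f2: str = "R2-F2",
    f3: str = "R2-F3",
    lakes: tuple[str, ...] = ("L1-F0", "L2-F0"),
) -> GenerationPattern:
    """Read the Fig-style expected-pattern logic off the Tukey letters.

    "Differs from lake" means differing from every lake reference group
    (conservative; with identical lake means the readings coincide).
    """
    for g in (river_f0, f1, f2, f3, *lakes):
        if g not in tukey.letters:
            raise ConfigurationError(f"group {g!r} missing from post-hoc result")
    pattern = classify_from_flags(
        f1_differs_f0=tukey.differs(f1, river_f0),
        f2_differs_f0=tukey.differs(f2, river_f0),
        f3_differs_f0=tukey.differs(f3, river_f0),
        f1_differs_lake=all(tukey.differs(f1, lk) for lk in lakes),
        f3_differs_lake=all(tukey.differs(f3, lk) for lk in lakes),
    )
    pattern.supporting = tukey.pairs
    return pattern


def lineage_subset_analysis(
    records: pd.DataFrame,
    keep_lineages,
    group_col: str = "population",
    value_col: str = "aperture_index",
    alpha: float = 0.05,
) -> tuple[AnovaResult, TukeyResult, GenerationPattern]:
    """Re-run the pipeline keeping only the given maternal lineages.

    Rows without a lineage (wild lake references) are always kept.  Erroring
    out when the filter empties a population guards the sensitivity check
    against silently dropping a generation.
    """
    keep = set(keep_lineages)
    mask = records["lineage"].isna() | records["lineage"].isin(keep)
    sub = records[mask]
    for g in dict.fromkeys(records[group_col]):
        if (sub[group_col] == g).sum() < 2:
            raise ConfigurationError(
                f"lineage filter leaves group {g!r} with <2 records"
            )
    anova = one_way_anova(sub, group_col, value_col)
    tukey = tukey_hsd(sub, group_col, value_col, alpha=alpha)
    pattern = classify_pattern(tukey)
    return anova, tukey, pattern
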