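#!/usr/bin/env python
"""Shell-shape arm: ANOVA, Tukey letters, and the transgenerational verdict.

Computes the aperture index per individual, tests for differences among the
seven populations/generations, assigns compact letters from the Tukey
post-hoc, classifies the generation pattern (developmental vs
transgenerational vs heritable), and repeats the analysis restricted to the
maternal lineages represented in every lab generation as a sensitivity
check.
"""

import argparse
from pathlib import Path

import methylstab as ms
from methylstab.io import read_table, write_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--outdir", type=Path, default=Path("results/phenotype"))
    ap.add_argument("--keep-lineages", type=str, default="2,3,5")
    args = ap.parse_args()

    shells = ms.with_aperture_index(read_table(args.indir / "shells.tsv"))
    anova = ms.one_way_anova(shells)
    tukey = ms.tukey_hsd(shells)
    pattern = ms.classify_pattern(tukey)

    print(f"one-way ANOVA across {anova.df_between + 1} groups: "
          f"F={anova.f_statistic:.1f} on ({anova.df_between}, "
          f"{anova.df_within}) df, p={anova.p_value:.3g}")
    print("group means (aperture index) with Tukey letters:")
    for g in tukey.group_order:
        print(f"  {g}: {anova.group_means[g]:.3f} +/- "
              f"{anova.group_se[g]:.3f}  [{tukey.letters[g]}]")
    print(f"pattern: {pattern.label} "
          f"(heritable component: {pattern.heritable_component})")

    keep = [int(x) for x in args.keep_lineages.split(",")]
    sub_anova, sub_tukey, sub_pattern = ms.lineage_subset_analysis(
        shells, keep
    )
    print(f"lineage subset {keep}: F={sub_anova.f_statistic:.1f}, "
          f"pattern {sub_pattern.label} -> "
          f"{'preserved' if sub_pattern.label == pattern.label else 'CHANGED'}")

    args.outdir.mkdir(parents=True, exist_ok=True)
    write_table(tukey.pairs, args.outdir / "tukey_pairs.tsv")
    letters = [
        {"population": g, "mean": anova.group_means[g],
         "se": anova.group_se[g], "letters": tukey.letters[g]}
        for g in tukey.group_order
    ]
    import pandas as pd

    write_table(pd.DataFrame(letters), args.outdir / "letters.tsv")
    (args.outdir / "verdict.txt").write_text(
        f"{pattern.label}\nheritable_component={pattern.heritable_component}\n"
    )
    print(f"written to {args.outdir}/")


if __name__ == "__main__":
    main()
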