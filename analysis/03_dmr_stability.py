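#!/usr/bin/env python
"""Between-generation stability of DMRs: overlaps and the tier funnel.

Rebuilds DMR sets from the persisted window tables, reports pairwise overlap
of the two F1-vs-lake DMR sets, the relaxed-threshold (p < 0.05) support of
each in the other comparison, and the three-tier habitat-stability funnel
against the four lake-vs-river comparisons; checks tier-3 calls against the
planted truth.
"""

import argparse
from pathlib import Path

import methylstab as ms
from methylstab.io import read_table, write_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--simdir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--dmrdir", type=Path, default=Path("results/dmr"))
    ap.add_argument("--outdir", type=Path, default=Path("results/stability"))
    args = ap.parse_args()

    config = ms.study_config_from_json(
        (args.simdir / "config.json").read_text()
    )
    results = {
        comp.name: read_table(args.dmrdir / f"windows.{comp.name}.tsv")
        for comp in config.comparisons
    }
    sets = {
        name: ms.extend_and_merge(res, config.thresholds, comparison=name)
        for name, res in results.items()
    }

    f1_lake = ["R2F1_vs_L1", "R2F1_vs_L2"]
    quartet = ["R1_vs_L1", "R1_vs_L2", "R2F0_vs_L1", "R2F0_vs_L2"]

    rep = ms.overlap_dmr_sets(sets[f1_lake[0]], sets[f1_lake[1]])
    print(f"overlap {rep.label_a} ({rep.n_a}) vs {rep.label_b} ({rep.n_b}): "
          f"{rep.n_overlap_a}/{rep.n_a} share windows, "
          f"jaccard={rep.jaccard:.2f}")
    for a, b in [(f1_lake[0], f1_lake[1]), (f1_lake[1], f1_lake[0])]:
        frac = ms.relaxed_overlap_fraction(sets[a], results[b])
        print(f"relaxed support of {a} DMRs at p<0.05 in {b}: {100*frac:.1f}%")

    tiers = ms.habitat_stability_tiers(
        sets[f1_lake[0]], sets[f1_lake[1]], [sets[n] for n in quartet]
    )
    t1, t2, t3 = tiers.sizes
    print(f"stability funnel: tier1={t1} (F1 vs both lakes), "
          f"tier2={t2} (also in >=1 lake-vs-river), "
          f"tier3={t3} (in all 4 lake-vs-river)")

    truth = read_table(args.simdir / "truth.tsv")
    t3_cores = set().union(
        *[set(d.core_window_ids) for d in tiers.tier3]
    ) if tiers.tier3 else set()
    regions = truth[truth.truth_class != "null"].groupby(
        ["region_id", "truth_class"]
    )["window_id"].agg(set)
    for cls in ("habitat_divergent_stable", "habitat_divergent_responsive"):
        hits = [bool(w & t3_cores) for (_, c), w in regions.items() if c == cls]
        if hits:
            print(f"tier3 hits {sum(hits)}/{len(hits)} planted {cls} regions")

    args.outdir.mkdir(parents=True, exist_ok=True)
    write_table(tiers.provenance, args.outdir / "stability_tiers.tsv")
    print(f"written to {args.outdir}/")


if __name__ == "__main__":
    main()
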