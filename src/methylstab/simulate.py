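"""Synthetic MeDIP study generator.

Produces a reference sequence with controlled CpG structure, pooled window
counts with planted differential regions (the truth table), and multi-
generation shell-shape tables under three transgenerational scenarios.

Three independent random streams are spawned from the config seed (reference,
counts, phenotypes) so each artifact is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    LAB_F1,
    LAKE,
    NULL,
    RESPONSIVE,
    RIVER,
    SITE_SPECIFIC,
    STABLE,
    ConfigurationError,
    PhenotypeScenario,
    SimulationConfig,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# stream indices under the config seed
_REF_STREAM = 0
_COUNT_STREAM = 1
_PHENO_STREAM = 2


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, seed])


@dataclass
class CountMatrix:
    """Windows x samples fragment counts plus sample metadata.

    ``counts`` is indexed by window_id with one column per pool;
    ``samples`` has one row per column (sample, population, habitat,
    generation, n_individuals); ``library_size`` is total fragments per pool;
    ``windows`` is the grid (contig, start, end, window_id[, cpg_count]).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    library_size: pd.Series
    windows: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples["sample"]):
            raise ValueError("count columns and sample sheet rows must align")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        colsum = self.counts.sum(axis=0)
        if (self.library_size < colsum).any():
            raise ValueError("library_size must be >= column sums")

    @property
    def n_windows(self) -> int:
        return len(self.counts)

    @property
    def sample_names(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, populations) -> list[str]:
        """Sample ids belonging to the given population labels, sheet order."""
        populations = list(populations)
        known = set(self.samples["population"])
        missing = set(populations) - known
        if missing:
            raise ConfigurationError(
                f"unknown population label(s) {sorted(missing)}"
            )
        mask = self.samples["population"].isin(populations)
        return list(self.samples.loc[mask, "sample"])

    def subset_windows(self, window_ids) -> "CountMatrix":
        keep = self.counts.index.isin(set(window_ids))
        return CountMatrix(
            counts=self.counts.loc[keep],
            samples=self.samples,
            library_size=self.library_size,
            windows=self.windows[self.windows["window_id"].isin(
                set(window_ids))].reset_index(drop=True),
        )


def generate_reference(
    config: SimulationConfig,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Build contig sequences and their 100-bp window grid with CpG counts.

    Each window is drawn as a CpG island (>= 10 CpG/100 bp) with probability
    ``cpg_island_fraction``, otherwise a desert window with 0-8 CpG.  The
    background sequence is scrubbed of accidental CG dinucleotides and the
    target number of CGs is planted at even in-window offsets, so the emitted
    per-window CpG counts are exact by construction (and verifiable by an
    independent dinucleotide scan).
    """
    ws = config.window_size
    if config.contig_length < ws:
        raise ConfigurationError("contig_length must be >= window_size")
    rng = _rng(config.seed, _REF_STREAM)
    n_win = config.windows_per_contig
    n_slots = (ws - 1) // 2  # non-overlapping CG slots at even offsets
    island_low, island_high = 10, min(20, n_slots)
    if island_high < island_low and config.cpg_island_fraction > 0:
        raise ConfigurationError(
            "window_size too small to host a CpG island (>=10 CpG)"
        )

    contigs: dict[str, str] = {}
    rows = []
    window_id = 0
    for c in range(config.n_contigs):
        name = f"contig_{c + 1:03d}"
        seq = rng.choice(_BASES, size=config.contig_length)
        # scrub accidental CG so planted counts are exact
        cg = (seq[:-1] == b"C") & (seq[1:] == b"G")
        seq[1:][cg] = b"T"

        island = rng.random(n_win) < config.cpg_island_fraction
        targets = np.where(
            island,
            rng.integers(island_low, island_high + 1, size=n_win),
            rng.integers(0, 9, size=n_win),
        )
        for w in range(n_win):
            start = w * ws
            c_target = int(targets[w])
            if c_target:
                offs = rng.choice(n_slots, size=c_target, replace=False) * 2
                seq[start + offs] = b"C"
                seq[start + offs + 1] = b"G"
            rows.append((name, start, start + ws, window_id, c_target))
            window_id += 1
        contigs[name] = seq.tobytes().decode("ascii")

    windows = pd.DataFrame(
        rows, columns=["contig", "start", "end", "window_id", "cpg_count"]
    )
    return contigs, windows


def _plant_regions(
    config: SimulationConfig, windows: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Choose non-overlapping planted regions; returns per-window truth rows.

    Regions are spaced by >= 20 windows and kept >= 10 windows from contig
    ends so distinct regions stay well separated; note that edge extension
    can still occasionally bridge neighbours through sub-0.1 null windows,
    which is why truth matching downstream uses core windows.
    """
    span = config.dmr_span_windows
    margin, spacing = 10, 20
    total = sum(config.n_planted.get(cls, 0) for cls in (STABLE, RESPONSIVE,
                                                         SITE_SPECIFIC))
    if config.effect_fold == 1.0:
        total = 0  # degenerate planting: no effect => everything is null

    candidates: list[int] = []  # global window index of region start
    for contig, grp in windows.groupby("contig", sort=False):
        ids = grp["window_id"].to_numpy()
        n = len(ids)
        starts = np.arange(margin, n - span - margin, span + spacing)
        candidates.extend(int(ids[s]) for s in starts)
    if total > len(candidates):
        raise ConfigurationError(
            f"cannot place {total} planted regions in {len(candidates)} slots; "
            "increase genome size or reduce n_planted"
        )

    chosen = rng.permutation(len(candidates))[:total]
    pop_labels = [p.label for p in config.populations]
    rows = []
    region_id = 0
    order = [
        (STABLE, config.n_planted.get(STABLE, 0)),
        (RESPONSIVE, config.n_planted.get(RESPONSIVE, 0)),
        (SITE_SPECIFIC, config.n_planted.get(SITE_SPECIFIC, 0)),
    ]
    k = 0
    for cls, n_regions in order:
        for _ in range(n_regions if total else 0):
            start = candidates[chosen[k]]
            k += 1
            direction = "hyper" if rng.random() < 0.5 else "hypo"
            target_pop = (
                pop_labels[region_id % len(pop_labels)]
                if cls == SITE_SPECIFIC
                else ""
            )
            for w in range(span):
                rows.append((start + w, cls, direction, region_id, target_pop))
            region_id += 1
    planted = pd.DataFrame(
        rows,
        columns=["window_id", "truth_class", "direction", "region_id",
                 "target_population"],
    )
    return planted


def simulate_counts(
    config: SimulationConfig, windows: pd.DataFrame
) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw NB pooled counts with planted truth.

    Truth classes act on the mean: habitat_divergent_stable windows carry the
    fold change in river *and* lab_F1 pools, habitat_divergent_responsive in
    river pools only (the lab F1 reverts to lake-like), site_specific in
    exactly one population.  'hypo' directions divide instead of multiply.
    The truth table has one row per window; unplanted windows are class
    'null'.
    """
    if windows.empty:
        raise ConfigurationError("windows must be nonempty")
    if not config.populations:
        raise ConfigurationError("populations must be nonempty")
    rng = _rng(config.seed, _COUNT_STREAM)

    sample_rows = []
    for pop in config.populations:
        generation = "F1" if pop.habitat == LAB_F1 else "F0"
        for i in range(pop.n_pools):
            sample_rows.append(
                (f"{pop.label}_p{i + 1}", pop.label, pop.habitat, generation,
                 pop.pool_size)
            )
    samples = pd.DataFrame(
        sample_rows,
        columns=["sample", "population", "habitat", "generation",
                 "n_individuals"],
    )
    n_samples = len(samples)
    n_windows = len(windows)

    planted = _plant_regions(config, windows, rng)

    # per-window x per-sample mean matrix
    depth = np.exp(rng.normal(0.0, config.library_size_sigma, size=n_samples))
    mu = np.full((n_windows, n_samples), config.baseline_mean)
    wid_to_row = pd.Series(
        np.arange(n_windows), index=windows["window_id"].to_numpy()
    )
    habitat = samples["habitat"].to_numpy()
    population = samples["population"].to_numpy()
    for (cls, direction, target_pop), grp in planted.groupby(
        ["truth_class", "direction", "target_population"], sort=False
    ):
        if cls == STABLE:
            affected = (habitat == RIVER) | (habitat == LAB_F1)
        elif cls == RESPONSIVE:
            affected = habitat == RIVER
        else:
            affected = population == target_pop
        factor = config.effect_fold if direction == "hyper" else 1.0 / config.effect_fold
        rows = wid_to_row.loc[grp["window_id"].to_numpy()].to_numpy()
        mu[np.ix_(rows, np.flatnonzero(affected))] *= factor
    mu *= depth[np.newaxis, :]

    phi = config.dispersion
    if phi == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / phi
        p = 1.0 / (1.0 + phi * mu)
        counts = rng.negative_binomial(r, p)

    counts_df = pd.DataFrame(
        counts, index=windows["window_id"].to_numpy(), columns=samples["sample"]
    )
    counts_df.index.name = "window_id"
    library_size = counts_df.sum(axis=0)
    library_size.name = "library_size"

    truth = windows[["window_id"]].copy()
    truth["truth_class"] = NULL
    truth["direction"] = ""
    truth["region_id"] = -1
    truth["target_population"] = ""
    if not planted.empty:
        truth = truth.set_index("window_id")
        p = planted.set_index("window_id")
        truth.loc[p.index, ["truth_class", "direction", "region_id",
                            "target_population"]] = p[
            ["truth_class", "direction", "region_id", "target_population"]
        ]
        truth = truth.reset_index()

    cm = CountMatrix(
        counts=counts_df,
        samples=samples,
        library_size=library_size,
        windows=windows.reset_index(drop=True),
    )
    return cm, truth


def simulate_phenotypes(
    scenario: PhenotypeScenario, seed: int
) -> pd.DataFrame:
    """Shell-measurement table for F0 river, lab F1-F3, and two lake refs.

    Aperture index is drawn Normal(mu_generation, sd); shell height is drawn
    around 4 mm and aperture width set as index * height, so the index is
    recovered exactly by width/height.  Maternal lineages are assigned
    round-robin to river-derived individuals.
    """
    rng = _rng(seed, _PHENO_STREAM)
    groups: list[tuple[str, str, str, float, bool]] = [
        ("R2-F0", RIVER, "F0", scenario.mu_river, True),
        ("R2-F1", LAB_F1, "F1", scenario.generation_mean(1), True),
        ("R2-F2", LAB_F1, "F2", scenario.generation_mean(2), True),
        ("R2-F3", LAB_F1, "F3", scenario.generation_mean(3), True),
        ("L1-F0", LAKE, "F0", scenario.mu_lake, False),
        ("L2-F0", LAKE, "F0", scenario.mu_lake, False),
    ]
    lineage_effect = (
        rng.normal(0.0, scenario.lineage_sd, size=scenario.n_lineages)
        if scenario.lineage_sd > 0
        else np.zeros(scenario.n_lineages)
    )
    rows = []
    for pop, habitat, gen, mu, lineaged in groups:
        n = scenario.n_per_generation
        for i in range(n):
            lineage = (i % scenario.n_lineages) + 1 if lineaged else pd.NA
            shift = lineage_effect[i % scenario.n_lineages] if lineaged else 0.0
            index = rng.normal(mu + shift, scenario.sd)
            height = max(0.5, rng.normal(4.0, 0.2))
            index = max(index, 1e-3)  # aperture widths must stay positive
            rows.append(
                (f"{pop}_{i + 1:03d}", pop, habitat, gen, lineage,
                 height, index * height)
            )
    return pd.DataFrame(
        rows,
        columns=["individual", "population", "habitat", "generation",
                 "lineage", "shell_height", "aperture_width"],
    )


def fragments_from_counts(
    cm: CountMatrix, seed: int = 0, fragment_length: int = 300
) -> dict[str, pd.DataFrame]:
    """Optional read-level adapter: expand window counts into fragment BEDs.

    Each counted fragment gets a midpoint uniform within its window, so the
    midpoint-rule counter recovers the original matrix exactly.  Coordinates
    may extend past contig bounds by half a fragment; downstream only the
    midpoint matters.
    """
    rng = np.random.default_rng([3, seed])
    half = fragment_length // 2
    out: dict[str, pd.DataFrame] = {}
    win = cm.windows.set_index("window_id")
    for sample in cm.sample_names:
        col = cm.counts[sample]
        contigs, starts, ends = [], [], []
        for wid, count in col.items():
            if count == 0:
                continue
            w = win.loc[wid]
            mids = rng.integers(w["start"], w["end"], size=int(count))
            s = np.maximum(mids - half, 0)  # clamp preserves the midpoint
            e = 2 * mids - s
            contigs.extend([w["contig"]] * int(count))
            starts.extend(s.tolist())
            ends.extend(e.tolist())
        out[sample] = pd.DataFrame(
            {"contig": contigs,
             "start": np.array(starts, dtype=int),
             "end": np.array(ends, dtype=int)}
        )
    return out
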