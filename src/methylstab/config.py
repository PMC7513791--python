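"""Configuration objects for the synthetic study and the analysis thresholds.

All configs are frozen dataclasses with JSON round-trip support; the study
config hashes canonically so a report can state exactly which conditions
produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping

# habitat labels
LAKE = "lake"
RIVER = "river"
LAB_F1 = "lab_F1"
HABITATS = (LAKE, RIVER, LAB_F1)

# truth classes for planted differential regions
NULL = "null"
STABLE = "habitat_divergent_stable"
RESPONSIVE = "habitat_divergent_responsive"
SITE_SPECIFIC = "site_specific"
TRUTH_CLASSES = (STABLE, RESPONSIVE, SITE_SPECIFIC)

# phenotype scenarios
DEVELOPMENTAL = "developmental"
WASHOUT = "transgenerational_washout"
HERITABLE = "heritable"
SCENARIOS = (DEVELOPMENTAL, WASHOUT, HERITABLE)


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class PopulationSpec:
    """One pooled population: a label, its habitat, and its pooling design."""

    label: str
    habitat: str
    n_pools: int = 3
    pool_size: int = 10

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise ConfigurationError(
                f"habitat must be one of {HABITATS}, got {self.habitat!r}"
            )
        if self.n_pools < 1:
            raise ConfigurationError(f"{self.label}: n_pools must be >= 1")
        if self.pool_size < 1:
            raise ConfigurationError(f"{self.label}: pool_size must be >= 1")


def default_populations() -> tuple[PopulationSpec, ...]:
    """The five-population design: two lakes, two rivers, and the lab-reared F1.

    Wild river pools hold 20 individuals, lake and lab pools 10, matching
    pools of 10-20 individuals per population, three pools each.
    """
    return (
        PopulationSpec("L1", LAKE, 3, 10),
        PopulationSpec("L2", LAKE, 3, 10),
        PopulationSpec("R1", RIVER, 3, 20),
        PopulationSpec("R2F0", RIVER, 3, 20),
        PopulationSpec("R2F1", LAB_F1, 3, 10),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for the synthetic MeDIP study.

    Counts are negative-binomial per window x pool with variance mu + phi*mu^2.
    ``n_planted`` maps truth class -> number of planted regions, each spanning
    ``dmr_span_windows`` consecutive windows at ``effect_fold`` fold change in
    the elevated (or reduced, for hypomethylated) group.
    """

    seed: int = 0
    n_contigs: int = 20
    contig_length: int = 50_000
    window_size: int = 100
    populations: tuple[PopulationSpec, ...] = field(
        default_factory=default_populations
    )
    baseline_mean: float = 50.0
    dispersion: float = 0.1
    n_planted: Mapping[str, int] = field(
        default_factory=lambda: {STABLE: 40, RESPONSIVE: 4, SITE_SPECIFIC: 5}
    )
    effect_fold: float = 4.0
    dmr_span_windows: int = 4
    cpg_island_fraction: float = 0.1
    library_size_sigma: float = 0.1

    def __post_init__(self) -> None:
        object.__setattr__(self, "populations", tuple(self.populations))
        object.__setattr__(self, "n_planted", dict(self.n_planted))
        if self.n_contigs < 1 or self.contig_length < 1:
            raise ConfigurationError("n_contigs and contig_length must be positive")
        if self.window_size < 2:
            raise ConfigurationError("window_size must be >= 2")
        if self.contig_length < self.window_size:
            raise ConfigurationError("contig_length must be >= window_size")
        if not self.populations:
            raise ConfigurationError("at least one population is required")
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("population labels must be unique")
        if self.baseline_mean <= 0:
            raise ConfigurationError("baseline_mean must be positive")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion (phi) must be >= 0")
        if self.effect_fold < 1:
            raise ConfigurationError("effect_fold must be >= 1")
        if self.dmr_span_windows < 1:
            raise ConfigurationError("dmr_span_windows must be >= 1")
        if not 0 <= self.cpg_island_fraction <= 1:
            raise ConfigurationError("cpg_island_fraction must lie in [0, 1]")
        for cls, n in self.n_planted.items():
            if cls not in TRUTH_CLASSES:
                raise ConfigurationError(f"unknown truth class {cls!r}")
            if n < 0:
                raise ConfigurationError(f"n_planted[{cls!r}] must be >= 0")

    @property
    def windows_per_contig(self) -> int:
        return self.contig_length // self.window_size

    @property
    def n_windows(self) -> int:
        return self.n_contigs * self.windows_per_contig

    def population(self, label: str) -> PopulationSpec:
        for p in self.populations:
            if p.label == label:
                return p
        raise ConfigurationError(f"unknown population {label!r}")


@dataclass(frozen=True)
class PhenotypeScenario:
    """Generating model for the aperture-index table across generations.

    Under the washout model the lab generations decay geometrically from the
    river mean toward the lake mean: mu_Fg = mu_lake + (mu_river - mu_lake) *
    r**(g-1) for g >= 1.  r = 1 is full heritability; the developmental
    scenario snaps every lab generation to the lake mean.
    """

    scenario: str = WASHOUT
    mu_river: float = 0.8
    mu_lake: float = 0.6
    washout_rate: float = 0.5
    sd: float = 0.05
    n_per_generation: int = 30
    n_lineages: int = 5
    lineage_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(f"scenario must be one of {SCENARIOS}")
        if self.sd <= 0:
            raise ConfigurationError("sd must be positive")
        if not 0 <= self.washout_rate <= 1:
            raise ConfigurationError("washout_rate must lie in [0, 1]")
        if self.n_per_generation < 2:
            raise ConfigurationError("n_per_generation must be >= 2")
        if self.n_lineages < 1:
            raise ConfigurationError("n_lineages must be >= 1")
        if self.lineage_sd < 0:
            raise ConfigurationError("lineage_sd must be >= 0")

    def generation_mean(self, generation: int) -> float:
        """Expected aperture index of lab generation Fg (g >= 1); g=0 is F0."""
        if generation == 0:
            return self.mu_river
        if self.scenario == DEVELOPMENTAL:
            return self.mu_lake
        r = 1.0 if self.scenario == HERITABLE else self.washout_rate
        return self.mu_lake + (self.mu_river - self.mu_lake) * r ** (generation - 1)


@dataclass(frozen=True)
class AnalysisThresholds:
    """DMR calling and reporting thresholds.

    alpha_core seeds DMRs (strict p < alpha_core); edges extend through
    windows with p < alpha_edge lying within extension_distance bp of the
    growing DMR boundary; regions averaging fewer than cpg_desert_cutoff CpG
    per 100 bp are deserts.
    """

    alpha_core: float = 1e-5
    alpha_edge: float = 0.1
    extension_distance: int = 1_000
    alpha_relaxed: float = 0.05
    window_size: int = 100
    cpg_desert_cutoff: float = 10.0
    fdr_report_cutoffs: tuple[float, ...] = (0.01, 0.1)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "fdr_report_cutoffs", tuple(self.fdr_report_cutoffs)
        )
        for name in ("alpha_core", "alpha_edge", "alpha_relaxed"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigurationError(f"{name} must lie in (0, 1]")
        if self.alpha_core >= self.alpha_edge:
            raise ConfigurationError("alpha_core must be < alpha_edge")
        if self.extension_distance <= 0 or self.window_size <= 0:
            raise ConfigurationError(
                "extension_distance and window_size must be positive"
            )
        if self.cpg_desert_cutoff <= 0:
            raise ConfigurationError("cpg_desert_cutoff must be positive")


@dataclass(frozen=True)
class Comparison:
    """A two-group contrast named by its populations (group A vs group B)."""

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "group_a", tuple(self.group_a))
        object.__setattr__(self, "group_b", tuple(self.group_b))
        if not self.group_a or not self.group_b:
            raise ConfigurationError(f"{self.name}: both groups must be nonempty")
        if set(self.group_a) & set(self.group_b):
            raise ConfigurationError(f"{self.name}: groups must be disjoint")


def default_comparisons() -> tuple[Comparison, ...]:
    """F1 against each wild population, plus the lake-vs-river quartet."""
    return (
        Comparison("R2F1_vs_L1", ("R2F1",), ("L1",)),
        Comparison("R2F1_vs_L2", ("R2F1",), ("L2",)),
        Comparison("R2F1_vs_R1", ("R2F1",), ("R1",)),
        Comparison("R2F1_vs_R2F0", ("R2F1",), ("R2F0",)),
        Comparison("R1_vs_L1", ("R1",), ("L1",)),
        Comparison("R1_vs_L2", ("R1",), ("L2",)),
        Comparison("R2F0_vs_L1", ("R2F0",), ("L1",)),
        Comparison("R2F0_vs_L2", ("R2F0",), ("L2",)),
    )


@dataclass(frozen=True)
class StudyConfig:
    """Everything the end-to-end study replica needs."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: AnalysisThresholds = field(default_factory=AnalysisThresholds)
    phenotype: PhenotypeScenario = field(default_factory=PhenotypeScenario)
    comparisons: tuple[Comparison, ...] = field(default_factory=default_comparisons)
    min_total: int | None = None  # coverage filter; None -> number of samples
    pca_components: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "comparisons", tuple(self.comparisons))
        known = {p.label for p in self.simulation.populations}
        for comp in self.comparisons:
            missing = (set(comp.group_a) | set(comp.group_b)) - known
            if missing:
                raise ConfigurationError(
                    f"comparison {comp.name} references unknown populations "
                    f"{sorted(missing)}"
                )
        if self.pca_components < 1:
            raise ConfigurationError("pca_components must be >= 1")

    def with_seed(self, seed: int) -> "StudyConfig":
        return replace(self, simulation=replace(self.simulation, seed=seed))

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)

    def config_hash(self) -> str:
        canonical = json.dumps(asdict(self), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canonical.encode()).hexdigest()


def study_config_from_json(text: str) -> StudyConfig:
    """Rebuild a StudyConfig from ``StudyConfig.to_json`` output."""
    raw = json.loads(text)
    sim = dict(raw["simulation"])
    sim["populations"] = tuple(
        PopulationSpec(**p) for p in sim.get("populations", ())
    )
    comps = tuple(Comparison(**c) for c in raw.get("comparisons", ()))
    return StudyConfig(
        simulation=SimulationConfig(**sim),
        thresholds=AnalysisThresholds(**raw["thresholds"]),
        phenotype=PhenotypeScenario(**raw["phenotype"]),
        comparisons=comps,
        min_total=raw.get("min_total"),
        pca_components=raw.get("pca_components", 2),
    )
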