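"""End-to-end study replica: simulate -> windows -> counts -> test -> DMRs ->
stability tiers -> PCA -> phenotype -> unified report.

The report carries no timestamps, so two runs under the same config and seed
produce byte-identical JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .config import LAKE, RIVER, StudyConfig
from .diffmeth import estimate_common_dispersion, test_windows
from .dmr import DMRSet, annotate_cpg_class, dmr_summary, extend_and_merge
from .io import (
    write_count_matrix,
    write_fasta,
    write_table,
    write_windows_bed,
)
from .pca import group_centroid_distances, run_pca
from .phenotype import (
    classify_pattern,
    one_way_anova,
    tukey_hsd,
    with_aperture_index,
)
from .simulate import (
    CountMatrix,
    generate_reference,
    simulate_counts,
    simulate_phenotypes,
)
from .stability import habitat_stability_tiers, relaxed_overlap_fraction
from .windows import filter_windows, rpkm_normalize

logger = logging.getLogger("methylstab")

__all__ = ["StudyReport", "StageError", "run_study", "write_report"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class StudyReport:
    seed: int
    config_hash: str
    version: str
    n_windows_total: int
    n_windows_tested: int
    phi_estimates: dict[str, float]
    dmr_counts: dict[str, int]
    dmr_summaries: dict[str, dict]
    tier_sizes: dict[str, int]
    relaxed_overlap: dict[str, float]
    pca: dict
    phenotype: dict
    dmr_count_ratio_f1_lakes_over_rivers: float | None

    # artifacts not serialized into the JSON report
    dmr_sets: dict[str, DMRSet] = field(default_factory=dict, repr=False)
    window_results: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)
    tiers: object = field(default=None, repr=False)
    count_matrix: CountMatrix | None = field(default=None, repr=False)
    truth: pd.DataFrame | None = field(default=None, repr=False)
    shells: pd.DataFrame | None = field(default=None, repr=False)
    pca_scores: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config_hash": self.config_hash,
            "version": self.version,
            "n_windows_total": self.n_windows_total,
            "n_windows_tested": self.n_windows_tested,
            "phi_estimates": self.phi_estimates,
            "dmr_counts": self.dmr_counts,
            "dmr_summaries": self.dmr_summaries,
            "tier_sizes": self.tier_sizes,
            "relaxed_overlap": self.relaxed_overlap,
            "pca": self.pca,
            "phenotype": self.phenotype,
            "dmr_count_ratio_f1_lakes_over_rivers":
                self.dmr_count_ratio_f1_lakes_over_rivers,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise StageError(name, exc) from exc
        return wrapped
    return deco


def _f1_comparison_groups(config: StudyConfig):
    """Split default comparisons into F1-vs-lake / F1-vs-river / quartet."""
    habitat = {p.label: p.habitat for p in config.simulation.populations}
    f1_lake, f1_river, quartet = [], [], []
    for comp in config.comparisons:
        habs_a = {habitat[l] for l in comp.group_a}
        habs_b = {habitat[l] for l in comp.group_b}
        if habs_a == {"lab_F1"}:
            (f1_lake if habs_b == {LAKE} else f1_river).append(comp.name)
        elif (habs_a == {RIVER} and habs_b == {LAKE}) or (
            habs_a == {LAKE} and habs_b == {RIVER}
        ):
            quartet.append(comp.name)
    return f1_lake, f1_river, quartet


def run_study(
    config: StudyConfig,
    outdir: str | Path | None = None,
    write_intermediates: bool = True,
) -> StudyReport:
    """Execute every stage of the study replica; optionally persist artifacts."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    sim = config.simulation

    contigs, windows = _stage("reference")(generate_reference)(sim)
    cm, truth = _stage("counts")(simulate_counts)(sim, windows)

    min_total = (
        config.min_total if config.min_total is not None else len(cm.sample_names)
    )
    cm_f = _stage("coverage_filter")(filter_windows)(cm, min_total)
    rpkm = _stage("rpkm")(rpkm_normalize)(cm_f)

    phi_estimates: dict[str, float] = {}
    window_results: dict[str, pd.DataFrame] = {}
    dmr_sets: dict[str, DMRSet] = {}
    dmr_counts: dict[str, int] = {}
    summaries: dict[str, dict] = {}

    @_stage("diff_methylation")
    def _run_comparisons():
        for comp in config.comparisons:
            cols = (
                cm_f.samples_for(comp.group_a),
                cm_f.samples_for(comp.group_b),
            )
            phi = estimate_common_dispersion(cm_f, cols).phi_common
            phi_estimates[comp.name] = phi
            res = test_windows(cm_f, (comp.group_a, comp.group_b), phi=phi)
            window_results[comp.name] = res
            dmrs = extend_and_merge(res, config.thresholds, comparison=comp.name)
            annotate_cpg_class(dmrs, cm_f.windows)
            dmr_sets[comp.name] = dmrs
            dmr_counts[comp.name] = len(dmrs)
            summaries[comp.name] = dmr_summary(dmrs)
            logger.info("  %s: %d DMRs (phi=%.4f)", comp.name, len(dmrs), phi)

    _run_comparisons()

    f1_lake, f1_river, quartet = _f1_comparison_groups(config)

    @_stage("stability")
    def _stability():
        tiers = None
        relaxed: dict[str, float] = {}
        if len(f1_lake) >= 2 and len(quartet) == 4:
            tiers = habitat_stability_tiers(
                dmr_sets[f1_lake[0]],
                dmr_sets[f1_lake[1]],
                [dmr_sets[n] for n in quartet],
            )
            relaxed[f"{f1_lake[0]}_in_{f1_lake[1]}"] = relaxed_overlap_fraction(
                dmr_sets[f1_lake[0]], window_results[f1_lake[1]]
            )
            relaxed[f"{f1_lake[1]}_in_{f1_lake[0]}"] = relaxed_overlap_fraction(
                dmr_sets[f1_lake[1]], window_results[f1_lake[0]]
            )
        return tiers, relaxed

    tiers, relaxed = _stability()
    tier_sizes = (
        {"tier1": tiers.sizes[0], "tier2": tiers.sizes[1], "tier3": tiers.sizes[2]}
        if tiers is not None
        else {}
    )

    @_stage("pca")
    def _pca():
        pca = run_pca(rpkm, n_components=config.pca_components)
        report = group_centroid_distances(
            pca, cm_f.samples, n_components=config.pca_components
        )
        return pca, report

    pca_result, centroid = _pca()

    @_stage("phenotype")
    def _phenotype():
        shells = simulate_phenotypes(config.phenotype, sim.seed)
        shells = with_aperture_index(shells)
        anova = one_way_anova(shells)
        tukey = tukey_hsd(shells)
        pattern = classify_pattern(tukey)
        return shells, anova, tukey, pattern

    shells, anova, tukey, pattern = _phenotype()

    n_f1_lake = sum(dmr_counts[n] for n in f1_lake)
    n_f1_river = sum(dmr_counts[n] for n in f1_river)
    ratio = n_f1_lake / n_f1_river if n_f1_river else None

    report = StudyReport(
        seed=sim.seed,
        config_hash=config.config_hash(),
        version=__version__,
        n_windows_total=len(windows),
        n_windows_tested=cm_f.n_windows,
        phi_estimates=phi_estimates,
        dmr_counts=dmr_counts,
        dmr_summaries=summaries,
        tier_sizes=tier_sizes,
        relaxed_overlap=relaxed,
        pca={
            "f1_river_like": centroid.f1_river_like,
            "tie": centroid.tie,
            "explained_variance_ratio": [
                float(v) for v in pca_result.explained_variance_ratio
            ],
            "centroid_distances": {
                a: {b: float(centroid.distances.loc[a, b])
                    for b in centroid.distances.columns}
                for a in centroid.distances.index
            },
        },
        phenotype={
            "anova_f": anova.f_statistic,
            "anova_p": anova.p_value,
            "df_between": anova.df_between,
            "df_within": anova.df_within,
            "scenario": pattern.label,
            "heritable_component": pattern.heritable_component,
            "letters": tukey.letters,
            "group_means": {k: float(v) for k, v in anova.group_means.items()},
        },
        dmr_count_ratio_f1_lakes_over_rivers=ratio,
        dmr_sets=dmr_sets,
        window_results=window_results,
        tiers=tiers,
        count_matrix=cm_f,
        truth=truth,
        shells=shells,
        pca_scores=pca_result.scores,
    )

    if out is not None:
        write_report(report, out)
        if write_intermediates:
            _write_intermediates(out, contigs, windows, cm, truth, shells,
                                 pca_result, window_results, dmr_sets, tiers,
                                 config)
    return report


def _write_intermediates(out, contigs, windows, cm, truth, shells, pca_result,
                         window_results, dmr_sets, tiers, config) -> None:
    inter = out / "intermediates"
    inter.mkdir(parents=True, exist_ok=True)
    write_fasta(contigs, inter / "reference.fa")
    write_windows_bed(windows, inter / "windows.bed")
    write_count_matrix(cm, inter / "study")
    write_table(truth, inter / "truth.tsv")
    write_table(shells, inter / "shells.tsv")
    write_table(pca_result.scores, inter / "pca_scores.tsv", index=True)
    (inter / "config.json").write_text(config.to_json())
    for name, res in window_results.items():
        write_table(res, inter / f"windows.{name}.tsv")
    for name, dmrs in dmr_sets.items():
        write_table(dmrs.to_frame(), inter / f"dmrs.{name}.tsv")
        write_table(dmrs.to_bed(), inter / f"dmrs.{name}.bed")
    if tiers is not None:
        write_table(tiers.provenance, inter / "stability_tiers.tsv")


def write_report(report: StudyReport, outdir: str | Path) -> Path:
    """Persist report.json (deterministic) plus a human-readable summary."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    path.write_text(report.to_json() + "\n")
    lines = [
        f"methylstab study report (seed {report.seed})",
        f"windows: {report.n_windows_tested}/{report.n_windows_total} tested",
        "DMR counts: "
        + ", ".join(f"{k}={v}" for k, v in report.dmr_counts.items()),
        f"stability tiers: {report.tier_sizes}",
        f"F1-vs-lakes / F1-vs-rivers DMR ratio: "
        f"{report.dmr_count_ratio_f1_lakes_over_rivers}",
        f"PCA verdict f1_river_like: {report.pca['f1_river_like']} "
        f"(tie={report.pca['tie']})",
        f"phenotype: {report.phenotype['scenario']} "
        f"(ANOVA F={report.phenotype['anova_f']:.2f}, "
        f"p={report.phenotype['anova_p']:.3g})",
    ]
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return path
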