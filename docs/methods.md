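# Methods

This note documents the models implemented in `methylstab`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
studies can and cannot show about real MeDIP data.

## 1. Synthetic study generator

### What it emulates

A five-population pooled MeDIP design: two lake populations (L1, L2), two
river populations (R1, R2F0), and a lab-reared first generation derived from
R2 (R2F1), each sequenced as three pools of 10–20 individuals.  Coverage is
summarized as fragment counts over fixed 100-bp windows; the generator works
directly at the window level because every downstream statistic does too.  A
read-level adapter (`fragments_from_counts`) expands counts into fragment
BEDs whose midpoints reproduce the matrix exactly, for exercising the
counting path.

### Reference sequence

Each contig is random sequence scrubbed of accidental CG dinucleotides, after
which each window receives an exact number of planted CGs at even offsets:
islands (probability `cpg_island_fraction`, default 0.1) get 10–20 CpG per
100 bp, deserts 0–8.  Construction makes the emitted per-window CpG counts
exact, so an independent dinucleotide scan is a strict oracle.

### Counts

Counts are negative binomial with variance μ + φμ² (the parameterization
standard in count genomics).  Defaults and rationale:

| parameter | default | rationale |
|---|---|---|
| genome | 20 contigs × 50 kb = 10,000 windows | a desk-scale stand-in for a 739k-window genome; large enough for stable type-I measurement |
| `baseline_mean` | 50 fragments/window | ~60 M reads/pool scaled to the synthetic genome |
| `dispersion` φ | 0.1 | moderate biological overdispersion between pools |
| `effect_fold` | 4 | a strong but not saturating MeDIP enrichment difference |
| `dmr_span_windows` | 4 (400 bp) | mid-range of the 200–600 bp DMR lengths typical of this assay |
| planted regions | 40 stable, 4 responsive, 5 site-specific | the stable ≫ responsive asymmetry produces the near-order-of-magnitude F1-vs-river vs F1-vs-lake DMR contrast the design predicts |
| `library_size_sigma` | 0.1 | mild log-normal depth variation across pools (within-pool variance structure and depth variability are free knobs, not claims about any real study) |

Truth classes act on window means: *habitat_divergent_stable* regions carry
the fold change in river **and** lab-F1 pools, *responsive* regions in river
pools only (the F1 reverts to lake-like), *site_specific* in exactly one
population; `hypo` directions divide instead of multiply.  Planted regions
are spaced ≥ 20 windows apart and ≥ 10 windows from contig ends.
Lake and river baselines are identical outside planted regions (no global
habitat offset is simulated), and pool size is metadata only — the NB model
already absorbs within-pool effects into φ.

`n_planted` counts **regions** per class; each region spans
`dmr_span_windows` consecutive windows, and the truth table carries one row
per window with a region id.  `effect_fold = 1` degenerates to an all-null
truth table rather than planting unobservable "effects".

### Phenotypes

Aperture index is Normal(μ_g, sd) per individual with
μ_Fg = μ_lake + (μ_river − μ_lake)·r^(g−1) for lab generations g ≥ 1 under
the washout model; r = 1 is the heritable scenario and the developmental
scenario pins every lab generation at μ_lake.  Defaults μ_river = 0.8,
μ_lake = 0.6, sd = 0.05, r = 0.5, 30 individuals per group: effect sizes at
which the classifier should be near-certain while single pairwise errors
remain possible, which is what the recovery tests measure.  Shell height is
drawn around 4 mm and aperture width set as index × height, so the index is
recovered exactly.  Maternal lineages (default 5) are assigned round-robin;
a lineage variance component (`lineage_sd`, default 0) exists for the
lineage-subset sensitivity analysis.

### What passing tests do not show

The generator omits sequencing error, GC/mappability bias,
fragment-length effects, genetic variation (the organism is clonal), global
methylation shifts between habitats, and any correlation structure among
windows.  Passing recovery tests therefore validates the *rules* of the
pipeline, not its robustness to artifacts of real libraries.

## 2. Differential methylation test

Normalization uses library size only (no trimmed-mean factor): MeDIP window
counts are dominated by enrichment, and the simulation has no compositional
bias to correct.  Counts are rescaled to the geometric-mean library size,
rounded half-even (deterministic), and collapsed to group pseudo-totals.
Conditional on the total n, the probability of a split k is

P(k) ∝ NB(k; r_A, μ̂ n_A) · NB(n−k; r_B, μ̂ n_B),  r_g = n_g/φ,  μ̂ = n/(n_A+n_B),

and the two-sided p-value is the sum of P(k) over all splits with
P(k) ≤ P(observed) (ties included, log-space with a 10⁻¹² tie tolerance,
capped at 1).  With φ = 0 the NB kernels collapse to Poisson and the
conditional distribution is exactly Binomial(n, n_A/(n_A+n_B)); the test
equals full enumeration to 10⁻¹⁰, which the acceptance suite checks.  Both
groups all-zero is defined as p = 1, log2FC = 0.

A single common φ is shared across windows — three pools per group cannot
support per-window dispersion.  The estimator is a median method of moments:
on depth-normalized counts, φ_w = max(0, (v−m)/m²) with v the pooled
within-group variance and m the grand mean, φ̂ = median over
coverage-filtered windows.  With 4 within-group degrees of freedom the
median is biased low (≈ 0.08 recovered at true φ = 0.1); the bias is
accepted as the price of robustness and noted here rather than corrected,
and experiments that state φ as a condition pass the known value instead.

Fold changes are log2 of depth-normalized group means with +0.5 in numerator
and denominator, finite at zero and exactly antisymmetric under group swap.
FDR is Benjamini–Hochberg over all tested windows.

## 3. DMR calling

Core windows: p < 10⁻⁵, strict.  Extension: a tested window with p < 0.1
whose gap to the current DMR boundary is ≤ 1,000 bp is absorbed together
with every window between it and the region, keeping DMRs contiguous —
non-contiguous DMRs would make reported lengths meaningless.  Extension
iterates to a fixed point (absorbed windows bring new neighbours into
range): the fixed point is deterministic and order-independent, whereas a
single pass depends on scan direction.  Distances are measured from the
*growing edge*, the natural reading of "within 1,000 bp of the region".
Extended regions that overlap or touch are merged.  Windows removed by the
coverage filter can be spanned but never qualify as extension candidates.

Member windows split into core (p < 10⁻⁵), edge (10⁻⁵ ≤ p < 0.1), and gap
windows (members for contiguity only).  `min_q` is the window-level BH
minimum over members — region-level FDR is not defined for this procedure.
CpG class: mean member CpG per 100 bp, desert iff strictly < 10.

A consequence of the extension rule on calibrated p-values: ~10% of null
windows sit below 0.1, so DMRs absorb long chains of null windows and two
nearby true regions can fuse.  Truth matching therefore uses **core**
windows (`evaluation.region_recovery`): a planted region is recovered when
some DMR's core windows intersect it, and a DMR is a false positive when
none of its core windows lie in any planted region.  Matching on full spans
would credit sprawl, not signal.

## 4. Stability analysis

Overlap between DMR sets is "share ≥ 1 member window id" — window-native
and exact on a common grid (sets record a grid signature and refuse
cross-grid comparison).  The tier funnel anchors on the F1-vs-L1 DMR list
(each DMR counted once): tier 1 requires overlap with the F1-vs-L2 set,
tier 2 additionally with ≥ 1 of the four lake-vs-river sets, tier 3 with
all four, each set matched independently (no single window need be shared
by all).  The relaxed-overlap statistic reports the fraction of one
comparison's strict (p < 10⁻⁵) DMRs containing ≥ 1 window at p < 0.05 in
another comparison, the cross-threshold support measure of the overlap
analysis.  The four lake-vs-river sets enter the funnel at the strict
threshold; the relaxed threshold is reported separately.

## 5. Methylome PCA

RPKM values of coverage-filtered windows, samples as observations; windows
are mean-centered, not scaled (scaling would equalize the 10,000 null
windows with the ~160 informative ones) and not log-transformed by default.
SVD with a deterministic sign convention: the largest-magnitude loading of
each component is positive.  The clustering claim is scored as Euclidean
distance between the F1 centroid and the river vs lake centroids in the
first two components; a relative difference below 10⁻⁹ is flagged as a tie
instead of being silently resolved.

## 6. Phenotype arm

ANOVA is the classical between/within decomposition; Tukey post-hoc uses
the studentized-range distribution with the Tukey–Kramer standard error for
unbalanced designs; compact letters come from insert-and-absorb over the
non-significance graph at α = 0.05, letters ordered by group appearance.
The generation-pattern classifier is a pure function of five booleans read
off the letters (F1/F2/F3 vs F0; F1 and F3 vs lakes): heritable if no lab
generation differs from F0; developmental plasticity if F1 differs from F0
and matches the lakes; transgenerational plasticity if F1 matches F0 and a
later generation moved, with a heritable-component flag when F3 still
differs from every lake; anything else is mixed/indeterminate.  "Differs
from lake" requires differing from *every* lake reference group.  The
borderline observed-style configuration (F1 ≈ F0; F2, F3 shifted yet
distinct from lakes) is deliberately labelled transgenerational **with**
the flag rather than forced into a single panel.

## 7. Pipeline and problem sizes

`run_study` composes all stages on one config and seed; three independent
RNG streams (reference, counts, phenotypes) are spawned from the seed, so
each artifact is separately reproducible and the report is byte-identical
across same-seed runs (it carries no timestamps).  The default synthetic
study uses 10,000 windows and 15 pools; the acceptance script's dedicated
experiments use 10,000 null windows (calibration), 1,000 random
p-landscapes (DMR-rule oracle), 50 planted regions (recovery), and 100
replicates per phenotype scenario — sizes chosen so every Monte-Carlo check
has usable resolution while the whole suite stays interactive.

## 8. Known limitations

* The exact test conditions on a plug-in common mean; its calibration is
  empirically nominal at the simulated depths but is not exact for very
  small totals.
* The dispersion estimator is median-biased low at 3-vs-3 pools.
* DMR spans are upward-biased by edge sprawl under calibrated nulls (see
  §3); consumers should treat core windows as the signal-bearing unit.
* The stability tiers count DMRs, not base pairs, and depend on the
  anchoring set when the two F1-vs-lake lists differ.
* Synthetic phenotypes are i.i.d. normal within groups; real shell data are
  unbalanced with lineage structure, which only enters through the optional
  lineage variance component.
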