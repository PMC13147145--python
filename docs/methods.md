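# Methods

This note documents the models, conventions and numerical choices behind
`speclock`, and what the synthetic-data tests do and do not establish
about real data.

## Cline database workflow

A published cline width enters as a `ClineRecord` with its inference
method (*single* one-locus cline, *median* over many one-locus clines,
*average* over genomic ancestry), marker genome and count, and the cline
tail frequencies p_min / p_max.

**Diagnosticity.** A marker is non-diagnostic when its cline never
approaches parental fixation. The rule is conjunctive — p_min > 0.2
**and** p_max < 0.8 — because a disjunctive reading would also discard
clines with one fixed side, which do carry a fixed allelic difference
between the lineages. A `diagnostic_rule: or` switch exposes the other
reading. Single and average records flagged non-diagnostic are dropped;
a median record is dropped only when a strict majority (> 50%, ties
keep) of the single-marker clines on its pair and transect are
non-diagnostic, and is kept (logged unverifiable) when no linked singles
exist.

**Width categories.** Eight categories cross the inference method with
marker class/count: single-mitochondrial, single-nuclear, and
median/average each split at 2–10, 11–100 and > 100 markers. A single
record with unknown genome falls to single-nuclear with a warning. The
scheme is replaceable in code.

**Aggregation.** Within each (pair, category), the representative width
is a double median: median across records per transect, then median
across transect medians; even counts use the mean of the two central
values. Pairs without a divergence time go to a side table and are
excluded from analysis. *Dataset B* keeps, per pair, only the
average-method category with the largest marker count (genome-scale
averages track reproductive isolation best); exact marker-count ties are
resolved by the median across the tied categories.

**Dispersal bins.** Eight half-open bins (lower, upper] tile
(0, ∞) km/generation: A (0, 0.25], B (0.25, 0.75], C (0.75, 2.5],
D (2.5, 7.5], E (7.5, 25], F (25, 75], G (75, 250], H (250, ∞). Printed
bin bounds in the source literature contain small typographic gaps
(7.5 → 7.6 etc.), treated here as contiguous. The representative σ is
the geometric midpoint √(lower·upper); the open-ended bins extend by the
neighbouring geometric ratio, A → 0.25/√3, H → 250·√3. A missing or
non-positive rate maps to an explicit `uncategorized` marker, never to a
default bin.

## Scaling models

**Correlation.** Pearson r on (log w, log T); the base of the logarithm
cancels. Two-sided p from t = r·√((n−2)/(1−r²)) with n−2 df. Group-wise
p-values are reported raw (per-panel convention); no cross-panel
correction.

**Selection coefficient.** s = 8σ²/w² from the tension-zone relation
w = σ√(8/s), with σ the representative dispersal of the pair's bin. This
is an ad-hoc dispersal correction: it assumes the zone is a tension zone
at dispersal–selection equilibrium.

**Gamma GLM.** Widths are positive and right-skewed, so the mean model
is a gamma GLM with log link; divergence time enters log-transformed
(`glm_time_scale: linear` available). The mean structure is fitted by
IRLS (statsmodels; relative tolerance 1e-8, ≤ 100 iterations). The gamma
shape α is then profiled by maximum likelihood given the fitted means —
solving log α − ψ(α) = mean(log μ − log y + y/μ − 1) by bracketed root
finding — and counted as a parameter, so k = (mean parameters) + 1 and

    AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1).

A (near-)perfect fit leaves the shape unbounded; it is capped at 1e12.
Candidate sets enumerate either all 2³ main-effect subsets of
{T, D, G} or, with pairwise interactions under marginality, 18 formulas,
in a deterministic size-then-position order; an explicit formula list
can be supplied for arbitrary candidate sets. Akaike weights are
w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2) over converged fits. "ANOVA-like" tests
are Type-II likelihood ratios: each term is dropped (interactions
containing it removed from both models first), the statistic is 2Δℓ
against χ² with df = parameters removed; Type III is available.

## Reference points and half-time

Steepness classes follow the established amphibian convention: shallow
> 50 km, very steep < 10 km, boundaries inclusive to steep. Ellipses are
fitted in (log T, log w) — both variables span orders of magnitude — to
the multi-marker (> 2 markers) average widths of each extreme class.
The default scatter estimator is the EM fit of a bivariate
t-distribution with 7 df (tolerance 1e-8), mirroring the common
plotting-library convention for t-ellipses, with sample moments as the
alternative; since the source convention is not pinned down, both the
estimator and the denominator df of the radius √(2·F(level; 2, n−1))
are configuration keys. The x-extremes of an ellipse with center c and
scatter Σ are c_x ± radius·√Σ_xx (vertical-tangent points), exponentiated
back to Ma. At least three points per class are required; collinear
points give a singular-scatter error.

The half-time to speciation fits log w = a + b·log T by ordinary least
squares and inverts at the pivot width (default 30 km, the approximate
anuran species/subspecies transition). Its confidence interval inverts
the mean-response band (Fieller): solving
(a + bx − log w₀)² = t²s²(1/n + (x − x̄)²/Sxx) for x. When b² does not
exceed the band curvature (slope |t| < 2) the estimate is flagged
unreliable and the interval is unbounded.

## Inflation clock

Trees must be ultrametric within a relative depth tolerance of 1e-6 and
carry unique tip labels. Patristic distances are branch-length path sums
(dendropy); on an ultrametric tree the divergence of a pair is half the
patristic distance. Each species is paired with its minimum-patristic
partner, ties broken alphabetically; "species pairs" are counted per
species (mutual nearest neighbours yield two records, n_pairs =
n_species), which is the convention under which the published amphibian
arithmetic (216/2523 → 8.6%) comes out; a `unique_pairs` mode collapses
mutual duplicates. Thresholds compare divergence time strictly
("younger than 2 Ma" means divergence < 2), with a `patristic` switch
for full path lengths.

Interval slicing prunes the tree to the species described by each
cutoff (default decadal from 1758, the start of zoological
nomenclature), preserving path lengths exactly (unary nodes suppressed,
merged branches summed — verified against the full-matrix submatrix).
Species in the year list missing from the tree are skipped with a
warning; name reconciliation is upstream of this package. The
inflation-increase statistic is
100·((SP_young_recent/SP_recent)/(SP_young/SP) − 1) to 2 decimals, with
an undefined marker when SP_young = 0. Note the published count
structure allows SP_young_recent to exceed SP_young in principle, so
only SP_young ≤ SP and SP_young_recent ≤ SP_recent ≤ SP are enforced.
Group age comparisons are Welch t-tests with Bonferroni adjustment
(multiplied by the number of comparisons, capped at 1) and a greedy
compact-letter display.

Written Newick carries 10 significant digits: with 6, root-to-tip sums
of a freshly written tree can violate the 1e-6 ultrametricity tolerance
on re-read. `read_tree` warns when the depth spread is within a decade
of the tolerance.

## Synthetic data: what it emulates

`simulate_yule_tree` is a forward pure-birth simulation (exponential
waiting times at rate k·λ, uniform splitting lineage, final stretch to
the present), sufficient for ultrametric structure; extinction is out of
scope. `assign_description_years` perturbs a uniform draw logistically
by the standardized log nearest-relative divergence, so distinct species
are described early; bias 0 is exactly uniform. `simulate_cline_study`
draws divergence times log-uniformly on 0.05–20 Ma (the span of
published hybrid-zone ages), group frequencies proportional to the
published per-group pair counts, and record-level multiplicative noise
(0.1 log₁₀ units) around pair-level widths from
log₁₀ w = 2.0 − 0.5·log₁₀ T + offsets + N(0, 0.2); 30% of single/average
records are made non-diagnostic. These defaults are the package's
reference study conditions.

The generator does **not** emulate: phylogenetic correlation between
pairs, heterogeneous divergence-time error, cline-fitting uncertainty,
hybrid-zone movement, or taxonomy-dependent description effort beyond
the single bias parameter. Passing recovery tests therefore show the
estimators are consistent under the assumed generating model, not that
the biological assumptions hold in any particular empirical dataset.

## Problem sizes

Tests and the analysis scripts use 200 simulated pairs (~1400 records),
trees of 30–400 tips, 100 model-selection replicates and 300-replicate
coverage checks — sizes at which every Monte-Carlo check is stable under
its fixed seed while the whole suite stays fast. The study-scale inputs
(the compiled cline database, timetree.org trees) are external deposits;
the pipeline consumes them through the same TSV/Newick readers.
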