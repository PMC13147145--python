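# speclock

Tools for relating hybrid-zone cline width to divergence time, deriving
time-to-speciation reference points, and detecting taxonomic inflation
from timetrees and species description years.

## The scientific problem

When two divergent lineages meet and interbreed, the transition of allele
frequencies (or average genomic ancestry) along a transect through the
hybrid zone follows a sigmoid cline whose width *w* (km) measures how far
genes flow between them. In a tension zone — a balance of dispersal σ
(km/generation) into the zone against selection *s* against hybrids —

    w = σ √(8 / s)   ⇒   s = 8 σ² / w².

Because intrinsic post-zygotic incompatibilities accumulate with time,
cline width is expected to shrink with the divergence time *T* (Ma) of
the hybridizing pair. `speclock` implements the full analysis chain
around this idea:

1. **hz_database** — validates published cline measurements, removes
   non-diagnostic clines (tail frequencies p_min > 0.2 **and**
   p_max < 0.8), classifies widths into eight categories (inference
   method × marker class/count), and aggregates them by a double median
   (per transect, then across transects) into *dataset A* (one width per
   pair and category) and *dataset B* (one multi-marker average-method
   width per pair).
2. **scaling_models** — Pearson correlation of (log w, log T), the
   tension-zone selection coefficient, and gamma GLMs with a log link for
   *w* on {log T, dispersal category D, taxonomic group G}, scored by
   AICc weights over an exhaustive candidate set (8 main-effect models,
   or 18 with marginality-respecting pairwise interactions), with
   Type-II likelihood-ratio tests on the best model.
3. **refpoints** — widths classified as shallow (> 50 km), steep
   (10–50 km) or very steep (< 10 km); bivariate confidence ellipses
   (robust multivariate-t or moment scatter, radius √(2·F(level; 2, n−1)))
   fitted to the extreme classes in (log T, log w). The x-maximum of the
   shallow ellipse estimates the divergence above which reproductive
   isolation is presumed complete; the x-minimum of the very-steep
   ellipse the divergence below which it is presumed incomplete. The
   *half-time to speciation* inverts the log-log regression at a pivot
   width (default 30 km) with a Fieller-style confidence interval.
4. **inflation_clock** — on an ultrametric timetree, each species' age is
   half the patristic distance to its nearest relative. Pruning the tree
   to the species described by each decadal cutoff (1758 onward) tracks
   how the age distribution of recognized species changed over taxonomic
   history; the proportion of pairs below a reference age and its
   relative increase among recent descriptions,
   100·((SPᵧ,ᵣ/SPᵣ)/(SPᵧ/SP) − 1), quantify potential taxonomic
   inflation.
5. **synthetic_data** — Yule timetrees, description years biased toward
   early description of divergent species, and cline tables with
   log₁₀ w = a + b·log₁₀ T + group/dispersal offsets + noise, so the
   whole pipeline is testable without external downloads.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on
synthetic data and write their tables under `results/`:

```sh
python analysis/01_simulate_data.py
python analysis/02_build_datasets.py
python analysis/03_scaling_models.py
python analysis/04_reference_points.py
python analysis/05_taxonomic_inflation.py
```

`02` reports, for 1374 simulated cline records over 200 pairs:

```
excluded as non-diagnostic: 399
dataset A: 667 representative widths, 195 pairs
dataset B: 151 one-per-pair average widths
```

`03` then finds the generating structure back:

```
overall log-log correlation: r = -0.716 (n = 151, p = 4.5e-25)
best gamma-GLM: width ~ T + D + G (AICc weight 1.000)
```

i.e. widths fall with divergence time, and the model containing
divergence time, dispersal category and group carries essentially all
AICc weight — all three predictors are likelihood-ratio significant.
`05` slices a 400-tip timetree by description decade:

```
114/400 species pairs (28.5%) diverged < 2.0 Ma
young-pair share among 1980-2010 descriptions: 74.4% vs 28.5% overall
  -> increase 160.91%
```

showing the signature of biased description order: recently described
species are disproportionately young, the pattern the inflation-increase
statistic is designed to expose.

The same operations are available as a CLI (`speclock --help`):
`speclock simulate`, `speclock hzdb build`, `speclock correlate`,
`speclock glm-select`, `speclock selection`, `speclock refpoints`,
`speclock halftime`, `speclock inflation run`.

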