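# fdsweep

Trait-subset sensitivity analysis for functional diversity metrics in plant
communities.

Functional diversity (FD) metrics summarise a community by the spread and
packing of its species in multidimensional trait space. Their values,
however, depend not only on ecology but on an analyst's choices: how many
traits go into the calculation, and how correlated those traits are. Two
communities can differ in functional richness simply because one study
measured six traits and another ten, or because one trait set leans on the
leaf economics spectrum. `fdsweep` quantifies that sensitivity for grassland
(or any plot-based) community data: it computes eight FD metrics for **every
combination of traits** from pairs up to the full trait set, then models
each metric as a function of trait number and of trait correlation.

It is aimed at community ecologists who work with plot-by-species cover
tables and species-by-trait tables and want to know how robust their FD
conclusions are to trait selection.

## The metrics

For a plot with `S` species at relative abundances `p_i` (summing to 1) and
pairwise trait dissimilarities `d_ij` (Gower for mixed trait types,
Euclidean on z-scored columns for continuous subsets):

- **FRich** — convex-hull volume of the species' PCoA coordinates
  (2-D by default, with a 3/4/max-dimension sensitivity option).
- **FEve** — evenness of the minimum spanning tree: per branch `l` joining
  species `i, j`, `EW_l = d_ij / (p_i + p_j)`, normalised to `PEW_l`, and
  `FEve = [Σ_l min(PEW_l, 1/(S−1)) − 1/(S−1)] / [1 − 1/(S−1)]`.
- **FDis** — `Σ p_j z_j` with `z_j` the distance of species `j` to the
  abundance-weighted centroid.
- **FDiv** — `(Δd + dḠ) / (Δ|d| + dḠ)`, where `dḠ` is the mean distance of
  species to the hull-vertex centroid and `Δd`, `Δ|d|` are the
  abundance-weighted (absolute) deviations from it.
- **Rao's Q** — `Σ_{i<j} d_ij p_i p_j`, the expected trait distance between
  two randomly drawn individuals.
- **KDE richness / evenness / dispersion** — volume, abundance-weighted vs
  uniform overlap, and internal dispersion of a Gaussian kernel-density
  hypervolume bounded at the 0.95 probability-mass density quantile.

Species with incomplete coverage on a trait subset are removed before any
computation, and a plot is excluded for that subset when less than 80% of
its original abundance survives the removal.

The inference stage fits, per metric,
`metric ~ poly(trait number, degree) + (1 | plot)` and
`metric ~ poly(trait correlation, degree) + (1 | plot)` for degrees 1–4 by
maximum likelihood, selects the degree by AIC, and adjusts the family of
likelihood-ratio p-values with the Benjamini–Hochberg procedure.

## Worked example

```python
import fdsweep as fd

# one synthetic study shaped like a planted 16-species experiment
spec = fd.SyntheticStudySpec(
    "demo", n_species=16, n_plots=24, n_traits_continuous=6,
    correlation=fd.leaf_economics_correlation(6),
    richness_range=(6, 12), missingness=0.05, seed=42,
)
traits = fd.generate_traits(spec)
comm = fd.generate_communities(spec)

mean_traits = fd.species_mean_traits(traits)
subsets = fd.enumerate_subsets(mean_traits.traits, 2, 6)
print(len(subsets))                       # 57  (C(6,2)+...+C(6,6))

cfg = fd.SweepConfig(kde_samples=2000, seed=1)
sweep = fd.run_sweep(comm, mean_traits, subsets, cfg)

res = fd.TraitNumberModel.from_sweep(sweep, "FRich", distance="gower").fit()
print(res.summary())
```

Output of the final `print`:

```
Metric trend model: value ~ poly(k, degree=2) + (1 | plot_key)
n_obs = 1368, groups = 24, RE variance = 0.001649

AIC comparison:
 degree       aic      llf  lr_pvalue  selected
      1 -4601.326 2304.663      0.024     False
      2 -4602.300 2306.150      0.018      True
      3 -4601.292 2306.646      0.028     False
      4 -4599.350 2306.675      0.058     False

Selected coefficients (predictor centred at 3.263):
           estimate        se         p
Intercept    0.1412  0.008434 7.054e-63
x^1       -0.001811  0.001239    0.1437
x^2        -0.00171 0.0009912   0.08444
LR test vs intercept-only: p = 0.01768
```

Read: 2-D convex-hull richness of these communities drifts gently downward
and concave as more traits enter the calculation (AIC narrowly prefers the
quadratic; the trend as a whole is significant at p ≈ 0.018), and the plot
random effect is tiny relative to the residual spread. The same call with
`metric="FEve"` on this dataset selects a clearly increasing quadratic
(slope 0.026 ± 0.002 per trait) — a reminder that sensitivity to trait
number is itself metric- and data-dependent, which is exactly what the
sweep is for.

`fd.analyze_study(traits, comm, config=cfg)` wraps the whole chain —
filtering, both distance types, all eight metrics, the 4-trait correlation
table, and all trait-number/correlation models with one BH family — and
returns a `StudyAnalysis` bundle.

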