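# Methods

## Problem and scope

`fdsweep` measures how much the value of a functional diversity (FD) metric
owes to the analyst's trait selection rather than to the community itself.
For a dataset of plots (with species relative abundances) and species-mean
traits, it computes eight FD metrics for every trait subset of size 2 up to
the full trait set, under two dissimilarity measures, and then regresses
each metric on (a) the number of traits in the subset and (b) — at a fixed
subset size of four — the minimum, maximum and mean absolute pairwise
correlation among the subset's traits.

No real site data ship with the package; a generator produces synthetic
communities with the statistical structure the analysis assumes (see
below). The pipeline itself is agnostic to the data source: any CSV pair of
community and trait tables in the documented layouts runs through the same
code path.

## Data preparation

Trait tables are long-format, one row per (species, trait, replicate
measurement). Replicates are collapsed to species means (arithmetic mean
for continuous traits; categorical traits must be constant within a species
and keep their level). For every trait subset independently:

1. species missing any subset trait are removed from all plots ("100% trait
   coverage");
2. each plot's remaining abundances are renormalised to sum to one;
3. plots retaining less than 80% of their original abundance are excluded
   for that subset.

The 80% rule is applied per plot. The threshold could also be read as a
study-level rule; plot-level exclusion discards the least data and keeps
the retained-abundance bookkeeping exact, so it is the default
(`min_retained` in `SweepConfig` changes the cut). Zero-abundance rows are
dropped on read since they carry no weight in any metric.

## Dissimilarity and ordination

Gower dissimilarity averages range-normalised absolute differences
(continuous) and 0/1 mismatches (categorical) over the subset. Ranges are
global over all coverage-complete species in the table — not per plot — so
distances are comparable across plots. A zero-range trait contributes zero
with a warning. Euclidean distances are defined only for all-continuous
subsets and default to z-scored columns (sample SD) because traits mix
units; `standardize=False` restores raw-unit distances.

PCoA eigendecomposes the double-centred Gram matrix. Eigenvalues at or
below `max(|λ|)·1e-10` are treated as zero. Negative eigenvalues — which
Gower matrices can produce — are dropped, not corrected (no Cailliez or
Lingoes constant); the summed magnitude of dropped negative inertia is
carried on the `OrdinationResult` so the distortion is inspectable. This is
the simplest defensible treatment: a correction constant changes every
distance, while dropping axes leaves the positive-part geometry intact and
quantifies the cost.

## The classic metrics

- **FRich**: convex-hull volume (Qhull) of present species' PCoA
  coordinates truncated to `dims` axes; 2-D by default, with a sensitivity
  list `frich_dims=(2, 3, 4, "max")` available, where `"max"` resolves to
  the subset size for all-continuous subsets and size − 1 when categorical
  traits force the Gower/PCoA route. Degenerate configurations (fewer than
  `dims + 1` species, collinear points) yield a missing value, never 0 —
  zeros would masquerade as "no trait space occupied" and bias the
  trait-number regressions.
- **FEve**: Kruskal MST on the plot's distance submatrix with ties broken
  by (length, i, j), making the tree — and FEve under tied distances —
  reproducible. Undefined for fewer than three species.
- **FDis / FDiv**: need a centroid, hence coordinates. In distance-driven
  use they run on all positive PCoA axes, which reproduces every pairwise
  distance exactly for Euclidean-embeddable inputs, so "distance-only" and
  coordinate computation agree. FDiv's reference centroid is the unweighted
  mean of the convex-hull vertex species when a hull exists (1-D: the two
  extremes), otherwise the all-species mean. The vertex hull is only
  attempted up to 8 dimensions: Qhull's cost grows roughly as `n^(d/2)`,
  and in the near-full-rank PCoA spaces that arise from distance-only use
  essentially every species is a hull vertex, making the all-species mean
  the correct high-dimensional limit (with `n ≤ d + 1` points every point
  is a vertex exactly, and that case is short-circuited).
- **Rao's Q**: `Σ_{i<j} d_ij p_i p_j`, computed as `p'Dp/2`.

FEve and FDiv live in [0, 1]; FRich, FDis and Q are non-negative. All
undefined values propagate as missing records.

## KDE hypervolumes

A hypervolume is a weighted Gaussian mixture over the z-scored continuous
traits of the subset, one kernel per species, with per-dimension
Silverman-type bandwidths `σ_j (4/((d+2) n_eff))^(1/(d+4))` using the Kish
effective sample size of the weights. The region is bounded at the density
quantile enclosing 95% of probability mass. Volume is estimated by
importance sampling from the mixture itself: with N draws from density f,
`V ≈ (1/N) Σ 1{f(x) ≥ t}/f(x)`. Retained draws ("support points"), carrying
weights 1/f, are a uniform sample of the bounded region; they drive the
dispersion statistic (mean distance to the weighted centroid) and the
overlap estimate (cross-inclusion of each hypervolume's support in the
other, averaged, then Jaccard-normalised — symmetric by construction and
exactly 1 for self-overlap).

Defaults: mass 0.95, 10,000 samples, seed 1; all three are config. KDE
metrics use continuous traits only — a Gaussian kernel has no meaning on
unordered categories — and the "evenly distributed" reference for KDE
evenness is the same species coordinates with uniform weights, the closest
constructible reading of an evenness baseline (a uniform lattice over the
hull would be an alternative; observed-point uniform weights keep the
comparison on the community's own support). Everything is deterministic
given the seed; in the sweep, per-cell seeds are derived by CRC32 from
(master seed, subset, study, plot), so runs are reproducible and
order-independent.

Known behaviour worth remembering: kernel smoothing widens regions, so a
1-D standard-normal sample's 95% region comes out a few percent above the
analytic 3.92, shrinking with sample size; and volumes in d dimensions
scale as `c^d` under isotropic rescaling, which the tests exploit.

## Sweep engine

`run_sweep` crosses subsets × plots and emits one long-format row per
(study, plot, metric, distance, subset, dims). Euclidean records are only
emitted for all-continuous subsets; KDE metrics are distance-free and carry
the distance label `"traits"`. Per-cell failures are logged and recorded as
missing; a sweep never aborts mid-design. `resume_from` skips subsets
already present in a previous result. `max_subsets_per_k` deterministically
subsamples the design per subset size for desk-scale runs — the enumeration
itself is always exhaustive.

Correlation summaries for 4-trait all-continuous subsets use absolute
Pearson correlations over the six pairs, on species-mean values. Absolute
rather than signed: the redundancy question concerns correlation strength,
not direction (signed summaries are available via `absolute=False`).

## Inference

`metric ~ poly(predictor, degree) + (1 | plot)` for degree 1..4, maximum
likelihood (not REML, so AICs are comparable across fixed-effect
structures), predictor centred at its mean before raising to powers. AIC is
computed as `2k − 2 logLik` with k counting fixed effects, the
random-intercept variance and the residual variance. The minimum-AIC degree
wins; ties (within 1e-6) go to the lower degree. With a single plot the
model degrades to OLS. Boundary ML solutions (random-effect variance
estimated at zero) are kept: they are valid likelihood values, and
discarding them would censor exactly the cases where plots are
homogeneous.

Each selected model carries a likelihood-ratio p-value against the
intercept-only model with the same grouping; one pipeline pass collects all
selected models (every metric × predictor) into a single family for
Benjamini–Hochberg adjustment — the widest defensible family given that no
narrower grouping is canonical. The BH step-up rule is implemented
directly (sort, `q_(i) = min_{j≥i} m p_(j)/j`, cap at 1) and cross-checked
against statsmodels in the tests.

An autoregressive within-plot correlation structure is deliberately
omitted: AR(1) needs an ordering of the repeated measures, and trait
subsets have none. The random intercept remains as the repeated-measures
control. Note a calibration fact about AIC selection: with four candidate
degrees, each unneeded extra degree overtakes the true one with probability
≈ 0.16, so exact-degree recovery tops out near 0.72 even in clean data;
AIC essentially never underfits a clear trend, though. The test suite
asserts exactly that pair of properties.

## Synthetic data generator

The generator is the package's stand-in for three grassland community
datasets and fixes the study conditions:

- a planted 16-species experiment: 48 plots, 10 continuous traits,
  moderate lognormal dominance, 5% trait missingness;
- a species-rich watershed site: 60 species, 4 transects, 12 traits of
  which 2 categorical (2 and 3 levels), 15% missingness;
- a desert grassland: 40 species, 60 quadrats, 10 traits (1 categorical),
  geometric rank-abundance with ratio 0.5 — the dominant species holds
  ~50% of cover, echoing strong single-species dominance — and 20%
  missingness.

Continuous traits come from a Gaussian copula with a target correlation
matrix containing a leaf-economics-like block (ρ = 0.7 among four traits,
0.1 background). Margins are transformed monotonically — lognormal with
σ = 0.3 for size-like traits, logit-normal for fraction-like, affine for
the rest — scales mild enough that achieved Pearson correlations stay
within sampling error (±0.05 at 500 species) of their targets. Species
index equals regional abundance rank; missingness ramps linearly from 0
for the most abundant species to twice the nominal rate for the rarest,
reproducing the real-world pattern that rare species lack trait
measurements. Plots draw their richness uniformly from a configured range
and their species weighted by regional abundance, then assign local
abundances from the same rank-abundance model.

What the generator does *not* emulate: environmental gradients between
plots, phylogenetic signal in traits, trait–abundance dependence (dominant
species are no more functionally "central" than rare ones), intraspecific
trait variation beyond small replicate noise, and temporal structure.
Passing tests therefore show that the pipeline measures what it claims on
data with known structure — not that any particular ecological conclusion
transfers to a real site.

## Problem sizes

The test suite and the acceptance script subsample the sweep design
(typically 12 subsets per size, sizes 2–4, 1,500–2,000 KDE samples) so an
end-to-end three-study pass completes in minutes on a single core; the
exhaustive design (e.g. 1,013 subsets for 10 traits) runs through exactly
the same code path and is a matter of wall time, not capability. Inference
simulations use 12–40 plots and 9 trait-number levels.

## Numerical conventions

Symmetry tolerance for distance matrices 1e-12; PCoA eigenvalue zero
threshold relative at 1e-10; abundance normalisation checked to 1e-9;
relative abundances validated to sum to 1 within 1e-6 at metric entry.
Degenerate inputs (single species, coincident points, zero-length MSTs,
constant traits) return missing values or raise, per operation, and are
exercised in the tests.

## Known limitations

- Gower is unweighted; ordinal traits are not supported.
- Negative-inertia reporting quantifies PCoA distortion but no correction
  is offered.
- KDE evenness compares against uniform weights on observed points, not a
  uniform density over the occupied region; strongly clustered species
  coordinates make that baseline itself uneven.
- The BH family spans one pipeline pass; re-running per site and pooling
  afterwards changes the family and hence the adjusted values.
- Volume estimates inherit Monte-Carlo error of order 1/√N; comparisons
  across communities should use a common sample size and seed protocol.
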