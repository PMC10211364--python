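# Methods

`chronoveg` analyses woody-vegetation structure along a land-abandonment
chronosequence: a space-for-time design in which sites that differ only in
years since a disturbance ended (here, cattle grazing in Tamaulipan
thornscrub) are compared as if they were successive stages of one
succession. This note documents the models, the conventions that were
genuinely open choices, the synthetic-data generator, and the limits of
what the tests demonstrate.

## Sampling model and data flow

The census unit is a woody individual with basal diameter `d_0.10 >= 1 cm`
measured 10 cm above ground; each record carries a species binomial, the
diameter (cm) and total height (m). Individuals nest in fixed-area plots
(default 40 m x 40 m = 1600 m²), plots in site conditions labelled by
years of abandonment, sites in an ordered chronosequence. Rows violating
the census rule are dropped with a warning rather than raising, so real
exports containing sub-census stems remain loadable; the dropped count is
reported. Species names are whitespace-normalized and matched
case-insensitively, but never corrected or resolved against a taxonomic
backbone — published tables in this field are occasionally internally
inconsistent on a taxon, and silently "fixing" names would corrupt
comparisons against them.

All density-type quantities scale by `10^4 / area_m2` to per-hectare
units. The sites x species density matrix (`N ha^-1`) takes the species
union over sites with zeros where absent, and conserves totals exactly:
each row sums to the site's record count over its sampled area.

## Diversity

Richness `S` counts species with positive abundance. Shannon entropy
`H' = -sum p_i ln p_i` uses natural logarithms; the effective number of
species is the first-order Hill number `¹D = exp(H')` — the number of
equally-common species with the same entropy. Proportions are
scale-invariant, so the functions accept counts or densities
interchangeably. Per-site `¹D` is computed on abundances pooled over the
site's plots, not as a mean of per-plot values: pooled computation is the
convention that reproduces published per-site effective-species values
from pooled density tables, and it is the scale at which the similarity
analysis operates. Per-plot diversity is computed separately where
replicate values are needed (group comparisons). No rarefaction or
asymptotic richness estimation is attempted; `¹D` compares observed
assemblages at face value.

## Vertical structure (species height profile index)

Pretzsch's A-index assigns each individual to one of three relative-height
zones anchored at the tallest individual in scope (100%): zone I above
80%, zone II above 50% up to 80%, zone III at or below 50%. A is the
Shannon entropy over occupied (species, zone) cells; its ceiling is
`ln(3 S)`, attained only if all `3S` cells are equally filled. Two
conventions had to be fixed:

- **Boundary ties fall in the lower zone** (strict inequality upward).
  The interval notation "100–80%, 80–50%, 50–0%" leaves the boundaries
  ambiguous; a fixed rule matters only for heights landing exactly on
  `0.8 H*` or `0.5 H*` and is stated here so results are reproducible.
- **The reference height is per plot**, i.e. each plot's own tallest
  individual defines its 100%. Sites are then summarized as mean ± sample
  SD (n−1) of plot-level A values, matching the replicated reporting
  structure of field studies with this design. Site-level pooling would
  mix plots against a common reference tree and is not the default.

The zone capacity in the ceiling is fixed at 3 regardless of occupancy.
A useful internal check: collapsing the three zones into one reduces A to
the plain species entropy of the plot, so zone refinement can only add
information — the test suite verifies this on random inventories.

## Importance values and stand volume

For species *i* in one site: absolute abundance `A_i` (N ha^-1), absolute
dominance `D_i` (m² ha^-1) from summed basal areas
`g = pi (d/200)²`, and absolute frequency `F_i` = number of plots
occupied. Relative forms normalize each column to 100, and
`IVI_i = (RA_i + Rd_i + Rf_i)/3`, so IVI also sums to 100 over species.
The frequency unit is the **plot**: with four plots per site,
`F_i ∈ {1..4}`. (A site-level frequency would be constant within a single
site's table and could not contribute ranking information.) Tables carry
full precision; rounding is left to the report layer.

Stand volume applies `V = g · h · MC` per stem with morphic coefficient
(form factor) `MC = 0.5`, the constant used for Tamaulipan thornscrub,
then scales to m³ ha^-1. No diameter-class structure or biomass allometry
beyond this form factor is provided.

## Similarity, clustering, and support

Between-site similarity is quantitative Bray-Curtis,
`BC = 2 Σ min(x_i, y_i) / (Σx + Σy)`, on pooled per-site density vectors —
the pooled scale is what published similarity matrices in this design are
computed on. Clustering is UPGMA (unweighted average linkage) on the
distance view `1 − BC`, implemented in-package: the closest pair merges at
its current distance and the merged cluster's distance to any other is the
size-weighted Lance-Williams update, equivalent to the arithmetic mean
over all cross leaf pairs. Ties on the minimum distance resolve toward the
lexicographically smallest label pair; clustering software rarely
documents its tie rule, so fixing one keeps output deterministic. The test
suite checks merge orders and heights against both a from-scratch
re-averaging oracle and scipy's average-linkage implementation.

Tree fit is the cophenetic correlation: Pearson r between original and
tree-implied (merge-height) distances over all unordered pairs, reported
as a magnitude. Node stability uses a species-level bootstrap: matrix
columns resampled with replacement, tree rebuilt, and each internal node
scored by the percentage of replicates containing the same leaf
bipartition (`--support-scheme bootstrap-species`; the flag exists so
alternative resampling units could be added without breaking
comparability). Replicates leaving a site with an all-zero vector are
redrawn and counted in the log. Leaves are 100% by convention.

## Group comparisons

Per-plot metrics (richness, effective species, A-index, stem density,
basal-area dominance, volume) are compared across sites with an
assumption-gated flow: Shapiro-Wilk on the ANOVA residuals and a
Brown-Forsythe Levene test (median-centred; mean-centring by flag) run
first; if Levene rejects at the routing alpha (default 0.05, configurable)
the omnibus switches from classic one-way ANOVA + Tukey HSD to Welch's
ANOVA + Games-Howell. Normality is reported but never drives routing: with
four plots per site Shapiro-Wilk has essentially no power, and variance
heterogeneity is the assumption that actually distorts F at this design
size. Assumptions are tested per metric, and the route taken is recorded
in the output.

Welch's F uses weights `w_i = n_i/s_i²` with the Welch-Satterthwaite
denominator df (non-integer in general). Games-Howell computes per-pair
`t = (m_i − m_j)/√(s_i²/n_i + s_j²/n_j)` with per-pair Satterthwaite df
and takes p from the studentized range at `q = |t|·√2`. Both are
implemented on scipy's distributions and cross-checked against pingouin in
the test suite. One caveat worth recording: Welch's and classic F coincide
exactly only for k = 2 groups; for k > 2 the Welch correction factor
`1 + 2λ(k−2)` exceeds 1 even when sample variances are identical, with the
gap vanishing as group sizes grow. Significance letters use the standard
insert-and-absorb compact letter display and are collapsed to a single
letter when the omnibus is not significant.

The routed omnibus holds its nominal level: under a 4-groups-of-4 normal
null its type-I error stays within [0.03, 0.07] at alpha = 0.05 over 5,000
replicates (verified in the acceptance tests).

## Synthetic inventory generator

The generator produces stem-level inventories with the statistical
structure the pipeline assumes, so every stage is testable without field
data. Per stage: total stem count ~ Poisson(density x site area), stems
assigned multinomially to species and uniformly to plots, heights
log-normal, and diameters allometric in height on the log scale
(`ln d = a + b ln h + ε`) with noise redrawn, then clipped, to respect the
1 cm census rule.

Within-stage relative abundances follow a **geometric rank-abundance
series** with ratio c: the entropy of a geometric series has a closed form,
giving the generator an analytic oracle (`geometric_effective_species`)
against which simulated pooled `¹D` is tested. Stage species lists are
**nested prefixes of one shuffled regional pool** — later stages accrete
species rather than drawing independently — and a per-stage `rank_shift`
rotates the rank order so the pioneer dominant of the young stages sinks
toward rarity in the oldest stage. Independent per-stage species draws
were considered and rejected: they make between-stage overlap random,
which cannot produce the empirical signature of succession (adjacent
stages more similar than extreme ones). Accretion-with-dominance-turnover
is the simplest mechanism that does.

The shipped `thornscrub_config()` encodes the study conditions of a
four-stage abandonment gradient: 4 plots of 1600 m² per site; richness
4 / 13 / 12 / 21; total densities 1500 / 1158 / 762 / 1828 N ha^-1; decay
ratios 0.062 / 0.300 / 0.546 / 0.750 solved once (Brent root-finding on
the closed form) so each stage's expected `¹D` matches the field profile
1.28 / 2.39 / 4.54 / 9.31; median heights rising 1.6 → 3.8 m with
log-spreads 0.35 → 0.50; `rank_shift = 3` in the oldest stage. Parameter
recovery is part of the acceptance suite: over 500 seeded draws the
pipeline recovers the `¹D` stage ordering (youngest < both intermediates
< oldest) and the adjacent-vs-extreme similarity ordering in ≥95% of runs.

What the generator does **not** emulate: spatial point patterns within
plots, species interactions or true successional dynamics, non-geometric
rank-abundance shapes (real assemblages hold more rare species than a
geometric series, so simulated realized richness at fixed `¹D` falls below
the nominal stage richness), measurement error, and between-plot habitat
heterogeneity beyond multinomial noise. Passing the parameter-recovery
tests therefore shows the pipeline is consistent and well-calibrated under
its own assumptions — not that those assumptions hold in any particular
field system. Simulated stand volumes, in particular, are only
order-of-magnitude realistic (the lognormal tails of height and diameter
compound in `g·h`).

## Numerical conventions and degenerate inputs

- Natural logarithms throughout; entropies in nats.
- Empty plots are allowed, logged, and skipped in per-plot summaries;
  empty sites yield undefined-flagged diversity (NaN) and zero volume with
  a warning; importance tables require at least one record.
- All-zero abundance vectors raise domain errors where proportions are
  undefined (Shannon, Bray-Curtis).
- Cophenetic correlation requires ≥3 labels and returns NaN when either
  distance set is constant.
- UPGMA tie-break: lexicographically smallest label pair (see above).
- Problem sizes in the test and acceptance runs — 5,000 null replicates
  for the type-I calibration, 500 generator draws (~3,300 stems each) for
  parameter recovery, 200 draws for the entropy oracle — were chosen as
  the smallest sizes at which the binomial noise on the checked
  frequencies is comfortably below the asserted margins.

## Known limitations

- Bray-Curtis on pooled densities ignores within-site plot variance; no
  PERMANOVA/ANOSIM-style test accompanies the dendrogram.
- Bootstrap support resamples species columns; other resampling schemes
  (e.g. permuting individuals) would answer different questions and are
  deliberately out of scope.
- The comparison module applies no multiplicity correction across
  metrics, matching standard practice in this literature; interpret
  six metric-level p-values accordingly.
- Published per-species IVI values cannot be recomputed from density and
  dominance columns alone (the frequency column is typically unprinted),
  so IVI validation is structural — column sums, ranking behaviour —
  rather than cell-exact.
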