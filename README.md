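# chronoveg

Chronosequence analysis of woody-vegetation structure after land
abandonment, for community ecologists working with stem-level inventory
data. Given censuses of woody individuals (species, basal diameter
`d_0.10`, height) in fixed-area plots across sites that differ in years
since disturbance, the package computes:

- **Diversity** — richness *S*, Shannon `H' = −Σ p_i ln p_i`, and the
  effective number of species `¹D = exp(H')` (first-order Hill number),
  per plot and per pooled site;
- **Vertical structure** — Pretzsch's species height profile index
  (A-index): Shannon entropy over species x relative-height-zone cells
  (zones I/II/III at >80%, 50–80%, ≤50% of the tallest individual);
- **Importance values** — per-species relative abundance, basal-area
  dominance and plot frequency, averaged into
  `IVI_i = (RA_i + Rd_i + Rf_i)/3`, plus stand volume
  `V = g·h·MC` (form factor MC = 0.5 for thornscrub);
- **Between-site similarity** — Bray-Curtis
  `2Σmin(x,y)/(Σx+Σy)` on pooled densities, UPGMA dendrogram with
  cophenetic correlation and species-bootstrap branch support, Newick
  export;
- **Group comparisons** — assumption-gated one-way ANOVA: Shapiro-Wilk
  and Brown-Forsythe Levene first, then classic ANOVA + Tukey HSD or
  Welch ANOVA + Games-Howell depending on the homoscedasticity verdict,
  with compact letter displays;
- **Synthetic inventories** — a seeded generator of chronosequence
  censuses (geometric rank-abundance with analytic entropy oracle, nested
  species accretion, log-normal heights, allometric diameters) calibrated
  to a published Tamaulipan thornscrub abandonment gradient, so the whole
  pipeline is testable without field data.

A published per-site density table from that gradient (four sites: 10,
20, 30, >30 years abandoned; 4 x 1600 m² plots each) ships with the
package (`chronoveg.datasets`) and anchors the reproduction tests.

## Worked example

Simulate a chronosequence inventory and analyse it:

```bash
chronoveg simulate --seed 42 -o demo.csv
chronoveg diversity -i demo.csv
```

```
scope,richness,shannon_h,effective_species,defined
10,3,0.23878168397197427,1.2697013101766368,True
20,6,0.8523600041843029,2.3451749488865237,True
30,9,1.512883913368179,4.539804336186204,True
>30,21,2.227163440470216,9.273523834066374,True
```

Diversity climbs with time since abandonment: the youngest site is a
near-monoculture (`¹D ≈ 1.27` effective species despite 3 observed),
while the undisturbed site supports ~9.3 equally-weighted species — the
successional gradient built into the generator's defaults.

```bash
chronoveg similarity -i demo.csv --support-reps 999 --seed 42
```

```
,10,20,30,>30
10,1.0,0.6589805825242718,0.37834132967786155,0.005545286506469501
...
(((20:0.165549,30:0.165549)62:0.0751205,10:0.24067)100:0.235896,>30:0.476565)100;
# cophenetic r = 0.9506
```

Adjacent stages are compositionally similar (BC ≈ 0.66–0.67) while the
extreme pair is nearly disjoint (BC ≈ 0.006); the Newick tree carries
bootstrap support on internal nodes and half-merge-height branch lengths,
and the cophenetic correlation (≈0.95) says the ultrametric tree
faithfully summarizes the distance matrix.

The full pipeline — diversity, vertical structure, importance tables,
volumes, clustering, and the six routed group comparisons — runs as

```bash
chronoveg report -i demo.csv --output-dir results/ --seed 42
```

and from Python:

```python
import chronoveg as cv

chrono = cv.read_inventory("demo.csv")
cv.site_a_summary(chrono)            # per-site mean ± SD of plot A-index
cv.importance_table(chrono.site("10")).table   # IVI ranking, sums to 100
cv.compare_metric(chrono, "a_index") # Levene-gated ANOVA with posthoc
```

On the seed-42 inventory the A-index rises from 0.75 ± 0.16 nats at the
youngest site to 2.38 ± 0.12 at the oldest, and the young site's pioneer
dominant carries IVI ≈ 75 of 100 — the early-succession signature of one
species monopolizing abundance, dominance and frequency at once.

## Layout

```
src/chronoveg/
  inventory.py    stem-table I/O, data model, per-hectare aggregation
  diversity.py    S, H', effective species
  vertical.py     height zones and A-index
  importance.py   basal area, IVI tables, stand volume
  similarity.py   Bray-Curtis, UPGMA, cophenetic r, bootstrap support
  comparison.py   Levene-gated ANOVA/Welch with Tukey/Games-Howell
  synthetic.py    seeded chronosequence generator + shipped config
  datasets.py     bundled published density table
  pipeline.py     run_all orchestration
  cli.py          `chronoveg` command group
docs/methods.md   models, conventions, generator scope, limitations
```
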