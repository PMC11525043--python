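# Methods

This note documents the statistical model behind each pipeline stage, the
parameters that matter, the numerical and design choices made where the
design was open, and what the synthetic benchmark can and cannot show.

## 1. Data model and preprocessing

All community data live in a single container type: a sites × species
abundance matrix tagged with a guild (`plant` = percent cover,
`butterfly` = pooled transect counts, `flower` = mean flowering units).
Presence is derived strictly as `abundance > 0` — no minimum-cover
threshold is applied anywhere. Sites are rows and species are columns
throughout.

Butterfly field surveys are pooled by summing counts over transect
intervals within a survey and averaging the sums across surveys (the
seasonal total per species and site); flower surveys are averaged across
sampling dates and `log(x+1)`-transformed to tame their dynamic range (a
monotone map fixing zero, so presence patterns are unaffected).

The interaction matrix codes literature-compiled flower-visitation records
on an ordinal strength scale — by default the six-level coding
{0, 0.2, 0.4, 0.6, 0.8, 1} from "no recorded visit" to "nectar plant of
paramount importance"; a reduced four-level variant {0, 0.2, 0.6, 1} is
also declared for compilations that do not score the intermediate levels.
When occurrence and interaction data are joined, sites missing from either
guild's survey are dropped, interaction-matrix species unobserved in the
field are dropped, and field species absent from the literature are kept
with strength 0 toward every partner — so the pair universe is always
(observed plants) × (observed butterflies), and every such pair counts as a
potential interaction. A `merge_duplicate_plants` utility collapses
duplicate plant records (synonyms, aggregates) keeping the highest coded
strength; this mirrors how compilations treat species aggregates and is
deliberately not part of the core join.

## 2. Pairwise association methods

For one pair, the sufficient statistics are `S` (sites), `n1, n2`
(occupancies) and `O` (co-occupied sites); `E = n1·n2/S` is the expected
co-occurrence under independent placement.

**RII on counts.** The relative interaction intensity index is defined on
performance measures in the plant-interaction literature; its exact
transplantation to co-occurrence data is not uniquely determined, so this
package uses the standard form applied to counts, `(O − E)/(O + E)`, which
preserves the index's defining properties: range [−1, 1], symmetry around
zero, sign equal to `sign(O − E)`, and sigmoid saturation. When
`O + E = 0` (one species absent everywhere) the association is defined as
0. This choice is the package's own reading and is flagged here
prominently; any analysis consuming RII values should note it.

**Fixed-margin null model.** Significance for RII comes from the
fixed-row, fixed-column ensemble sampled by curveball trades: two species
rows are picked uniformly, and the presences they do not share are
redistributed uniformly over the union of their exclusive sites, keeping
both row counts (hence all margins). Each null matrix applies
`⌈m·L⌉` trades to the observed matrix, with `L` the total number of
presences and multiplier `m = 5` by default (satisfying the usual
"more than 4·L" mixing rule); the default ensemble size is 1000. Design
choices, each exposed in `NullModelConfig`:

* *Joint stacking (default).* Both guilds are stacked into one
  species × sites matrix and randomized together, preserving per-site
  total richness and per-species occupancy simultaneously; per-guild
  randomization is available (`per_guild=True`).
* *Independent chains.* Every null matrix restarts from the observed
  matrix with its own seeded chain, rather than thinning one long chain;
  ensembles are therefore embarrassingly reproducible
  (seed → bit-identical p-values).
* *Tie handling.* `p_upper` counts null RII **≥** observed and `p_lower`
  **≤** observed — ties contribute to both tails, the conservative
  reading. P-values are plain proportions `k/n` by default; the
  `(k+1)/(n+1)` estimator is optional (`add_one_correction`) and off by
  default because attainable zeros matter when sweeping α up to 0.5.

Because margins are fixed, `E` is constant across the ensemble and RII is
monotone in `O`; the implementation exploits this but the contract is
stated in terms of RII. The trade kernel is a numba-compiled loop (the
pure-numpy single trade is kept as the reference implementation and the
two are property-tested against each other via the margin class they
sample).

**Analytic (probabilistic) method.** Under uniform random placement of
both occupancy patterns the co-occurrence count is hypergeometric; the
pmf is computed with exact integer arithmetic (`math.comb`), with an
exact-`Fraction` path used by the enumeration tests. The significance
measure for a positive association is the strict aggregation tail
`p_gt = P(X > O)`; `p_lt` and `p_eq` are also reported. The intensity
measure is the effect size standardized by the number of sites,
`(O − E)/S`.

**Spearman correlation.** Mid-rank (tie-corrected) Spearman rho per pair,
two-sided p from the large-sample t approximation, vectorized over all
pairs; an exact permutation p-value is available for ≤ 10 sites and
serves as the test oracle. Constant abundance vectors leave the
correlation undefined: such pairs are reported as NaN with a warning and
counted as non-significant, so confusion-table denominators never shift.
P-values are BH-adjusted across all pairs of one method × one community
run — the tested family is the full pair universe of a region.

**Detection rule.** A pair is *detected* at level α when its statistic is
positive **and** its method-specific p-value is below α: the null-model
upper tail for RII, `p_gt` for the analytic method, the BH-adjusted p for
the Spearman variants. Negative (segregation) associations are never
detections — mutualism can only appear as aggregation.

## 3. Accuracy framework

Known links are the strictly positive strengths in the interaction
matrix. TP = link detected, FN = link missed, FP = non-link detected,
TN = non-link not detected; sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP). (Published prose descriptions of FP/FN are sometimes swapped
relative to these formulas; the formulas and the printed tables are the
authority here — an erratum note worth keeping in mind when comparing
against text.) Confusion tables are computed over the α sweep
{0.05, 0.1, 0.2, 0.5}; detection sets are nested in α, so TP is
non-decreasing and TN non-increasing. Method comparisons use Pearson's
chi-squared **with Yates continuity correction** on 2×2 tables — rows =
methods, columns = (TP, FN) or (TN, FP). The Yates correction was
verified to reproduce all eight published comparison statistics from the
reference counts, whereas the uncorrected statistic does not; when the
two methods cover different pair universes (the flower variant covers
fewer pairs) each method's own totals enter unchanged. Network metrics:
potential = n_plants × n_butterflies, realized = TP (or the known-link
count for the empirical row), connectance = realized/potential; ratios
and connectance are displayed at 3 d.p., full precision retained
internally.

A validation report against independent flower-visitation counts gives
(1) the count/percentage of visited pairs with negative associations,
(2) an OLS fit of visits on the association values of significant positive
pairs, (3) Spearman rho between visits and coded interaction strengths.

## 4. Congruence analysis

Each pair is placed at (association strength, interaction strength);
quadrant splits default to x = 0 (aggregation vs. segregation) and y = the
smallest positive strength code (link vs. no link) — the natural reading
of the published quadrant display, which draws the dividers without
printing thresholds; both are arguments. One-way ANOVA compares mean
association across strength levels (levels with < 2 observations are
dropped with a warning); Tukey HSD contrasts use the Tukey–Kramer
harmonic-mean treatment of unbalanced groups at 95% family-wise coverage.
The optional proportional-odds ordinal regression of strength category on
association (positively associated pairs only) is labelled exploratory:
its parallel-lines diagnostic refits a binary logit at every category
threshold and reports the slope spread, and the fit refuses outright on
separation or fewer than three outcome levels. The minimal
one-predictor, intercepts-only-thresholds model is used.

## 5. Synthetic communities

The generator emulates the structure of the target field data at
desk-test scale. Defaults: 60 sites (regions in comparable field designs
span roughly 40–90), 50 plants × 20 butterflies, connectance target 0.12
(empirical plant–butterfly networks run ≈ 0.12–0.20), the six-level
strength scale with weights {0.2: .4, 0.4: .2, 0.6: .2, 0.8: .1, 1: .1}
(literature compilations carry many singleton records and few
top-strength partners), Beta(2, 4) species-level baseline occupancy
(mean 1/3 of sites).

Links are independent Bernoulli(connectance) draws; plants are placed
independently site-by-site at their species-level probability;
butterfly presence follows a logistic model,

```
P(b at s) = logistic( logit(base_b) + κ · Σ_p strength(p, b) · presence(s, p) )
```

so κ = 0 decouples the guilds exactly and κ > 0 aggregates interacting
pairs (directional coupling — butterflies track nectar resources;
symmetric coupling is an option). Abundances are drawn on the presence
support only (log-normal percent cover truncated to (0, 100];
shifted-negative-binomial counts ≥ 1), so binarizing abundances recovers
the presence matrices exactly. Flower availability multiplies cover by a
species flowering rate and log-normal noise with phenological dropout;
visitation counts are Poisson with mean visit_rate × strength ×
co-occupied sites. All draws descend from one seed through per-stage
streams; identical configs yield byte-identical files.

**What the generator does not emulate:** environmental gradients and
spatial autocorrelation among sites, dispersal limitation, indirect
(shared-partner) dependencies between pairs, observation error in the
literature network, and observer effort in visitation counts. Passing
calibration/power checks on these communities therefore shows the
methods behave as their own theory predicts under ideal sampling — it
does not certify performance on field data, where those missing factors
are exactly what degrades it.

## 6. Calibration reference for discrete tests

The one-tailed P/A tests have discrete support, so their false-positive
rate at level α is not α. With the strict tail, the analytic method
rejects when `P(X > O) < α`, i.e. when `O ≥ q` for the smallest `q` with
`P(X > q) < α`, giving an operating level `P(X ≥ q) ≥ α` (liberal: ≈ 0.32
at α = 0.2 on the default communities). The tie-inclusive null-model RII
test is the opposite (valid/conservative: ≈ 0.11). Calibration is
therefore checked against each method's **exact attainable level**,
computed in closed form from the hypergeometric pmf
(`null_detection_rate`, including the positive-statistic condition), with
the hypergeometric standing in for the fixed-fixed marginal in the RII
case; the raw (unadjusted) Spearman test with the sign constraint has
nominal level α/2. The BH-adjusted Spearman rejection rate is *not* a
calibration object — FDR control makes per-pair rejection rates
intentionally sub-nominal under the null.

Benchmark problem sizes (the package's own choices): calibration and
power use the default 60×50×20 communities with 200 null-model
randomizations (upper-tail resolution 0.005, ample for α ≥ 0.05) — 20
seeds per coupling level in the test suite, 10 in the acceptance script;
uniformity checks use 10,000 ensemble samples over fully enumerable
margin classes; hypergeometric exactness is verified against complete
enumeration for all problems with ≤ 7 sites.

## 7. Known limitations

* The RII-on-counts form is a documented interpretation, not a unique
  derivation (§2 above).
* The closed-form calibration reference for the null-model RII test uses
  the hypergeometric marginal, which ignores the fixed-fixed ensemble's
  conditioning on site richness; the residual discrepancy observed at the
  default scale is well inside the Monte-Carlo band.
* The ordinal regression is exploratory by construction; its
  proportional-odds diagnostic is a heuristic (threshold-wise slope
  spread), not a formal test.
* Exact Spearman permutation p-values are limited to ≤ 10 sites
  (factorial enumeration).
* Reported region-level accuracy values from field studies depend on the
  underlying field and literature data; the packaged reference tables
  support recomputing ratios, test statistics and connectance from the
  published counts, not re-running inference on the original data.
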