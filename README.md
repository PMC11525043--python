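# mutualink

Do spatial co-occurrence patterns predict mutualistic interactions?
`mutualink` is a benchmarking pipeline for that question, built around the
plant–butterfly (pollination) case: it infers pairwise species associations
from site-by-species data with three standard co-occurrence methods, scores
the inferred links against a known interaction network with a
sensitivity/specificity framework, and quantifies how association strength
relates to interaction strength. A synthetic community generator with a
known ground-truth network and a tunable interaction→aggregation coupling
makes every stage testable offline.

It is aimed at community ecologists who want to evaluate co-occurrence
based network inference before trusting it on field data.

## Methods at the core

For a pair of species occupying `n1` and `n2` of `S` sites and co-occurring
at `O` of them, the expected co-occurrence under independent placement is
`E = n1·n2/S`, and:

* **RII with pairwise null models** (presence/absence). The relative
  interaction intensity on counts, `RII = (O − E)/(O + E) ∈ [−1, 1]`
  (positive = aggregation, negative = segregation). Significance comes
  from a fixed-row, fixed-column null model: the stacked two-guild binary
  matrix is re-randomized (default 1000 times) by curveball trades —
  `⌈5·L⌉` trades per matrix, `L` = total presences, respecting the
  \>4·L rule of thumb — and the upper/lower tail p-values are the
  proportions of null matrices whose RII is ≥ / ≤ the observed value.
* **Probabilistic (analytic hypergeometric)** (presence/absence). Under
  random placement the co-occurrence count is hypergeometric,
  `P(j) = C(S,j)·C(S−j,n1−j)·C(S−n1,n2−j) / [C(S,n1)·C(S,n2)]`;
  the aggregation tail `P(X > O)` is the significance measure, and
  `(O − E)/S` the effect size standardized by the number of sites.
* **Spearman rank correlation** (abundance), with Benjamini–Hochberg
  control of the false discovery rate across all pairs of a run; a
  flower-availability variant substitutes `log(x+1)`-transformed flowering
  units for plant cover.

Detections (positive, significant associations at level α) are classified
against the known links: sensitivity = TP/(TP+FN), specificity =
TN/(TN+FP); methods are compared with Yates-corrected chi-squared tests,
and networks summarized by connectance = realized/potential links.
Association vs. interaction strength is examined with quadrant analysis,
one-way ANOVA with Tukey HSD contrasts, and an exploratory
proportional-odds ordinal regression.

## Worked example

Generate a community of 40 sites, 15 plants and 8 butterflies with
connectance 0.2 and a strong interaction→aggregation coupling (κ = 2),
then infer and evaluate:

```sh
cat > config.yaml <<EOF
n_sites: 40
n_plants: 15
n_butterflies: 8
connectance_target: 0.2
coupling: 2.0
EOF
mutualink simulate --config config.yaml --seed 11 --out data
mutualink infer --data data --seed 11 --randomizations 1000 --out assoc
mutualink evaluate --data data --associations assoc --out results
mutualink report --results results
```

which prints (abridged):

```
wrote community (40 sites, 15 plants, 8 butterflies, 26 links) to data
rii_null: 21 significant positive pairs of 120 at alpha=0.2
probabilistic: 58 significant positive pairs of 120 at alpha=0.2
spearman_plants: 0 significant positive pairs of 120 at alpha=0.2

== Accuracy by method and significance level ==
          Method    Region  alpha  TP  TN  FP  FN  Sensitivity  Specificity
   probabilistic synthetic   0.20  21  57  37   5        0.808        0.606
        rii_null synthetic   0.20  11  84  10  15        0.423        0.894
 spearman_plants synthetic   0.20   0  94   0  26        0.000        1.000

== Network-level metrics (alpha = 0.2) ==
          Method    Region  Potential associations  Realized associations  Connectance
       Empirical synthetic                     120                     26        0.217
   probabilistic synthetic                     120                     21        0.175
        rii_null synthetic                     120                     11        0.092
```

Reading: of the 26 true links, the liberal analytic method detects 21 (at
the cost of 37 false positives among the 94 non-links), the conservative
null-model RII detects 11 with only 10 false positives, and the BH-corrected
rank correlation detects none at α = 0.2. All reconstructed networks are
sparser than the true one (connectance 0.217). The same objects are
available as a library (`mutualink.run_method`, `classify_pairs`,
`sweep_alphas`, `assign_quadrants`, ...) for use in notebooks.

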