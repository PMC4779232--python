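# curvegroups

Permutation-based *curve group analysis* of longitudinal gene expression
from matched case-control pairs.

In a prospective nested case-control design, each cancer case is matched
to a healthy control and the analysis unit is the per-pair log2
expression difference `X[g, p]` for gene *g* and pair *p*. Each pair
belongs to a clinical **stratum** *s* (e.g. lymph node status) and a
**time period** *t* ∈ 1..T before diagnosis (*t* = 1 nearest diagnosis).
Blood-borne signals of carcinogenesis are weak and no parametric shape
for a gene's trajectory can be assumed, so the method aggregates
evidence over many genes instead of testing genes one by one:

* **Curve groups.** Within a stratum, a gene's trajectory is summarised
  by its per-period means X̄(g,T,s) … X̄(g,1,s). The strict ordering of
  those means, written as a rank string from the farthest to the nearest
  period, is the gene's curve group — with T = 3 there are 3! = 6 groups
  (`123` = rising toward diagnosis, `132` = peaking in the middle
  period, …). A gene joins its group only if its extreme period means
  differ by a two-sided Welch test with p-value p(g,c) below α
  (inclusion criterion 1) or within the M smallest p-values for that
  group (inclusion criterion 2).
* **Development over time** (one stratum): the test statistics are the
  member-gene count per curve group and their total (global test). The
  null permutes the stratum's pairs among time periods, re-running the
  whole assignment for every randomization.
* **Comparing two strata**: either the curve-group variable
  `Z[c,s,p] = mean over g in G[c,s] of X[g,p]` (G selected with
  criterion 2, M = 100, from stratum *s*; compared between strata with
  a Welch t), or the weighted t-statistic sum `L_k = Σ_{g∈G_k} F_g`
  with `F_g = Σ_t w_t |T[g,t]|`, where T[g,t] is the per-gene Welch t
  between the strata within period *t* and G_k holds the k largest
  F_g. The null permutes stratum labels within each period.

All p-values are permutation p-values `(K+1)/(N+1)`, where K of N label
randomizations give an equal-or-more-extreme statistic. Permuting
labels only (never values) preserves each pair's gene vector and hence
the inter-gene correlation structure under the null.

## Worked example

Simulate 500 genes in two strata of 15 pairs per period, with 40 signal
genes following the `132` pattern (rising then falling, spacing 0.8
log2 units) planted in the `node_positive` stratum only:

```sh
curvegroups simulate --config sim.yaml --out-prefix demo
curvegroups trend-test --matrix demo.matrix.tsv --annotations demo.annotation.tsv \
    --stratum node_positive --alpha 0.01 --n-perm 999 --seed 7 --out trend.tsv
```

```
stratum        curve_group  observed  expected  p_value
node_positive  global       50        12.89     0.002
node_positive  123          3         2.21      0.336
node_positive  132          42        2.07      0.001
node_positive  213          2         2.19      0.565
...
```

The planted group `132` holds 42 member genes against ~2 expected by
chance (p = 0.001, the smallest value attainable with 999
randomizations); the global count is inflated accordingly (50 vs ~13,
p = 0.002); all other groups are at their null level.

Comparing the strata with the curve-group variable in the middle
period, where the `132` pattern peaks:

```sh
curvegroups strata-test --matrix demo.matrix.tsv --annotations demo.annotation.tsv \
    --mode z --curve-group 132 --selection-stratum node_positive \
    --strata node_positive,node_negative --scope period:2 --n-perm 999 --seed 7 --out z.tsv
```

```
curve_group  selection_stratum  scope     observed_t  p_value
132          node_positive      period:2  20.22       0.001
```

and with the weighted t-statistic sum over all periods:

```
k    observed_L_k  p_value
10   39.11         0.001
50   142.21        0.001
100  212.27        0.001
200  316.03        0.001
```

Every run writes a JSON manifest next to its output;
`curvegroups rerun <manifest>` reproduces the output byte-identically.

The same pipelines are available as library functions
(`assign_curve_groups`, `trend_test_stratum`, `z_strata_test`,
`lk_test`, `generate_dataset`, `estimate_error_rates`, …).

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
generator, parameter defaults, numerical conventions and known
limitations.
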