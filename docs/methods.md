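# Methods

## Data model

The analysed quantity is the matrix of paired log2 expression
differences `X[g, p] = log2(case) − log2(control)` for gene *g* and
matched case-control pair *p*. Each pair carries two design labels: a
stratum *s* (a clinical subgroup; pairs belong to exactly one) and a
time period *t* ∈ {1, …, T}, an ordinal bin of time-to-diagnosis with
*t* = 1 the bin nearest diagnosis. Missing values are rejected at load
time rather than imputed: every statistic below assumes a complete
matrix, and silent imputation would distort the permutation null.

For a gene unrelated to disease progression, the case−control
difference fluctuates around a constant over time (day-to-day exposure
noise affects case and control alike); a gene involved in progression
may drift in a non-random way as diagnosis approaches. The method asks
whether such drift exists at all, and whether it differs between
strata, without modelling any per-gene trajectory shape.

## Preprocessing

Four generic steps turn raw intensity matrices into `X`:

1. **Quantile normalization** on the original scale: all columns are
   forced onto the reference distribution obtained by averaging the
   column-sorted matrix. Ties within a column receive the mean of the
   reference values spanning their ranks — a deterministic convention
   that keeps the operation idempotent on tie-free data (verified
   against limma's implementation in the test suite).
2. **Presence filter**: a feature is kept if detected in at least
   `ceil(min_fraction × n_samples)` samples (1 % of 882 samples ⇒ 9).
   What counts as "detected" is the caller's choice (detection p-value
   or intensity threshold); the filter takes a boolean matrix.
3. **Probe collapse**: when several probes map to one gene, the probe
   with the highest mean intensity across all samples is kept, ties
   broken by the lexicographically smallest probe id. Any
   deterministic rule would do; highest mean is a common convention
   that favours well-measured probes.
4. **Paired log2 differences** per (case, control, pair) triple.
   Intensities must be strictly positive.

## Curve groups

Within stratum *s*, gene *g* has per-period means X̄(g,t,s). If the T
means are strictly ordered, the gene's curve group is the string of
their ranks read from period T (left) to period 1 (right); there are
T! groups (6 for T = 3, 24 for T = 4). Exactly tied means — a
probability-zero event for continuous data, but constructible — yield
no group.

"Sufficient change over time" is judged by a two-sample Welch
(unequal-variance) t-test between the pair values of the minimum-mean
and maximum-mean periods, p-value p(g,c). The test is two-sided: the
extreme periods are data-chosen, so a one-sided test would be
anti-conservative. Degenerate zero-variance samples follow the
continuous limit (equal means ⇒ p = 1, unequal ⇒ p = 0).

Membership then uses one of two criteria:

* **criterion 1**: p(g,c) < α, default α = 0.01 — used by the
  development-over-time tests;
* **criterion 2**: the M genes with smallest p(g,c) among genes whose
  ordering is c, default M = 100 — used to build the curve-group
  variable. Ranking is restricted to genes carrying the ordering c
  (a gene that rises cannot represent a falling group); ties at the
  M-th smallest p are broken by lexicographic gene id. When fewer
  than M genes carry the ordering, all are taken and downstream
  averages divide by the actual count.

A gene belongs to at most one group, so no multiplicity is introduced
by the classification itself.

## Permutation tests

All tests share one machinery: a statistic, a label-randomization
scheme defining the null, and the p-value `(K+1)/(N+1)` where K of N
randomized datasets give an equal-or-more-extreme statistic (ties
count as extreme; the estimator is conservative and its floor is
1/(N+1)). N defaults to 1000. Randomizations permute labels, never
values, so each pair's gene vector — and with it the inter-gene
correlation structure — is intact under the null. Everything
downstream of the labels, gene selection included, is recomputed
inside every randomization; selection outside the loop would bias the
null toward the observed selection. Randomization *i* uses stream *i*
of a `SeedSequence` spawned from the master seed, so results are
independent of execution order and enlarging N extends the ensemble
rather than reshuffling it.

**Development over time** (per stratum): statistics are the member
count per curve group and the total over groups (global test), under
criterion 1. The null shuffles the stratum's pairs among time periods
(per-period counts fixed). The 1 + T! p-values are upper-tail — the
alternative is "more genes than expected by chance" — and share one
randomization ensemble, which makes them mutually consistent and
halves compute. The "expected" counts reported beside the observed
ones are the means of the null counts from the same ensemble. No
multiple-testing adjustment is applied across the tests: the grouped
design is the paper-level control, and raw permutation p-values are
reported.

**Curve-group variable Z** (two strata): `Z[c,s,p]` is the mean of
`X[g,p]` over the gene set selected for group c from stratum s by
criterion 2. Genes are selected from the selection stratum only, but Z
is evaluated for every pair, so strata can be compared on it. The
observed statistic is the Welch two-sample t of Z between the two
strata over the in-scope pairs (all periods, or one period); the
comparison scheme never re-selects genes per period — scoping affects
only which pairs enter the t. The null permutes stratum labels within
each period between the two compared strata and re-selects the gene
set each time; the p-value is two-sided. The Welch t is a pragmatic
choice of test statistic: the permutation null makes the distributional
form immaterial, and it matches the package's other two-sample
comparisons. In the (practically unreachable at realistic scale) event
that a null randomization leaves no gene with ordering c, that draw's
statistic is 0; on the observed data it is an error.

**Weighted t-statistic sum L_k** (two strata, curve-group-free): per
gene and period, T[g,t] is the Welch t between the strata within
period t; `F_g = Σ_t w_t |T[g,t]|` with non-negative weights summing
to 1 (equal `1/T` by default, or proportional to period pair counts,
or custom); `L_k` is the sum of the k largest F_g. Upper-tail p-values
are computed for a grid of k (default {10, 50, 100, 200, 500, 1000}
clipped to the gene count): scanning k shows whether a difference is
carried by few strong genes or many weak ones. Per-period scopes use
only that period's pairs with weight 1. Genes with a degenerate
t-statistic (zero variance in both groups, unequal means) are flagged
and excluded from the top-k sums so that L_k stays finite.

## Synthetic data generator

`generate_dataset` draws

    X[g, p] = mu[g, t(p), s(p)] + b[g] · f[p] + eps[g, p]

with `f[p] ~ N(0,1)` per pair, `b[g] ~ N(0, factor_loading_sd²)` and
`eps ~ N(0, noise_sd²)`. A signal gene with label c has period mean
`delta × (rank of t in c − (T+1)/2)`: consecutive rank levels are
`delta` apart and the levels are centered, so the time effect carries
no marginal shift and a trajectory cannot be detected as a plain mean
offset. Background genes have mean zero everywhere. Optional knobs
restrict the trajectory to named strata (`signal_strata`) or add a
constant per-stratum shift to signal genes (`stratum_shift`) for
between-strata scenarios.

Defaults: `noise_sd = 0.5` log2 units (a typical per-gene spread for
paired expression differences) and `factor_loading_sd = 0.2`, giving
mild but non-negligible inter-gene correlation — the single latent
factor is the simplest mechanism producing the correlated-genes
property the permutation schemes are designed to preserve. The
generator emulates *differences*, not raw intensities: probe-level
artefacts, batch effects (removed by the paired design) and
heavy-tailed outliers are deliberately out of scope, so passing tests
demonstrate correctness of the statistical machinery under the
model's assumptions, not robustness to every artefact of real arrays.
Under `effect_size = 0` all pairs of a stratum are exchangeable across
periods, which is exactly the permutation null.

`estimate_error_rates` replicates generate → test → reject-at-level
over a config grid; replicate r of a config derives its data seed and
test seed from `(cfg.seed, r)`, so tables are reproducible and
configs independent.

## Validation study sizes

The packaged acceptance checks use 500 genes, 20 pairs per period (per
stratum), 199 permutations and 200 replicates for null calibration,
and 100 replicates for the power curve over effect sizes
{0, 0.5, 1.0} with 50 signal genes — sizes at which the Monte-Carlo
binomial envelope around a 0.05 level is ±0.04 and a single study runs
in well under a minute. Measured rates on this build: 0.04–0.08 for
the three tests' type-I error, and power 0.07 / 1.0 / 1.0 across the
effect-size grid.

One subtlety of the count statistic worth knowing: when many signal
genes share one planted pattern, a time-label permutation occasionally
re-aligns *all* of them at once, so the null count distribution has a
small heavy upper tail and the p-value under overwhelming signal may
sit slightly above the 1/(N+1) floor at large N (e.g. ≈ 0.009 at
N = 999 in the acceptance script's scenario). This is a property of
jointly-patterned signal, not a calibration defect — type-I error is
unaffected.

## Numerical conventions

* Welch degrees of freedom by Welch–Satterthwaite; p-values via the
  Student-t survival function, vectorized over genes.
* Group means/variances computed from per-period sums and sums of
  squares; variances clipped at 0 against round-off.
* TSV writers emit shortest round-trip decimal representations and the
  readers parse with round-trip precision, so write∘read is exact.
* Every period must hold ≥ 2 pairs of the analysed stratum (Welch
  requirement); violations raise errors naming the period.

## Limitations

* Counts are discrete, so the per-group tests are conservative when
  ties between observed and null counts are common (small α or few
  genes); the calibration study quantifies the effect.
* T! grows quickly: labels are supported for T ≤ 9, and per-group
  counts thin out as T grows, weakening per-group (not global) power.
* The generator's Gaussian single-factor correlation structure is a
  deliberate simplification; real expression data have richer
  correlation and tail behaviour.
* Real-data cohort results cannot be reproduced here; validation is
  via synthetic data with known ground truth.
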