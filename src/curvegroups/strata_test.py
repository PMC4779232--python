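"""Permutation tests comparing the development of two strata.

Two complementary statistics are provided:

* the **curve-group variable** Z[c, s, p]: the per-pair average of
  X[g, p] over the gene set G[c, s] selected for curve group ``c``
  from stratum ``s`` by inclusion criterion 2 (the M = 100 smallest
  Welch p-values among genes carrying ordering ``c``).  The observed
  statistic is the Welch two-sample t of Z between the two compared
  strata, either over all time periods or within one period;

* the **weighted t-statistic sum** L_k: per gene, F_g is the weighted
  sum over periods of |T_{g,t}|, the absolute Welch t comparing the
  two strata within period t; L_k is the sum of the k largest F_g.

Both nulls permute the stratum labels of the compared pairs within
each time period, and everything downstream of the labels — gene
selection included — is recomputed for every randomization, which
protects the tests from selection bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .curve_groups import _StratumAssigner, _welch_from_stats, enumerate_curve_groups
from .data_model import ExpressionDiffMatrix, PairAnnotation
from .resampling import PermutationTestResult, permutation_p_value, spawn_rngs

__all__ = [
    "CurveGroupVariable",
    "LkTestResult",
    "build_curve_group_variable",
    "z_strata_test",
    "gene_period_tstat",
    "l_k_statistic",
    "lk_test",
    "resolve_weights",
]

#: Sentinel for a degenerate (zero-variance, unequal-mean) t-statistic.
DEGENERATE_T = np.inf


@dataclass(frozen=True)
class CurveGroupVariable:
    """Per-pair average of X over the genes selected for one curve group."""

    label: str
    selection_stratum: str
    gene_ids: tuple[str, ...]
    z: pd.Series  # indexed by pair id, covers every pair in the dataset

    @property
    def size(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class LkTestResult:
    """Observed L_k and permutation p-value for each requested k."""

    strata: tuple[str, str]
    scope: str
    weights: tuple[float, ...]
    k_grid: tuple[int, ...]
    observed: tuple[float, ...]
    p_values: tuple[float, ...]
    n_perm: int
    seed: int
    flagged_genes: tuple[str, ...]  # degenerate-variance genes excluded from top-k

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"k": self.k_grid, "observed_L_k": self.observed, "p_value": self.p_values}
        )
        df["scope"] = self.scope
        df["n_perm"] = self.n_perm
        df["seed"] = self.seed
        return df


# ---------------------------------------------------------------------------
# Curve-group variable Z
# ---------------------------------------------------------------------------


def _top_m_for_label(assigner: _StratumAssigner, period_idx: np.ndarray, label_pos: int, m: int) -> np.ndarray:
    """Row indices of the (up to) m smallest-p genes with the given ordering."""
    label_idx, p = assigner.assign(period_idx)
    candidates = np.flatnonzero(label_idx == label_pos)
    if candidates.size == 0:
        return candidates
    order = np.lexsort((assigner.lex_rank[candidates], p[candidates]))
    return candidates[order[:m]]


def _aligned(x: ExpressionDiffMatrix, ann: PairAnnotation):
    strata, periods = ann.aligned(x.pair_ids)
    return strata, periods


def build_curve_group_variable(
    x: ExpressionDiffMatrix,
    ann: PairAnnotation,
    label: str,
    selection_stratum: str,
    m: int = 100,
) -> CurveGroupVariable:
    """Select G[c, s] by inclusion criterion 2 and average X over it.

    Genes are selected from the selection stratum only, but Z is
    computed for every pair in the dataset, whatever its stratum.  If
    fewer than ``m`` genes carry the ordering, all of them are used
    and the average divides by the actual count.
    """
    strata, periods = _aligned(x, ann)
    T = ann.n_periods
    labels = enumerate_curve_groups(T)
    if label not in labels:
        raise ValueError(f"unknown curve-group label {label!r} for {T} periods")
    sel = np.flatnonzero(strata == selection_stratum)
    if sel.size == 0:
        raise ValueError(f"stratum {selection_stratum!r} has no pairs")
    assigner = _StratumAssigner(x.values[:, sel], T, gene_ids=x.gene_ids)
    genes = _top_m_for_label(assigner, periods[sel] - 1, labels.index(label), m)
    if genes.size == 0:
        raise ValueError(
            f"no gene carries ordering {label!r} in stratum {selection_stratum!r}"
        )
    z = x.values[genes].mean(axis=0)
    return CurveGroupVariable(
        label=label,
        selection_stratum=selection_stratum,
        gene_ids=tuple(x.gene_ids[g] for g in genes),
        z=pd.Series(z, index=list(x.pair_ids), name=f"Z[{label},{selection_stratum}]"),
    )


def _parse_scope(scope, periods: np.ndarray) -> np.ndarray:
    """Boolean in-scope mask over pairs; scope is 'all' or a period number."""
    if scope == "all" or scope == "all_periods":
        return np.ones(periods.shape, dtype=bool)
    t = int(scope)
    if t not in set(int(p) for p in periods):
        raise ValueError(f"no pairs in time period {t}")
    return periods == t


def _welch_t_two_groups(values: np.ndarray, in_a: np.ndarray, in_b: np.ndarray) -> float:
    a = values[in_a]
    b = values[in_b]
    if a.size < 2 or b.size < 2:
        raise ValueError("each stratum needs at least 2 pairs in scope")
    t, _ = _welch_from_stats(a.mean(), a.var(ddof=1), a.size, b.mean(), b.var(ddof=1), b.size)
    return float(t)


def z_strata_test(
    x: ExpressionDiffMatrix,
    ann: PairAnnotation,
    label: str,
    selection_stratum: str,
    strata: tuple[str, str],
    scope="all",
    m: int = 100,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationTestResult:
    """Two-sided permutation test of Z[c, s, p] between two strata.

    The observed statistic is the Welch two-sample t of the curve-group
    variable between the strata over the in-scope pairs.  Each
    randomization permutes stratum labels within every time period and
    re-selects the gene set from the permuted data before recomputing
    the statistic.
    """
    s1, s2 = strata
    strata_arr, periods = _aligned(x, ann)
    T = ann.n_periods
    labels = enumerate_curve_groups(T)
    if label not in labels:
        raise ValueError(f"unknown curve-group label {label!r} for {T} periods")
    label_pos = labels.index(label)
    for s in (s1, s2, selection_stratum):
        if not np.any(strata_arr == s):
            raise ValueError(f"stratum {s!r} has no pairs")

    pool = np.flatnonzero((strata_arr == s1) | (strata_arr == s2))
    scope_mask = _parse_scope(scope, periods)
    bits = (strata_arr[pool] == s2).astype(np.intp)  # 0 = s1, 1 = s2

    def statistic(bits_now: np.ndarray, observed_pass: bool) -> float:
        # Current stratum membership over all pairs.
        current = strata_arr.copy()
        current[pool] = np.where(bits_now == 0, s1, s2)
        sel = np.flatnonzero(current == selection_stratum)
        assigner = _StratumAssigner(x.values[:, sel], T, gene_ids=x.gene_ids)
        genes = _top_m_for_label(assigner, periods[sel] - 1, label_pos, m)
        if genes.size == 0:
            if observed_pass:
                raise ValueError(
                    f"no gene carries ordering {label!r} in stratum {selection_stratum!r}"
                )
            return 0.0
        z = x.values[genes].mean(axis=0)
        in_a = scope_mask & (current == s1)
        in_b = scope_mask & (current == s2)
        return _welch_t_two_groups(z, in_a, in_b)

    observed = statistic(bits, observed_pass=True)
    by_period = [np.flatnonzero(periods[pool] == t) for t in range(1, T + 1)]
    nulls = np.empty(n_perm)
    for i, rng in enumerate(spawn_rngs(seed, n_perm)):
        perm_bits = bits.copy()
        for idx in by_period:
            if idx.size > 1:
                perm_bits[idx] = perm_bits[idx][rng.permutation(idx.size)]
        nulls[i] = statistic(perm_bits, observed_pass=False)
    return permutation_p_value(observed, nulls, direction="two_sided", seed=seed)


# ---------------------------------------------------------------------------
# Weighted t-statistic sum L_k
# ---------------------------------------------------------------------------


class _TwoStrataTstats:
    """Per-gene, per-period Welch t between two strata (vectorized).

    Built once on the pooled columns of the two strata; each call takes
    the current 0/1 stratum assignment of those columns, so a stratum-
    label permutation costs one group-statistics pass.
    """

    def __init__(self, values: np.ndarray, period_idx: np.ndarray, n_periods: int):
        self.x = np.asarray(values, dtype=float)
        self.x2 = self.x**2
        self.period_idx = np.asarray(period_idx, dtype=np.intp)
        self.n_periods = int(n_periods)

    def tstats(self, bits: np.ndarray, periods_used: Sequence[int]):
        """t matrix (genes x len(periods_used)) and a degenerate-gene mask.

        ``bits`` assigns each pooled column to stratum 0 or 1; the t is
        stratum 0 minus stratum 1.  Degenerate entries (zero variance
        in both groups, unequal means) are set to ``DEGENERATE_T``.
        """
        T = self.n_periods
        group = bits * T + self.period_idx  # 2T groups
        counts = np.bincount(group, minlength=2 * T).astype(float)
        onehot = np.zeros((len(group), 2 * T))
        onehot[np.arange(len(group)), group] = 1.0
        s1 = self.x @ onehot
        s2 = self.x2 @ onehot
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = s1 / counts
            var = (s2 - s1 * mean) / (counts - 1)
        np.maximum(var, 0.0, out=var)
        t_cols = []
        for t in periods_used:
            j0, j1 = t - 1, T + t - 1
            for j in (j0, j1):
                if counts[j] < 2:
                    raise ValueError(
                        f"time period {t} has fewer than 2 pairs in one stratum"
                    )
            tt, _ = _welch_from_stats(
                mean[:, j0], var[:, j0], counts[j0], mean[:, j1], var[:, j1], counts[j1]
            )
            t_cols.append(tt)
        t_mat = np.column_stack(t_cols)
        degenerate = ~np.isfinite(t_mat)
        t_mat[degenerate] = DEGENERATE_T
        return t_mat, degenerate.any(axis=1)


def gene_period_tstat(
    x: ExpressionDiffMatrix,
    ann: PairAnnotation,
    strata: tuple[str, str],
    period: int,
) -> pd.Series:
    """Welch two-sample t per gene between two strata within one period.

    Sign convention: first stratum minus second stratum.
    """
    s1, s2 = strata
    strata_arr, periods = _aligned(x, ann)
    pool = np.flatnonzero(((strata_arr == s1) | (strata_arr == s2)) & (periods == period))
    if pool.size == 0:
        raise ValueError(f"no pairs of strata {strata!r} in period {period}")
    bits = (strata_arr[pool] == s2).astype(np.intp)
    if np.sum(bits == 0) < 2 or np.sum(bits == 1) < 2:
        raise ValueError(f"each stratum needs at least 2 pairs in period {period}")
    engine = _TwoStrataTstats(x.values[:, pool], np.zeros(pool.size, dtype=np.intp), 1)
    t_mat, _ = engine.tstats(bits, [1])
    return pd.Series(t_mat[:, 0], index=list(x.gene_ids), name=f"T[{s1}-{s2},t={period}]")


def l_k_statistic(f_values, k: int) -> float:
    """Sum of the k largest entries of a vector of non-negative scores."""
    f = np.asarray(f_values, dtype=float)
    if not (1 <= k <= f.size):
        raise ValueError(f"k must be in 1..{f.size}; got {k}")
    return float(np.partition(f, f.size - k)[f.size - k :].sum())


def resolve_weights(weights, period_counts: np.ndarray) -> np.ndarray:
    """Per-period weights summing to 1.

    ``weights`` is ``"equal"`` (1/T each), ``"proportional"`` (period
    pair counts across both strata, normalized), or an explicit
    non-negative vector which is normalized to sum 1.
    """
    T = len(period_counts)
    if isinstance(weights, str):
        if weights == "equal":
            return np.full(T, 1.0 / T)
        if weights == "proportional":
            total = float(np.sum(period_counts))
            return np.asarray(period_counts, dtype=float) / total
        raise ValueError(f"unknown weight scheme {weights!r}")
    w = np.asarray(weights, dtype=float)
    if w.shape != (T,) or np.any(w < 0) or w.sum() <= 0:
        raise ValueError("custom weights must be a non-negative length-T vector")
    return w / w.sum()


def _f_scores(t_mat: np.ndarray, degenerate: np.ndarray, w: np.ndarray) -> np.ndarray:
    """F_g = sum_t w_t |T_{g,t}|, with degenerate genes masked to -inf."""
    f = np.abs(t_mat) @ w
    f[degenerate] = -np.inf
    return f


def _top_k_sums(f: np.ndarray, k_grid: Sequence[int]) -> np.ndarray:
    finite = f[np.isfinite(f)]
    srt = np.sort(finite)[::-1]
    csum = np.concatenate([[0.0], np.cumsum(srt)])
    return np.array([csum[min(k, srt.size)] for k in k_grid])


def lk_test(
    x: ExpressionDiffMatrix,
    ann: PairAnnotation,
    strata: tuple[str, str],
    weights="equal",
    k_grid: Sequence[int] | None = None,
    scope="all",
    n_perm: int = 1000,
    seed: int = 0,
) -> LkTestResult:
    """Upper-tail permutation test of L_k for each k in the grid.

    ``scope="all"`` combines all periods with the requested weights; a
    period-number scope uses only that period's pairs with weight 1 on
    it.  Genes with a degenerate (zero-variance, unequal-mean)
    t-statistic in any used period are flagged and excluded from the
    top-k sums, keeping L_k finite.
    """
    s1, s2 = strata
    strata_arr, periods = _aligned(x, ann)
    for s in (s1, s2):
        if not np.any(strata_arr == s):
            raise ValueError(f"stratum {s!r} has no pairs")
    pool = np.flatnonzero((strata_arr == s1) | (strata_arr == s2))
    scope_mask = _parse_scope(scope, periods[pool])
    pool = pool[scope_mask]
    T = ann.n_periods
    periods_used = list(range(1, T + 1)) if scope in ("all", "all_periods") else [int(scope)]
    bits = (strata_arr[pool] == s2).astype(np.intp)

    counts_by_period = np.array(
        [np.sum(periods[pool] == t) for t in periods_used], dtype=float
    )
    if len(periods_used) == 1:
        w = np.array([1.0])
    else:
        w = resolve_weights(weights, counts_by_period)

    if k_grid is None:
        k_grid = [k for k in (10, 50, 100, 200, 500, 1000) if k <= x.n_genes]
    k_grid = [int(k) for k in k_grid]
    for k in k_grid:
        if not (1 <= k <= x.n_genes):
            raise ValueError(f"k must be in 1..{x.n_genes}; got {k}")

    engine = _TwoStrataTstats(
        x.values[:, pool],
        np.asarray([periods_used.index(int(t)) for t in periods[pool]], dtype=np.intp),
        len(periods_used),
    )
    t_mat, degenerate = engine.tstats(bits, list(range(1, len(periods_used) + 1)))
    observed = _top_k_sums(_f_scores(t_mat, degenerate, w), k_grid)
    flagged = tuple(x.gene_ids[g] for g in np.flatnonzero(degenerate))

    by_period = [np.flatnonzero(engine.period_idx == j) for j in range(len(periods_used))]
    null_lk = np.empty((n_perm, len(k_grid)))
    for i, rng in enumerate(spawn_rngs(seed, n_perm)):
        perm_bits = bits.copy()
        for idx in by_period:
            if idx.size > 1:
                perm_bits[idx] = perm_bits[idx][rng.permutation(idx.size)]
        tm, dg = engine.tstats(perm_bits, list(range(1, len(periods_used) + 1)))
        null_lk[i] = _top_k_sums(_f_scores(tm, dg, w), k_grid)

    k_counts = (null_lk >= observed[None, :]).sum(axis=0)
    p_values = (k_counts + 1) / (n_perm + 1)
    return LkTestResult(
        strata=(s1, s2),
        scope=str(scope),
        weights=tuple(float(v) for v in w),
        k_grid=tuple(k_grid),
        observed=tuple(float(v) for v in observed),
        p_values=tuple(float(v) for v in p_values),
        n_perm=n_perm,
        seed=seed,
        flagged_genes=flagged,
    )
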