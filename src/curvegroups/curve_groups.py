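"""Curve-group classification of gene trajectories within a stratum.

A gene's trajectory is summarised by its per-period mean log2
difference.  The *curve group* of a gene is the strict ordering of
those T means, written as a string of ranks read from the farthest
period (left) to the period nearest diagnosis (right).  With T = 3
there are 3! = 6 possible groups: 123 (rising toward diagnosis), 321
(falling), 132, 213, 231 and 312.  Genes whose extreme period means
are "too similar" are excluded from all groups; similarity is judged
by a two-sided Welch two-sample t-test between the pairs of the
minimum-mean and maximum-mean periods, with p-value ``p_gc``.

Membership uses one of two inclusion criteria:

* criterion 1 (``alpha`` mode): member iff ``p_gc < alpha``;
* criterion 2 (``top_m`` mode): for each group, the M genes with the
  smallest ``p_gc`` among genes carrying that ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ExpressionDiffMatrix, PairAnnotation

__all__ = [
    "InclusionCriteria",
    "enumerate_curve_groups",
    "ordering_label",
    "welch_p_value",
    "period_means",
    "assign_curve_groups",
]


@dataclass(frozen=True)
class InclusionCriteria:
    """Rule admitting a gene to its curve group.

    Exactly one mode is active: ``"alpha"`` (Welch p-value below
    ``alpha``) or ``"top_m"`` (the ``m`` smallest p-values per group).
    """

    mode: str
    alpha: float = 0.01
    m: int = 100

    def __post_init__(self) -> None:
        if self.mode not in ("alpha", "top_m"):
            raise ValueError(f"mode must be 'alpha' or 'top_m'; got {self.mode!r}")
        if self.mode == "alpha" and not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0, 1); got {self.alpha}")
        if self.mode == "top_m" and self.m < 1:
            raise ValueError(f"m must be a positive integer; got {self.m}")

    @classmethod
    def by_alpha(cls, alpha: float = 0.01) -> "InclusionCriteria":
        return cls("alpha", alpha=alpha)

    @classmethod
    def top_m(cls, m: int = 100) -> "InclusionCriteria":
        return cls("top_m", m=m)


def enumerate_curve_groups(n_periods: int) -> list[str]:
    """All T! strict-order labels for T periods, lexicographically sorted."""
    if n_periods < 2:
        raise ValueError(f"need at least 2 time periods; got {n_periods}")
    if n_periods > 9:
        raise ValueError("labels use single digits; at most 9 periods supported")
    digits = "".join(str(d) for d in range(1, n_periods + 1))
    return ["".join(p) for p in permutations(digits)]


def ordering_label(means: Sequence[float]) -> str | None:
    """Curve-group label of a vector of period means (farthest first).

    The digit at position i is the rank (1 = smallest) of the i-th
    mean.  Returns ``None`` when any two means are exactly tied, since
    the groups are defined only for strict orderings.
    """
    m = np.asarray(means, dtype=float)
    if m.ndim != 1 or m.size < 2:
        raise ValueError("need a 1-D vector of at least two period means")
    if np.unique(m).size < m.size:
        return None
    ranks = np.argsort(np.argsort(m)) + 1
    return "".join(str(r) for r in ranks)


def _welch_from_stats(m1, v1, n1, m2, v2, n2):
    """Welch t and two-sided p from summary statistics (vectorized).

    Degenerate zero-variance inputs follow the continuous limit: equal
    means give t = 0, p = 1; unequal means give t = +/-inf, p = 0.
    """
    m1, v1, m2, v2 = (np.asarray(a, dtype=float) for a in (m1, v1, m2, v2))
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    se2 = v1 / n1 + v2 / n2
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    degenerate = se2 == 0
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), np.where(degenerate, 1.0, df))
    p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    return t, p


def welch_p_value(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Welch (unequal-variance) two-sample t-test p-value.

    Requires at least two observations per sample.  When both samples
    have zero variance the p-value is 1 for equal means and 0 for
    unequal means (the continuous limit).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Welch test requires at least two observations per sample")
    _, p = _welch_from_stats(
        a.mean(), a.var(ddof=1), a.size, b.mean(), b.var(ddof=1), b.size
    )
    return float(p)


class _StratumAssigner:
    """Vectorized curve-group assignment for one stratum's pair columns.

    Built once from the stratum's (genes x pairs) values; each call to
    :meth:`assign` takes a 0-based period index per pair, so permuting
    time labels inside a resampling loop costs only one group-stats
    pass.  ``values`` and its square are cached across calls.
    """

    def __init__(self, values: np.ndarray, n_periods: int, gene_ids: Sequence[str] | None = None):
        self.x = np.asarray(values, dtype=float)
        self.x2 = self.x**2
        self.n_periods = int(n_periods)
        self.labels = enumerate_curve_groups(self.n_periods)
        # Integer code of each lexicographic label, for rank -> label lookup.
        base = self.n_periods + 1
        codes = []
        for lab in self.labels:
            code = 0
            for ch in lab:
                code = code * base + int(ch)
            codes.append(code)
        self._label_codes = np.asarray(codes)  # already sorted (labels lexicographic)
        if gene_ids is not None:
            # Rank of each gene id in lexicographic order, for deterministic
            # tie-breaking in top-m selection.
            order = np.argsort(np.asarray(gene_ids, dtype=object), kind="stable")
            lex = np.empty(len(order), dtype=np.intp)
            lex[order] = np.arange(len(order))
            self.lex_rank = lex
        else:
            self.lex_rank = np.arange(self.x.shape[0])

    def period_stats(self, period_idx: np.ndarray):
        """Per-gene per-period (mean, sample variance) and per-period counts."""
        T = self.n_periods
        counts = np.bincount(period_idx, minlength=T).astype(float)
        if np.any(counts < 2):
            t_bad = int(np.argmin(counts)) + 1
            raise ValueError(
                f"time period {t_bad} has {int(counts.min())} pair(s); "
                "each period needs at least 2 pairs in the stratum"
            )
        onehot = np.zeros((len(period_idx), T))
        onehot[np.arange(len(period_idx)), period_idx] = 1.0
        s1 = self.x @ onehot
        s2 = self.x2 @ onehot
        mean = s1 / counts
        var = (s2 - s1 * mean) / (counts - 1)
        np.maximum(var, 0.0, out=var)  # guard tiny negative round-off
        return mean, var, counts

    def assign(self, period_idx: np.ndarray):
        """Label index (-1 = tied means) and Welch p-value per gene.

        The label index refers to :attr:`labels` (lexicographic order).
        """
        mean, var, counts = self.period_stats(period_idx)
        T = self.n_periods
        # Rank of each period mean within its gene (1 = smallest).
        ranks = np.argsort(np.argsort(mean, axis=1, kind="stable"), axis=1) + 1
        srt = np.sort(mean, axis=1)
        tied = (np.diff(srt, axis=1) == 0).any(axis=1)
        # Label reads periods farthest -> nearest, i.e. period T..1.
        base = T + 1
        code = np.zeros(mean.shape[0], dtype=np.int64)
        for t in range(T, 0, -1):
            code = code * base + ranks[:, t - 1]
        label_idx = np.searchsorted(self._label_codes, code).astype(np.intp)
        label_idx[tied] = -1
        i_min = np.argmin(mean, axis=1)
        i_max = np.argmax(mean, axis=1)
        rows = np.arange(mean.shape[0])
        _, p = _welch_from_stats(
            mean[rows, i_min],
            var[rows, i_min],
            counts[i_min],
            mean[rows, i_max],
            var[rows, i_max],
            counts[i_max],
        )
        return label_idx, p

    def members(self, label_idx: np.ndarray, p: np.ndarray, criteria: InclusionCriteria) -> np.ndarray:
        """Boolean membership per gene under the given inclusion criterion."""
        labelled = label_idx >= 0
        if criteria.mode == "alpha":
            return labelled & (p < criteria.alpha)
        member = np.zeros(label_idx.shape[0], dtype=bool)
        order = np.lexsort((self.lex_rank, p, label_idx))
        order = order[labelled[order]]
        lab_sorted = label_idx[order]
        # Rank within each label block; keep the first m of each.
        block_start = np.r_[True, lab_sorted[1:] != lab_sorted[:-1]]
        starts = np.flatnonzero(block_start)
        within = np.arange(len(order)) - np.repeat(starts, np.diff(np.r_[starts, len(order)]))
        member[order[within < criteria.m]] = True
        return member


def _stratum_columns(x: ExpressionDiffMatrix, ann: PairAnnotation, stratum: str):
    strata, periods = ann.aligned(x.pair_ids)
    mask = strata == stratum
    if not mask.any():
        raise ValueError(f"stratum {stratum!r} has no pairs")
    return np.flatnonzero(mask), periods[mask]


def period_means(x: ExpressionDiffMatrix, ann: PairAnnotation, stratum: str) -> pd.DataFrame:
    """Per-gene mean of X over the stratum's pairs, in each time period.

    Returns a genes x periods table with integer period columns 1..T.
    Every period 1..T must contain at least one pair of the stratum.
    """
    cols, periods = _stratum_columns(x, ann, stratum)
    T = ann.n_periods
    out = np.empty((x.n_genes, T))
    for t in range(1, T + 1):
        sel = cols[periods == t]
        if sel.size == 0:
            raise ValueError(f"time period {t} has no pairs in stratum {stratum!r}")
        out[:, t - 1] = x.values[:, sel].mean(axis=1)
    return pd.DataFrame(out, index=pd.Index(x.gene_ids, name="gene_id"), columns=range(1, T + 1))


def assign_curve_groups(
    x: ExpressionDiffMatrix,
    ann: PairAnnotation,
    stratum: str,
    criteria: InclusionCriteria,
) -> pd.DataFrame:
    """Assign every gene its curve-group label, Welch p-value and membership.

    Returns a table with columns ``gene_id``, ``stratum``, ``label``
    (empty string when period means are tied), ``p_value`` and
    ``member`` (0/1 under the given inclusion criterion).
    """
    cols, periods = _stratum_columns(x, ann, stratum)
    T = ann.n_periods
    assigner = _StratumAssigner(x.values[:, cols], T, gene_ids=x.gene_ids)
    label_idx, p = assigner.assign(periods - 1)
    member = assigner.members(label_idx, p, criteria)
    labels = np.asarray(assigner.labels, dtype=object)
    label_col = np.where(label_idx >= 0, labels[np.clip(label_idx, 0, None)], "")
    return pd.DataFrame(
        {
            "gene_id": list(x.gene_ids),
            "stratum": stratum,
            "label": label_col,
            "p_value": p,
            "member": member.astype(int),
        }
    )
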