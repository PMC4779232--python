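"""Within-stratum permutation tests for development over time.

For one stratum, genes are assigned to curve groups under inclusion
criterion 1 (Welch p-value < alpha).  The test statistics are gene
counts: the count in each of the T! curve groups, and their total for
the global test.  The null distribution comes from permuting the
stratum's pairs among time periods, re-running the whole assignment
pipeline for every randomization (the curve groups are redefined
before each null sample).  All seven p-values (global + per group,
for T = 3) share one randomization ensemble, which keeps them
mutually consistent; they are upper-tail, since the alternative is
"more genes in the groups than expected by chance".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curve_groups import InclusionCriteria, _StratumAssigner, _stratum_columns
from .data_model import ExpressionDiffMatrix, PairAnnotation
from .resampling import spawn_rngs

__all__ = ["TrendTestReport", "curve_group_counts", "trend_test_stratum"]


@dataclass(frozen=True)
class TrendTestReport:
    """Observed/expected curve-group gene counts and permutation p-values."""

    stratum: str
    labels: tuple[str, ...]
    observed: tuple[int, ...]
    expected: tuple[float, ...]  # mean count under the permutation null
    p_values: tuple[float, ...]
    global_observed: int
    global_expected: float
    global_p_value: float
    alpha: float
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        if self.global_observed != sum(self.observed):
            raise ValueError("global observed count must equal the sum of per-label counts")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "stratum": self.stratum,
                "curve_group": "global",
                "observed": self.global_observed,
                "expected": self.global_expected,
                "p_value": self.global_p_value,
            }
        ]
        for lab, obs, exp, p in zip(self.labels, self.observed, self.expected, self.p_values):
            rows.append(
                {
                    "stratum": self.stratum,
                    "curve_group": lab,
                    "observed": obs,
                    "expected": exp,
                    "p_value": p,
                }
            )
        df = pd.DataFrame(rows)
        df["alpha"] = self.alpha
        df["n_perm"] = self.n_perm
        df["seed"] = self.seed
        return df


def curve_group_counts(assignments: pd.DataFrame, labels=None):
    """Member-gene count per curve-group label, plus their total.

    ``assignments`` is the table produced by
    :func:`curvegroups.curve_groups.assign_curve_groups` for one
    stratum.  ``labels`` fixes the label universe; by default it is
    inferred from the label length found in the table (all T! labels).
    """
    from .curve_groups import enumerate_curve_groups

    if labels is None:
        present = [lab for lab in assignments["label"] if lab]
        if not present:
            raise ValueError("cannot infer the number of periods from an all-tied table")
        labels = enumerate_curve_groups(len(present[0]))
    members = assignments[assignments["member"].astype(bool)]
    raw = members["label"].value_counts()
    counts = {lab: int(raw.get(lab, 0)) for lab in labels}
    return counts, sum(counts.values())


def _count_members(label_idx: np.ndarray, p: np.ndarray, alpha: float, n_labels: int) -> np.ndarray:
    sel = (label_idx >= 0) & (p < alpha)
    return np.bincount(label_idx[sel], minlength=n_labels)


def trend_test_stratum(
    x: ExpressionDiffMatrix,
    ann: PairAnnotation,
    stratum: str,
    alpha: float = 0.01,
    n_perm: int = 1000,
    seed: int = 0,
) -> TrendTestReport:
    """Global and per-curve-group tests for development over time.

    Returns a :class:`TrendTestReport` whose expected counts are the
    mean counts over the permutation null ensemble and whose p-values
    are upper-tail ``(K + 1)/(N + 1)`` permutation p-values.
    """
    criteria = InclusionCriteria.by_alpha(alpha)
    cols, periods = _stratum_columns(x, ann, stratum)
    T = ann.n_periods
    assigner = _StratumAssigner(x.values[:, cols], T, gene_ids=x.gene_ids)
    period_idx = periods - 1

    label_idx, p = assigner.assign(period_idx)
    observed = _count_members(label_idx, p, alpha, len(assigner.labels))

    null_counts = np.empty((n_perm, len(assigner.labels)), dtype=np.int64)
    for i, rng in enumerate(spawn_rngs(seed, n_perm)):
        perm = rng.permutation(period_idx)
        li, pi = assigner.assign(perm)
        null_counts[i] = _count_members(li, pi, alpha, len(assigner.labels))
    null_totals = null_counts.sum(axis=1)

    k_label = (null_counts >= observed[None, :]).sum(axis=0)
    p_label = (k_label + 1) / (n_perm + 1)
    k_total = int(np.sum(null_totals >= observed.sum()))

    return TrendTestReport(
        stratum=stratum,
        labels=tuple(assigner.labels),
        observed=tuple(int(c) for c in observed),
        expected=tuple(float(e) for e in null_counts.mean(axis=0)),
        p_values=tuple(float(v) for v in p_label),
        global_observed=int(observed.sum()),
        global_expected=float(null_totals.mean()),
        global_p_value=(k_total + 1) / (n_perm + 1),
        alpha=alpha,
        n_perm=n_perm,
        seed=seed,
    )
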