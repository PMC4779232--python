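"""Randomization schemes and the permutation p-value.

Both null models permute design labels only; every pair's vector of
gene values stays intact, so the inter-gene correlation structure of
the data is preserved under the null:

* time-label permutation (development-over-time tests): the time
  periods of one stratum's pairs are shuffled among those pairs;
* stratum-label permutation (two-strata tests): within each time
  period, the stratum labels of the two compared strata's pairs are
  shuffled among those pairs.

The permutation p-value is ``(K + 1) / (N + 1)`` with K the number of
null statistics at least as extreme as the observed one; ties count
as extreme, which keeps the test conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import PairAnnotation

__all__ = [
    "PermutationTestResult",
    "permutation_p_value",
    "permute_time_labels",
    "permute_stratum_labels",
    "spawn_rngs",
]


@dataclass(frozen=True)
class PermutationTestResult:
    """Observed statistic, its permutation null sample, and the p-value."""

    observed: float
    null_statistics: np.ndarray
    k: int
    n: int
    p_value: float
    seed: int | None = None

    def __post_init__(self) -> None:
        nulls = np.asarray(self.null_statistics, dtype=float)
        object.__setattr__(self, "null_statistics", nulls)
        if self.n != nulls.size or not (0 <= self.k <= self.n):
            raise ValueError("inconsistent permutation counts")
        expected = (self.k + 1) / (self.n + 1)
        if abs(self.p_value - expected) > 1e-12:
            raise ValueError("p_value must equal (K + 1) / (N + 1)")


def permutation_p_value(
    observed: float,
    nulls,
    direction: str = "upper",
    seed: int | None = None,
) -> PermutationTestResult:
    """p = (K + 1)/(N + 1) with K the count of equal-or-more-extreme nulls.

    ``direction="upper"`` counts ``null >= observed``;
    ``direction="two_sided"`` counts ``|null| >= |observed|``.
    """
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size == 0:
        raise ValueError("need at least one null statistic")
    if direction == "upper":
        k = int(np.sum(nulls >= observed))
    elif direction == "two_sided":
        k = int(np.sum(np.abs(nulls) >= abs(observed)))
    else:
        raise ValueError(f"direction must be 'upper' or 'two_sided'; got {direction!r}")
    n = int(nulls.size)
    return PermutationTestResult(float(observed), nulls, k, n, (k + 1) / (n + 1), seed)


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """n independent generators derived from one master seed.

    Randomization i always uses stream i, so results do not depend on
    execution order, and increasing the number of randomizations
    extends the ensemble instead of reshuffling it.
    """
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def permute_time_labels(ann: PairAnnotation, stratum: str, seed) -> PairAnnotation:
    """Shuffle one stratum's pairs among its time periods.

    Per-period pair counts within the stratum are preserved; pairs of
    other strata are untouched.  ``seed`` may be an integer or a
    ``numpy.random.Generator``.
    """
    if stratum not in ann.strata:
        raise ValueError(f"unknown stratum {stratum!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = [i for i, s in enumerate(ann.stratum) if s == stratum]
    periods = np.array([ann.time_period[i] for i in idx])
    shuffled = rng.permutation(periods)
    return ann.with_time_periods(
        {ann.pair_ids[i]: int(t) for i, t in zip(idx, shuffled)}
    )


def permute_stratum_labels(ann: PairAnnotation, strata: tuple[str, str], seed) -> PairAnnotation:
    """Shuffle two strata's pairs between the strata, within each period.

    Per-period per-stratum counts are preserved; time periods never
    change under this scheme.
    """
    s1, s2 = strata
    known = set(ann.strata)
    for s in (s1, s2):
        if s not in known:
            raise ValueError(f"unknown stratum {s!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    replacement: dict[str, str] = {}
    for t in sorted(set(ann.time_period)):
        idx = [
            i
            for i, (s, tp) in enumerate(zip(ann.stratum, ann.time_period))
            if tp == t and s in (s1, s2)
        ]
        labels = np.array([ann.stratum[i] for i in idx], dtype=object)
        shuffled = rng.permutation(labels)
        replacement.update(
            {ann.pair_ids[i]: str(lab) for i, lab in zip(idx, shuffled)}
        )
    return ann.with_strata(replacement)
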