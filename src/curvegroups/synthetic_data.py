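"""Synthetic paired log2-difference data with planted trajectories.

The generator emulates the statistical structure the curve-group
method assumes:

* per-gene Gaussian noise around a per-period mean,
* inter-gene correlation within a pair, induced by a pair-level latent
  factor with per-gene loadings (all genes of a pair share one draw of
  the factor),
* planted trajectories: a signal gene with curve-group label ``c``
  has period mean ``delta * (rank of the period in c - (T+1)/2)``,
  so consecutive rank levels are ``delta`` apart and the means are
  centered (the time effect carries no marginal shift).

Model per gene g and pair p (stratum s, period t):

    X[g, p] = mu[g, t, s] + b[g] * f[p] + eps[g, p]

with ``f[p] ~ N(0, 1)``, ``b[g] ~ N(0, factor_loading_sd^2)`` and
``eps ~ N(0, noise_sd^2)``.  Background genes have ``mu = 0`` in every
period.  An optional per-stratum constant shift of the signal genes
supports simulations of between-strata expression differences.

:func:`estimate_error_rates` is a small Monte-Carlo harness measuring
the type-I error (``effect_size = 0``) or power of any of the
package's tests across a grid of configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import ExpressionDiffMatrix, PairAnnotation

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "generate_dataset",
    "estimate_error_rates",
    "trend_global_pvalue",
    "z_test_pvalue",
    "lk_test_pvalue",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    Attributes
    ----------
    n_genes : int
        Total number of genes (signal + background).
    strata_design : mapping stratum -> {period: n_pairs}
        Number of case-control pairs per stratum and time period; every
        stratum must cover periods 1..T with at least 2 pairs each.
    n_signal : int
        Number of signal genes (the first ``n_signal`` gene ids).
    signal_label : str
        Curve-group label planted in every signal gene (ignored when
        ``signal_labels`` gives an explicit per-gene mapping).
    signal_labels : mapping gene_id -> label, optional
        Explicit trajectory pattern per signal gene.
    effect_size : float
        Spacing ``delta`` (log2 units) between consecutive planted rank
        levels; 0 means no time structure anywhere.
    noise_sd : float
        Per-gene Gaussian noise standard deviation (log2 units).
    factor_loading_sd : float
        Standard deviation of the per-gene loadings on the pair-level
        latent factor; 0 removes inter-gene correlation.
    signal_strata : tuple of str, optional
        Strata receiving the planted trajectory (default: all).
    stratum_shift : mapping stratum -> float, optional
        Constant (period-independent) shift added to the signal genes
        of a stratum, for between-strata difference scenarios.
    seed : int
        Master seed; the dataset is a pure function of the config.
    """

    n_genes: int
    strata_design: Mapping[str, Mapping[int, int]]
    n_signal: int = 0
    signal_label: str = "123"
    signal_labels: Mapping[str, str] | None = None
    effect_size: float = 0.0
    noise_sd: float = 0.5
    factor_loading_sd: float = 0.2
    signal_strata: tuple[str, ...] | None = None
    stratum_shift: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not (0 <= self.n_signal <= self.n_genes):
            raise ValueError("n_signal must be in 0..n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.factor_loading_sd < 0:
            raise ValueError("factor_loading_sd must be non-negative")
        if not self.strata_design:
            raise ValueError("strata_design must define at least one stratum")
        periods = None
        for s, design in self.strata_design.items():
            ts = sorted(int(t) for t in design)
            if periods is None:
                periods = ts
            elif ts != periods:
                raise ValueError("all strata must cover the same set of periods")
            for t, n in design.items():
                if int(n) < 2:
                    raise ValueError(
                        f"stratum {s!r}, period {t}: need at least 2 pairs, got {n}"
                    )
        if periods != list(range(1, len(periods) + 1)):
            raise ValueError("periods must be consecutive integers starting at 1")

    @property
    def n_periods(self) -> int:
        return len(next(iter(self.strata_design.values())))

    @property
    def gene_ids(self) -> tuple[str, ...]:
        width = max(4, len(str(self.n_genes)))
        return tuple(f"g{i:0{width}d}" for i in range(1, self.n_genes + 1))

    def resolved_signal_labels(self) -> dict[str, str]:
        """Label per signal gene, defaulting to ``signal_label`` for all."""
        genes = self.gene_ids
        if self.signal_labels is not None:
            mapping = {str(g): str(lab) for g, lab in self.signal_labels.items()}
            unknown = set(mapping) - set(genes)
            if unknown:
                raise ValueError(f"signal_labels refers to unknown genes: {sorted(unknown)}")
            return mapping
        return {g: self.signal_label for g in genes[: self.n_signal]}


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a synthetic dataset: who is signal, and how."""

    table: pd.DataFrame  # gene_id, is_signal, label, mu_<t> per period

    @property
    def signal_genes(self) -> tuple[str, ...]:
        sig = self.table[self.table["is_signal"] == 1]
        return tuple(sig["gene_id"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _label_period_means(label: str, n_periods: int, delta: float) -> np.ndarray:
    """Planted mean per period 1..T for a label; centered rank levels."""
    if len(label) != n_periods or sorted(label) != [str(d) for d in range(1, n_periods + 1)]:
        raise ValueError(f"invalid curve-group label {label!r} for {n_periods} periods")
    mu = np.empty(n_periods)
    for pos, ch in enumerate(label):  # position 0 = period T (farthest)
        t = n_periods - pos
        mu[t - 1] = delta * (int(ch) - (n_periods + 1) / 2.0)
    return mu


def generate_dataset(
    cfg: SimulationConfig,
) -> tuple[ExpressionDiffMatrix, PairAnnotation, PlantedTruth]:
    """Draw one dataset (matrix, annotation, truth) from the config."""
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    T = cfg.n_periods
    genes = cfg.gene_ids
    signal = cfg.resolved_signal_labels()

    pair_ids: list[str] = []
    strata: list[str] = []
    periods: list[int] = []
    for s in cfg.strata_design:
        for t in range(1, T + 1):
            for _ in range(int(cfg.strata_design[s][t])):
                pair_ids.append(f"p{len(pair_ids) + 1:04d}")
                strata.append(s)
                periods.append(t)
    ann = PairAnnotation(tuple(pair_ids), tuple(strata), tuple(periods))
    n_pairs = len(pair_ids)

    # Planted means per gene x pair.
    mu = np.zeros((cfg.n_genes, n_pairs))
    gene_index = {g: i for i, g in enumerate(genes)}
    period_arr = np.asarray(periods, dtype=np.intp)
    strata_arr = np.asarray(strata, dtype=object)
    signal_strata = (
        set(cfg.signal_strata) if cfg.signal_strata is not None else set(cfg.strata_design)
    )
    rows_labels = []
    for g in genes:
        lab = signal.get(g)
        if lab is None:
            rows_labels.append({"gene_id": g, "is_signal": 0, "label": ""})
            continue
        mu_t = _label_period_means(lab, T, cfg.effect_size)
        row = mu_t[period_arr - 1] * np.isin(strata_arr, list(signal_strata))
        if cfg.stratum_shift:
            for s, shift in cfg.stratum_shift.items():
                row = row + float(shift) * (strata_arr == s)
        mu[gene_index[g]] = row
        rows_labels.append({"gene_id": g, "is_signal": 1, "label": lab})

    loadings = rng.normal(0.0, cfg.factor_loading_sd, size=cfg.n_genes)
    factors = rng.normal(0.0, 1.0, size=n_pairs)
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_pairs))
    values = mu + np.outer(loadings, factors) + noise
    x = ExpressionDiffMatrix(genes, tuple(pair_ids), values)

    truth = pd.DataFrame(rows_labels)
    for t in range(1, T + 1):
        truth[f"mu_{t}"] = [
            _label_period_means(signal[g], T, cfg.effect_size)[t - 1] if g in signal else 0.0
            for g in genes
        ]
    return x, ann, PlantedTruth(truth)


# ---------------------------------------------------------------------------
# Monte-Carlo harness
# ---------------------------------------------------------------------------


def _rep_seeds(master_seed: int, rep: int) -> tuple[int, int]:
    """Deterministic (data seed, test seed) below 2**31 for replicate rep."""
    ss = np.random.SeedSequence([int(master_seed), int(rep)])
    a, b = ss.generate_state(2)
    return int(a % 2**31), int(b % 2**31)


def estimate_error_rates(
    cfg_grid: Sequence[SimulationConfig],
    test: Callable[[ExpressionDiffMatrix, PairAnnotation, int], float],
    n_reps: int,
    level: float = 0.05,
) -> pd.DataFrame:
    """Rejection rate of a test over replicated synthetic datasets.

    ``test(x, ann, seed) -> p`` runs the test of interest with the
    given seed for its permutations.  For each config, replicate r uses
    data seed and test seed derived from ``cfg.seed`` and r, so the
    whole table is reproducible.  The standard error is the binomial
    ``sqrt(rate * (1 - rate) / n_reps)``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    rows = []
    for ci, cfg in enumerate(cfg_grid):
        rejections = 0
        for rep in range(n_reps):
            data_seed, test_seed = _rep_seeds(cfg.seed, rep)
            x, ann, _ = generate_dataset(replace(cfg, seed=data_seed))
            p = test(x, ann, test_seed)
            rejections += p <= level
        rate = rejections / n_reps
        rows.append(
            {
                "config": ci,
                "effect_size": cfg.effect_size,
                "n_genes": cfg.n_genes,
                "n_signal": cfg.n_signal,
                "level": level,
                "n_reps": n_reps,
                "rejection_rate": rate,
                "se": float(np.sqrt(rate * (1 - rate) / n_reps)),
            }
        )
    return pd.DataFrame(rows)


def trend_global_pvalue(stratum: str, alpha: float = 0.01, n_perm: int = 199):
    """Test factory: global development-over-time p-value in one stratum."""
    from .trend_test import trend_test_stratum

    def run(x: ExpressionDiffMatrix, ann: PairAnnotation, seed: int) -> float:
        return trend_test_stratum(x, ann, stratum, alpha=alpha, n_perm=n_perm, seed=seed).global_p_value

    return run


def z_test_pvalue(
    label: str,
    selection_stratum: str,
    strata: tuple[str, str],
    scope="all",
    m: int = 100,
    n_perm: int = 199,
):
    """Test factory: curve-group-variable comparison of two strata."""
    from .strata_test import z_strata_test

    def run(x: ExpressionDiffMatrix, ann: PairAnnotation, seed: int) -> float:
        return z_strata_test(
            x, ann, label, selection_stratum, strata, scope=scope, m=m, n_perm=n_perm, seed=seed
        ).p_value

    return run


def lk_test_pvalue(
    strata: tuple[str, str],
    k: int,
    weights="equal",
    scope="all",
    n_perm: int = 199,
):
    """Test factory: weighted t-statistic sum L_k comparison at one k."""
    from .strata_test import lk_test

    def run(x: ExpressionDiffMatrix, ann: PairAnnotation, seed: int) -> float:
        return lk_test(
            x, ann, strata, weights=weights, k_grid=[k], scope=scope, n_perm=n_perm, seed=seed
        ).p_values[0]

    return run
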