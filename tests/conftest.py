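import numpy as np
import pytest

from curvegroups import ExpressionDiffMatrix, PairAnnotation, SimulationConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_matrix():
    """4 genes x 6 pairs, hand-set values."""
    values = np.array(
        [
            [0.1, 0.2, 0.5, 0.6, 1.0, 1.1],
            [1.0, 0.9, 0.5, 0.4, 0.1, 0.0],
            [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            [0.3, -0.3, 0.8, -0.8, 0.2, -0.2],
        ]
    )
    return ExpressionDiffMatrix(
        ("gA", "gB", "gC", "gD"), ("p1", "p2", "p3", "p4", "p5", "p6"), values
    )


@pytest.fixture
def tiny_ann():
    """One stratum, three periods, two pairs each (farthest first)."""
    return PairAnnotation(
        ("p1", "p2", "p3", "p4", "p5", "p6"),
        ("S",) * 6,
        (3, 3, 2, 2, 1, 1),
    )


@pytest.fixture
def null_two_strata():
    """No time structure, no strata difference; moderate size."""
    cfg = SimulationConfig(
        n_genes=150,
        strata_design={"A": {1: 8, 2: 8, 3: 8}, "B": {1: 8, 2: 8, 3: 8}},
        seed=42,
    )
    return generate_dataset(cfg)


def random_dataset(rng, n_genes=50, pairs_per_period=10, n_periods=3, strata=("S",)):
    """Unstructured dataset with explicit ids, for oracle comparisons."""
    pair_ids, strat, periods = [], [], []
    for s in strata:
        for t in range(1, n_periods + 1):
            for _ in range(pairs_per_period):
                pair_ids.append(f"p{len(pair_ids):03d}")
                strat.append(s)
                periods.append(t)
    genes = tuple(f"g{i:03d}" for i in range(n_genes))
    x = ExpressionDiffMatrix(
        genes, tuple(pair_ids), rng.normal(size=(n_genes, len(pair_ids)))
    )
    return x, PairAnnotation(tuple(pair_ids), tuple(strat), tuple(periods))
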