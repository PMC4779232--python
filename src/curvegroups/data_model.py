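"""Domain types, TSV input/output, and generic preprocessing steps.

The analysis unit throughout the package is the matched case-control
*pair*.  For gene ``g`` and pair ``p`` the quantity analysed is the
log2-expression difference ``X[g, p] = log2(case) - log2(control)``.
Each pair belongs to one stratum (a clinical subgroup) and one time
period ``t`` in ``1..T``, where ``t = 1`` is the period nearest
diagnosis.

Preprocessing offered here covers the generic steps that produce such a
matrix from raw intensities: quantile normalization on the original
scale, a detection ("presence") filter, collapsing multiple probes per
gene to a single probe, and the paired log2 difference itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDiffMatrix",
    "IntensityMatrix",
    "PairAnnotation",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_intensity_matrix",
    "write_intensity_matrix",
    "read_pair_annotation",
    "write_pair_annotation",
    "compute_log2_differences",
    "quantile_normalize",
    "presence_threshold",
    "filter_by_presence",
    "collapse_probes_to_genes",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class ExpressionDiffMatrix:
    """Genes x pairs matrix of paired log2 expression differences.

    Attributes
    ----------
    gene_ids : tuple of str
        Unique gene identifiers, one per row.
    pair_ids : tuple of str
        Unique case-control pair identifiers, one per column.
    values : ndarray of float, shape (n_genes, n_pairs)
        Finite log2 differences; missing values are not permitted
        because every downstream statistic assumes a complete matrix.
    """

    gene_ids: tuple[str, ...]
    pair_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "pair_ids", tuple(str(p) for p in self.pair_ids))
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.pair_ids, "pair id")
        if values.ndim != 2 or values.shape != (len(self.gene_ids), len(self.pair_ids)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.pair_ids)} pairs"
            )
        if not np.all(np.isfinite(values)):
            g, p = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value for gene {self.gene_ids[g]!r}, pair {self.pair_ids[p]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(),
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=list(self.pair_ids),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionDiffMatrix":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)), df.to_numpy(dtype=float))

    def pair_index(self, pair_ids: Iterable[str]) -> np.ndarray:
        """Column indices of the given pair ids, in the given order."""
        lookup = {p: i for i, p in enumerate(self.pair_ids)}
        try:
            return np.array([lookup[p] for p in pair_ids], dtype=np.intp)
        except KeyError as exc:
            raise ValueError(f"pair id {exc.args[0]!r} not present in matrix") from None


@dataclass(frozen=True)
class IntensityMatrix:
    """Features x samples matrix of strictly positive raw-scale intensities."""

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        _check_unique(self.feature_ids, "feature id")
        _check_unique(self.sample_ids, "sample id")
        if values.ndim != 2 or values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("values shape inconsistent with feature/sample ids")
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            f, s = np.argwhere(~(np.isfinite(values) & (values > 0)))[0]
            raise ValueError(
                f"intensity must be a finite positive number; offending entry at "
                f"feature {self.feature_ids[f]!r}, sample {self.sample_ids[s]!r}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(),
            index=pd.Index(self.feature_ids, name="feature_id"),
            columns=list(self.sample_ids),
        )


@dataclass(frozen=True)
class PairAnnotation:
    """Per-pair design information: stratum label and time period.

    ``time_period`` is an integer in ``1..T`` with 1 the period closest
    to diagnosis; larger values are further back in time.
    """

    pair_ids: tuple[str, ...]
    stratum: tuple[str, ...]
    time_period: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair_ids", tuple(str(p) for p in self.pair_ids))
        object.__setattr__(self, "stratum", tuple(str(s) for s in self.stratum))
        object.__setattr__(self, "time_period", tuple(int(t) for t in self.time_period))
        _check_unique(self.pair_ids, "pair id")
        if not (len(self.pair_ids) == len(self.stratum) == len(self.time_period)):
            raise ValueError("pair_ids, stratum and time_period must have equal length")
        for p, s, t in zip(self.pair_ids, self.stratum, self.time_period):
            if t < 1:
                raise ValueError(f"time_period must be >= 1; pair {p!r} has {t}")
            if not s:
                raise ValueError(f"empty stratum label for pair {p!r}")

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    @property
    def n_periods(self) -> int:
        return max(self.time_period)

    @property
    def strata(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.stratum:
            seen.setdefault(s)
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pair_id": list(self.pair_ids),
                "stratum": list(self.stratum),
                "time_period": list(self.time_period),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PairAnnotation":
        required = {"pair_id", "stratum", "time_period"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        return cls(
            tuple(map(str, df["pair_id"])),
            tuple(map(str, df["stratum"])),
            tuple(int(t) for t in df["time_period"]),
        )

    def aligned(self, pair_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Stratum and period arrays aligned to the given pair order.

        Every requested pair must be annotated exactly once.
        """
        lookup = {p: i for i, p in enumerate(self.pair_ids)}
        idx = []
        for p in pair_ids:
            if p not in lookup:
                raise ValueError(f"pair {p!r} has no annotation")
            idx.append(lookup[p])
        strata = np.array([self.stratum[i] for i in idx], dtype=object)
        periods = np.array([self.time_period[i] for i in idx], dtype=np.intp)
        return strata, periods

    def with_time_periods(self, periods: Mapping[str, int]) -> "PairAnnotation":
        """Copy with the time periods of selected pairs replaced."""
        new = [periods.get(p, t) for p, t in zip(self.pair_ids, self.time_period)]
        return PairAnnotation(self.pair_ids, self.stratum, tuple(new))

    def with_strata(self, strata: Mapping[str, str]) -> "PairAnnotation":
        """Copy with the stratum labels of selected pairs replaced."""
        new = [strata.get(p, s) for p, s in zip(self.pair_ids, self.stratum)]
        return PairAnnotation(self.pair_ids, tuple(new), self.time_period)


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------


def _read_numeric_table(path, sep: str, index_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0, dtype={0: str}, float_precision="round_trip")
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate {index_name}: {dup!r}")
    cols = pd.Index(map(str, df.columns))
    if cols.has_duplicates:
        dup = cols[cols.duplicated()][0]
        raise ValueError(f"duplicate column id: {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-numeric or missing value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    numeric.columns = cols
    return numeric


def read_expression_matrix(path, sep: str = "\t") -> ExpressionDiffMatrix:
    """Read a genes x pairs TSV: header row of pair ids, first column gene ids."""
    df = _read_numeric_table(path, sep, "gene id")
    return ExpressionDiffMatrix.from_frame(df)


def write_expression_matrix(x: ExpressionDiffMatrix, path, sep: str = "\t") -> None:
    # repr gives the shortest decimal that round-trips to the same float
    x.to_frame().to_csv(path, sep=sep, index_label="gene_id", float_format=lambda v: repr(float(v)))


def read_intensity_matrix(path, sep: str = "\t") -> IntensityMatrix:
    df = _read_numeric_table(path, sep, "feature id")
    return IntensityMatrix(tuple(df.index), tuple(df.columns), df.to_numpy(dtype=float))


def write_intensity_matrix(m: IntensityMatrix, path, sep: str = "\t") -> None:
    m.to_frame().to_csv(path, sep=sep, index_label="feature_id", float_format=lambda v: repr(float(v)))


def read_pair_annotation(path, sep: str = "\t") -> PairAnnotation:
    df = pd.read_csv(path, sep=sep, dtype={"pair_id": str, "stratum": str})
    return PairAnnotation.from_frame(df)


def write_pair_annotation(ann: PairAnnotation, path, sep: str = "\t") -> None:
    ann.to_frame().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------


def compute_log2_differences(
    cases: IntensityMatrix,
    controls: IntensityMatrix,
    pairing: Sequence[tuple[str, str, str]],
) -> ExpressionDiffMatrix:
    """Paired log2 differences ``log2(case) - log2(control)``.

    Parameters
    ----------
    pairing : sequence of (case_sample, control_sample, pair_id)
        Which case column is matched with which control column, and the
        identifier of the resulting pair.
    """
    if cases.feature_ids != controls.feature_ids:
        raise ValueError("case and control matrices must share identical feature ids")
    case_lookup = {s: i for i, s in enumerate(cases.sample_ids)}
    control_lookup = {s: i for i, s in enumerate(controls.sample_ids)}
    cols = []
    pair_ids = []
    for case_sample, control_sample, pair_id in pairing:
        if case_sample not in case_lookup:
            raise ValueError(f"unknown case sample {case_sample!r} in pairing")
        if control_sample not in control_lookup:
            raise ValueError(f"unknown control sample {control_sample!r} in pairing")
        cols.append(
            np.log2(cases.values[:, case_lookup[case_sample]])
            - np.log2(controls.values[:, control_lookup[control_sample]])
        )
        pair_ids.append(pair_id)
    if not cols:
        raise ValueError("empty pairing")
    return ExpressionDiffMatrix(cases.feature_ids, tuple(pair_ids), np.column_stack(cols))


def quantile_normalize(m: IntensityMatrix) -> IntensityMatrix:
    """Quantile normalization on the original scale.

    Every column is forced onto the common reference distribution
    obtained by averaging the column-sorted matrix across columns.
    Within-column rank order is preserved; tied values within a column
    all receive the mean of the reference values spanning their ranks.
    """
    vals = m.values
    if vals.size == 0:
        raise ValueError("cannot normalize an empty matrix")
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    n = vals.shape[0]
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        # Boundaries of runs of tied values in the sorted column.
        starts = np.flatnonzero(np.r_[True, sorted_col[1:] != sorted_col[:-1]])
        run_sums = np.add.reduceat(ref, starts)
        run_lengths = np.diff(np.r_[starts, n])
        assigned = np.repeat(run_sums / run_lengths, run_lengths)
        out[order, j] = assigned
    return IntensityMatrix(m.feature_ids, m.sample_ids, out)


def presence_threshold(n_samples: int, min_fraction: float) -> int:
    """Minimum number of detecting samples implied by a presence fraction.

    Uses a ceiling so that, e.g., 1 % of 882 samples requires detection
    in at least 9 of them.
    """
    if not (0 < min_fraction <= 1):
        raise ValueError(f"min_fraction must be in (0, 1]; got {min_fraction}")
    if n_samples < 1:
        raise ValueError("need at least one sample")
    # Small slack guards against ceil(k/n * n) overshooting to k+1.
    return int(math.ceil(min_fraction * n_samples - 1e-9))


def filter_by_presence(detected: pd.DataFrame, min_fraction: float) -> list[str]:
    """Feature ids detected in at least ``ceil(min_fraction * n_samples)`` samples.

    ``detected`` is a features x samples table of truthy/falsy detection
    calls (index = feature ids).  Ids are returned in input order.
    """
    required = presence_threshold(detected.shape[1], min_fraction)
    counts = detected.astype(bool).to_numpy().sum(axis=1)
    return [str(f) for f, c in zip(detected.index, counts) if c >= required]


def collapse_probes_to_genes(m, probe_to_gene: Mapping[str, str]):
    """Keep one probe per gene: the probe with the highest mean value.

    Probes without a mapping are dropped.  Ties on the mean are broken
    by the lexicographically smallest probe id.  Works on either an
    :class:`IntensityMatrix` (rows = probes) or an
    :class:`ExpressionDiffMatrix`; the returned object is of the same
    type with rows keyed by gene id.
    """
    if not probe_to_gene:
        raise ValueError("probe_to_gene mapping is empty")
    if isinstance(m, IntensityMatrix):
        row_ids = m.feature_ids
    elif isinstance(m, ExpressionDiffMatrix):
        row_ids = m.gene_ids
    else:
        raise TypeError(f"unsupported matrix type {type(m).__name__}")
    row_means = m.values.mean(axis=1)
    best: dict[str, tuple[float, str, int]] = {}
    for i, probe in enumerate(row_ids):
        gene = probe_to_gene.get(probe)
        if gene is None:
            continue
        key = (-row_means[i], probe)
        if gene not in best or key < (best[gene][0], best[gene][1]):
            best[gene] = (-row_means[i], probe, i)
    if not best:
        raise ValueError("no probe in the matrix is covered by the mapping")
    # Preserve input row order of the selected probes.
    chosen = sorted(best.items(), key=lambda kv: kv[1][2])
    genes = tuple(g for g, _ in chosen)
    rows = np.array([i for _, (_, _, i) in chosen], dtype=np.intp)
    if isinstance(m, IntensityMatrix):
        return IntensityMatrix(genes, m.sample_ids, m.values[rows])
    return ExpressionDiffMatrix(genes, m.pair_ids, m.values[rows])
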