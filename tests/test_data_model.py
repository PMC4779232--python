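import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from curvegroups import (
    ExpressionDiffMatrix,
    IntensityMatrix,
    collapse_probes_to_genes,
    compute_log2_differences,
    filter_by_presence,
    presence_threshold,
    quantile_normalize,
    read_expression_matrix,
    write_expression_matrix,
)


class TestExpressionMatrixIO:
    def test_parse_well_formed(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("gene_id\tp1\tp2\tp3\ngA\t0.5\t-1.25\t2.0\ngB\t0\t3.5\t-0.125\n")
        x = read_expression_matrix(p)
        assert x.gene_ids == ("gA", "gB")
        assert x.pair_ids == ("p1", "p2", "p3")
        np.testing.assert_array_equal(x.values, [[0.5, -1.25, 2.0], [0.0, 3.5, -0.125]])

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("gene_id\tp1\ngA\t1\ngA\t2\n")
        with pytest.raises(ValueError, match="gA"):
            read_expression_matrix(p)

    def test_missing_cell_located(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("gene_id\tp1\tp2\ngA\t1\t2\ngB\t\t4\n")
        with pytest.raises(ValueError, match="gB.*p1"):
            read_expression_matrix(p)

    def test_roundtrip_full_precision(self, tmp_path, rng):
        x = ExpressionDiffMatrix(
            ("g1", "g2", "g3"), ("a", "b"), rng.normal(size=(3, 2)) * 1e3
        )
        p = tmp_path / "x.tsv"
        write_expression_matrix(x, p)
        back = read_expression_matrix(p)
        np.testing.assert_array_equal(back.values, x.values)
        # Canonical files round-trip byte-identically through write(read(f)).
        p2 = tmp_path / "x2.tsv"
        write_expression_matrix(back, p2)
        assert p.read_bytes() == p2.read_bytes()

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            ExpressionDiffMatrix(("g",), ("p",), np.array([[np.nan]]))


class TestLog2Differences:
    def _pairing(self):
        cases = IntensityMatrix(("g",), ("c1",), np.array([[8.0]]))
        controls = IntensityMatrix(("g",), ("k1",), np.array([[2.0]]))
        return cases, controls

    def test_ratio_of_8_to_2_gives_2(self):
        cases, controls = self._pairing()
        x = compute_log2_differences(cases, controls, [("c1", "k1", "p1")])
        assert x.values[0, 0] == pytest.approx(2.0)

    def test_equal_intensities_give_zero(self):
        m = IntensityMatrix(("g",), ("s",), np.array([[5.0]]))
        x = compute_log2_differences(m, m, [("s", "s", "p1")])
        assert x.values[0, 0] == 0.0

    def test_nonpositive_intensity_rejected_at_construction(self):
        with pytest.raises(ValueError, match="positive"):
            IntensityMatrix(("g",), ("s",), np.array([[0.0]]))

    def test_unknown_sample_in_pairing(self):
        cases, controls = self._pairing()
        with pytest.raises(ValueError, match="nope"):
            compute_log2_differences(cases, controls, [("nope", "k1", "p1")])

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetric_under_case_control_swap(self, seed):
        r = np.random.default_rng(seed)
        vals_a = np.exp(r.normal(size=(4, 3)))
        vals_b = np.exp(r.normal(size=(4, 3)))
        genes = ("g1", "g2", "g3", "g4")
        a = IntensityMatrix(genes, ("s1", "s2", "s3"), vals_a)
        b = IntensityMatrix(genes, ("s1", "s2", "s3"), vals_b)
        pairing = [(f"s{i}", f"s{i}", f"p{i}") for i in (1, 2, 3)]
        fwd = compute_log2_differences(a, b, pairing)
        rev = compute_log2_differences(b, a, pairing)
        np.testing.assert_allclose(fwd.values, -rev.values, atol=1e-12)


class TestQuantileNormalize:
    def test_two_columns_forced_to_common_reference(self):
        m = IntensityMatrix(
            ("f1", "f2", "f3"), ("s1", "s2"), np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
        )
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_single_column_unchanged(self):
        m = IntensityMatrix(("f1", "f2"), ("s1",), np.array([[3.0], [1.0]]))
        np.testing.assert_allclose(quantile_normalize(m).values, m.values)

    def test_tied_values_share_mean_of_reference_over_rank_span(self):
        # Hand computation: sorted columns [1,1,3] and [2,4,6] give
        # reference (1.5, 2.5, 4.5); the tie in column 1 spans ranks
        # 1-2, so both tied entries get (1.5 + 2.5)/2 = 2.
        m = IntensityMatrix(
            ("f1", "f2", "f3"), ("s1", "s2"), np.array([[1.0, 2.0], [1.0, 4.0], [3.0, 6.0]])
        )
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, [[2.0, 1.5], [2.0, 2.5], [4.5, 4.5]])

    def test_idempotent_on_tie_free_input(self, rng):
        m = IntensityMatrix(
            tuple(f"f{i}" for i in range(10)),
            ("a", "b", "c"),
            np.exp(rng.normal(size=(10, 3))),
        )
        once = quantile_normalize(m)
        twice = quantile_normalize(once)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_preserves_within_column_rank_order(self, rng):
        vals = np.exp(rng.normal(size=(12, 4)))
        m = IntensityMatrix(tuple(f"f{i}" for i in range(12)), tuple("abcd"), vals)
        out = quantile_normalize(m)
        for j in range(4):
            np.testing.assert_array_equal(
                np.argsort(vals[:, j], kind="stable"), np.argsort(out.values[:, j], kind="stable")
            )

    def test_matches_limma_reference_implementation(self, tmp_path, rng):
        """Independent oracle: limma::normalizeQuantiles on a tie-free matrix."""
        vals = np.round(np.exp(rng.normal(size=(8, 4))), 6)
        m = IntensityMatrix(tuple(f"f{i}" for i in range(8)), tuple("abcd"), vals)
        inp = tmp_path / "m.tsv"
        pd.DataFrame(vals).to_csv(inp, sep="\t", index=False, header=False)
        script = tmp_path / "qn.R"
        script.write_text(
            textwrap.dedent(
                """
                suppressMessages(library(limma))
                m <- as.matrix(read.table(commandArgs(TRUE)[1]))
                write.table(normalizeQuantiles(m), commandArgs(TRUE)[2],
                            sep="\\t", row.names=FALSE, col.names=FALSE)
                """
            )
        )
        outp = tmp_path / "out.tsv"
        subprocess.run(
            ["Rscript", str(script), str(inp), str(outp)], check=True, capture_output=True
        )
        expected = pd.read_csv(outp, sep="\t", header=None).to_numpy()
        np.testing.assert_allclose(quantile_normalize(m).values, expected, atol=1e-9)


class TestPresenceFilter:
    def test_one_percent_of_882_requires_nine(self):
        assert presence_threshold(882, 0.01) == 9

    def test_undetected_feature_removed_and_order_kept(self):
        det = pd.DataFrame(
            [[1, 1, 0], [0, 0, 0], [1, 0, 0]], index=["f1", "f2", "f3"]
        )
        assert filter_by_presence(det, 1 / 3) == ["f1", "f3"]

    def test_full_fraction_keeps_only_ubiquitous_features(self):
        det = pd.DataFrame([[1, 1], [1, 0]], index=["f1", "f2"])
        assert filter_by_presence(det, 1.0) == ["f1"]

    def test_min_fraction_one_over_n_keeps_anything_detected_once(self):
        det = pd.DataFrame(np.eye(7, dtype=int), index=[f"f{i}" for i in range(7)])
        assert filter_by_presence(det, 1 / 7) == [f"f{i}" for i in range(7)]

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_fraction_outside_unit_interval_rejected(self, bad):
        with pytest.raises(ValueError):
            presence_threshold(10, bad)


class TestProbeCollapse:
    def test_highest_mean_probe_kept(self):
        m = IntensityMatrix(
            ("pr1", "pr2"), ("s1", "s2"), np.array([[5.0, 5.0], [9.0, 9.0]])
        )
        out = collapse_probes_to_genes(m, {"pr1": "G", "pr2": "G"})
        assert out.feature_ids == ("G",)
        np.testing.assert_array_equal(out.values, [[9.0, 9.0]])

    def test_mean_tie_broken_by_smallest_probe_id(self):
        m = IntensityMatrix(
            ("prB", "prA"), ("s1",), np.array([[4.0], [4.0]])
        )
        out = collapse_probes_to_genes(m, {"prA": "G", "prB": "G"})
        np.testing.assert_array_equal(out.values, [[4.0]])
        # prA wins the tie; its row is the second input row.
        assert out.values[0, 0] == m.values[1, 0]

    def test_unmapped_probes_dropped_and_two_genes_kept(self):
        m = IntensityMatrix(
            ("pr1", "pr2", "pr3"), ("s1",), np.array([[1.0], [2.0], [3.0]])
        )
        out = collapse_probes_to_genes(m, {"pr1": "G1", "pr2": "G2"})
        assert out.feature_ids == ("G1", "G2")

    def test_empty_mapping_rejected(self):
        m = IntensityMatrix(("pr1",), ("s1",), np.array([[1.0]]))
        with pytest.raises(ValueError, match="empty"):
            collapse_probes_to_genes(m, {})
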