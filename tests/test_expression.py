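"""Differential-expression caller, concordance r² and gene-set overlap."""

import numpy as np
import pandas as pd
import pytest

from peakscape import (
    DEParams,
    DifferentialExpression,
    ExpressionMatrix,
    bound_gene_overlap,
    call_de,
    concordance_r2,
    read_expression,
    simulate_expression,
)
from peakscape.errors import FormatError
from peakscape.simulate import ExpressionSpec

GROUPS = {"WT_1": "WT", "WT_2": "WT", "KO_1": "KO", "KO_2": "KO"}


def matrix_from(rows: dict) -> ExpressionMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["WT_1", "WT_2", "KO_1", "KO_2"])
    return ExpressionMatrix(df, GROUPS)


class TestReadExpression:
    def test_round_trip(self, tmp_path):
        df = pd.DataFrame({"WT_1": [100.0, 50], "WT_2": [110.0, 55],
                           "KO_1": [200.0, 20], "KO_2": [190.0, 25]},
                          index=pd.Index(["g1", "g2"], name="gene_id"))
        p = tmp_path / "expr.tsv"
        df.to_csv(p, sep="\t")
        m = read_expression(p, GROUPS)
        assert m.genes == ["g1", "g2"]
        assert m.samples_in("KO") == ["KO_1", "KO_2"]

    def test_duplicate_gene_rejected(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("gene_id\tWT_1\tWT_2\tKO_1\tKO_2\ng1\t1\t1\t1\t1\ng1\t2\t2\t2\t2\n")
        with pytest.raises(FormatError):
            read_expression(p, GROUPS)

    def test_negative_signal_rejected(self, tmp_path):
        p = tmp_path / "expr.tsv"
        p.write_text("gene_id\tWT_1\tWT_2\tKO_1\tKO_2\ng1\t1\t-1\t1\t1\n")
        with pytest.raises(FormatError):
            read_expression(p, GROUPS)


class TestCallDE:
    def test_floor_excludes_dim_gene(self):
        # 1.4-fold change, but every signal <= 45: excluded by the floor
        m = matrix_from({"g": [40, 42, 30, 28]})
        res = call_de(m, "WT", "KO")
        assert res.table.loc["g", "reason"] == "floor"
        assert res.genes_at(1.5) == set()

    def test_floor_is_strict(self):
        m = matrix_from({"g": [45, 45, 45, 45]})
        assert call_de(m, "WT", "KO").table.loc["g", "reason"] == "floor"

    def test_tiered_fold_call(self):
        m = matrix_from({"g": [100, 100, 160, 160]})
        res = call_de(m, "WT", "KO")
        row = res.table.loc["g"]
        assert row["direction"] == "up"
        assert row["fold"] == pytest.approx(1.6)
        assert res.genes_at(1.5) == {"g"} and res.genes_at(2.5) == set()

    def test_inconsistent_direction_excluded(self):
        # pairwise ratios straddle 1: {2.0, 0.5, ...}
        m = matrix_from({"g": [100, 200, 200, 100]})
        res = call_de(m, "WT", "KO")
        assert res.table.loc["g", "reason"] == "inconsistent"
        assert res.table.loc["g", "direction"] == "none"

    def test_down_direction_and_fold(self):
        m = matrix_from({"g": [300, 300, 100, 100]})
        row = call_de(m, "WT", "KO").table.loc["g"]
        assert row["direction"] == "down"
        assert row["fold"] == pytest.approx(3.0)

    def test_tier_nesting(self):
        rng = np.random.default_rng(8)
        rows = {f"g{i}": list(rng.uniform(20, 500, 4)) for i in range(200)}
        res = call_de(matrix_from(rows), "WT", "KO")
        assert res.genes_at(2.5) <= res.genes_at(1.5)

    def test_group_swap_symmetry(self):
        rows = {f"g{i}": list(np.random.default_rng(i).uniform(50, 500, 4))
                for i in range(50)}
        m = matrix_from(rows)
        fwd = call_de(m, "WT", "KO").table
        rev = call_de(m, "KO", "WT").table
        swap = {"up": "down", "down": "up", "none": "none"}
        assert list(rev["direction"]) == [swap[d] for d in fwd["direction"]]
        np.testing.assert_allclose(rev["fold"].to_numpy(dtype=float),
                                   fwd["fold"].to_numpy(dtype=float))

    def test_floor_monotonicity(self):
        rng = np.random.default_rng(9)
        rows = {f"g{i}": list(rng.uniform(10, 200, 4)) for i in range(150)}
        m = matrix_from(rows)
        lo = call_de(m, "WT", "KO", DEParams(floor=20.0)).genes_at(1.5)
        hi = call_de(m, "WT", "KO", DEParams(floor=80.0)).genes_at(1.5)
        assert hi <= lo

    def test_zero_denominator_handled(self):
        # WT at zero but KO well above floor: infinite fold, called up
        m = matrix_from({"g": [0, 0, 100, 100]})
        row = call_de(m, "WT", "KO").table.loc["g"]
        assert row["direction"] == "up" and np.isinf(row["fold"])

    def test_mean_comparison_mode(self):
        m = matrix_from({"g": [100, 200, 200, 100]})  # inconsistent pairwise
        res = call_de(m, "WT", "KO", DEParams(comparison="mean"))
        assert res.table.loc["g", "reason"] == "floor" or \
            res.table.loc["g", "direction"] == "none"
        # means are equal (150 vs 150): no direction either way
        assert res.genes_at(1.5) == set()


class TestSimulatedRecovery:
    def test_noiseless_exact_recovery(self):
        spec = ExpressionSpec(n_genes=400, n_de=40, fold=2.0, noise_cv=0.0)
        matrix, truth = simulate_expression(spec, seed=77)
        res = call_de(matrix, "WT", "KO")
        planted = set(truth.data["de_up"]) | set(truth.data["de_down"])
        assert res.genes_at(1.5) == planted
        up = res.table[res.table["direction"] == "up"]
        assert set(truth.data["de_up"]) == set(up.index) & planted

    def test_floor_genes_never_called(self):
        spec = ExpressionSpec(n_genes=300, n_de=30, fold=3.0, noise_cv=0.1)
        matrix, truth = simulate_expression(spec, seed=78)
        res = call_de(matrix, "WT", "KO")
        assert res.genes_at(1.5).isdisjoint(truth.data["floor_genes"])


class TestConcordanceR2:
    def test_identical_vectors(self):
        assert concordance_r2([1.5, 2.0, 3.0], [1.5, 2.0, 3.0]) == pytest.approx(1.0)

    def test_affine_on_log_scale(self):
        a = np.array([1.2, 2.0, 4.0, 0.5])
        assert concordance_r2(a, 2.0 * a) == pytest.approx(1.0)

    def test_three_point_ols_closed_form(self):
        # r^2 of (1,2,3) vs (1,2,2) on the raw scale is 3/4
        assert concordance_r2([1, 2, 3], [1, 2, 2],
                              log2_scale=False) == pytest.approx(0.75)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            concordance_r2([1, 2], [1, 2])
        with pytest.raises(ValueError):
            concordance_r2([2, 2, 2], [1, 2, 3])


class TestBoundGeneOverlap:
    def test_disjoint_sets(self):
        res = bound_gene_overlap({"a"}, {"b"}, {"a", "b", "c"})
        assert res.p_value == 1.0

    def test_full_overlap_degenerate(self):
        u = {"a", "b", "c"}
        assert bound_gene_overlap(u, u, u).p_value == 1.0

    def test_worked_value(self):
        universe = [f"g{i}" for i in range(10)]
        bound = set(universe[:4])
        de = set(universe[:3]) | {universe[5], universe[6]}
        res = bound_gene_overlap(bound, de, universe)
        assert (res.n_bound, res.n_de, res.n_intersection) == (4, 5, 3)
        assert res.p_value == pytest.approx(66 / 252)

    def test_set_containment_enforced(self):
        with pytest.raises(ValueError):
            bound_gene_overlap({"x"}, {"a"}, {"a", "b"})
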