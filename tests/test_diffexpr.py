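import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from lncoexp import (ExpressionMatrix, bh_adjust, call_differential,
                     differential_table, fold_change, hierarchical_cluster,
                     t_test)
from lncoexp.datasets import (load_top30_lncrna, load_top30_lncrna_matrix,
                              three_pair_design)


def _row_matrix(c_values, n_values):
    values = np.array([list(c_values) + list(n_values)], dtype=float)
    return ExpressionMatrix(["probe"], ["C1", "C2", "C3", "N1", "N2", "N3"],
                            values, None)


class TestFoldChange:
    @pytest.mark.parametrize("c, n, expected_fc, expected_reg", [
        # printed per-sample values of the most extreme probes
        ((9.31, 1.54, 3.97), (14.14, 10.96, 14.27), 291.27, "down"),
        ((9.95, 6.97, 7.45), (2.17, 5.68, 2.77), 23.95, "up"),
        ((8.00, 1.60, 3.85), (12.90, 9.32, 13.06), 155.29, "down"),
        ((9.83, 6.92, 7.36), (2.58, 5.42, 2.57), 22.83, "up"),
    ])
    def test_reproduces_published_fold_changes(self, paired_design, c, n,
                                               expected_fc, expected_reg):
        fc = fold_change(_row_matrix(c, n), paired_design)
        assert fc["fc_abs"].iloc[0] == pytest.approx(expected_fc, rel=0.01)
        assert fc["regulation"].iloc[0] == expected_reg

    def test_identical_groups_give_unit_fold(self, paired_design):
        fc = fold_change(_row_matrix((5, 5, 5), (5, 5, 5)), paired_design)
        assert fc["log2fc"].iloc[0] == 0
        assert fc["fc_abs"].iloc[0] == 1

    def test_label_swap_antisymmetry(self, paired_design):
        rng = np.random.default_rng(1)
        c, n = rng.normal(8, 2, 3), rng.normal(8, 2, 3)
        fwd = fold_change(_row_matrix(c, n), paired_design)
        rev = fold_change(_row_matrix(n, c), paired_design)
        assert fwd["log2fc"].iloc[0] == pytest.approx(-rev["log2fc"].iloc[0])
        assert fwd["fc_abs"].iloc[0] == pytest.approx(rev["fc_abs"].iloc[0])
        assert {fwd["regulation"].iloc[0], rev["regulation"].iloc[0]} == \
            {"up", "down"}


def _pooled_t_oracle(x, y):
    """Textbook pooled t-test via numerical integration of the t density."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))

    def density(u):
        c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi)
                                        * math.gamma(df / 2))
        return c * (1 + u * u / df) ** (-(df + 1) / 2)

    tail, _ = quad(density, abs(t), np.inf)
    return 2 * tail


class TestTTest:
    def test_published_row_rounds_to_printed_p(self):
        c = [9.31, 1.54, 3.97]
        n = [14.14, 10.96, 14.27]
        p = t_test(c, n, "pooled_unpaired")
        assert round(p, 2) == 0.03

    def test_identical_groups_give_p_one(self):
        assert t_test([4.0, 4.0, 4.0], [4.0, 4.0, 4.0]) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_pooled_matches_numerical_integration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(0, 1, 4), rng.normal(0.5, 2, 5)
        assert t_test(x, y, "pooled_unpaired") == \
            pytest.approx(_pooled_t_oracle(x, y), abs=1e-8)

    def test_group_exchange_symmetry(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=4), rng.normal(size=4)
        for mode in ("pooled_unpaired", "welch"):
            assert t_test(x, y, mode) == pytest.approx(t_test(y, x, mode))

    def test_paired_differs_from_pooled_on_published_row(self):
        c = [9.31, 1.54, 3.97]
        n = [14.14, 10.96, 14.27]
        assert round(t_test(c, n, "paired"), 2) == 0.04

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            t_test([1.0], [2.0, 3.0])


def _bh_oracle(pvalues):
    """Brute-force step-up definition: q_i = min_{p_(j) >= p_i} p_(j)*m/j."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    out = [None] * m
    for i in range(m):
        candidates = [p[order[j]] * m / (j + 1) for j in range(m)
                      if p[order[j]] >= p[i]]
        out[i] = min(1.0, min(candidates))
    return out


class TestBHAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @pytest.mark.parametrize("length", range(1, 5))
    def test_exhaustive_grid_matches_brute_force(self, length):
        grid = (0.001, 0.04, 0.05, 0.5, 1.0)
        for combo in itertools.product(grid, repeat=length):
            np.testing.assert_allclose(bh_adjust(list(combo)),
                                       _bh_oracle(combo), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_matches_brute_force_and_dominates_input(self, pvalues):
        q = bh_adjust(pvalues)
        np.testing.assert_allclose(q, _bh_oracle(pvalues), atol=1e-12)
        assert np.all(q >= np.asarray(pvalues) - 1e-15)
        assert np.all(q <= 1.0)


class TestCallDifferential:
    def test_threshold_boundaries(self, paired_design):
        import pandas as pd
        table = pd.DataFrame({
            "fc_abs": [2.5, 1.9, 291.27, 2.0],
            "p": [0.01, 0.001, 0.03, 0.05],
            "regulation": ["up", "up", "down", "down"],
        }, index=["a", "b", "c", "d"])
        de = call_differential(table, 2.0, 0.05)
        assert list(de.index) == ["a", "c", "d"]


class TestHierarchicalCluster:
    def test_identical_profiles_merge_first_at_zero(self):
        values = np.array([[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1]],
                          dtype=float)
        m = ExpressionMatrix(["a", "b", "c"], list("wxyz"), values, None)
        result = hierarchical_cluster(m, axis="probes")
        assert result.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(result.linkage[0, 0]), int(result.linkage[0, 1])} == {0, 1}

    def test_anticorrelated_profile_merges_last(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        third = x + np.array([0.01, -0.02, 0.02, -0.01])
        values = np.vstack([x, -x, third])
        m = ExpressionMatrix(["x", "negx", "noisy"], list("abcd"), values,
                             None)
        result = hierarchical_cluster(m, axis="probes")
        first = {int(result.linkage[0, 0]), int(result.linkage[0, 1])}
        assert first == {0, 2}   # x joins its noisy copy, -x joins last

    def test_published_table_separates_tumor_from_normal(self):
        result = hierarchical_cluster(load_top30_lncrna_matrix(),
                                      axis="samples")
        left, right = result.top_split()
        assert {frozenset(left), frozenset(right)} == {
            frozenset({"C1", "C2", "C3"}), frozenset({"N1", "N2", "N3"})}

    def test_constant_profile_handled(self):
        values = np.array([[1, 1, 1, 1], [1, 2, 3, 4], [2, 4, 6, 9]],
                          dtype=float)
        m = ExpressionMatrix(["const", "a", "b"], list("wxyz"), values, None)
        result = hierarchical_cluster(m, axis="probes")
        assert result.linkage.shape == (2, 4)


@pytest.mark.parametrize("loader", ["lncrna", "mrna"])
def test_differential_table_reproduces_published_tables(loader):
    """End-to-end: printed top-30 per-sample values reproduce the printed
    fold changes, directions and (to rounding) p values."""
    from lncoexp.datasets import as_expression_matrix, load_top30_mrna
    table = load_top30_lncrna() if loader == "lncrna" else load_top30_mrna()
    matrix = as_expression_matrix(table)
    result = differential_table(matrix, three_pair_design())
    fc_err = np.abs(result["fc_abs"].to_numpy()
                    / table["fc_abs"].to_numpy() - 1)
    assert fc_err.max() < 0.01
    assert (result["regulation"].to_numpy()
            == table["regulation"].to_numpy()).all()
    # printed p values are rounded to 2 decimals
    assert np.abs(result["p"].to_numpy()
                  - table["p"].to_numpy()).max() <= 0.005 + 1e-9
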