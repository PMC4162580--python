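"""Tests for discretization and the two association tests."""

import numpy as np
import pandas as pd
import pytest

from grnbench import discretize, fisher_z_test, g2_test
from grnbench.ci_tests import TernaryMatrix
from grnbench.containers import ExpressionMatrix


def expr_from(rows: dict[str, list[float]]) -> ExpressionMatrix:
    df = pd.DataFrame(rows).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(values=df.astype(float))


def tern_from(rows: dict[str, list[int]]) -> TernaryMatrix:
    df = pd.DataFrame(rows).T.astype(np.int8)
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return TernaryMatrix(values=df)


class TestDiscretize:
    def test_constant_gene_maps_to_middle(self):
        t = discretize(expr_from({"g": [5.0] * 6}))
        assert (t.values.loc["g"] == 1).all()

    def test_hand_example(self):
        # sd with n-1 denominator is sqrt(20/3) ≈ 2.582;
        # standardized ≈ {-1.162, -0.387, 0.387, 1.162} -> {0, 1, 1, 2}
        t = discretize(expr_from({"g": [-3, -1, 1, 3]}))
        assert t.values.loc["g"].tolist() == [0, 1, 1, 2]

    def test_boundaries_are_inclusive(self):
        # values [sqrt(2), -sqrt(2), 1, -1] standardize to [1, -1, .707, -.707]
        s2 = np.sqrt(2)
        t = discretize(expr_from({"g": [s2, -s2, 1, -1]}))
        assert t.values.loc["g"].tolist() == [1, 1, 1, 1]

    def test_shape_and_identifiers_preserved(self):
        e = expr_from({"a": [1, 2, 3], "b": [0, 0, 1]})
        t = discretize(e)
        assert list(t.values.index) == ["a", "b"]
        assert t.values.shape == e.values.shape
        assert set(np.unique(t.values)) <= {0, 1, 2}


def correlated_pair(n: int, rho: float, seed: int = 0) -> ExpressionMatrix:
    """Two vectors whose *sample* correlation equals rho exactly."""
    rng = np.random.default_rng(seed)
    v1 = rng.normal(size=n)
    v2 = rng.normal(size=n)
    v1 -= v1.mean()
    v2 -= v2.mean()
    v2 -= v1 * (v1 @ v2) / (v1 @ v1)  # orthogonalize
    v1 /= np.linalg.norm(v1)
    v2 /= np.linalg.norm(v2)
    y = rho * v1 + np.sqrt(1 - rho**2) * v2
    return expr_from({"x": v1.tolist(), "y": y.tolist()})


class TestFisherZ:
    def test_exact_independence_gives_p_one(self):
        e = correlated_pair(30, 0.0)
        res = fisher_z_test(e, "x", "y")
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_numeric_oracle_r_half_n_30(self):
        # z(0.5) = 0.5493, statistic = sqrt(27)*z ≈ 2.8543, p ≈ 0.00431
        e = correlated_pair(30, 0.5)
        res = fisher_z_test(e, "x", "y")
        assert res.statistic == pytest.approx(2.854278, abs=1e-5)
        assert res.p_value == pytest.approx(0.0043135, abs=1e-6)
        assert res.n == 30 and res.cond_size == 0 and res.reliable

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(3)
        e = expr_from({"x": rng.normal(size=50).tolist(),
                       "y": rng.normal(size=50).tolist(),
                       "z": rng.normal(size=50).tolist()})
        a = fisher_z_test(e, "x", "y", ["z"])
        b = fisher_z_test(e, "y", "x", ["z"])
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)
        scaled = e.values.copy()
        scaled.loc["y"] = -7.5 * scaled.loc["y"] + 3.0
        c = fisher_z_test(ExpressionMatrix(values=scaled), "x", "y", ["z"])
        assert c.statistic == pytest.approx(a.statistic, rel=1e-9)

    def test_exact_conditional_independence(self):
        # x = z + u, y = z + v with u ⟂ v ⟂ z exactly: partial corr = 0
        rng = np.random.default_rng(7)
        raw = rng.normal(size=(3, 40))
        q, _ = np.linalg.qr((raw - raw.mean(axis=1, keepdims=True)).T)
        z, u, v = q.T
        e = expr_from({"x": (z + 0.8 * u).tolist(), "y": (z + 0.8 * v).tolist(),
                       "z": z.tolist()})
        uncond = fisher_z_test(e, "x", "y")
        cond = fisher_z_test(e, "x", "y", ["z"])
        assert uncond.p_value < 0.01
        assert cond.p_value == pytest.approx(1.0, abs=1e-6)

    def test_partial_correlation_matches_pingouin(self):
        # independent route: pingouin's partial correlation on the same data
        import pingouin as pg

        rng = np.random.default_rng(13)
        z = rng.normal(size=80)
        w = rng.normal(size=80)
        x = z + 0.5 * w + rng.normal(size=80)
        y = -z + 0.3 * w + rng.normal(size=80)
        e = expr_from({"x": x.tolist(), "y": y.tolist(),
                       "z": z.tolist(), "w": w.tolist()})
        res = fisher_z_test(e, "x", "y", ["z", "w"])
        ref = pg.partial_corr(
            pd.DataFrame({"x": x, "y": y, "z": z, "w": w}),
            x="x", y="y", covar=["z", "w"],
        )["r"].iloc[0]
        r_ours = np.tanh(res.statistic / np.sqrt(res.n - res.cond_size - 3))
        assert r_ours == pytest.approx(abs(ref), abs=1e-9)

    def test_singular_submatrix_flagged_unreliable(self):
        x = np.linspace(0, 1, 20)
        e = expr_from({"x": x.tolist(), "y": (2 * x).tolist(), "w": (-x).tolist(),
                       "t": np.cos(x).tolist()})
        res = fisher_z_test(e, "x", "t", ["y", "w"])
        assert not res.reliable and res.p_value == 1.0

    def test_preconditions(self):
        e = correlated_pair(10, 0.3)
        with pytest.raises(ValueError):
            fisher_z_test(e, "x", "x")
        with pytest.raises(ValueError):
            fisher_z_test(e, "x", "y", ["y"])


class TestG2:
    def test_product_table_gives_zero(self):
        # x blocks of 30 per category, y uniform within each block: O = E
        x = [0] * 30 + [1] * 30 + [2] * 30
        y = ([0] * 10 + [1] * 10 + [2] * 10) * 3
        res = g2_test(tern_from({"x": x, "y": y}), "x", "y")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0
        assert res.reliable  # n = 90 >= 45

    def test_diagonal_counts_oracle(self):
        # counts [[10,0,0],[0,10,0],[0,0,10]]: G2 = 2·30·ln 3 ≈ 65.917
        x = [0] * 10 + [1] * 10 + [2] * 10
        res = g2_test(tern_from({"x": x, "y": list(x)}), "x", "y")
        assert res.statistic == pytest.approx(2 * 30 * np.log(3), rel=1e-12)
        assert res.p_value < 1e-12

    def test_deterministic_conditional_independence(self):
        # x = z and y = z: within every stratum of z both are constant
        z = [0] * 20 + [1] * 20 + [2] * 20
        res = g2_test(tern_from({"x": z, "y": list(z), "z": list(z)}), "x", "y", ["z"])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_symmetry_and_label_permutation_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 3, 120).tolist()
        y = rng.integers(0, 3, 120).tolist()
        a = g2_test(tern_from({"x": x, "y": y}), "x", "y")
        b = g2_test(tern_from({"x": x, "y": y}), "y", "x")
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)
        perm = {0: 2, 1: 0, 2: 1}
        c = g2_test(tern_from({"x": [perm[v] for v in x], "y": y}), "x", "y")
        assert c.statistic == pytest.approx(a.statistic, rel=1e-12)

    def test_matches_scipy_log_likelihood_statistic(self):
        # independent route: scipy's likelihood-ratio chi-square on the
        # same 3x3 contingency table
        from scipy import stats as sps

        rng = np.random.default_rng(21)
        z = rng.integers(0, 3, 500)
        x = np.clip(z + rng.integers(-1, 2, 500), 0, 2).tolist()
        y = np.clip(z + rng.integers(-1, 2, 500), 0, 2).tolist()
        res = g2_test(tern_from({"x": x, "y": y}), "x", "y")
        obs = np.zeros((3, 3))
        np.add.at(obs, (x, y), 1)
        ref = sps.chi2_contingency(obs, correction=False, lambda_="log-likelihood")
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)

    def test_constant_variable_unreliable(self):
        res = g2_test(tern_from({"x": [1] * 50, "y": [0, 1, 2] * 16 + [0, 1]}), "x", "y")
        assert res.statistic == 0.0 and res.p_value == 1.0 and not res.reliable

    def test_reliability_heuristic_with_conditioning(self):
        # 3 non-empty strata -> needs n >= 135; n = 100 is unreliable
        rng = np.random.default_rng(11)
        x = rng.integers(0, 3, 100).tolist()
        y = rng.integers(0, 3, 100).tolist()
        z = rng.integers(0, 3, 100).tolist()
        res = g2_test(tern_from({"x": x, "y": y, "z": z}), "x", "y", ["z"])
        assert not res.reliable
        big = 300
        rng = np.random.default_rng(12)
        x = rng.integers(0, 3, big).tolist()
        y = rng.integers(0, 3, big).tolist()
        z = rng.integers(0, 3, big).tolist()
        res2 = g2_test(tern_from({"x": x, "y": y, "z": z}), "x", "y", ["z"])
        assert res2.reliable
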