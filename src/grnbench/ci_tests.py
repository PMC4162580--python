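"""Conditional-independence tests for network inference.

Two association tests drive every inference approach in this package:

* **Fisher's Z** on continuous data: the partial correlation ``r`` of two
  genes given a conditioning set is obtained from the inverse of the
  sample correlation matrix, transformed as ``z = ½·ln((1+r)/(1−r))``, and
  ``√(n−|S|−3)·|z|`` is referred to the standard normal.
* **G²** (the likelihood-ratio statistic for independence) on
  ternary-discretized data: within each joint stratum of the conditioning
  genes a 3×3 contingency table contributes ``2·Σ O·ln(O/E)``, with
  degrees of freedom ``4·(number of non-empty strata)``.

Discretization standardizes each gene to mean 0 / sd 1 and cuts at ±1 into
three categories (low / mid / high).

A G² result is flagged *unreliable* when the sample is too thin for the
table (fewer than five samples per cell on average across non-empty
strata); unreliable tests must never be used to declare independence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

__all__ = ["TernaryMatrix", "TestResult", "discretize", "fisher_z_test", "g2_test"]

#: partial correlations are clamped to ±(1 − R_CLAMP) before the z-transform
R_CLAMP = 1e-7


@dataclass
class TernaryMatrix:
    """Genes × samples matrix with values in {0, 1, 2} (low/mid/high)."""

    values: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    cond_size: int
    reliable: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


def discretize(expr: ExpressionMatrix) -> TernaryMatrix:
    """Standardize each gene and cut at ±1 into three categories.

    Values strictly below −1 map to 0, values in the closed interval
    [−1, 1] map to 1 and values strictly above +1 map to 2.  The sample
    standard deviation uses the n−1 denominator; constant genes map
    entirely to the middle category.
    """
    if expr.n_samples < 2:
        raise ValueError("need at least 2 samples to discretize")
    x = expr.values.to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    z = np.divide(x - mu, sd, out=np.zeros_like(x), where=sd > 0)
    cats = np.ones_like(z, dtype=np.int8)
    cats[z < -1] = 0
    cats[z > 1] = 2
    return TernaryMatrix(
        values=pd.DataFrame(cats, index=expr.values.index, columns=expr.values.columns)
    )


def _as_frame(data: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    return data.values if isinstance(data, ExpressionMatrix) else data


def _fisher_from_corr(corr: np.ndarray, n: int, k: int) -> TestResult:
    """Fisher's Z from the correlation submatrix of {i, j} ∪ cond.

    The first two rows/columns must correspond to the tested pair.
    """
    if np.any(np.isnan(corr)):  # constant gene
        return TestResult(0.0, 1.0, n, k, reliable=False)
    if k == 0:
        r = corr[0, 1]
    else:
        try:
            prec = np.linalg.inv(corr)
        except np.linalg.LinAlgError:
            return TestResult(0.0, 1.0, n, k, reliable=False)
        denom = prec[0, 0] * prec[1, 1]
        if not np.isfinite(denom) or denom <= 0:
            return TestResult(0.0, 1.0, n, k, reliable=False)
        r = -prec[0, 1] / np.sqrt(denom)
    r = float(np.clip(r, -1 + R_CLAMP, 1 - R_CLAMP))
    z = 0.5 * np.log((1 + r) / (1 - r))
    statistic = float(np.sqrt(n - k - 3) * abs(z))
    p = float(2 * stats.norm.sf(statistic))
    return TestResult(statistic, min(p, 1.0), n, k, reliable=True)


def fisher_z_test(
    expr: ExpressionMatrix | pd.DataFrame,
    i: str,
    j: str,
    cond: Iterable[str] = (),
) -> TestResult:
    """Partial-correlation test of genes *i* and *j* given ``cond``.

    The partial correlation is computed by inverting the sample correlation
    matrix of ``{i, j} ∪ cond``; a numerically singular submatrix yields an
    unreliable result with ``p = 1``.
    """
    cond = sorted(set(cond))
    if i == j or i in cond or j in cond:
        raise ValueError("genes i, j must be distinct and outside cond")
    df = _as_frame(expr)
    n = df.shape[1]
    k = len(cond)
    if n <= k + 3:
        raise ValueError(f"need n > |cond| + 3 (n={n}, |cond|={k})")
    sub = df.loc[[i, j] + cond].to_numpy(float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    return _fisher_from_corr(corr, n, k)


def _g2_strata(xc: np.ndarray | None, n: int) -> np.ndarray:
    """Encode joint conditioning categories as integer stratum codes."""
    if xc is None or xc.shape[0] == 0:
        return np.zeros(n, dtype=np.int64)
    strata = np.zeros(n, dtype=np.int64)
    for row in xc:
        strata = strata * 3 + row
    return strata


def _g2_core(
    xi: np.ndarray, xj: np.ndarray, xc: np.ndarray | None, cond_size: int
) -> TestResult:
    """G² machinery shared by :func:`g2_test` and the inference engines."""
    n = xi.shape[0]
    if len(np.unique(xi)) < 2 or len(np.unique(xj)) < 2:
        return TestResult(0.0, 1.0, n, cond_size, reliable=False)
    strata = _g2_strata(xc, n)
    g2 = 0.0
    n_strata = 0
    for s in np.unique(strata):
        mask = strata == s
        obs = np.zeros((3, 3))
        np.add.at(obs, (xi[mask], xj[mask]), 1.0)
        total = obs.sum()
        if total == 0:
            continue
        n_strata += 1
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
        nz = obs > 0
        g2 += 2.0 * float(np.sum(obs[nz] * np.log(obs[nz] / expected[nz])))
    dof = 4 * n_strata
    if dof == 0:
        return TestResult(0.0, 1.0, n, cond_size, reliable=False)
    g2 = max(g2, 0.0)
    p = float(stats.chi2.sf(g2, dof))
    reliable = n >= 5 * (9 * n_strata)
    return TestResult(g2, min(p, 1.0), n, cond_size, reliable=reliable)


def g2_test(
    tern: TernaryMatrix | pd.DataFrame,
    i: str,
    j: str,
    cond: Iterable[str] = (),
) -> TestResult:
    """G² likelihood-ratio test of genes *i* and *j* given ``cond``.

    Zero observed cells contribute nothing to the statistic; expected
    counts come from the row/column margins within each conditioning
    stratum.  The degrees of freedom are fixed at 4 per non-empty stratum
    (no adjustment for zero margins), which keeps results bit-for-bit
    reproducible across conventions.
    """
    cond = sorted(set(cond))
    if i == j or i in cond or j in cond:
        raise ValueError("genes i, j must be distinct and outside cond")
    df = tern.values if isinstance(tern, TernaryMatrix) else tern
    xi = df.loc[i].to_numpy(np.int64)
    xj = df.loc[j].to_numpy(np.int64)
    xc = df.loc[cond].to_numpy(np.int64) if cond else None
    return _g2_core(xi, xj, xc, len(cond))
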