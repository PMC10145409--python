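"""Ordinary least squares with the fit statistics the selection loop needs.

The design matrix is a pandas DataFrame whose columns are predictor codes;
an intercept is always included.  Implemented directly on numpy's
least-squares solver so that the thousands of small fits performed during
forward selection stay cheap; standard errors and p-values follow the
textbook formulas (t reference distribution on n - p - 1 degrees of
freedom).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class SingularDesignError(ValueError):
    """Raised when the design matrix is rank deficient."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(
            "design matrix is rank deficient; dependent columns: "
            + ", ".join(columns)
        )


@dataclass
class OLSFit:
    """A fitted linear model y = intercept + X beta + e."""

    intercept: float
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    intercept_se: float
    intercept_p: float
    r2: float
    adj_r2: float
    residuals: np.ndarray
    fitted: np.ndarray
    n: int
    p: int
    sigma2: float  # residual variance e'e / (n - p - 1)
    xtx_inv: np.ndarray = field(repr=False, default=None)

    @property
    def codes(self) -> list[str]:
        return list(self.coefficients)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        vals = np.full(len(X), self.intercept)
        for code, beta in self.coefficients.items():
            vals = vals + beta * X[code].to_numpy(dtype=float)
        return vals


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """1 - (1 - R^2) (n - 1) / (n - p - 1)."""
    if n <= p + 1:
        raise ValueError(f"adjusted R^2 undefined for n={n}, p={p}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _dependent_columns(design: np.ndarray, names: list[str]) -> list[str]:
    _, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    bad = [names[j] for j in range(len(names)) if j < len(diag) and diag[j] <= tol]
    return bad or names


def fit_ols(y: np.ndarray, X: pd.DataFrame) -> OLSFit:
    """Fit y on the columns of X plus an intercept.

    An empty X yields the intercept-only model (prediction = mean(y),
    R^2 defined as 0).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    codes = list(X.columns)
    p = len(codes)
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    xmat = X.to_numpy(dtype=float) if p else np.empty((n, 0))
    for j, code in enumerate(codes):
        if np.ptp(xmat[:, j]) == 0.0:
            raise SingularDesignError([code])
    design = np.column_stack([np.ones(n), xmat])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        raise SingularDesignError(_dependent_columns(design, ["const"] + codes))

    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    resid = y - fitted
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum(resid**2))
    r2 = 0.0 if (p == 0 or sst == 0.0) else 1.0 - sse / sst
    dof = n - p - 1
    sigma2 = sse / dof
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)

    return OLSFit(
        intercept=float(beta[0]),
        coefficients={c: float(b) for c, b in zip(codes, beta[1:])},
        std_errors={c: float(s) for c, s in zip(codes, se[1:])},
        p_values={c: float(v) for c, v in zip(codes, pvals[1:])},
        intercept_se=float(se[0]),
        intercept_p=float(pvals[0]),
        r2=r2,
        adj_r2=adjusted_r2(r2, n, p) if p else 0.0,
        residuals=resid,
        fitted=fitted,
        n=n,
        p=p,
        sigma2=sigma2,
        xtx_inv=xtx_inv,
    )
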