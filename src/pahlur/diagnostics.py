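"""Regression diagnostics: collinearity (VIF), influence (Cook's distance)
and residual spatial autocorrelation (Moran's I)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regression import OLSFit, fit_ols


@dataclass
class MoranResult:
    observed: float
    expected: float  # -1/(n-1) under exchangeability
    p_value: float   # permutation p, two-sided about the permutation mean
    n_permutations: int


@dataclass
class Diagnostics:
    vif: dict[str, float]
    cooks_d: np.ndarray
    cooks_flags: list[int]  # observation indices with D >= 1
    morans_i: MoranResult | None


def vif(X: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factors via auxiliary regressions.

    VIF_j = 1 / (1 - R^2_j) where R^2_j regresses column j on the other
    columns (with intercept).  A single-column design gets VIF = 1 by
    convention.  Perfect collinearity raises with the offending column
    named.
    """
    codes = list(X.columns)
    if len(codes) <= 1:
        return {c: 1.0 for c in codes}
    out = {}
    for code in codes:
        others = [c for c in codes if c != code]
        aux = fit_ols(X[code].to_numpy(dtype=float), X[others])
        if aux.r2 >= 1.0 - 1e-12:
            raise ValueError(
                f"predictor {code!r} is perfectly collinear with the rest "
                "(infinite VIF)"
            )
        out[code] = 1.0 / (1.0 - aux.r2)
    return out


def cooks_distance(fit: OLSFit, X: pd.DataFrame) -> np.ndarray:
    """Cook's D per observation:

        D_i = (e_i^2 / (p' s^2)) * h_i / (1 - h_i)^2,  p' = p + 1,

    with h_i the hat-matrix leverages of the intercept-augmented design.
    """
    n = fit.n
    xmat = X.to_numpy(dtype=float) if fit.p else np.empty((n, 0))
    design = np.column_stack([np.ones(n), xmat])
    h = np.einsum("ij,jk,ik->i", design, fit.xtx_inv, design)
    if np.any(h >= 1.0 - 1e-12):
        idx = int(np.argmax(h))
        raise ValueError(f"observation {idx} has leverage 1 (degenerate design)")
    pprime = fit.p + 1
    return (fit.residuals**2 / (pprime * fit.sigma2)) * h / (1.0 - h) ** 2


def inverse_distance_weights(coords: np.ndarray) -> np.ndarray:
    """w_ij = 1 / d_ij, w_ii = 0; no cutoff, not row-standardized."""
    coords = np.asarray(coords, dtype=float)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    if not np.isfinite(w).all():
        raise ValueError("duplicate coordinates give infinite inverse-distance weights")
    return w


def morans_i(
    residuals: np.ndarray,
    coords: np.ndarray,
    weights: np.ndarray | None = None,
    n_permutations: int = 9999,
    rng: np.random.Generator | None = None,
) -> MoranResult:
    """Moran's I of residuals with a permutation test.

        I = (n / W) * sum_ij w_ij z_i z_j / sum_i z_i^2,   z = e - mean(e)

    The permutation p-value is two-sided: the fraction of relabelings whose
    |I - mean(I_perm)| reaches |I_obs - mean(I_perm)| (add-one corrected).
    """
    e = np.asarray(residuals, dtype=float)
    n = len(e)
    if n < 4:
        raise ValueError("Moran's I requires n >= 4")
    z = e - e.mean()
    denom = float(np.sum(z**2))
    if denom == 0.0:
        raise ValueError("Moran's I undefined for constant residuals")
    w = inverse_distance_weights(coords) if weights is None else np.asarray(weights, float)
    wsum = float(w.sum())
    obs = float(n / wsum * (z @ w @ z) / denom)
    expected = -1.0 / (n - 1)

    rng = rng or np.random.default_rng(0)
    perm = np.empty(n_permutations)
    zmat = np.empty((n_permutations, n))
    for k in range(n_permutations):
        zmat[k] = z[rng.permutation(n)]
    # denom is permutation invariant
    perm = n / wsum * np.einsum("ki,ij,kj->k", zmat, w, zmat) / denom
    center = perm.mean()
    p = (1 + np.sum(np.abs(perm - center) >= abs(obs - center))) / (
        n_permutations + 1
    )
    return MoranResult(obs, expected, float(p), n_permutations)
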