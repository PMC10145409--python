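"""Supervised forward selection with a-priori sign constraints.

The procedure (the ESCAPE convention for land-use-regression models):

1. Fit every candidate alone; among those whose slope agrees with its
   a-priori direction of effect, start from the one with the highest R^2.
2. Greedily add variables: at each step every remaining candidate is
   tried; an addition qualifies only if the entering slope has the
   permitted sign, no already-entered slope flips sign, and the adjusted
   R^2 gain is at least ``gain_threshold`` (absolute increment by default).
   The qualifying addition with the highest adjusted R^2 is kept.
3. Backward pruning: variables with p >= alpha are removed one at a time
   (largest p first, refitting each time).
4. Collinearity pruning: while any VIF >= the threshold, the variable with
   the largest VIF is dropped and significance pruning is re-run.
5. Cook's distances are flagged (D >= 1) and Moran's I of the residuals is
   reported; neither changes the model.

Every decision is recorded in an ordered trace, from which the final model
can be replayed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagnostics import Diagnostics, cooks_distance, morans_i, vif
from .predictors import PredictorSpec
from .regression import OLSFit, adjusted_r2, fit_ols


@dataclass(frozen=True)
class SelectionConfig:
    gain_threshold: float = 0.01
    gain_mode: str = "absolute"  # or "relative" (fraction of previous adj R^2)
    alpha: float = 0.05
    vif_threshold: float = 5.0
    min_rows: int = 10
    moran_permutations: int = 9999

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.gain_threshold < 0:
            raise ValueError("gain_threshold must be >= 0")
        if self.vif_threshold <= 1:
            raise ValueError("vif_threshold must exceed 1")
        if self.gain_mode not in ("absolute", "relative"):
            raise ValueError(f"unknown gain_mode {self.gain_mode!r}")


@dataclass
class TraceStep:
    step: int
    candidate: str
    adj_r2_before: float
    adj_r2_after: float
    # added | rejected_sign | rejected_gain | removed_pvalue |
    # removed_sign_flip | removed_vif
    action: str


@dataclass
class Candidate:
    code: str
    r2: float
    slope: float
    eligible: bool


@dataclass
class LURModel:
    species: str
    season: str
    phase: str
    fit: OLSFit
    trace: list[TraceStep] = field(default_factory=list)

    @property
    def codes(self) -> list[str]:
        return self.fit.codes

    def equation(self) -> str:
        terms = [f"{b:+.6g} {c}" for c, b in self.fit.coefficients.items()]
        terms.append(f"{self.fit.intercept:+.6g}")
        return " ".join(terms).lstrip("+")


def _slope_permitted(slope: float, spec: PredictorSpec) -> bool:
    if spec.expected_sign == "uncertain":
        return True
    if spec.expected_sign == "+":
        return slope > 0
    return slope < 0


def _loo_stable(x: np.ndarray) -> bool:
    """True when the column stays non-constant after deleting any single
    observation (at least two values differ from the most frequent one).
    Near-indicator covariates observed at a single site fail this and are
    excluded: they cannot be cross-validated and carry no generalizable
    signal."""
    _, counts = np.unique(x, return_counts=True)
    return len(counts) > 1 and len(x) - counts.max() >= 2


def screen_univariate(
    y: np.ndarray, X: pd.DataFrame, registry: dict[str, PredictorSpec]
) -> list[Candidate]:
    """One single-predictor fit per registered column of X.

    Constant and leave-one-out-unstable columns are dropped.  Candidates
    whose slope contradicts a non-uncertain a-priori sign are marked
    ineligible.  The returned list has eligible candidates first, ranked
    by R^2 descending with lexicographic code tie-break, followed by the
    ineligible ones in the same order.  Computed in closed form
    (slope = Sxy/Sxx, R^2 = Sxy^2/(Sxx Syy)), identical to per-candidate
    OLS fits.
    """
    y = np.asarray(y, dtype=float)
    codes = [c for c in X.columns if c in registry]
    xmat = X[codes].to_numpy(dtype=float)
    xc = xmat - xmat.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=0)
    syy = float((yc**2).sum())
    sxy = xc.T @ yc
    cands = []
    for j, code in enumerate(codes):
        if sxx[j] == 0.0 or not _loo_stable(xmat[:, j]):
            continue
        slope = float(sxy[j] / sxx[j])
        r2 = 0.0 if syy == 0.0 else float(sxy[j] ** 2 / (sxx[j] * syy))
        cands.append(
            Candidate(code, r2, slope, _slope_permitted(slope, registry[code]))
        )
    cands.sort(key=lambda c: (not c.eligible, -c.r2, c.code))
    return cands


def _gain_ok(before: float, after: float, config: SelectionConfig) -> bool:
    if config.gain_mode == "absolute":
        return after - before >= config.gain_threshold
    return after - before >= config.gain_threshold * abs(before)


def forward_select(
    y: np.ndarray,
    X: pd.DataFrame,
    registry: dict[str, PredictorSpec],
    config: SelectionConfig | None = None,
    species: str = "",
    season: str = "",
    phase: str = "",
) -> LURModel:
    """Greedy sign-constrained forward selection (pre-diagnostics).

    The first variable is admitted purely by the highest-R^2-with-correct-
    sign rule (there is no previous model to gain over); later additions
    must clear the adjusted-R^2 gain threshold.
    """
    config = config or SelectionConfig()
    y = np.asarray(y, dtype=float)
    trace: list[TraceStep] = []
    cands = screen_univariate(y, X, registry)
    eligible = [c.code for c in cands if c.eligible]
    if not eligible:
        fit = fit_ols(y, X[[]])
        return LURModel(species, season, phase, fit, trace)

    n = len(y)
    all_codes = [c.code for c in cands]
    colpos = {c: j for j, c in enumerate(X.columns)}
    xall = X.to_numpy(dtype=float)
    sst = float(np.sum((y - y.mean()) ** 2))

    def quick_fit(codes: list[str]):
        """(betas excl. intercept, adjusted R^2) via bare least squares;
        None when the augmented design is rank deficient."""
        design = np.column_stack(
            [np.ones(n), xall[:, [colpos[c] for c in codes]]]
        )
        beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rank < design.shape[1]:
            return None
        sse = float(np.sum((y - design @ beta) ** 2))
        r2 = 0.0 if sst == 0.0 else 1.0 - sse / sst
        return beta[1:], adjusted_r2(r2, n, len(codes))

    current = [eligible[0]]
    fit = fit_ols(y, X[current])
    trace.append(TraceStep(1, eligible[0], 0.0, fit.adj_r2, "added"))
    step = 1
    remaining = [c for c in all_codes if c != eligible[0]]

    while remaining:
        step += 1
        best: tuple[float, str] | None = None
        sign_rejected: list[str] = []
        if len(current) + 2 >= n:
            break  # no degrees of freedom left for another variable
        for code in sorted(remaining):
            res = quick_fit(current + [code])
            if res is None:
                continue
            betas, adj = res
            slopes = dict(zip(current + [code], betas))
            if not all(
                _slope_permitted(slopes[c], registry[c])
                for c in current + [code]
            ):
                sign_rejected.append(code)
                continue
            # strict > with lexicographic iteration keeps the first code on ties
            if best is None or adj > best[0]:
                best = (adj, code)
        for code in sign_rejected:
            trace.append(TraceStep(step, code, fit.adj_r2, np.nan, "rejected_sign"))
        if best is None:
            break
        adj, code = best
        if not _gain_ok(fit.adj_r2, adj, config):
            trace.append(TraceStep(step, code, fit.adj_r2, adj, "rejected_gain"))
            break
        trace.append(TraceStep(step, code, fit.adj_r2, adj, "added"))
        current.append(code)
        fit = fit_ols(y, X[current])
        remaining = [c for c in remaining if c != code]

    return LURModel(species, season, phase, fit, trace)


def prune_significance(
    model: LURModel,
    y: np.ndarray,
    X: pd.DataFrame,
    alpha: float = 0.05,
) -> LURModel:
    """Drop variables with p >= alpha, largest p first, refitting each time."""
    fit = model.fit
    trace = list(model.trace)
    step = max((t.step for t in trace), default=0)
    while fit.p > 0:
        worst = max(fit.p_values, key=lambda c: (fit.p_values[c], c))
        if fit.p_values[worst] < alpha:
            break
        step += 1
        keep = [c for c in fit.codes if c != worst]
        new_fit = fit_ols(y, X[keep])
        trace.append(
            TraceStep(step, worst, fit.adj_r2, new_fit.adj_r2, "removed_pvalue")
        )
        fit = new_fit
    return LURModel(model.species, model.season, model.phase, fit, trace)


def _remove_sign_flips(
    model: LURModel,
    y: np.ndarray,
    X: pd.DataFrame,
    registry: dict[str, PredictorSpec],
) -> LURModel:
    """Drop variables whose slope left its permitted direction.

    Backward pruning refits the model, which can flip a surviving slope
    out of its a-priori direction; such variables are removed (worst
    p-value first) until every retained slope complies."""
    fit = model.fit
    trace = list(model.trace)
    step = max((t.step for t in trace), default=0)
    while True:
        violators = [
            c for c, b in fit.coefficients.items()
            if not _slope_permitted(b, registry[c])
        ]
        if not violators:
            break
        worst = max(violators, key=lambda c: (fit.p_values[c], c))
        step += 1
        keep = [c for c in fit.codes if c != worst]
        new_fit = fit_ols(y, X[keep])
        trace.append(
            TraceStep(step, worst, fit.adj_r2, new_fit.adj_r2,
                      "removed_sign_flip")
        )
        fit = new_fit
    return LURModel(model.species, model.season, model.phase, fit, trace)


def _prune_fixpoint(
    model: LURModel,
    y: np.ndarray,
    X: pd.DataFrame,
    registry: dict[str, PredictorSpec],
    alpha: float,
) -> LURModel:
    """Alternate significance pruning and sign-flip removal to a fixpoint."""
    while True:
        before = tuple(model.fit.codes)
        model = prune_significance(model, y, X, alpha)
        model = _remove_sign_flips(model, y, X, registry)
        if tuple(model.fit.codes) == before:
            return model


def replay_trace(
    trace: list[TraceStep], y: np.ndarray, X: pd.DataFrame
) -> OLSFit:
    """Re-apply the added/removed actions of a trace and refit."""
    current: list[str] = []
    for t in trace:
        if t.action == "added":
            current.append(t.candidate)
        elif t.action in ("removed_pvalue", "removed_sign_flip",
                          "removed_vif"):
            current.remove(t.candidate)
    return fit_ols(np.asarray(y, dtype=float), X[current])


def check_invariants(
    model: LURModel, registry: dict[str, PredictorSpec], config: SelectionConfig,
    vif_map: dict[str, float],
) -> None:
    """Raise if the emitted model violates the sign/p/VIF contract."""
    fit = model.fit
    for code, beta in fit.coefficients.items():
        if not _slope_permitted(beta, registry[code]):
            raise AssertionError(f"{code}: slope {beta} violates a-priori sign")
        if fit.p_values[code] >= config.alpha:
            raise AssertionError(f"{code}: p={fit.p_values[code]} >= alpha")
    for code, v in vif_map.items():
        if v >= config.vif_threshold:
            raise AssertionError(f"{code}: VIF={v} >= threshold")


def develop_model(
    y: np.ndarray,
    X: pd.DataFrame,
    registry: dict[str, PredictorSpec],
    coords: np.ndarray | None = None,
    config: SelectionConfig | None = None,
    rng: np.random.Generator | None = None,
    species: str = "",
    season: str = "",
    phase: str = "",
) -> tuple[LURModel, Diagnostics]:
    """Full model development: selection, pruning, diagnostics.

    Cook's distances and Moran's I (when site coordinates are supplied)
    are reported but never alter the selected model.
    """
    config = config or SelectionConfig()
    y = np.asarray(y, dtype=float)
    if len(y) < config.min_rows:
        raise ValueError(
            f"need at least {config.min_rows} observations, got {len(y)}"
        )
    model = forward_select(y, X, registry, config, species, season, phase)
    model = _prune_fixpoint(model, y, X, registry, config.alpha)

    trace = model.trace
    fit = model.fit
    step = max((t.step for t in trace), default=0)
    vif_map = vif(X[fit.codes]) if fit.p else {}
    while vif_map and max(vif_map.values()) >= config.vif_threshold:
        worst = max(vif_map, key=lambda c: (vif_map[c], c))
        step += 1
        keep = [c for c in fit.codes if c != worst]
        new_fit = fit_ols(y, X[keep])
        trace.append(TraceStep(step, worst, fit.adj_r2, new_fit.adj_r2, "removed_vif"))
        fit = new_fit
        model = _prune_fixpoint(
            LURModel(species, season, phase, fit, trace), y, X, registry,
            config.alpha,
        )
        fit, trace = model.fit, model.trace
        step = max((t.step for t in trace), default=0)
        vif_map = vif(X[fit.codes]) if fit.p else {}

    model = LURModel(species, season, phase, fit, trace)
    check_invariants(model, registry, config, vif_map)

    try:
        cooks = cooks_distance(fit, X[fit.codes])
    except ValueError:
        # a leverage-1 observation has unbounded influence: flag it as
        # infinite rather than abort the stratum
        xmat = X[fit.codes].to_numpy(dtype=float) if fit.p else np.empty((fit.n, 0))
        design = np.column_stack([np.ones(fit.n), xmat])
        h = np.einsum("ij,jk,ik->i", design, fit.xtx_inv, design)
        with np.errstate(divide="ignore", invalid="ignore"):
            cooks = (
                fit.residuals**2 / ((fit.p + 1) * fit.sigma2)
            ) * h / (1.0 - h) ** 2
        cooks = np.where(h >= 1.0 - 1e-12, np.inf, cooks)
    flags = [int(i) for i in np.nonzero(cooks >= 1.0)[0]]
    moran = None
    if coords is not None and np.ptp(fit.residuals) > 0:
        moran = morans_i(
            fit.residuals,
            coords,
            n_permutations=config.moran_permutations,
            rng=rng,
        )
    diags = Diagnostics(vif=vif_map, cooks_d=cooks, cooks_flags=flags, morans_i=moran)
    return model, diags
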