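"""Model validation and the species x season x phase batch runner.

Leave-one-out cross-validation refits the coefficients of the *fixed*
selected structure on each set of n-1 sites and predicts the held-out
site; re-running variable selection inside each fold is available behind a
flag for sensitivity analysis.  Strata are modelled only when enough of
their records exceed the detection limit (the detection gate); gated-out
strata are reported as skips, never silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .concentrations import ConcentrationRecord
from .covariates import CovariateTable
from .predictors import PredictorSpec
from .regression import fit_ols
from .selection import LURModel, SelectionConfig, develop_model, forward_select, prune_significance
from .species import PHASES, SEASONS


@dataclass
class ValidationResult:
    predictions: np.ndarray  # held-out prediction per site, ng/m^3
    observed: np.ndarray
    rmse: float
    pearson_r: float  # NaN when the predictions are constant
    n_folds: int


def rmse(observed, predicted) -> float:
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: {observed.shape} vs {predicted.shape}"
        )
    if observed.size == 0:
        raise ValueError("rmse of empty vectors")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def loocv(
    y: np.ndarray,
    X: pd.DataFrame,
    structure: list[str],
    reselect: bool = False,
    registry: dict[str, PredictorSpec] | None = None,
    config: SelectionConfig | None = None,
) -> ValidationResult:
    """Leave-one-out cross-validation of a fixed model structure.

    With ``reselect=True`` the full forward selection + significance
    pruning is re-run inside each fold (needs ``registry``).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 5:
        raise ValueError(f"LOOCV needs n >= 5, got {n}")
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xi = X.iloc[mask]
        try:
            if reselect:
                if registry is None:
                    raise ValueError("reselect=True requires a registry")
                m = forward_select(y[mask], Xi, registry, config)
                m = prune_significance(m, y[mask], Xi, (config or SelectionConfig()).alpha)
                fit = m.fit
                preds[i] = fit.predict(X.iloc[[i]][fit.codes])[0]
            else:
                fit = fit_ols(y[mask], Xi[structure])
                preds[i] = fit.predict(X.iloc[[i]][structure])[0]
        except ValueError as exc:
            raise ValueError(f"LOOCV fold for row {i} failed: {exc}") from exc
    err = rmse(y, preds)
    if np.ptp(preds) == 0.0 or np.ptp(y) == 0.0:
        warnings.warn(
            "constant held-out predictions or observations; "
            "Pearson r undefined",
            stacklevel=2,
        )
        r = float("nan")
    else:
        r = float(np.corrcoef(preds, y)[0, 1])
    return ValidationResult(preds, y, err, r, n)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k-1 df).

    All values identical across all groups is the degenerate no-signal
    case and returns (0, 1).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    allv = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if allv.size < 3:
        raise ValueError("need at least 3 observations in total")
    if np.ptp(allv) == 0.0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def detection_gate(
    records: list[ConcentrationRecord], threshold: float = 0.5
) -> tuple[bool, float]:
    """(pass, detection rate) for one stratum's records."""
    if not records:
        raise ValueError("detection gate on empty record list")
    rate = sum(r.detected for r in records) / len(records)
    return rate >= threshold, rate


@dataclass
class BatchRow:
    species: str
    season: str
    phase: str
    model: LURModel
    r2: float
    adj_r2: float
    rmse: float
    loocv_r: float
    detection_rate: float
    n: int
    cooks_flags: list[int]
    moran_i: float | None
    moran_p: float | None


@dataclass
class SkippedStratum:
    species: str
    season: str
    phase: str
    reason: str


@dataclass
class BatchReport:
    rows: list[BatchRow] = field(default_factory=list)
    skipped: list[SkippedStratum] = field(default_factory=list)

    def strata(self) -> set[tuple[str, str, str]]:
        modeled = {(r.species, r.season, r.phase) for r in self.rows}
        skipped = {(s.species, s.season, s.phase) for s in self.skipped}
        overlap = modeled & skipped
        if overlap:
            raise AssertionError(f"strata both modeled and skipped: {overlap}")
        return modeled | skipped

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "PAH": r.species,
                "Season": r.season,
                "Phase": r.phase,
                "LUR Model": r.model.equation(),
                "R2": round(r.r2, 4),
                "adj_R2": round(r.adj_r2, 4),
                "RMSE": round(r.rmse, 4),
                "LOOCV_r": round(r.loocv_r, 4) if np.isfinite(r.loocv_r) else "",
                "detection_rate": round(r.detection_rate, 4),
                "n": r.n,
            }
            for r in self.rows
        ]
        return pd.DataFrame(
            rows,
            columns=["PAH", "Season", "Phase", "LUR Model", "R2", "adj_R2",
                     "RMSE", "LOOCV_r", "detection_rate", "n"],
        )


def substitute_nondetects(
    values: np.ndarray,
    detected: np.ndarray,
    detection_limit: float,
    rule: str = "dl_sqrt2",
) -> np.ndarray:
    out = np.asarray(values, dtype=float).copy()
    sub = {
        "dl_sqrt2": detection_limit / np.sqrt(2.0),
        "dl_half": detection_limit / 2.0,
        "zero": 0.0,
    }
    if rule not in sub:
        raise ValueError(f"unknown non-detect rule {rule!r}")
    out[~np.asarray(detected, dtype=bool)] = sub[rule]
    return out


def run_batch(
    records: list[ConcentrationRecord],
    table: CovariateTable,
    registry: dict[str, PredictorSpec],
    coords: np.ndarray | None = None,
    config: SelectionConfig | None = None,
    detection_threshold: float = 0.5,
    detection_limits: dict[tuple[str, str], float] | float = 0.05,
    nondetect_rule: str = "dl_sqrt2",
    seed: int = 0,
) -> BatchReport:
    """Develop and cross-validate one model per passing stratum.

    Every stratum present in the records ends up either as a model row or
    as a skip entry (with the gate rate or the error message as reason);
    per-stratum failures never abort the batch.
    """
    config = config or SelectionConfig()
    by_stratum: dict[tuple[str, str, str], list[ConcentrationRecord]] = {}
    for r in records:
        by_stratum.setdefault((r.species, r.season, r.phase), []).append(r)

    report = BatchReport()
    order = sorted(
        by_stratum,
        key=lambda k: (k[0], SEASONS.index(k[1]) if k[1] in SEASONS else 99,
                       PHASES.index(k[2]) if k[2] in PHASES else 99),
    )
    for idx, key in enumerate(order):
        species, season, phase = key
        recs = by_stratum[key]
        ok, rate = detection_gate(recs, detection_threshold)
        if not ok:
            report.skipped.append(
                SkippedStratum(species, season, phase,
                               f"detection rate {rate:.2f} below "
                               f"threshold {detection_threshold:.2f}")
            )
            continue
        try:
            x = table.for_season(season)
            site_ids = list(x.index)
            by_site = {r.site_id: r for r in recs}
            missing = [s for s in site_ids if s not in by_site]
            if missing:
                raise ValueError(f"records missing for sites {missing}")
            vals = np.array([by_site[s].value for s in site_ids])
            det = np.array([by_site[s].detected for s in site_ids])
            dl = (
                detection_limits.get((species, season), 0.0)
                if isinstance(detection_limits, dict)
                else float(detection_limits)
            )
            y = substitute_nondetects(vals, det, dl, nondetect_rule)
            rng = np.random.default_rng([seed % (2**31), 2, idx])
            model, diags = develop_model(
                y, x[list(registry)], registry, coords=coords, config=config,
                rng=rng, species=species, season=season, phase=phase,
            )
            val = loocv(y, x, model.codes)
            report.rows.append(
                BatchRow(
                    species, season, phase, model,
                    r2=model.fit.r2, adj_r2=model.fit.adj_r2,
                    rmse=val.rmse, loocv_r=val.pearson_r,
                    detection_rate=rate, n=len(y),
                    cooks_flags=diags.cooks_flags,
                    moran_i=(diags.morans_i.observed if diags.morans_i else None),
                    moran_p=(diags.morans_i.p_value if diags.morans_i else None),
                )
            )
        except Exception as exc:
            report.skipped.append(
                SkippedStratum(species, season, phase, f"error: {exc}")
            )
    report.strata()  # assert the model-XOR-skip partition
    return report
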