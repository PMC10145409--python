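"""Season- and phase-resolved concentration generation with known truth.

Totals follow the same linear form the regression stage assumes:

    total_is = intercept + sum_j beta_j x_ij + Normal(0, noise_sd),

floored at zero, then split into gaseous and particle phases by the
logistic Kow/temperature partition.  Each phase record carries a detection
flag (value >= detection limit); non-detects are kept, not dropped, so the
downstream detection gate sees them.  A species configured
gaseous-undetectable in a season gets detected=False for every gaseous
record of that season regardless of value.

Scenario calibration targets (e.g. a windy-season gaseous mean of
16.42 ng/m^3 for acenaphthene) are honoured by solving the intercept so
that the deterministic site-mean times the phase fraction equals the
target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .covariates import CovariateTable, build_covariate_table
from .partition import partition_phase, particle_fraction
from .predictors import make_spec
from .world import GISWorld, SiteNetwork, SyntheticScenario, TrueModel


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class ConcentrationRecord:
    site_id: str
    species: str
    season: str
    phase: str  # gaseous | particle
    value: float  # ng/m^3
    detected: bool


def true_model_registry(scenario: SyntheticScenario):
    """Predictor registry spanning every code any true model references."""
    codes: set[str] = set()
    for tm in scenario.true_models.values():
        codes.update(tm.coefficients)
    registry = {}
    for code in sorted(codes):
        try:
            registry[code] = make_spec(code)
        except ValueError as exc:
            raise ConfigurationError(
                f"true model references unknown predictor code {code!r}: {exc}"
            ) from exc
    return registry


def _deterministic_totals(
    tm: TrueModel, table: CovariateTable, site_ids: list[str]
) -> np.ndarray:
    x = table.for_season(tm.season).loc[site_ids]
    vals = np.full(len(site_ids), tm.intercept)
    for code, beta in tm.coefficients.items():
        if code not in x.columns:
            raise ConfigurationError(
                f"covariate table lacks true-model predictor {code!r}"
            )
        vals = vals + beta * x[code].to_numpy(dtype=float)
    return vals


def calibrate_true_models(
    scenario: SyntheticScenario, table: CovariateTable, site_ids: list[str]
) -> dict[tuple[str, str], TrueModel]:
    """Solve intercepts so configured phase means are hit in expectation."""
    models = dict(scenario.true_models)
    by_name = scenario.species_by_name()
    for (name, season, phase), target in scenario.calibration_targets.items():
        key = (name, season)
        if key not in models:
            raise ConfigurationError(f"calibration target for unknown model {key}")
        tm = models[key]
        sp = by_name[name]
        phi = particle_fraction(
            sp, scenario.season_temperatures[season], scenario.partition
        )
        frac = phi if phase == "particle" else 1.0 - phi
        det = _deterministic_totals(tm, table, site_ids)
        slope_mean = float(det.mean() - tm.intercept)
        new_intercept = target / frac - slope_mean
        models[key] = TrueModel(
            tm.species, tm.season, new_intercept, dict(tm.coefficients),
            tm.noise_sd, tm.detection_limit, tm.phase,
        )
    return models


def generate_concentrations(
    world: GISWorld,
    network: SiteNetwork,
    scenario: SyntheticScenario,
    table: CovariateTable | None = None,
) -> list[ConcentrationRecord]:
    """Generate the full (site x species x season x 2 phases) record list.

    A covariate table restricted to the true-model predictors is built on
    the fly when none is supplied.  The RNG stream is derived from the
    scenario seed and independent of the world-generation stream.
    """
    registry = true_model_registry(scenario)
    site_ids = network.ids()
    if table is None:
        targets = [(s[0], s[1], s[2]) for s in network.sites]
        table = build_covariate_table(world, targets, registry)
    models = calibrate_true_models(scenario, table, site_ids)
    rng = np.random.default_rng([scenario.seed, 1])
    by_name = scenario.species_by_name()

    records: list[ConcentrationRecord] = []
    for sp in scenario.species:
        for season in scenario.season_temperatures:
            tm = models[(sp.name, season)]
            det = _deterministic_totals(tm, table, site_ids)
            noise = (
                rng.normal(0.0, tm.noise_sd, len(site_ids))
                if tm.noise_sd > 0
                else np.zeros(len(site_ids))
            )
            totals = np.maximum(det + noise, 0.0)
            temp = scenario.season_temperatures[season]
            gas_ok = by_name[sp.name].gaseous_detectable.get(season, True)
            for sid, total in zip(site_ids, totals):
                gas, part = partition_phase(
                    float(total), sp, temp, scenario.partition
                )
                records.append(
                    ConcentrationRecord(
                        sid, sp.name, season, "gaseous", gas,
                        bool(gas_ok and gas >= tm.detection_limit),
                    )
                )
                records.append(
                    ConcentrationRecord(
                        sid, sp.name, season, "particle", part,
                        bool(part >= tm.detection_limit),
                    )
                )
    return records
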