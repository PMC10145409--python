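"""Gas-particle partitioning of semivolatile PAHs.

The particle-bound fraction of a compound's total concentration is modelled
as a logistic function of its lipophilicity (log Kow) and of the seasonal
mean temperature:

    phi = logistic(alpha * (log_kow - kappa) + beta * (t_ref - T_season))

so that heavier (high-Kow) compounds and colder seasons push mass onto the
particle phase.  The split conserves mass exactly: gaseous + particle ==
total for every record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .species import PAHSpecies


@dataclass(frozen=True)
class PartitionParams:
    """Logistic partition parameters.

    alpha : sensitivity to log Kow (per log-unit); > 0.
    kappa : log Kow at which the split is 50/50 at the reference temperature.
    beta  : sensitivity to seasonal temperature (per degree C); > 0.
    t_ref : reference temperature, degrees C.
    """

    alpha: float = 1.5
    kappa: float = 5.5
    beta: float = 0.15
    t_ref: float = 15.0


def particle_fraction(
    species: PAHSpecies, temperature: float, params: PartitionParams
) -> float:
    """Particle-bound fraction phi in (0, 1)."""
    z = params.alpha * (species.log_kow - params.kappa) + params.beta * (
        params.t_ref - temperature
    )
    return float(1.0 / (1.0 + np.exp(-z)))


def partition_phase(
    total: float,
    species: PAHSpecies,
    temperature: float,
    params: PartitionParams | None = None,
) -> tuple[float, float]:
    """Split a total concentration (ng/m^3) into (gaseous, particle).

    Mass is conserved exactly: the gaseous part is computed as the
    remainder ``total - particle``.

    Raises
    ------
    ValueError
        If ``total`` is negative.
    """
    if total < 0:
        raise ValueError(f"total concentration must be >= 0, got {total}")
    params = params or PartitionParams()
    phi = particle_fraction(species, temperature, params)
    gaseous = total - phi * total
    # Recompute the particle part as the exact complement of the rounded
    # gaseous part so the returned pair sums to ``total`` bit-for-bit.
    particle = total - gaseous
    return gaseous, particle
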