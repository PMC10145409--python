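"""PAH species descriptors.

A species is characterised by its ring count and octanol-water partition
coefficient (log Kow), which together govern how the compound distributes
between the gaseous and particle-bound phases of the atmosphere: heavier,
more lipophilic PAHs sorb to particles, light ones stay mostly gaseous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

SEASONS = ("windy", "non-heating", "heating")
PHASES = ("gaseous", "particle")


@dataclass(frozen=True)
class PAHSpecies:
    """One polycyclic aromatic hydrocarbon.

    Parameters
    ----------
    name:
        Conventional short name, e.g. ``"Ace"`` for acenaphthene.
    ring_count:
        Number of fused aromatic rings (>= 2).
    log_kow:
        Base-10 logarithm of the octanol-water partition coefficient.
    gaseous_detectable:
        Per-season flag; a ``False`` entry marks a season in which the
        gaseous phase of this compound falls below any detection limit
        (e.g. benzo[ghi]perylene, which is essentially fully
        particle-bound).
    """

    name: str
    ring_count: int
    log_kow: float
    gaseous_detectable: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in SEASONS}
    )

    def __post_init__(self) -> None:
        if self.ring_count < 2:
            raise ValueError(
                f"{self.name}: ring_count must be >= 2, got {self.ring_count}"
            )
        unknown = set(self.gaseous_detectable) - set(SEASONS)
        if unknown:
            raise ValueError(f"{self.name}: unknown seasons {sorted(unknown)}")
        for s in SEASONS:
            self.gaseous_detectable.setdefault(s, True)


def _undetectable_all_seasons() -> dict[str, bool]:
    return {s: False for s in SEASONS}


def default_species() -> list[PAHSpecies]:
    """The 15 priority-controlled PAHs with literature ring counts / log Kow.

    Benzo[ghi]perylene is configured gaseous-undetectable in every season.
    """
    rows = [
        ("Ace", 3, 3.92),
        ("Acy", 3, 3.94),
        ("Flo", 3, 4.18),
        ("Phe", 3, 4.46),
        ("Ant", 3, 4.45),
        ("Fla", 4, 5.16),
        ("Pyr", 4, 4.88),
        ("BaA", 4, 5.76),
        ("Chr", 4, 5.81),
        ("BbF", 5, 5.78),
        ("BkF", 5, 6.11),
        ("BaP", 5, 6.13),
        ("DahA", 5, 6.75),
        ("IcdP", 6, 6.70),
        ("BghiP", 6, 6.63),
    ]
    out = []
    for name, rings, kow in rows:
        if name == "BghiP":
            out.append(
                PAHSpecies(name, rings, kow, _undetectable_all_seasons())
            )
        else:
            out.append(PAHSpecies(name, rings, kow))
    names = [s.name for s in out]
    assert len(names) == len(set(names))
    return out
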