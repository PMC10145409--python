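"""Pipeline configuration: a versioned YAML schema with validated ranges.

All analysis constants live here in one place: the adjusted-R^2 gain for
forward selection (0.01 absolute), the significance level (0.05), the VIF
threshold (5), the Cook's-distance flag level (1), the detection-gate
threshold, the buffer set, the 500 m prediction-cell size, and the seed
that drives every stochastic stage.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .predictors import DEFAULT_BUFFER_SIZES

CONFIG_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    seed: int = 0
    buffer_sizes: tuple[int, ...] = DEFAULT_BUFFER_SIZES
    gain_threshold: float = 0.01
    gain_mode: str = "absolute"
    alpha: float = 0.05
    vif_threshold: float = 5.0
    cooks_flag: float = 1.0
    detection_threshold: float = 0.5
    nondetect_rule: str = "dl_sqrt2"
    moran_permutations: int = 999
    variogram_model: str = "exponential"
    cell_size: float = 500.0
    surface_resolution: float = 500.0
    include_met: bool = False
    species: list[str] | None = None   # None = all present in the data
    seasons: list[str] | None = None
    phases: list[str] | None = None
    # [species, season, phase] triples to map; None maps every fitted model
    map_strata: list[list[str]] | None = field(
        default_factory=lambda: [
            ["Ace", "windy", "gaseous"],
            ["Flo", "heating", "gaseous"],
            ["BghiP", "heating", "particle"],
        ]
    )
    loocv_reselect: bool = False
    schema_version: int = CONFIG_SCHEMA_VERSION

    def validate(self) -> None:
        checks = [
            (0 < self.alpha < 1, "alpha", "(0, 1)", self.alpha),
            (self.gain_threshold >= 0, "gain_threshold", ">= 0", self.gain_threshold),
            (self.gain_mode in ("absolute", "relative"), "gain_mode",
             "absolute|relative", self.gain_mode),
            (self.vif_threshold > 1, "vif_threshold", "> 1", self.vif_threshold),
            (0 <= self.detection_threshold <= 1, "detection_threshold",
             "[0, 1]", self.detection_threshold),
            (self.nondetect_rule in ("dl_sqrt2", "dl_half", "zero"),
             "nondetect_rule", "dl_sqrt2|dl_half|zero", self.nondetect_rule),
            (self.moran_permutations >= 99, "moran_permutations", ">= 99",
             self.moran_permutations),
            (self.cell_size > 0, "cell_size", "> 0", self.cell_size),
            (self.surface_resolution > 0, "surface_resolution", "> 0",
             self.surface_resolution),
            (self.variogram_model in ("exponential", "spherical", "gaussian"),
             "variogram_model", "exponential|spherical|gaussian",
             self.variogram_model),
            (isinstance(self.seed, int), "seed", "integer", self.seed),
            (len(self.buffer_sizes) > 0 and all(b > 0 for b in self.buffer_sizes),
             "buffer_sizes", "non-empty, positive", self.buffer_sizes),
        ]
        for ok, fieldname, admissible, value in checks:
            if not ok:
                raise ValueError(
                    f"config field {fieldname!r}={value!r} outside admissible "
                    f"range {admissible}"
                )

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["buffer_sizes"] = list(self.buffer_sizes)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config fields {sorted(unknown)}")
        if "buffer_sizes" in data:
            data["buffer_sizes"] = tuple(data["buffer_sizes"])
        cfg = cls(**data)
        cfg.validate()
        return cfg
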