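"""Typed CSV readers/writers with schema checking.

Schemas
-------
sites.csv          : site_id, x, y, class
concentrations.csv : site_id, species, season, phase, value_ng_m3, detected
covariates.csv     : site_id, season, code, value   (long form)

Round trips are value-identical and locale-independent (decimal point).
"""

from __future__ import annotations

import pandas as pd

from .concentrations import ConcentrationRecord
from .covariates import CovariateTable
from .world import SiteNetwork

SITE_COLUMNS = ["site_id", "x", "y", "class"]
CONC_COLUMNS = ["site_id", "species", "season", "phase", "value_ng_m3", "detected"]
COV_COLUMNS = ["site_id", "season", "code", "value"]


class SchemaError(ValueError):
    pass


def _check_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def write_sites(network: SiteNetwork, path) -> None:
    pd.DataFrame(network.sites, columns=SITE_COLUMNS).to_csv(path, index=False)


def read_sites(path) -> SiteNetwork:
    df = pd.read_csv(path)
    _check_columns(df, SITE_COLUMNS, path)
    ids = df["site_id"].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].tolist()
        raise SchemaError(f"{path}: duplicate site ids {dup}")
    return SiteNetwork(
        [
            (str(r.site_id), float(r.x), float(r.y), str(r["class"]))
            for _, r in df.iterrows()
        ]
    )


def write_concentrations(records: list[ConcentrationRecord], path) -> None:
    df = pd.DataFrame(
        [
            (r.site_id, r.species, r.season, r.phase, r.value, r.detected)
            for r in records
        ],
        columns=CONC_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_concentrations(path) -> list[ConcentrationRecord]:
    df = pd.read_csv(path)
    _check_columns(df, CONC_COLUMNS, path)
    bad = df.index[df["value_ng_m3"] < 0].tolist()
    if bad:
        raise SchemaError(f"{path}: negative concentrations at rows {bad}")
    return [
        ConcentrationRecord(
            str(r.site_id), str(r.species), str(r.season), str(r.phase),
            float(r.value_ng_m3), bool(r.detected),
        )
        for _, r in df.iterrows()
    ]


def write_covariates(table: CovariateTable, path) -> None:
    table.to_long().to_csv(path, index=False)


def read_covariates(path) -> CovariateTable:
    df = pd.read_csv(path)
    _check_columns(df, COV_COLUMNS, path)
    df["site_id"] = df["site_id"].astype(str)
    return CovariateTable.from_long(df)
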