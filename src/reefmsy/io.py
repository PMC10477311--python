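"""Flat-file interchange: site tables, posterior draws and structured reports.

Sites travel as one CSV row per surveyed reef (documented header below); posterior
draws as a flat (chain, draw, parameter...) CSV with a JSON sidecar carrying the
surplus family and the standardization constants, so reference-point propagation can
be rerun on new sites without refitting.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .design import CATEGORIES, CENSUS_METHODS, HABITATS, StandardizationSpec
from .model import PosteriorDraws
from .surplus import SurplusModel

log = logging.getLogger("reefmsy")

MANDATORY_COLUMNS = (
    "site_id", "jurisdiction_id", "category", "biomass_obs", "ocean_prod", "sst",
    "coral_cover", "atoll", "habitat", "depth", "census_method", "sampling_area", "gravity",
)
OPTIONAL_COLUMNS = ("reserve_age", "reserve_size", "catch_obs", "travel_time_h", "uninhabited")


def read_sites(path) -> pd.DataFrame:
    """Read and validate a site CSV.

    Mandatory columns must be present (error names the first missing one); unknown
    categorical levels raise with the offending rows; rows with non-positive biomass
    are dropped with a log entry; unknown extra columns are preserved.
    """
    table = pd.read_csv(path)
    for col in MANDATORY_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"site file {path} is missing mandatory column {col!r}")
    if len(table) == 0:
        warnings.warn(f"site file {path} has a header but no rows", stacklevel=2)
        return table
    for col, levels in (("category", CATEGORIES), ("habitat", HABITATS), ("census_method", CENSUS_METHODS)):
        bad = ~table[col].astype(str).isin(levels)
        if bad.any():
            rows = table.index[bad].tolist()[:20]
            raise ValueError(f"unknown {col} level(s) {sorted(set(table.loc[bad, col]))} in rows {rows}")
    bad_b = ~(table["biomass_obs"].astype(float) > 0)
    if bad_b.any():
        log.warning("dropping %d row(s) with non-positive biomass", int(bad_b.sum()))
        table = table[~bad_b].reset_index(drop=True)
    log.info("read %d sites (%s); missing coral cover: %d",
             len(table), dict(table["category"].value_counts()), int(table["coral_cover"].isna().sum()))
    return table


def write_sites(table: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def save_draws(draws: PosteriorDraws, path) -> None:
    """Posterior draws to CSV plus a '<stem>.meta.json' sidecar (family,
    standardization constants, jurisdiction labels)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    draws.to_dataframe().to_csv(path, index=False)
    meta = {
        "family": draws.model.family,
        "n_exponent": draws.model.n_exponent,
        "jurisdictions": list(draws.jurisdictions),
        "standardization": draws.spec.to_dict(),
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def load_draws(path) -> PosteriorDraws:
    path = Path(path)
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    model = SurplusModel(meta["family"], meta["n_exponent"])
    spec = StandardizationSpec.from_dict(meta["standardization"])
    return PosteriorDraws.from_dataframe(pd.read_csv(path), model, spec)
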