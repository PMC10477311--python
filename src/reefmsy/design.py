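"""Covariate standardization and design-matrix construction.

Continuous environmental covariates (ocean productivity, SST, hard-coral cover),
sampling covariates (depth, sampling area) and reserve size are mean-centered and
divided by *two* standard deviations, so their effect sizes are comparable to those of
the 0/1 dummies.  Gravity is deliberately left unstandardized (not centered): the
model intercepts then correspond to zero human pressure, which is what makes the
recovered B0 an *unfished* baseline.  Categorical covariates become 0/1 dummies with
slope habitat and belt transects as the reference levels.  Missing coral cover is
imputed at the covariate mean (hence standardized value 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HABITATS = ("slope", "crest", "flat", "lagoon_backreef")
CENSUS_METHODS = ("belt", "point_count", "distance")
CATEGORIES = ("reserve", "remote", "restricted", "open")

# continuous covariates standardized as (x - mean) / (2 sd)
STANDARDIZED = ("ocean_prod", "sst", "coral_cover", "depth", "sampling_area", "reserve_size")

ENV_COLUMNS = ("ocean_prod", "sst", "atoll", "coral_cover")
SAMPLING_COLUMNS = (
    "depth",
    "habitat_crest",
    "habitat_lagoon_backreef",
    "habitat_flat",
    "census_point_count",
    "census_distance",
    "sampling_area",
)


@dataclass
class StandardizationSpec:
    """Per-covariate centering/scaling constants; round-trippable to plain dicts."""

    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    not_centered: tuple[str, ...] = ("gravity",)

    def transform(self, name: str, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean[name]) / (2.0 * self.sd[name])

    def to_dict(self) -> dict:
        return {"mean": dict(self.mean), "sd": dict(self.sd), "not_centered": list(self.not_centered)}

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationSpec":
        return cls(mean=dict(d["mean"]), sd=dict(d["sd"]), not_centered=tuple(d["not_centered"]))


@dataclass
class DesignMatrices:
    """Standardized per-site design blocks, aligned with the input table's rows."""

    env: np.ndarray        # (n, 4): ocean_prod, sst, atoll, coral  (coral imputed)
    sampling: np.ndarray   # (n, 7): depth, crest, lagoon/backreef, flat, point-count, distance, area
    reserve_size: np.ndarray  # (n,), standardized; 0 where undefined
    gravity: np.ndarray    # (n,), untransformed
    spec: StandardizationSpec


def fit_standardization(table: pd.DataFrame) -> StandardizationSpec:
    """Estimate centering/scaling constants from a site table.

    Reserve size statistics are taken over reserve rows only (the covariate is
    undefined elsewhere); coral-cover statistics ignore missing values, which are
    imputed at the mean downstream.
    """
    spec = StandardizationSpec()
    for name in STANDARDIZED:
        if name == "reserve_size":
            x = table.loc[table["category"] == "reserve", name].dropna()
        else:
            x = table[name].dropna()
        if len(x) == 0:
            continue
        m, s = float(np.mean(x)), float(np.std(x, ddof=0))
        if s == 0.0:
            raise ValueError(f"covariate {name!r} has zero variance; cannot standardize")
        spec.mean[name] = m
        spec.sd[name] = s
    return spec


def build_design(table: pd.DataFrame, spec: StandardizationSpec | None = None) -> DesignMatrices:
    """Assemble the standardized design blocks for every row of ``table``.

    Pass the ``spec`` from a previous fit to standardize new sites on the same scale
    (e.g. when propagating posterior draws to sites not in the fitting data).
    """
    if spec is None:
        spec = fit_standardization(table)
    n = len(table)

    coral = table["coral_cover"].to_numpy(dtype=float)
    coral = np.where(np.isnan(coral), spec.mean["coral_cover"], coral)
    env = np.column_stack(
        [
            spec.transform("ocean_prod", table["ocean_prod"].to_numpy(dtype=float)),
            spec.transform("sst", table["sst"].to_numpy(dtype=float)),
            table["atoll"].to_numpy(dtype=float),
            spec.transform("coral_cover", coral),
        ]
    )

    habitat = table["habitat"].astype(str)
    census = table["census_method"].astype(str)
    bad_h = set(habitat) - set(HABITATS)
    if bad_h:
        raise ValueError(f"unknown habitat level(s) {sorted(bad_h)}")
    bad_c = set(census) - set(CENSUS_METHODS)
    if bad_c:
        raise ValueError(f"unknown census method(s) {sorted(bad_c)}")
    sampling = np.column_stack(
        [
            spec.transform("depth", table["depth"].to_numpy(dtype=float)),
            (habitat == "crest").to_numpy(dtype=float),
            (habitat == "lagoon_backreef").to_numpy(dtype=float),
            (habitat == "flat").to_numpy(dtype=float),
            (census == "point_count").to_numpy(dtype=float),
            (census == "distance").to_numpy(dtype=float),
            spec.transform("sampling_area", table["sampling_area"].to_numpy(dtype=float)),
        ]
    )

    size = np.zeros(n)
    if "reserve_size" in spec.mean:
        raw = table["reserve_size"].to_numpy(dtype=float)
        with_size = ~np.isnan(raw)
        size[with_size] = spec.transform("reserve_size", raw[with_size])

    gravity = table["gravity"].to_numpy(dtype=float)
    if np.any(np.isnan(gravity)) or np.any(gravity < 0):
        raise ValueError("gravity must be present and non-negative for all sites")

    return DesignMatrices(env=env, sampling=sampling, reserve_size=size, gravity=gravity, spec=spec)
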