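"""Synthetic reef-survey data with the statistical structure the joint model assumes.

One run produces a flat site table with three subsets — marine reserves of varying age
(recovering along a common trajectory), remote uninhabited reefs (at unfished biomass)
and fished reefs (openly fished or gear-restricted) — plus a truth record holding the
generating parameters and per-site latent quantities.  Covariates are drawn from the
same distributions in every subset so that the space-for-time substitution is not
confounded by covariate non-overlap.  Catches for fished sites are scattered
lognormally around a per-site multiple of the latent surplus; the exploitation-factor
mixture is chosen so that all four fishery-status categories occur.  Catch generation
is test scaffolding for the assessment stage, not part of the biomass model itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .design import build_design, DesignMatrices
from .params import ModelParams
from .surplus import CommunityParams, SurplusModel, mmsy, recovery_trajectory, surplus

__all__ = ["DatasetDesign", "TruthRecord", "simulate_dataset", "label_remote", "desk_design", "paper_design"]


@dataclass
class DatasetDesign:
    """Sample sizes and covariate distributions for one synthetic seascape."""

    n_reserve: int = 70
    n_remote: int = 80
    n_fished: int = 1903
    n_jurisdictions: int = 30
    restricted_fraction: float = 0.3
    # covariate distributions (identical across subsets, bar the structural zeros)
    sst_mean: float = 28.0
    sst_sd: float = 1.2            # °C
    ocean_prod_logmean: float = np.log(600.0)
    ocean_prod_logsd: float = 0.4  # mg C m^-2 d^-1
    coral_a: float = 2.0
    coral_b: float = 3.0           # Beta shape for proportional cover
    p_atoll: float = 0.25
    depth_min: float = 2.0
    depth_max: float = 18.0        # m
    sampling_area_logmean: float = np.log(500.0)
    sampling_area_logsd: float = 0.5   # m²
    reserve_age_min: float = 0.5
    reserve_age_max: float = 40.0  # years
    reserve_size_logmean: float = np.log(2.0)
    reserve_size_logsd: float = 1.0    # km²
    gravity_logmean: float = np.log(5.0)
    gravity_logsd: float = 1.0
    remote_travel_min: float = 21.0
    remote_travel_max: float = 80.0    # h
    fished_travel_max: float = 19.0
    habitat_probs: tuple = (0.40, 0.25, 0.20, 0.15)   # slope, crest, flat, lagoon/backreef
    census_probs: tuple = (0.70, 0.15, 0.15)          # belt, point count, distance
    missing_coral_rate: float = 0.10
    # catch scaffolding: C = surplus(B_latent) * factor * LN(0, sigma_catch)
    exploitation_factors: tuple = (0.3, 0.8, 1.3, 2.5)
    exploitation_probs: tuple = (0.35, 0.25, 0.20, 0.20)
    sigma_catch: float = 0.3

    def __post_init__(self) -> None:
        if min(self.n_reserve, self.n_remote, self.n_fished) < 0:
            raise ValueError("subset counts must be non-negative")
        if self.n_jurisdictions < 1:
            raise ValueError("need at least one jurisdiction")
        if abs(sum(self.exploitation_probs) - 1.0) > 1e-9:
            raise ValueError("exploitation_probs must sum to 1")


def paper_design() -> DatasetDesign:
    """Full-scale design: 70 reserves, 80 remote reefs, 1903 fished sites."""
    return DatasetDesign()


def desk_design() -> DatasetDesign:
    """Small design (30 reserves / 20 remote / 100 fished) for fast runs."""
    return DatasetDesign(n_reserve=30, n_remote=20, n_fished=100, n_jurisdictions=8)


@dataclass
class TruthRecord:
    """Everything needed to reproduce and verify one synthetic dataset."""

    params: ModelParams
    design: DatasetDesign
    seed: int
    model: SurplusModel
    B0_site: np.ndarray = field(repr=False, default=None)   # latent env-conditioned B0 per site
    mu: np.ndarray = field(repr=False, default=None)        # expected log-biomass per site
    B_latent: np.ndarray = field(repr=False, default=None)  # sampling-marginalized latent biomass
    designs: DesignMatrices = field(repr=False, default=None)

    def config_dict(self) -> dict:
        def clean(v):
            if isinstance(v, (tuple, list)):
                return [clean(x) for x in v]
            if isinstance(v, dict):
                return {k: clean(x) for k, x in v.items()}
            if isinstance(v, (np.floating, float)):
                return float(v)
            if isinstance(v, (np.integer, int)):
                return int(v)
            return v

        d = {"seed": self.seed, "family": self.model.family, "n_exponent": self.model.n_exponent}
        d["params"] = clean(asdict(self.params))
        d["design"] = clean(asdict(self.design))
        return d


def label_remote(travel_time_h, uninhabited, threshold_h: float = 20.0):
    """A reef counts as remote iff it is uninhabited and > ``threshold_h`` hours from
    the nearest settlement.  Missing travel time labels the site not-remote with a
    warning rather than failing."""
    tt = np.asarray(travel_time_h, dtype=float)
    uninh = np.asarray(uninhabited, dtype=bool)
    missing = np.isnan(tt)
    if np.any(missing):
        warnings.warn("missing travel time: site(s) labelled not-remote", stacklevel=2)
    out = np.where(missing, False, (tt > threshold_h) & uninh)
    return bool(out) if out.ndim == 0 else out


def _draw_shared_covariates(rng, n, d: DatasetDesign, habitats, methods, hab_probs, cen_probs):
    return {
        "sst": rng.normal(d.sst_mean, d.sst_sd, n),
        "ocean_prod": rng.lognormal(d.ocean_prod_logmean, d.ocean_prod_logsd, n),
        "coral_cover": rng.beta(d.coral_a, d.coral_b, n),
        "atoll": rng.random(n) < d.p_atoll,
        "habitat": rng.choice(habitats, size=n, p=hab_probs),
        "depth": rng.uniform(d.depth_min, d.depth_max, n),
        "census_method": rng.choice(methods, size=n, p=cen_probs),
        "sampling_area": rng.lognormal(d.sampling_area_logmean, d.sampling_area_logsd, n),
    }


def simulate_dataset(
    params: ModelParams | None = None,
    design: DatasetDesign | None = None,
    seed: int = 0,
    model: SurplusModel = SurplusModel.fox(),
) -> tuple[pd.DataFrame, TruthRecord]:
    """Draw one synthetic seascape.

    Expected log-biomass is computed exactly from the generating parameters and the
    standardized covariates (reserves follow the family's recovery trajectory from
    Bmin with environment acting on B0; remote reefs sit at their env-conditioned B0;
    fished reefs around the fished intercept with jurisdiction random intercepts),
    then observed biomass is drawn lognormally.  Identical seeds give identical
    tables.
    """
    params = params or ModelParams()
    design = design or DatasetDesign()
    rng = np.random.default_rng(seed)
    d = design
    n_i, n_j, n_z = d.n_reserve, d.n_remote, d.n_fished
    n = n_i + n_j + n_z

    p_hab = np.asarray(d.habitat_probs, dtype=float)
    p_cen = np.asarray(d.census_probs, dtype=float)
    habs = ["slope", "crest", "flat", "lagoon_backreef"]
    cens = ["belt", "point_count", "distance"]

    rows = {}
    # reserves: no distance sampling (that dummy is absent from the reserve mean)
    res_cen = p_cen[:2] / p_cen[:2].sum()
    rows["reserve"] = _draw_shared_covariates(rng, n_i, d, habs, cens[:2], p_hab, res_cen)
    # remote: no flat habitat and no point counts (absent from the remote mean)
    rem_hab = np.array([p_hab[0], p_hab[1], p_hab[3]])
    rem_hab /= rem_hab.sum()
    rem_cen = np.array([p_cen[0], p_cen[2]])
    rem_cen /= rem_cen.sum()
    rows["remote"] = _draw_shared_covariates(
        rng, n_j, d, ["slope", "crest", "lagoon_backreef"], ["belt", "distance"], rem_hab, rem_cen
    )
    rows["fished"] = _draw_shared_covariates(rng, n_z, d, habs, cens, p_hab, p_cen)

    table = pd.DataFrame(
        {
            "site_id": [f"s{k:05d}" for k in range(n)],
            "category": (["reserve"] * n_i) + (["remote"] * n_j) + ([""] * n_z),
        }
    )
    for col in ("sst", "ocean_prod", "coral_cover", "atoll", "habitat", "depth", "census_method", "sampling_area"):
        table[col] = np.concatenate([np.asarray(rows[g][col]) for g in ("reserve", "remote", "fished")])

    fished_cat = np.where(rng.random(n_z) < d.restricted_fraction, "restricted", "open")
    table.loc[n_i + n_j :, "category"] = fished_cat

    # jurisdictions for everyone (assessment aggregates over them)
    jur = rng.integers(0, d.n_jurisdictions, n)
    table["jurisdiction_id"] = [f"J{k:02d}" for k in jur]

    table["reserve_age"] = np.nan
    table.loc[: n_i - 1, "reserve_age"] = rng.uniform(d.reserve_age_min, d.reserve_age_max, n_i)
    table["reserve_size"] = np.nan
    table.loc[: n_i - 1, "reserve_size"] = rng.lognormal(d.reserve_size_logmean, d.reserve_size_logsd, n_i)

    gravity = rng.lognormal(d.gravity_logmean, d.gravity_logsd, n)
    gravity[n_i : n_i + n_j] = 0.0  # remote reefs have zero human pressure
    table["gravity"] = gravity
    travel = rng.uniform(0.2, d.fished_travel_max, n)
    travel[n_i : n_i + n_j] = rng.uniform(d.remote_travel_min, d.remote_travel_max, n_j)
    table["travel_time_h"] = travel
    table["uninhabited"] = np.concatenate([np.zeros(n_i, bool), np.ones(n_j, bool), np.zeros(n_z, bool)])

    # missing coral (fished subset only) exercises the mean-imputation path
    miss = rng.random(n_z) < d.missing_coral_rate
    idx_fished = np.arange(n_i + n_j, n)
    table.loc[idx_fished[miss], "coral_cover"] = np.nan

    dm = build_design(table)
    env_eff = dm.env @ params.env_beta()
    samp_eff = dm.sampling @ params.sampling_beta()
    log_B0_site = np.log(params.B0) + env_eff

    # jurisdiction random intercepts (draw any not supplied)
    jur_labels = sorted(table["jurisdiction_id"].unique())
    u = dict(params.u)
    missing_labels = [c for c in jur_labels if c not in u]
    draws = rng.normal(0.0, params.sigma_u, len(missing_labels))
    u.update({c: float(v) for c, v in zip(missing_labels, draws)})
    params = params.with_(u=u)
    u_site = np.array([u[c] for c in table["jurisdiction_id"]])

    mu = np.empty(n)
    ages = table["reserve_age"].to_numpy(float)[:n_i]
    B0_res = np.exp(log_B0_site[:n_i])
    traj = np.array(
        [recovery_trajectory(t, b0, params.Bmin, params.r, model) for t, b0 in zip(ages, B0_res)]
    )
    mu[:n_i] = (
        np.log(traj)
        + samp_eff[:n_i]
        + params.beta_reserve_size * dm.reserve_size[:n_i]
        + params.beta_gravity * dm.gravity[:n_i]
    )
    mu[n_i : n_i + n_j] = log_B0_site[n_i : n_i + n_j] + samp_eff[n_i : n_i + n_j]
    mu[n_i + n_j :] = (
        params.gamma
        + samp_eff[n_i + n_j :]
        + params.beta_gravity * dm.gravity[n_i + n_j :]
        + u_site[n_i + n_j :]
    )

    sigma = np.concatenate(
        [np.full(n_i, params.sigma_i), np.full(n_j, params.sigma_j), np.full(n_z, params.sigma_z)]
    )
    table["biomass_obs"] = np.exp(rng.normal(mu, sigma))

    # latent sampling-marginalized biomass (what status assessment should recover)
    B_latent = np.empty(n)
    B_latent[:n_i] = traj * np.exp(
        params.beta_reserve_size * dm.reserve_size[:n_i] + params.beta_gravity * dm.gravity[:n_i]
    )
    B_latent[n_i : n_i + n_j] = np.exp(log_B0_site[n_i : n_i + n_j])
    B_latent[n_i + n_j :] = np.exp(mu[n_i + n_j :] - samp_eff[n_i + n_j :])

    # catches for fished sites around a multiple of the latent surplus
    table["catch_obs"] = np.nan
    factors = rng.choice(d.exploitation_factors, size=n_z, p=d.exploitation_probs)
    B0_fz = np.exp(log_B0_site[n_i + n_j :])
    Bz = np.clip(B_latent[n_i + n_j :], 1.001, 0.999 * B0_fz)
    P = np.array(
        [surplus(b, CommunityParams(b0, params.r), model) for b, b0 in zip(Bz, B0_fz)]
    )
    floor = 0.02 * np.array([mmsy(CommunityParams(b0, params.r), model) for b0 in B0_fz])
    P = np.maximum(P, floor)
    table.loc[idx_fished, "catch_obs"] = P * factors * rng.lognormal(0.0, d.sigma_catch, n_z)

    truth = TruthRecord(
        params=params, design=design, seed=seed, model=model,
        B0_site=np.exp(log_B0_site), mu=mu, B_latent=B_latent, designs=dm,
    )
    return table, truth


def default_ecosystem_coeffs() -> dict:
    """Generating coefficients for the four ecosystem metrics.

    Link-scale intercepts at reference conditions; ``biomass_slope`` couples each
    metric to log standing biomass so metric-vs-biomass trade-off curves have
    structure.  Scraping has a hurdle zero process (~40% structural zeros at
    reference conditions)."""
    base_slopes = {
        "habitat_flat": -0.10, "habitat_crest": -0.05, "habitat_backreef": -0.10,
        "depth": 0.05, "ocean_prod": 0.10, "census_distance": -0.05,
        "census_point_count": 0.05, "sampling_area": 0.08, "atoll": 0.10,
        "sst": -0.08, "gravity": -0.01,
    }
    return {
        "length": {"intercept": np.log(22.0), "slopes": dict(base_slopes), "sigma": 0.15,
                   "sigma_u": 0.10, "biomass_slope": 0.12},
        "richness": {"intercept": np.log(60.0), "slopes": dict(base_slopes), "sigma": 0.20,
                     "sigma_u": 0.10, "biomass_slope": 0.18},
        "predators": {"intercept": -1.5, "slopes": {k: 4 * v for k, v in base_slopes.items()},
                      "sigma_u": 0.30, "biomass_slope": 1.2},
        "scraping": {"intercept": np.log(60.0), "slopes": dict(base_slopes), "sigma": 0.40,
                     "sigma_u": 0.15, "biomass_slope": 0.25,
                     "zero_intercept": -0.4, "zero_slopes": {k: 0.0 for k in base_slopes}},
    }


def simulate_ecosystem_metrics(
    table: pd.DataFrame, coeffs: dict | None = None, seed: int = 0
) -> pd.DataFrame:
    """Per-site ecosystem metrics generated from multilevel link-scale regressions.

    Mean fish length (cm) and total richness are lognormal, top-predator presence
    Bernoulli-logit, parrotfish scraping hurdle-lognormal (mm²/min/m²); all share
    jurisdiction random intercepts and the site covariates of ``table``.
    """
    from .ecosystem import _metric_design

    coeffs = coeffs or default_ecosystem_coeffs()
    rng = np.random.default_rng(seed)
    X, _ = _metric_design(table)
    logB = np.log(table["biomass_obs"].to_numpy(dtype=float))
    logB = logB - logB.mean()
    jur = table["jurisdiction_id"].astype(str).to_numpy()
    labels = sorted(set(jur))

    out = table[["site_id", "jurisdiction_id", "category", "biomass_obs", "gravity",
                 "habitat", "census_method", "depth", "sampling_area", "ocean_prod",
                 "sst", "atoll"]].copy()
    for metric, c in coeffs.items():
        u = dict(zip(labels, rng.normal(0.0, c["sigma_u"], len(labels))))
        eta = c["intercept"] + c["biomass_slope"] * logB + np.array([u[j] for j in jur])
        for name, b in c["slopes"].items():
            eta += b * X[name].to_numpy(dtype=float)
        if metric == "predators":
            out["top_predator"] = (rng.random(len(table)) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
        elif metric == "scraping":
            zeta = c["zero_intercept"] + sum(
                b * X[n].to_numpy(dtype=float) for n, b in c["zero_slopes"].items()
            )
            is_zero = rng.random(len(table)) < 1.0 / (1.0 + np.exp(-zeta))
            vals = np.exp(rng.normal(eta, c["sigma"]))
            out["scraping"] = np.where(is_zero, 0.0, vals)
        else:
            col = "mean_length" if metric == "length" else "richness"
            out[col] = np.exp(rng.normal(eta, c["sigma"]))
    return out
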