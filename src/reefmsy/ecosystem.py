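"""Ecosystem metrics along the surplus-production biomass gradient.

Four ecosystem metrics accompany the production assessment: community mean fish
length, total species richness (corrected for unseen species via a Poisson-lognormal
species-abundance fit), presence of top predators, and parrotfish scraping potential
(density x feeding rate x bite area).  Each metric is regressed on the sampling and
environmental covariates plus gravity with jurisdiction random intercepts — gaussian
on the log scale for length and richness, Bernoulli-logit for predator presence, and
a hurdle-lognormal for scraping (a Bernoulli zero process plus a lognormal for
positive values).  Marginalizing the metrics and biomass to common reference
conditions and smoothing metric-vs-biomass with penalized splines yields trade-off
curves: the expected relative change in each metric between unfished biomass, B_MMSY
and the PGMY biomass bounds.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2, norm

import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "PLNFit",
    "estimate_total_richness",
    "load_default_rate_table",
    "scraping_potential",
    "GlmmFit",
    "fit_metric_model",
    "marginalize_metric",
    "tradeoff_curve",
    "METRIC_COVARIATES",
]

# ---------------------------------------------------------------------------
# Poisson-lognormal species richness


@dataclass
class PLNFit:
    mu: float
    sigma: float
    p0: float                 # veil probability: P(species unobserved)
    richness_observed: int
    richness_estimate: float
    well_fitting: bool
    gof_pvalue: float


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(60)


def _pln_logpmf(k: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """log P(K=k) under K ~ Poisson(lam), log lam ~ N(mu, sigma); Gauss-Hermite."""
    k = np.asarray(k, dtype=float)
    loglam = mu + np.sqrt(2.0) * sigma * _GH_NODES          # (q,)
    logpois = (
        k[:, None] * loglam[None, :] - np.exp(loglam)[None, :] - gammaln(k + 1.0)[:, None]
    )
    return logsumexp(logpois + np.log(_GH_WEIGHTS)[None, :], axis=1) - 0.5 * np.log(np.pi)


def estimate_total_richness(counts, alpha: float = 0.05) -> PLNFit:
    """Total species richness from one site's species-abundance counts.

    A zero-truncated Poisson-lognormal is fitted by maximum likelihood to the
    observed counts; the fitted veil probability p0 (chance a species present in the
    community went unobserved) inflates observed richness to S_obs / (1 - p0).
    Sites with a single species (or a degenerate fit) return observed richness,
    flagged as poorly fitting; fit quality is a chi-square test on pooled abundance
    octaves at level ``alpha``.
    """
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    s_obs = len(counts)
    if s_obs < 2:
        return PLNFit(np.nan, np.nan, 0.0, s_obs, float(s_obs), False, np.nan)

    def nll(theta):
        mu, logsig = theta
        sig = np.exp(logsig)
        lp = _pln_logpmf(counts, mu, sig)
        lp0 = _pln_logpmf(np.array([0.0]), mu, sig)[0]
        if lp0 >= 0.0:
            return 1e10
        return -(np.sum(lp) - s_obs * np.log1p(-np.exp(lp0)))

    logc = np.log(counts)
    init = np.array([np.mean(logc), np.log(max(np.std(logc), 0.3))])
    res = minimize(nll, init, method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    mu, sigma = res.x[0], float(np.exp(res.x[1]))
    p0 = float(np.exp(_pln_logpmf(np.array([0.0]), mu, sigma)[0]))
    estimate = s_obs / (1.0 - p0)

    # goodness of fit on octave classes 1, 2, 3-4, 5-8, 9-16, ...
    edges = [1, 2]
    while edges[-1] <= counts.max():
        edges.append(2 * edges[-1] - 1)
    edges = np.unique(np.asarray(edges + [int(counts.max()) + 1]))
    obs_freq, _ = np.histogram(counts, bins=edges)
    kk = np.arange(1, edges[-1])
    pk = np.exp(_pln_logpmf(kk, mu, sigma))
    pk /= pk.sum()
    exp_freq = np.array([pk[(kk >= lo) & (kk < hi)].sum() for lo, hi in zip(edges[:-1], edges[1:])]) * s_obs
    keep = exp_freq > 1e-9
    stat = np.sum((obs_freq[keep] - exp_freq[keep]) ** 2 / exp_freq[keep])
    df = max(int(keep.sum()) - 1 - 2, 1)
    pval = float(chi2.sf(stat, df))
    ok = bool(res.success) and pval >= alpha
    return PLNFit(float(mu), sigma, p0, s_obs, float(estimate), ok, pval)


def simulate_species_counts(n_species: int, mu: float, sigma: float, seed: int = 0) -> np.ndarray:
    """Community of ``n_species`` with Poisson-lognormal abundances; only species
    with at least one observed individual are returned (the veiled tail is lost)."""
    rng = np.random.default_rng(seed)
    lam = np.exp(rng.normal(mu, sigma, n_species))
    counts = rng.poisson(lam)
    return counts[counts > 0]


# ---------------------------------------------------------------------------
# parrotfish scraping potential


def load_default_rate_table() -> pd.DataFrame:
    """Bundled synthetic species-by-size feeding-rate and bite-area table.

    The values are plausible magnitudes for scarids (bites/min declining and bite
    area growing with body size) but are synthetic placeholders, meant to be
    replaced with measured rates; the file is an editable CSV asset.
    """
    with importlib.resources.files("reefmsy.data").joinpath("parrotfish_rates_synthetic.csv").open() as fh:
        return pd.read_csv(fh)


def scraping_potential(census: pd.DataFrame, rates: pd.DataFrame | None = None) -> float:
    """Area grazed per minute per m² of reef: sum over species-size classes of
    density (ind/m²) x feeding rate (bites/min) x bite area (mm²).

    Census rows missing from the rate table fall back to the genus mean (genus =
    first token of the species name); classes without even a genus match raise,
    listing the offenders.  An empty census (no parrotfish) scores zero.
    """
    if len(census) == 0:
        return 0.0
    rates = rates if rates is not None else load_default_rate_table()
    key = ["species", "size_class"]
    merged = census.merge(rates, on=key, how="left")
    missing = merged["bites_per_min"].isna()
    if missing.any():
        rate_genus = rates.assign(genus=rates["species"].str.split().str[0])
        genus_means = rate_genus.groupby(["genus", "size_class"])[["bites_per_min", "bite_area_mm2"]].mean()
        for idx in merged.index[missing]:
            g = str(merged.loc[idx, "species"]).split()[0]
            sc = merged.loc[idx, "size_class"]
            if (g, sc) in genus_means.index:
                merged.loc[idx, ["bites_per_min", "bite_area_mm2"]] = genus_means.loc[(g, sc)].to_numpy()
    still = merged["bites_per_min"].isna()
    if still.any():
        bad = merged.loc[still, key].to_records(index=False).tolist()
        raise KeyError(f"no feeding-rate entry (species or genus) for classes: {bad}")
    return float((merged["density_ind_m2"] * merged["bites_per_min"] * merged["bite_area_mm2"]).sum())


# ---------------------------------------------------------------------------
# metric regressions

METRIC_COVARIATES = (
    "habitat_flat", "habitat_crest", "habitat_backreef", "depth", "ocean_prod",
    "census_distance", "census_point_count", "sampling_area", "atoll", "sst", "gravity",
)
_STANDARDIZED_COVS = ("depth", "ocean_prod", "sampling_area", "sst")
_RESPONSES = {"length": "mean_length", "richness": "richness", "predators": "top_predator", "scraping": "scraping"}


@dataclass
class GlmmFit:
    metric: str
    family: str                      # gaussian_log | bernoulli | hurdle_lognormal
    intercept: float
    slopes: dict[str, float]
    u: dict[str, float]
    sigma: float | None = None
    delta: float | None = None       # hurdle: structural-zero probability (mean)
    zero_intercept: float | None = None
    zero_slopes: dict[str, float] | None = None
    cov_scale: dict[str, tuple[float, float]] = field(default_factory=dict)

    def linear_predictor(self, X: pd.DataFrame, include_intercept: bool = True) -> np.ndarray:
        eta = np.zeros(len(X)) + (self.intercept if include_intercept else 0.0)
        for name, b in self.slopes.items():
            eta += b * X[name].to_numpy(dtype=float)
        return eta


def _metric_design(records: pd.DataFrame, scale: dict | None = None):
    """Covariate frame for the ecosystem regressions (2 SD standardization, like the
    biomass model; gravity untransformed)."""
    X = pd.DataFrame(index=records.index)
    hab = records["habitat"].astype(str)
    X["habitat_flat"] = (hab == "flat").astype(float)
    X["habitat_crest"] = (hab == "crest").astype(float)
    X["habitat_backreef"] = (hab == "lagoon_backreef").astype(float)
    cen = records["census_method"].astype(str)
    X["census_distance"] = (cen == "distance").astype(float)
    X["census_point_count"] = (cen == "point_count").astype(float)
    X["atoll"] = records["atoll"].astype(float)
    X["gravity"] = records["gravity"].astype(float)
    out_scale = {} if scale is None else dict(scale)
    for cov in _STANDARDIZED_COVS:
        x = records[cov].to_numpy(dtype=float)
        if scale is None:
            m, s = float(np.mean(x)), float(np.std(x))
            if s == 0:
                raise ValueError(f"covariate {cov!r} has zero variance")
            out_scale[cov] = (m, s)
        m, s = out_scale[cov]
        X[cov] = (x - m) / (2.0 * s)
    return X[list(METRIC_COVARIATES)], out_scale


def fit_metric_model(records: pd.DataFrame, metric: str) -> GlmmFit:
    """Multilevel regression of one ecosystem metric on sampling, environmental and
    gravity covariates with jurisdiction random intercepts.

    Gaussian on log response for length and richness; variational Bernoulli-logit
    for top-predator presence; hurdle-lognormal for scraping (logit zero part +
    lognormal positive part).  Point estimates (posterior means for the Bernoulli
    parts) are returned.
    """
    if metric not in _RESPONSES:
        raise ValueError(f"metric must be one of {sorted(_RESPONSES)}")
    resp = _RESPONSES[metric]
    records = records.dropna(subset=[resp]).reset_index(drop=True)
    X, scale = _metric_design(records)
    groups = records["jurisdiction_id"].astype(str)
    y = records[resp].to_numpy(dtype=float)

    # covariates constant in this dataset carry no information; drop them (slope 0)
    active = [c for c in METRIC_COVARIATES if float(X[c].std()) > 0.0]

    if metric in ("length", "richness"):
        if np.any(y <= 0):
            raise ValueError(f"{resp} must be positive for the lognormal model")
        mod = MixedLM(np.log(y), sm.add_constant(X[active]), groups=groups)
        res = mod.fit(reml=True)
        slopes = {c: float(res.fe_params[c]) if c in active else 0.0 for c in METRIC_COVARIATES}
        u = {g: float(re.iloc[0]) for g, re in res.random_effects.items()}
        return GlmmFit(metric, "gaussian_log", float(res.fe_params["const"]), slopes, u,
                       sigma=float(np.sqrt(res.scale)), cov_scale=scale)

    if metric == "predators":
        yb = y.astype(float)
        if len(np.unique(yb)) < 2:
            raise ValueError("top-predator presence is constant; cannot fit")
        fit = _bernoulli_mixed(yb, X, groups)
        fit.metric = metric
        fit.family = "bernoulli"
        fit.cov_scale = scale
        return fit

    # hurdle-lognormal scraping
    if np.any(y < 0):
        raise ValueError("scraping potential cannot be negative")
    zero = (y == 0).astype(float)
    if zero.all() or not zero.any():
        zfit = GlmmFit(metric, "bernoulli", -np.inf if not zero.any() else np.inf,
                       {c: 0.0 for c in METRIC_COVARIATES}, {})
    else:
        zfit = _bernoulli_mixed(zero, X, groups)
    pos = y > 0
    active_pos = [c for c in active if float(X.loc[pos, c].std()) > 0.0]
    mod = MixedLM(np.log(y[pos]), sm.add_constant(X.loc[pos, active_pos]), groups=groups[pos])
    res = mod.fit(reml=True)
    slopes = {c: float(res.fe_params[c]) if c in active_pos else 0.0 for c in METRIC_COVARIATES}
    u = {g: float(re.iloc[0]) for g, re in res.random_effects.items()}
    return GlmmFit(
        metric, "hurdle_lognormal", float(res.fe_params["const"]), slopes, u,
        sigma=float(np.sqrt(res.scale)), delta=float(zero.mean()),
        zero_intercept=float(zfit.intercept), zero_slopes=dict(zfit.slopes), cov_scale=scale,
    )


def _bernoulli_mixed(y: np.ndarray, X: pd.DataFrame, groups) -> GlmmFit:
    active = [c for c in METRIC_COVARIATES if float(X[c].std()) > 0.0]
    exog = sm.add_constant(X[active]).to_numpy(dtype=float)
    labels = sorted(set(groups))
    lut = {g: k for k, g in enumerate(labels)}
    exog_vc = np.zeros((len(y), len(labels)))
    exog_vc[np.arange(len(y)), [lut[g] for g in groups]] = 1.0
    ident = np.zeros(len(labels), dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mod = BinomialBayesMixedGLM(y, exog, exog_vc, ident)
        res = mod.fit_vb()
    fe = res.fe_mean
    slopes = {c: float(fe[active.index(c) + 1]) if c in active else 0.0 for c in METRIC_COVARIATES}
    u = {g: float(res.vc_mean[lut[g]]) for g in labels}
    return GlmmFit("", "bernoulli", float(fe[0]), slopes, u)


def marginalize_metric(fit: GlmmFit, records: pd.DataFrame, environment: bool = True) -> np.ndarray:
    """Observed metric corrected to reference conditions (slope habitat, belt
    transect, non-atoll, average depth/area/productivity/SST, zero gravity) by
    removing the estimated covariate effects on the link scale.

    For the Bernoulli family the 0/1 observations cannot be corrected; they are
    returned unchanged (the trade-off smoother handles covariates implicitly).
    """
    resp = _RESPONSES[fit.metric]
    y = records[resp].to_numpy(dtype=float)
    if fit.family == "bernoulli":
        return y
    X, _ = _metric_design(records, scale=fit.cov_scale)
    drop = () if environment else ("ocean_prod", "sst", "atoll")
    eta = np.zeros(len(X))
    for name, b in fit.slopes.items():
        if name in drop:
            continue
        eta += b * X[name].to_numpy(dtype=float)
    if fit.family == "hurdle_lognormal":
        out = y.copy()
        pos = y > 0
        out[pos] = np.exp(np.log(y[pos]) - eta[pos])
        return out
    return np.exp(np.log(y) - eta)


# ---------------------------------------------------------------------------
# trade-off curves


def tradeoff_curve(
    metric_values: np.ndarray,
    biomass: np.ndarray,
    reference_biomass: dict[str, float],
    binary: bool = False,
    n_grid: int = 200,
    spline_df: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Penalized-spline smooth of a (marginalized) metric along the biomass gradient.

    Returns (curve, changes): ``curve`` tabulates the expected metric over a biomass
    grid; ``changes`` gives the percent change of the curve value at each reference
    biomass (B_MMSY, PGMY bounds, ...) relative to the value at ``B0``.  Reference
    biomasses outside the data support are evaluated at the nearest support edge
    with a warning.
    """
    ok = np.isfinite(metric_values) & np.isfinite(biomass)
    y, B = np.asarray(metric_values, float)[ok], np.asarray(biomass, float)[ok]
    df_spl = int(np.clip(spline_df, 4, max(4, len(B) // 5)))
    basis = BSplines(B[:, None], df=[df_spl], degree=[3])
    family = sm.families.Binomial() if binary else sm.families.Gaussian()
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gam = GLMGam(y, np.ones((len(y), 1)), smoother=basis, family=family)
        try:
            alpha = gam.select_penweight()[0]
            gam = GLMGam(y, np.ones((len(y), 1)), smoother=basis, alpha=alpha, family=family)
        except Exception:
            pass
        try:
            coef = np.asarray(gam.fit().params)
        except PerfectSeparationError:
            # the smooth interpolates the data exactly (e.g. a deterministic
            # metric); plain least squares on the basis handles that fine
            design = np.column_stack([np.ones(len(y)), basis.transform(B[:, None])])
            coef = np.linalg.lstsq(design, y, rcond=None)[0]

    lo, hi = float(B.min()), float(B.max())
    grid = np.linspace(lo, hi, n_grid)

    def predict(bvals):
        bvals = np.asarray(bvals, dtype=float)
        clipped = np.clip(bvals, lo, hi)
        if np.any(clipped != bvals):
            warnings.warn("reference biomass outside data support; truncated to the support edge", stacklevel=2)
        ex = basis.transform(clipped[:, None])
        eta = coef[0] + ex @ coef[1:]
        return family.link.inverse(eta)

    curve = pd.DataFrame({"biomass": grid, "expected_metric": predict(grid)})
    if "B0" not in reference_biomass:
        raise ValueError("reference_biomass must include 'B0' (the baseline)")
    base = float(predict([reference_biomass["B0"]])[0])
    rows = []
    for name, bref in reference_biomass.items():
        val = float(predict([bref])[0])
        rows.append(
            {
                "reference": name, "biomass": bref, "expected_metric": val,
                "pct_change_vs_B0": 100.0 * (val - base) / base if base != 0 else np.nan,
            }
        )
    return curve, pd.DataFrame(rows)
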