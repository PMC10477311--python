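"""Posterior propagation to site-specific reference points and status ratios.

Every posterior draw of (B0, environmental effects, r) yields a draw of the
site-specific unfished biomass B0_s = exp(log B0 + x_env·beta_env), and with it MMSY_s,
B_MMSY_s and the PGMY biomass window.  All of these are proportional to B0_s for a
fixed family (the surplus curve is scale-free in B/B0), so the set is stored as the
B0_s draw matrix plus per-family shape constants.  Observed biomass is marginalized to
reference sampling conditions (slope habitat, belt transect, average depth and
sampling area) by subtracting the sampling effects on the log scale, and status ratios
B/B_MMSY and C/MMSY, the conditional surplus, and the relative catch potential are
computed draw-wise and summarized by the median and a central 90% interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import build_design
from .model import PosteriorDraws
from .surplus import CommunityParams, SurplusModel, bmmsy, mmsy, pgmy_bounds, surplus

__all__ = [
    "ReferencePointSet",
    "StatusResult",
    "site_reference_points",
    "marginalize_biomass",
    "site_status",
    "shape_constants",
]

INTERVAL = (5.0, 95.0)  # central 90% uncertainty interval


def shape_constants(model: SurplusModel, pgmy_fraction: float = 0.8) -> dict:
    """Scale-free shape of the surplus curve: B_MMSY/B0, MMSY/(r*B0) and the PGMY
    window as fractions of B0.  Exact for the whole family because P(B) factorizes
    as r*B0*f(B/B0)."""
    ref = CommunityParams(100.0, 1.0)
    lo, hi = pgmy_bounds(ref, model, pgmy_fraction)
    return {
        "bmmsy_over_b0": bmmsy(ref, model) / 100.0,
        "mmsy_over_rb0": mmsy(ref, model) / 100.0,
        "pgmy_lower_over_b0": lo / 100.0,
        "pgmy_upper_over_b0": hi / 100.0,
        "fraction": pgmy_fraction,
    }


def _summary(x: np.ndarray, name: str) -> pd.DataFrame:
    lo, hi = INTERVAL
    return pd.DataFrame(
        {
            f"{name}_median": np.median(x, axis=1),
            f"{name}_lo": np.percentile(x, lo, axis=1),
            f"{name}_hi": np.percentile(x, hi, axis=1),
        }
    )


@dataclass
class ReferencePointSet:
    """Per-site, per-draw reference points, stored via B0_s and shape constants."""

    site_ids: np.ndarray
    B0_s: np.ndarray          # (n_sites, n_draws)
    r: np.ndarray             # (n_draws,)
    model: SurplusModel
    pgmy_fraction: float = 0.8
    shapes: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.shapes:
            self.shapes = shape_constants(self.model, self.pgmy_fraction)

    @property
    def bmmsy_s(self) -> np.ndarray:
        return self.B0_s * self.shapes["bmmsy_over_b0"]

    @property
    def mmsy_s(self) -> np.ndarray:
        return self.B0_s * self.r[None, :] * self.shapes["mmsy_over_rb0"]

    @property
    def pgmy_lower(self) -> np.ndarray:
        return self.B0_s * self.shapes["pgmy_lower_over_b0"]

    @property
    def pgmy_upper(self) -> np.ndarray:
        return self.B0_s * self.shapes["pgmy_upper_over_b0"]

    def surplus_at(self, B: np.ndarray) -> np.ndarray:
        """Draw-wise surplus production at biomass B (same shape as B0_s), negative
        above B0_s."""
        return _surplus_matrix(B, self.B0_s, self.r[None, :], self.model)

    def summary(self) -> pd.DataFrame:
        out = pd.concat(
            [
                pd.DataFrame({"site_id": self.site_ids}),
                _summary(self.B0_s, "B0_s"),
                _summary(self.mmsy_s, "MMSY_s"),
                _summary(self.bmmsy_s, "BMMSY_s"),
            ],
            axis=1,
        )
        out["PGMY_lower_median"] = np.median(self.pgmy_lower, axis=1)
        out["PGMY_upper_median"] = np.median(self.pgmy_upper, axis=1)
        return out


def _surplus_matrix(B, B0, r, model: SurplusModel):
    """Vectorized surplus for broadcastable draw matrices (negative above B0)."""
    B = np.asarray(B, dtype=float)
    if model.family == "fox":
        return r * B * (np.log(B0) - np.log(B))
    n = model.effective_n
    return (r / (n - 1.0)) * B * (1.0 - (B / B0) ** (n - 1.0))


def site_reference_points(
    draws: PosteriorDraws,
    sites: pd.DataFrame,
    model: SurplusModel | None = None,
    pgmy_fraction: float = 0.8,
) -> ReferencePointSet:
    """Environmentally-conditioned reference points per site and posterior draw.

    Sites are standardized with the fit's standardization constants (missing coral
    cover imputed at the training mean); values far outside the training spread
    trigger an extrapolation warning, not an error.
    """
    model = model or draws.model
    dm = build_design(sites, draws.spec)
    if np.any(np.abs(dm.env[:, [0, 1, 3]]) > 3.0):
        warnings.warn("environmental covariate >6 SD from the training mean; extrapolating", stacklevel=2)
    log_B0_s = np.log(draws.get("B0"))[None, :] + dm.env @ draws.beta_env().T
    return ReferencePointSet(
        site_ids=sites["site_id"].to_numpy(),
        B0_s=np.exp(log_B0_s),
        r=draws.get("r"),
        model=model,
        pgmy_fraction=pgmy_fraction,
    )


def marginalize_biomass(draws: PosteriorDraws, sites: pd.DataFrame) -> np.ndarray:
    """Observed biomass corrected to reference sampling conditions, per draw.

    B_marg = exp(log B_obs - x_sampling · beta_sampling): slope habitat, belt
    transect, average depth and sampling area become the reference (their dummies
    and standardized values are zero there).  Returns an (n_sites, n_draws) matrix.
    """
    b = sites["biomass_obs"].to_numpy(dtype=float)
    if np.any(~(b > 0)):
        raise ValueError("biomass_obs must be positive to marginalize")
    dm = build_design(sites, draws.spec)
    return np.exp(np.log(b)[:, None] - dm.sampling @ draws.beta_sampling().T)


@dataclass
class StatusResult:
    """Draw-wise status ratios for a set of assessed units (sites or jurisdictions)."""

    site_ids: np.ndarray
    B_marg: np.ndarray | None       # (n, n_draws)
    catch: np.ndarray | None        # (n,) NaN where unavailable
    B_status: np.ndarray | None     # B_marg / B_MMSY
    F_status: np.ndarray | None     # C / MMSY
    P: np.ndarray | None            # surplus at B_marg
    C_pot: np.ndarray | None        # P / MMSY
    refpts: ReferencePointSet | None = None

    def overfishing(self) -> np.ndarray:
        """Per-draw overfishing indicator: catch above the conditional surplus."""
        return self.catch[:, None] > self.P

    def summary(self) -> pd.DataFrame:
        parts = [pd.DataFrame({"site_id": self.site_ids})]
        for name, x in (("B_marg", self.B_marg), ("B_status", self.B_status),
                        ("F_status", self.F_status), ("P", self.P), ("C_pot", self.C_pot)):
            if x is not None:
                parts.append(_summary(x, name))
        out = pd.concat(parts, axis=1)
        if self.catch is not None:
            out["catch"] = self.catch
        if self.P is not None and self.catch is not None:
            out["overfishing"] = np.median(self.overfishing(), axis=1) > 0.5
        return out


def site_status(
    refpts: ReferencePointSet,
    B_marg: np.ndarray | None,
    catch: np.ndarray | None = None,
) -> StatusResult:
    """Draw-wise biomass status, fishing status, conditional surplus and relative
    catch potential.  Sites without catch get biomass-only status; sites without
    biomass (``B_marg=None``) get fishing-only status."""
    mmsy_s = refpts.mmsy_s
    if np.any(mmsy_s <= 0):
        warnings.warn("non-positive MMSY draw encountered; excluded from ratios", stacklevel=2)
        mmsy_s = np.where(mmsy_s > 0, mmsy_s, np.nan)
    B_status = P = C_pot = None
    if B_marg is not None:
        B_status = B_marg / refpts.bmmsy_s
        P = refpts.surplus_at(B_marg)
        C_pot = P / mmsy_s
    F_status = None
    if catch is not None:
        catch = np.asarray(catch, dtype=float)
        if np.any(catch[~np.isnan(catch)] < 0):
            raise ValueError("catch must be non-negative")
        F_status = catch[:, None] / mmsy_s
    return StatusResult(
        site_ids=refpts.site_ids, B_marg=B_marg, catch=catch,
        B_status=B_status, F_status=F_status, P=P, C_pot=C_pot, refpts=refpts,
    )
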