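"""Closed-form multispecies surplus-production models and reference points.

The community biomass dynamics of a whole reef-fish assemblage are modelled by an
aggregate surplus-production curve P(B): the annual production (t/km²/y) of a standing
community biomass B (t/km²) relative to the unfished (carrying-capacity) biomass B0.
Three families are supported:

* Gompertz-Fox:      P = log(B0) * r * B * (1 - log(B)/log(B0)),   peak at B0/e
* Graham-Schaefer:   P = r * B * (1 - B/B0),                       peak at B0/2
* Pella-Tomlinson:   P = r/(n-1) * B * (1 - (B/B0)^(n-1)),         peak at B0*n^(1/(1-n))

Schaefer is the Pella-Tomlinson n=2 case, and the n→1 limit of Pella-Tomlinson
reproduces the Gompertz-Fox curve.  MMSY is the peak of the curve, B_MMSY the biomass
at which it is attained, and the "pretty good multispecies yield" (PGMY) biomass window
is the interval over which production stays within a stated fraction (default 0.8) of
MMSY.  All logarithms are natural.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "SurplusModel",
    "CommunityParams",
    "surplus",
    "bmmsy",
    "mmsy",
    "pgmy_bounds",
    "recovery_trajectory",
]

_FAMILIES = ("fox", "schaefer", "pella_tomlinson")


@dataclass(frozen=True)
class SurplusModel:
    """Which member of the surplus-production family to use.

    ``n_exponent`` is only meaningful for ``pella_tomlinson`` and must exceed 1;
    ``schaefer`` is the n=2 special case and ``fox`` the n→1 limit.
    """

    family: str = "fox"
    n_exponent: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown surplus family {self.family!r}; expected one of {_FAMILIES}")
        if self.family == "pella_tomlinson":
            if self.n_exponent is None or not self.n_exponent > 1:
                raise ValueError("pella_tomlinson requires n_exponent > 1")
        elif self.n_exponent is not None:
            raise ValueError(f"n_exponent only applies to pella_tomlinson, not {self.family!r}")

    @classmethod
    def fox(cls) -> "SurplusModel":
        return cls("fox")

    @classmethod
    def schaefer(cls) -> "SurplusModel":
        return cls("schaefer")

    @classmethod
    def pella_tomlinson(cls, n: float) -> "SurplusModel":
        return cls("pella_tomlinson", n)

    @classmethod
    def from_name(cls, name: str) -> "SurplusModel":
        """Parse 'fox', 'schaefer', or 'pt<n>' (e.g. 'pt3', 'pt4')."""
        name = name.strip().lower()
        if name in ("fox", "schaefer"):
            return cls(name)
        if name.startswith("pt"):
            return cls.pella_tomlinson(float(name[2:]))
        raise ValueError(f"cannot parse surplus model name {name!r}")

    @property
    def effective_n(self) -> float | None:
        """The Pella-Tomlinson exponent this family corresponds to (None for fox)."""
        if self.family == "schaefer":
            return 2.0
        return self.n_exponent


@dataclass(frozen=True)
class CommunityParams:
    """Unfished community biomass B0 (t/km²) and community biomass growth rate r (1/y)."""

    B0: float
    r: float

    def __post_init__(self) -> None:
        if not self.B0 > 0:
            raise ValueError("B0 must be positive")
        if not self.r > 0:
            raise ValueError("r must be positive")


def _check_fox_domain(B0) -> None:
    if np.any(np.asarray(B0) <= 1.0):
        raise ValueError("Gompertz-Fox surplus requires B0 > 1 (log(B0) > 0)")


def surplus(B, params: CommunityParams, model: SurplusModel = SurplusModel.fox()):
    """Annual surplus production P(B) in t/km²/y.

    Vanishes at B = B0 and is negative for B > B0 (so status assessment of
    observations above carrying capacity does not fail).
    """
    B = np.asarray(B, dtype=float)
    if np.any(B <= 0):
        raise ValueError("biomass must be positive")
    B0, r = params.B0, params.r
    if model.family == "fox":
        _check_fox_domain(B0)
        out = np.log(B0) * r * B * (1.0 - np.log(B) / np.log(B0))
    else:
        n = model.effective_n
        out = (r / (n - 1.0)) * B * (1.0 - (B / B0) ** (n - 1.0))
    return out.item() if out.ndim == 0 else out


def bmmsy(params: CommunityParams, model: SurplusModel = SurplusModel.fox()) -> float:
    """Biomass at which the surplus curve peaks (B_MMSY, t/km²)."""
    if model.family == "fox":
        _check_fox_domain(params.B0)
        return params.B0 / np.e
    n = model.effective_n
    return params.B0 * n ** (1.0 / (1.0 - n))


def mmsy(params: CommunityParams, model: SurplusModel = SurplusModel.fox()) -> float:
    """Peak surplus production (multispecies maximum sustainable yield, t/km²/y)."""
    if model.family == "fox":
        _check_fox_domain(params.B0)
        return params.r * params.B0 / np.e
    return float(surplus(bmmsy(params, model), params, model))


def pgmy_bounds(
    params: CommunityParams,
    model: SurplusModel = SurplusModel.fox(),
    fraction: float = 0.8,
) -> tuple[float, float]:
    """Biomass window [B_lower, B_upper] within which P(B) >= fraction * MMSY.

    The two roots of P(B) = fraction*MMSY bracket B_MMSY; found by bracketed
    root-finding to 1e-10 absolute tolerance in B.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("PGMY fraction must lie in (0, 1]")
    bm = bmmsy(params, model)
    if fraction == 1.0:
        return bm, bm
    target = fraction * mmsy(params, model)

    def f(B):
        return surplus(B, params, model) - target

    lo_start = max(1.0 + 1e-9, 1e-9 * params.B0) if model.family == "fox" else 1e-12 * params.B0
    lower = brentq(f, lo_start, bm, xtol=1e-10)
    upper = brentq(f, bm, params.B0 * (1.0 - 1e-13), xtol=1e-10)
    return float(lower), float(upper)


def _pt_trajectory(t, B0: float, Bmin: float, r: float, n: float):
    # u = (B/B0)^(n-1) follows logistic growth du/dt = r u (1-u)
    u0 = (Bmin / B0) ** (n - 1.0)
    e = np.exp(-r * np.asarray(t, dtype=float))
    u = u0 / (u0 + (1.0 - u0) * e)
    return B0 * u ** (1.0 / (n - 1.0))


def recovery_trajectory(
    t,
    B0: float,
    Bmin: float,
    r: float,
    model: SurplusModel = SurplusModel.fox(),
    method: str = "closed_form",
):
    """Biomass B(t) recovering from Bmin at t=0 under dB/dt = P(B).

    The Gompertz-Fox solution is B(t) = B0 * exp(log(Bmin/B0) * exp(-r t)); the
    Pella-Tomlinson family (including Schaefer) also has a closed form via the
    logistic substitution u = (B/B0)^(n-1).  ``method='ode'`` integrates dB/dt = P(B)
    numerically (rtol 1e-8) as an independent route.
    """
    if not 0 < Bmin < B0:
        raise ValueError("recovery requires 0 < Bmin < B0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if method == "ode":
        params = CommunityParams(B0, r)
        t_flat = np.atleast_1d(t)
        t_end = float(t_flat.max()) if t_flat.size else 0.0
        sol = solve_ivp(
            lambda _t, B: np.atleast_1d(surplus(B, params, model)),
            (0.0, max(t_end, 1e-12)),
            [Bmin],
            t_eval=np.sort(np.unique(np.append(t_flat, 0.0))),
            rtol=1e-8,
            atol=1e-10,
            dense_output=True,
        )
        out = sol.sol(t_flat)[0]
        out = out.reshape(t.shape)
        return out.item() if t.ndim == 0 else out
    if method != "closed_form":
        raise ValueError("method must be 'closed_form' or 'ode'")
    if model.family == "fox":
        _check_fox_domain(B0)
        out = B0 * np.exp(np.log(Bmin / B0) * np.exp(-r * t))
    else:
        out = _pt_trajectory(t, B0, Bmin, r, model.effective_n)
    return out.item() if np.ndim(out) == 0 else out
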