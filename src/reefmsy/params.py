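"""Parameter container shared by the generator, the likelihood and the sampler."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# order matters: this is the canonical layout of the beta block in design matrices
ENV_BETAS = ("beta_ocean_prod", "beta_sst", "beta_atoll", "beta_coral")
SAMPLING_BETAS = (
    "beta_depth",
    "beta_crest",
    "beta_lagoon_backreef",
    "beta_flat",
    "beta_pointcount",
    "beta_distancesampling",
    "beta_samplingarea",
)
ALL_BETAS = ENV_BETAS + SAMPLING_BETAS + ("beta_reserve_size", "beta_gravity")


@dataclass
class ModelParams:
    """All latent quantities of the joint hierarchical biomass model.

    ``B0`` is the unfished community biomass (t/km²) under average environmental and
    reference sampling conditions, ``r`` the community biomass growth rate (1/y) and
    ``Bmin`` the biomass at reserve age zero (t/km²).  The betas are linear effects on
    log-biomass: four environmental effects acting on log B0 (ocean productivity, SST,
    atoll, hard-coral cover), seven sampling effects (depth, habitat dummies relative
    to slope, census-method dummies relative to belt transects, sampling area), the
    reserve-size effect and the (unstandardized) gravity effect.  ``gamma`` is the
    fished-reef intercept on the log scale, the sigmas are residual SDs of log-biomass
    per data subset, and ``u`` maps jurisdiction labels to random intercepts with
    scale ``sigma_u``.
    """

    B0: float = 120.0
    r: float = 0.135
    Bmin: float = 10.0
    beta_ocean_prod: float = 0.20
    beta_sst: float = -0.15
    beta_atoll: float = 0.25
    beta_coral: float = 0.20
    beta_depth: float = 0.10
    beta_crest: float = -0.15
    beta_lagoon_backreef: float = -0.25
    beta_flat: float = -0.20
    beta_pointcount: float = 0.15
    beta_distancesampling: float = -0.10
    beta_samplingarea: float = 0.10
    beta_reserve_size: float = 0.10
    beta_gravity: float = -0.015
    gamma: float = 3.7
    sigma_i: float = 0.35
    sigma_j: float = 0.35
    sigma_z: float = 0.45
    sigma_u: float = 0.30
    u: dict[str, float] = field(default_factory=dict)

    def env_beta(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in ENV_BETAS])

    def sampling_beta(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in SAMPLING_BETAS])

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)
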