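"""Fishery classification at site and jurisdiction scale.

A unit with both biomass and catch lands in exactly one of four categories by
comparing its (median) biomass to B_MMSY and its catch to MMSY and to the surplus at
its current biomass:

* good_condition: B > B_MMSY and C < MMSY
* warning:        B > B_MMSY and C > MMSY   (stock expected to decline)
* recovering:     B < B_MMSY and C <= surplus
* unsustainable:  B < B_MMSY and C > surplus

"Conservation concern" is failing either benchmark (C > MMSY and/or B < B_MMSY), the
complement of good condition; "collapsed" is biomass at or below a fraction (default
0.1) of the unit's unfished biomass; PGMY flags report whether biomass lies in the
pretty-good-yield window.  Category assignment uses posterior medians; draw-wise
classification supplies the uncertainty intervals on the headline percentages.

Jurisdiction-scale reference points are draw-wise arithmetic means of the member
sites' reference points, and jurisdiction biomass can optionally be weighted by the
protected proportion of territorial waters (protected area assumed at unfished
biomass — an optimistic convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import refpoints as _rp
from .refpoints import ReferencePointSet, StatusResult, site_status

__all__ = [
    "FisheryCategory",
    "CATEGORY_NAMES",
    "classify_site",
    "classify_sites",
    "category_draws",
    "jurisdiction_reference_points",
    "jurisdiction_biomass",
    "jurisdiction_status",
    "summarize_assessment",
]

CATEGORY_NAMES = ("good_condition", "warning", "recovering", "unsustainable")


@dataclass(frozen=True)
class FisheryCategory:
    category: str | None
    conservation_concern: bool
    overfishing: bool | None
    collapsed: bool
    within_pgmy: bool
    below_pgmy_lower: bool


def _category_code(b_below, c_above_mmsy, c_above_surplus):
    """0 good, 1 warning, 2 recovering, 3 unsustainable (vectorized)."""
    return np.where(
        b_below,
        np.where(c_above_surplus, 3, 2),
        np.where(c_above_mmsy, 1, 0),
    )


def classify_sites(status: StatusResult, collapse_fraction: float = 0.1) -> pd.DataFrame:
    """Median-based category and flags per assessed unit.

    Units without catch keep their biomass-derived flags but no category; ties at
    exactly 1 count as not-below (strict inequalities throughout).
    """
    if status.B_status is None:
        raise ValueError("classification requires biomass status")
    med_B = np.median(status.B_status, axis=1)
    b_below = med_B < 1.0
    refpts = status.refpts
    collapsed = np.median(status.B_marg / refpts.B0_s, axis=1) <= collapse_fraction
    med_Bm = np.median(status.B_marg, axis=1)
    lo = np.median(refpts.pgmy_lower, axis=1)
    hi = np.median(refpts.pgmy_upper, axis=1)
    within = (med_Bm >= lo) & (med_Bm <= hi)
    below_lo = med_Bm < lo

    rows = []
    for k, sid in enumerate(status.site_ids):
        c = status.catch[k] if status.catch is not None else np.nan
        if np.isnan(c):
            rows.append(
                {
                    "site_id": sid, "category": None,
                    "conservation_concern": bool(b_below[k]), "overfishing": None,
                }
            )
            continue
        c_above_mmsy = c > np.median(status.refpts.mmsy_s[k])
        c_above_surplus = c > np.median(status.P[k])
        code = int(_category_code(b_below[k], c_above_mmsy, c_above_surplus))
        rows.append(
            {
                "site_id": sid,
                "category": CATEGORY_NAMES[code],
                "conservation_concern": bool(b_below[k] or c_above_mmsy),
                "overfishing": bool(c_above_surplus),
            }
        )
    out = pd.DataFrame(rows)
    out["collapsed"] = collapsed
    out["within_pgmy"] = within
    out["below_pgmy_lower"] = below_lo
    return out


def classify_site(status: StatusResult, index: int = 0, collapse_fraction: float = 0.1) -> FisheryCategory:
    """Category and flags for a single assessed unit, as a FisheryCategory."""
    row = classify_sites(status, collapse_fraction).iloc[index]
    return FisheryCategory(
        category=row["category"] if pd.notna(row["category"]) else None,
        conservation_concern=bool(row["conservation_concern"]),
        overfishing=None if row["overfishing"] is None else bool(row["overfishing"]),
        collapsed=bool(row["collapsed"]),
        within_pgmy=bool(row["within_pgmy"]),
        below_pgmy_lower=bool(row["below_pgmy_lower"]),
    )


def category_draws(status: StatusResult) -> np.ndarray:
    """(n_units, n_draws) category codes classified independently in every draw;
    -1 where catch is unavailable."""
    if status.B_status is None or status.catch is None:
        raise ValueError("draw-wise classification requires biomass and catch")
    C = status.catch[:, None]
    codes = _category_code(status.B_status < 1.0, C > status.refpts.mmsy_s, C > status.P)
    codes = np.where(np.isnan(C), -1, codes)
    return codes.astype(int)


def jurisdiction_reference_points(
    refpts: ReferencePointSet, jurisdiction_ids: np.ndarray
) -> tuple[list[str], ReferencePointSet]:
    """Draw-wise mean of member-site reference points per jurisdiction.

    Because every reference point is proportional to B0_s at fixed (r, family),
    averaging B0_s draw-wise reproduces the means of MMSY_s and B_MMSY_s exactly.
    Returns (labels, jurisdiction-level ReferencePointSet).
    """
    jurisdiction_ids = np.asarray(jurisdiction_ids)
    if len(jurisdiction_ids) != len(refpts.site_ids):
        raise ValueError("jurisdiction labels must align with refpts sites")
    labels = sorted(set(jurisdiction_ids.tolist()))
    if not labels:
        raise ValueError("no jurisdictions supplied")
    B0_c = np.vstack([refpts.B0_s[jurisdiction_ids == c].mean(axis=0) for c in labels])
    jur = ReferencePointSet(
        site_ids=np.asarray(labels), B0_s=B0_c, r=refpts.r,
        model=refpts.model, pgmy_fraction=refpts.pgmy_fraction, shapes=dict(refpts.shapes),
    )
    return labels, jur


def jurisdiction_biomass(
    B_marg_fished: np.ndarray,
    fished_jurisdiction: np.ndarray,
    mode: str = "raw",
    p_mpa: dict | None = None,
    B0_all_sites: np.ndarray | None = None,
    all_jurisdiction: np.ndarray | None = None,
) -> tuple[list[str], np.ndarray]:
    """Draw-wise jurisdiction biomass: mean marginalized fished biomass, optionally
    MPA-weighted with the mean unfished biomass of all the jurisdiction's sites:
    B_weighted = mean(B_marg)*(1-p_mpa) + mean(B0_s)*p_mpa."""
    fished_jurisdiction = np.asarray(fished_jurisdiction)
    labels = sorted(set(fished_jurisdiction.tolist()))
    B_c = np.vstack([B_marg_fished[fished_jurisdiction == c].mean(axis=0) for c in labels])
    if mode == "raw":
        return labels, B_c
    if mode != "weighted":
        raise ValueError("mode must be 'raw' or 'weighted'")
    if p_mpa is None or B0_all_sites is None or all_jurisdiction is None:
        raise ValueError("weighted mode needs p_mpa and all-site unfished biomass draws")
    all_jurisdiction = np.asarray(all_jurisdiction)
    out = np.empty_like(B_c)
    for k, c in enumerate(labels):
        p = float(p_mpa[c])
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p_mpa for {c!r} outside [0, 1]")
        B0_mean = B0_all_sites[all_jurisdiction == c].mean(axis=0)
        out[k] = B_c[k] * (1.0 - p) + B0_mean * p
    return labels, out


def jurisdiction_status(
    jur_refpts: ReferencePointSet,
    B_c: np.ndarray | None,
    C_c: np.ndarray | None = None,
) -> StatusResult:
    """Status ratios at jurisdiction scale; same construction as for sites, using
    the jurisdiction surplus curve.  Catch-only jurisdictions get fishing status
    alone."""
    return site_status(jur_refpts, B_c, C_c)


def _pct_summary(flag_matrix: np.ndarray, name: str) -> dict:
    """Median and 90% interval of a per-draw percentage across units."""
    pct = 100.0 * np.mean(flag_matrix, axis=0)
    lo, hi = _rp.INTERVAL
    return {
        "metric": name,
        "median": float(np.median(pct)),
        "lo": float(np.percentile(pct, lo)),
        "hi": float(np.percentile(pct, hi)),
    }


def summarize_assessment(status: StatusResult, collapse_fraction: float = 0.1) -> pd.DataFrame:
    """Headline percentages with draw-wise 90% intervals.

    Biomass-based rows use units with biomass; catch-based rows use units with both
    inputs and are reported NaN when no unit has catch data.
    """
    rows = []
    if status.B_status is not None:
        rows.append(_pct_summary(status.B_status < 1.0, "pct_below_bmmsy"))
        ratio = status.B_marg / status.refpts.B0_s
        rows.append(_pct_summary(ratio <= collapse_fraction, "pct_collapsed"))
        within = (status.B_marg >= status.refpts.pgmy_lower) & (status.B_marg <= status.refpts.pgmy_upper)
        rows.append(_pct_summary(within, "pct_within_pgmy"))
        rows.append(_pct_summary(status.B_marg < status.refpts.pgmy_lower, "pct_below_pgmy_lower"))

    has_catch = status.catch is not None and np.any(~np.isnan(status.catch))
    if has_catch:
        w = ~np.isnan(status.catch)
        rows.append(_pct_summary(status.F_status[w] > 1.0, "pct_above_mmsy"))
        if status.P is not None:
            rows.append(_pct_summary(status.catch[w, None] > status.P[w], "pct_overfishing"))
            codes = category_draws(
                StatusResult(
                    site_ids=status.site_ids[w], B_marg=status.B_marg[w], catch=status.catch[w],
                    B_status=status.B_status[w], F_status=status.F_status[w],
                    P=status.P[w], C_pot=status.C_pot[w],
                    refpts=ReferencePointSet(
                        site_ids=status.refpts.site_ids[w], B0_s=status.refpts.B0_s[w],
                        r=status.refpts.r, model=status.refpts.model,
                        pgmy_fraction=status.refpts.pgmy_fraction, shapes=dict(status.refpts.shapes),
                    ),
                )
            )
            for code, name in enumerate(CATEGORY_NAMES):
                rows.append(_pct_summary(codes == code, f"pct_{name}"))
            concern = (status.B_status[w] < 1.0) | (status.F_status[w] > 1.0)
            rows.append(_pct_summary(concern, "pct_conservation_concern"))
    else:
        for name in ("pct_above_mmsy", "pct_overfishing", "pct_conservation_concern"):
            rows.append({"metric": name, "median": np.nan, "lo": np.nan, "hi": np.nan})

    return pd.DataFrame(rows).set_index("metric")
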