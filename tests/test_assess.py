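"""Fishery classification rules and jurisdiction aggregation."""

import numpy as np
import pandas as pd
import pytest

from reefmsy import assess as A
from reefmsy import refpoints as RP
from reefmsy.surplus import SurplusModel

FOX = SurplusModel.fox()


def make_status(B0=100.0, r=0.2, B=None, C=None, n_draws=200, jitter=0.0, seed=0):
    """Hand-built draw matrices around deterministic values (optionally jittered)."""
    rng = np.random.default_rng(seed)
    B = np.asarray(B, dtype=float)
    n = len(B)
    B0_s = np.full((n, n_draws), B0) * np.exp(jitter * rng.standard_normal((n, n_draws)))
    refpts = RP.ReferencePointSet(
        site_ids=np.array([f"s{i}" for i in range(n)]),
        B0_s=B0_s, r=np.full(n_draws, r), model=FOX,
    )
    B_marg = np.tile(B[:, None], (1, n_draws))
    catch = None if C is None else np.asarray(C, dtype=float)
    return RP.site_status(refpts, B_marg, catch)


class TestClassificationTruthTable:
    """Exhaustive check of the four categories against the stated rules.

    With B0=100, r=0.2 (fox): B_MMSY = 36.79, MMSY = 7.36.  Surplus at B=30 is
    7.22; at B=50 it is 6.93.
    """

    @pytest.mark.parametrize(
        "B, C, expected",
        [
            (50.0, 5.0, "good_condition"),    # B>BMMSY, C<MMSY
            (44.0, 8.0, "warning"),           # B>BMMSY, C>MMSY
            (30.0, 5.0, "recovering"),        # B<BMMSY, C below surplus (7.22)
            (30.0, 7.3, "unsustainable"),     # B<BMMSY, C>surplus (C<MMSY still)
            (30.0, 9.0, "unsustainable"),     # B<BMMSY, C>surplus and C>MMSY
            (26.0, 7.0, "recovering"),        # surplus(26)=7.007 > C
        ],
    )
    def test_categories(self, B, C, expected):
        status = make_status(B=[B], C=[C])
        out = A.classify_sites(status)
        assert out.loc[0, "category"] == expected

    @pytest.mark.parametrize(
        "B, C, concern",
        [(50.0, 5.0, False), (44.0, 8.0, True), (30.0, 5.0, True), (30.0, 9.0, True)],
    )
    def test_conservation_concern_is_complement_of_good(self, B, C, concern):
        status = make_status(B=[B], C=[C])
        out = A.classify_sites(status)
        assert bool(out.loc[0, "conservation_concern"]) is concern
        assert (out.loc[0, "category"] == "good_condition") is (not concern)

    def test_partition_every_site_in_exactly_one_category(self):
        rng = np.random.default_rng(7)
        B = rng.uniform(5.0, 99.0, 40)
        C = rng.uniform(0.0, 12.0, 40)
        out = A.classify_sites(make_status(B=B, C=C, jitter=0.05))
        assert out["category"].isin(A.CATEGORY_NAMES).all()
        good = out["category"] == "good_condition"
        assert (out["conservation_concern"] == ~good).all()

    def test_collapse_flag_at_tenth_of_b0(self):
        out = A.classify_sites(make_status(B=[10.0, 10.1, 50.0], C=[1.0, 1.0, 1.0]))
        np.testing.assert_array_equal(out["collapsed"], [True, False, False])

    def test_pgmy_flags(self):
        # fox at B0=100: PGMY window for 0.8 is about [15.4, 66.2]
        lo, hi = RP.shape_constants(FOX, 0.8)["pgmy_lower_over_b0"] * 100, \
                 RP.shape_constants(FOX, 0.8)["pgmy_upper_over_b0"] * 100
        out = A.classify_sites(make_status(B=[lo - 2, (lo + hi) / 2, hi + 2], C=[1.0] * 3))
        np.testing.assert_array_equal(out["within_pgmy"], [False, True, False])
        np.testing.assert_array_equal(out["below_pgmy_lower"], [True, False, False])

    def test_missing_catch_leaves_category_undefined(self):
        status = make_status(B=[30.0, 50.0], C=[np.nan, np.nan])
        out = A.classify_sites(status)
        assert out["category"].isna().all()
        np.testing.assert_array_equal(out["conservation_concern"], [True, False])

    def test_ties_at_exactly_one_count_as_not_below(self):
        bmmsy = 100.0 / np.e
        status = make_status(B=[bmmsy], C=[1.0])
        out = A.classify_sites(status)
        assert out.loc[0, "category"] == "good_condition"


class TestJurisdictionAggregation:
    def test_singleton_jurisdiction_equals_site_draws(self):
        status = make_status(B=[30.0, 50.0], C=[1.0, 2.0], jitter=0.1)
        labels, jur = A.jurisdiction_reference_points(status.refpts, np.array(["A", "B"]))
        np.testing.assert_allclose(jur.B0_s[0], status.refpts.B0_s[0], rtol=1e-12)
        np.testing.assert_allclose(jur.mmsy_s[1], status.refpts.mmsy_s[1], rtol=1e-12)

    def test_two_site_mean(self):
        status = make_status(B=[30.0, 50.0], C=None)
        status.refpts.B0_s[0, :] = 80.0
        status.refpts.B0_s[1, :] = 120.0
        labels, jur = A.jurisdiction_reference_points(status.refpts, np.array(["A", "A"]))
        np.testing.assert_allclose(jur.B0_s[0], 100.0)

    def test_surplus_consistency_at_jurisdiction_scale(self):
        status = make_status(B=[30.0, 50.0, 70.0], C=None, jitter=0.1)
        labels, jur = A.jurisdiction_reference_points(status.refpts, np.array(["A", "A", "A"]))
        P = jur.surplus_at(jur.bmmsy_s)
        np.testing.assert_allclose(P, jur.mmsy_s, rtol=1e-8)

    def test_permutation_invariance(self):
        status = make_status(B=[30.0, 50.0, 70.0], C=None, jitter=0.1)
        ids = np.array(["A", "B", "A"])
        _, jur1 = A.jurisdiction_reference_points(status.refpts, ids)
        perm = [2, 0, 1]
        refpts_p = RP.ReferencePointSet(
            site_ids=status.refpts.site_ids[perm], B0_s=status.refpts.B0_s[perm],
            r=status.refpts.r, model=FOX,
        )
        _, jur2 = A.jurisdiction_reference_points(refpts_p, ids[perm])
        np.testing.assert_allclose(jur1.B0_s, jur2.B0_s, rtol=1e-12)

    def test_empty_rejected(self):
        status = make_status(B=[30.0], C=None)
        with pytest.raises(ValueError):
            A.jurisdiction_reference_points(status.refpts, np.array(["A", "B"]))


class TestJurisdictionBiomass:
    def setup_method(self):
        self.status = make_status(B=[40.0, 40.0], C=None)
        self.ids = np.array(["A", "A"])
        self.B0_all = np.full((3, 200), 120.0)
        self.all_ids = np.array(["A", "A", "A"])

    def test_p_mpa_zero_is_raw_mean(self):
        _, raw = A.jurisdiction_biomass(self.status.B_marg, self.ids)
        _, w = A.jurisdiction_biomass(self.status.B_marg, self.ids, "weighted", {"A": 0.0},
                                      self.B0_all, self.all_ids)
        np.testing.assert_allclose(w, raw)
        np.testing.assert_allclose(raw[0], 40.0)

    def test_p_mpa_one_is_unfished_mean(self):
        _, w = A.jurisdiction_biomass(self.status.B_marg, self.ids, "weighted", {"A": 1.0},
                                      self.B0_all, self.all_ids)
        np.testing.assert_allclose(w[0], 120.0)

    def test_half_mix(self):
        _, w = A.jurisdiction_biomass(self.status.B_marg, self.ids, "weighted", {"A": 0.5},
                                      self.B0_all, self.all_ids)
        np.testing.assert_allclose(w[0], 80.0)

    def test_weighted_without_pmpa_raises(self):
        with pytest.raises(ValueError):
            A.jurisdiction_biomass(self.status.B_marg, self.ids, "weighted")

    def test_weighting_cannot_increase_pct_below_bmmsy(self):
        """MPA weighting mixes in unfished biomass, so the share of jurisdictions
        below B_MMSY under weighted biomass is at most the share under raw."""
        rng = np.random.default_rng(3)
        B = rng.uniform(10.0, 80.0, 12)
        status = make_status(B=B, C=None, jitter=0.05)
        ids = np.array([f"J{i % 4}" for i in range(12)])
        labels, jur = A.jurisdiction_reference_points(status.refpts, ids)
        _, raw = A.jurisdiction_biomass(status.B_marg, ids)
        _, w = A.jurisdiction_biomass(status.B_marg, ids, "weighted",
                                      {c: 0.3 for c in labels}, status.refpts.B0_s, ids)
        st_raw = A.jurisdiction_status(jur, raw)
        st_w = A.jurisdiction_status(jur, w)
        below_raw = (np.median(st_raw.B_status, axis=1) < 1).mean()
        below_w = (np.median(st_w.B_status, axis=1) < 1).mean()
        assert below_w <= below_raw


class TestJurisdictionStatus:
    def test_catch_at_mmsy_gives_unit_fishing_status(self):
        status = make_status(B=[40.0], C=None)
        labels, jur = A.jurisdiction_reference_points(status.refpts, np.array(["A"]))
        C_c = np.array([float(np.median(jur.mmsy_s[0]))])
        st = A.jurisdiction_status(jur, None, C_c)
        assert float(np.median(st.F_status[0])) == pytest.approx(1.0, rel=1e-9)
        assert st.B_status is None

    def test_good_sites_give_good_jurisdiction(self):
        status = make_status(B=[50.0, 60.0], C=[2.0, 2.0])
        labels, jur = A.jurisdiction_reference_points(status.refpts, np.array(["A", "A"]))
        _, B_c = A.jurisdiction_biomass(status.B_marg, np.array(["A", "A"]))
        st = A.jurisdiction_status(jur, B_c, np.array([2.0]))
        out = A.classify_sites(st)
        assert out.loc[0, "category"] == "good_condition"


class TestSummaries:
    def test_all_below_gives_certain_percentage(self):
        status = make_status(B=[20.0, 25.0, 30.0], C=[1.0, 1.0, 1.0])
        s = A.summarize_assessment(status)
        row = s.loc["pct_below_bmmsy"]
        assert row["median"] == row["lo"] == row["hi"] == 100.0

    def test_no_catch_reports_unavailable(self):
        status = make_status(B=[20.0, 50.0], C=None)
        s = A.summarize_assessment(status)
        assert np.isnan(s.loc["pct_above_mmsy", "median"])
        assert s.loc["pct_below_bmmsy", "median"] == 50.0

    def test_category_percentages_sum_to_100(self):
        rng = np.random.default_rng(11)
        status = make_status(B=rng.uniform(5, 95, 30), C=rng.uniform(0, 12, 30), jitter=0.03)
        s = A.summarize_assessment(status)
        total = sum(s.loc[f"pct_{n}", "median"] for n in A.CATEGORY_NAMES)
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_recovers_designed_category_mix(self):
        """Sites constructed per the category rules are recovered at the designed
        proportions (exact here: no draw jitter)."""
        B = [50.0] * 5 + [44.0] * 3 + [30.0] * 2
        C = [5.0] * 5 + [8.0] * 3 + [9.0] * 2
        s = A.summarize_assessment(make_status(B=B, C=C))
        assert s.loc["pct_good_condition", "median"] == pytest.approx(50.0)
        assert s.loc["pct_warning", "median"] == pytest.approx(30.0)
        assert s.loc["pct_unsustainable", "median"] == pytest.approx(20.0)
        assert s.loc["pct_conservation_concern", "median"] == pytest.approx(50.0)


class TestSingleSiteClassification:
    def test_fishery_category_dataclass(self):
        status = make_status(B=[30.0], C=[9.0])
        cat = A.classify_site(status)
        assert cat.category == "unsustainable"
        assert cat.conservation_concern and cat.overfishing
        assert not cat.collapsed

    def test_invariant_unsustainable_implies_concern(self):
        rng = np.random.default_rng(1)
        status = make_status(B=rng.uniform(5, 95, 20), C=rng.uniform(0, 12, 20))
        for k in range(20):
            cat = A.classify_site(status, k)
            if cat.category == "unsustainable":
                assert cat.conservation_concern
            if cat.category == "good_condition":
                assert not cat.conservation_concern
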