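"""MED / DASH / DHD scoring engines and tertile assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dietmet import dietscores as ds


class TestReferenceCutoffs:
    def test_quantile_oracle_one_to_five(self):
        """Median and quintile boundaries of {1..5} under the linear
        interpolation convention."""
        df = pd.DataFrame({"vegetables": [1, 2, 3, 4, 5.0] * 2,
                           "sex": ["male"] * 10})
        cut = ds.compute_reference_cutoffs(df, df["sex"],
                                           components=["vegetables"])
        assert cut.medians["male"]["vegetables"] == 3.0
        np.testing.assert_allclose(cut.quintiles["male"]["vegetables"],
                                   [1.8, 2.6, 3.4, 4.2])

    def test_constant_intakes_degenerate_low_band(self):
        df = pd.DataFrame({"vegetables": [5.0] * 8, "sex": ["female"] * 8})
        cut = ds.compute_reference_cutoffs(df, df["sex"],
                                           components=["vegetables"])
        assert np.all(cut.quintiles["female"]["vegetables"] == 5.0)
        # tie rule puts everyone in the lowest band
        rank = ds._quintile_rank(np.array([5.0]),
                                 cut.quintiles["female"]["vegetables"])
        assert rank[0] == 1

    def test_sex_stratification(self):
        df = pd.DataFrame({
            "vegetables": [1, 2, 3, 4, 5, 101, 102, 103, 104, 105.0],
            "sex": ["male"] * 5 + ["female"] * 5,
        })
        cut = ds.compute_reference_cutoffs(df, df["sex"],
                                           components=["vegetables"])
        assert cut.medians["male"]["vegetables"] != \
            cut.medians["female"]["vegetables"]

    def test_small_stratum_raises(self):
        df = pd.DataFrame({"vegetables": [1.0, 2, 3, 4],
                           "sex": ["male"] * 4})
        with pytest.raises(ValueError, match="stratum"):
            ds.compute_reference_cutoffs(df, df["sex"],
                                         components=["vegetables"])


def _extremal_med(favourable, cutoffs, sex="male"):
    prof = {}
    med = cutoffs.medians[sex]
    for c in ds.MED_HEALTHY:
        prof[c] = med[c] * (2.0 if favourable else 0.5)
    for c in ds.MED_UNHEALTHY:
        prof[c] = med[c] * (0.5 if favourable else 2.0)
    return prof


class TestMedScore:
    def test_maximum_nine(self, reference_cutoffs):
        _, cut = reference_cutoffs
        prof = _extremal_med(True, cut)
        assert ds.med_score(prof, cut, "male", 30.0) == 9

    def test_alcohol_band_excludes_heavy_use(self, reference_cutoffs):
        _, cut = reference_cutoffs
        prof = _extremal_med(True, cut)
        assert ds.med_score(prof, cut, "male", 60.0) == 8
        assert ds.med_score(prof, cut, "male", 5.0) == 8  # below male band
        assert ds.med_score(prof, cut, "female", 5.0) == 9  # female band

    def test_minimum_zero(self, reference_cutoffs):
        _, cut = reference_cutoffs
        prof = _extremal_med(False, cut)
        assert ds.med_score(prof, cut, "male", 0.0) == 0

    def test_at_median_counts_favourably_for_healthy(self, reference_cutoffs):
        _, cut = reference_cutoffs
        prof = _extremal_med(False, cut)
        prof["fish"] = cut.medians["male"]["fish"]  # >= median scores 1
        assert ds.med_score(prof, cut, "male", 0.0) == 1

    def test_missing_component_raises(self, reference_cutoffs):
        _, cut = reference_cutoffs
        prof = _extremal_med(True, cut)
        del prof["fish"]
        with pytest.raises(KeyError, match="fish"):
            ds.med_score(prof, cut, "male", 0.0)


class TestDashScore:
    def test_extremes(self, reference_cutoffs):
        _, cut = reference_cutoffs
        best = {c: 1e9 for c in ds.DASH_HEALTHY}
        best.update({c: 0.0 for c in ds.DASH_UNHEALTHY})
        worst = {c: 0.0 for c in ds.DASH_HEALTHY}
        worst.update({c: 1e9 for c in ds.DASH_UNHEALTHY})
        assert ds.dash_score(best, cut, "male") == 40
        assert ds.dash_score(worst, cut, "male") == 8

    def test_boundary_tie_goes_to_lower_quintile(self, reference_cutoffs):
        _, cut = reference_cutoffs
        q = cut.quintiles["male"]["vegetables"]
        rank_at = ds._quintile_rank(np.array([q[1]]), q)[0]
        rank_above = ds._quintile_rank(np.array([q[1] + 1e-9]), q)[0]
        assert rank_at == 2 and rank_above == 3

    def test_rank_histogram_sums_to_n(self, reference_cutoffs):
        intakes, cut = reference_cutoffs
        males = intakes[intakes["sex"] == "male"]
        ranks = ds._quintile_rank(males["fruits"].to_numpy(),
                                  cut.quintiles["male"]["fruits"])
        assert len(ranks) == len(males)
        assert set(ranks) <= {1, 2, 3, 4, 5}

    def test_orientation_flag(self, reference_cutoffs):
        _, cut = reference_cutoffs
        prof = {c: 0.0 for c in ds.DASH_HEALTHY + ds.DASH_UNHEALTHY}
        standard = ds.dash_score(prof, cut, "male")
        flipped = ds.dash_score(prof, cut, "male", reverse_unhealthy=False)
        # all-zero profile: healthy ranks 1; unhealthy 5 reversed vs 1 raw
        assert standard == 5 + 15 and flipped == 5 + 3


class TestDhdScore:
    def test_maximum_140_at_cutoffs(self):
        tab = ds.DhdComponentTable.default()
        prof = {row.component: row.cutoff
                for _, row in tab.table[tab.table.scored == 1].iterrows()}
        assert ds.dhd_score(prof, tab) == pytest.approx(140.0)

    def test_midway_is_five(self):
        tab = ds.DhdComponentTable.default()
        prof = {row.component: row.cutoff
                for _, row in tab.table[tab.table.scored == 1].iterrows()}
        row = tab.table.set_index("component").loc["vegetables"]
        prof["vegetables"] = (row.threshold + row.cutoff) / 2
        assert ds.dhd_score(prof, tab) == pytest.approx(135.0)

    def test_unhealthy_above_threshold_scores_zero(self):
        tab = ds.DhdComponentTable.default()
        prof = {row.component: row.cutoff
                for _, row in tab.table[tab.table.scored == 1].iterrows()}
        row = tab.table.set_index("component").loc["red_meat"]
        prof["red_meat"] = row.threshold * 2
        assert ds.dhd_score(prof, tab) == pytest.approx(130.0)

    def test_coffee_unscored(self):
        tab = ds.DhdComponentTable.default()
        assert "coffee" not in tab.scored_components
        assert len(tab.scored_components) == 14

    def test_missing_component_raises(self):
        tab = ds.DhdComponentTable.default()
        with pytest.raises(KeyError, match="vegetables"):
            ds.dhd_score({"fruits": 100.0}, tab)


class TestTertiles:
    def test_equal_frequency_one_to_nine(self):
        vals = pd.Series(np.repeat(np.arange(1, 10), 30))
        t = ds.assign_tertiles(vals)
        assert (t[vals <= 3] == 1).all()
        assert (t[(vals >= 4) & (vals <= 6)] == 2).all()
        assert (t[vals >= 7] == 3).all()

    def test_all_equal_raises(self):
        with pytest.raises(ValueError, match="distinct"):
            ds.assign_tertiles(pd.Series([5.0] * 10))

    def test_ties_to_lower_tertile(self):
        vals = pd.Series([1.0, 1.0, 1.0, 2.0, 3.0, 4.0])
        t = ds.assign_tertiles(vals)
        q1 = np.quantile(vals, 1 / 3)
        assert (t[vals <= q1] == 1).all()


# ---------------------------------------------------------------------------
# properties
# ---------------------------------------------------------------------------

intake_profiles = st.fixed_dictionaries({
    c: st.floats(min_value=0.0, max_value=5000.0, allow_nan=False)
    for c in set(ds.MED_HEALTHY + ds.MED_UNHEALTHY + ds.DASH_HEALTHY
                 + ds.DASH_UNHEALTHY)
})


@given(prof=intake_profiles,
       alcohol=st.floats(min_value=0, max_value=200, allow_nan=False))
@settings(max_examples=300, deadline=None)
def test_score_bounds_random_profiles(reference_cutoffs, prof, alcohol):
    _, cut = reference_cutoffs
    assert 0 <= ds.med_score(prof, cut, "male", alcohol) <= 9
    assert 8 <= ds.dash_score(prof, cut, "female") <= 40


@given(data=st.data())
@settings(max_examples=150, deadline=None)
def test_monotonicity_in_single_components(reference_cutoffs, data):
    """Raising a healthy component never lowers a score; raising an
    unhealthy one never raises it."""
    _, cut = reference_cutoffs
    prof = data.draw(intake_profiles)
    bump = data.draw(st.floats(min_value=0.1, max_value=1000,
                               allow_nan=False))
    healthy = data.draw(st.sampled_from(ds.MED_HEALTHY))
    unhealthy = data.draw(st.sampled_from(ds.DASH_UNHEALTHY))
    base_med = ds.med_score(prof, cut, "male", 0.0)
    base_dash = ds.dash_score(prof, cut, "male")
    up = dict(prof); up[healthy] = prof[healthy] + bump
    assert ds.med_score(up, cut, "male", 0.0) >= base_med
    up = dict(prof); up[unhealthy] = prof[unhealthy] + bump
    assert ds.dash_score(up, cut, "male") <= base_dash


def test_affine_reuniting_invariance(reference_cutoffs):
    """Consistently rescaling intakes and cut-offs leaves MED/DASH fixed."""
    intakes, cut = reference_cutoffs
    scaled = intakes.copy()
    comps = [c for c in ds.REFERENCE_COMPONENTS]
    scaled[comps] = scaled[comps] * 2.2
    cut2 = ds.compute_reference_cutoffs(scaled, scaled["sex"])
    prof = intakes.iloc[0][comps].to_dict()
    prof2 = {k: v * 2.2 for k, v in prof.items()}
    assert ds.med_score(prof, cut, "male", 30.0) == \
        ds.med_score(prof2, cut2, "male", 30.0)
    assert ds.dash_score(prof, cut, "female") == \
        ds.dash_score(prof2, cut2, "female")


def test_diet_scorer_transformer(reference_cutoffs):
    from sklearn.base import clone

    intakes, _ = reference_cutoffs
    scorer = ds.DietScorer()
    clone(scorer)  # sklearn get_params/set_params contract
    df = intakes.copy()
    for c in ["wholegrain", "legumes", "nuts", "fish", "tea", "dairy",
              "fats_oils", "red_meat", "processed_meat", "sweet_beverages",
              "salt", "vegetables", "fruits"]:
        if c not in df.columns:
            df[c] = 10.0
    out = scorer.fit(df).transform(df)
    assert set(out.columns) >= {"med", "dash", "dhd", "med_tertile"}
    assert out["med"].between(0, 9).all()
    assert out["dash"].between(8, 40).all()
    assert out["dhd"].between(0, 140).all()
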