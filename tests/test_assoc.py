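"""Association screens: model fits, trend test, interactions, BH-FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import dietmet as dm
from dietmet.assoc import FitError, bh_fdr, intersect_signatures


def bh_bruteforce(p):
    """Independent step-up oracle: q_(i) = min_{j>=i} m p_(j)/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _ordinal_data(n, beta3, seed, beta2=None):
    """Latent-logistic ordinal outcome with tertile-coded exposure."""
    rng = np.random.default_rng(seed)
    tert = rng.integers(1, 4, n)
    beta2 = beta3 / 2 if beta2 is None else beta2
    lin = np.where(tert == 3, beta3, np.where(tert == 2, beta2, 0.0))
    latent = lin + rng.logistic(size=n)
    cuts = np.quantile(latent, [0.5, 0.8])
    y = (latent > cuts[0]).astype(int) + (latent > cuts[1]).astype(int)
    return pd.DataFrame({"gms": y, "tert": tert,
                         "score": tert + rng.normal(0, 0.1, n)})


class TestProportionalOdds:
    def test_planted_log_odds_recovered(self):
        """Tertile-3 log-odds −0.5 → OR ≈ 0.61 within ±0.1."""
        df = _ordinal_data(5000, beta3=-0.5, seed=4)
        r = dm.fit_proportional_odds(df, "gms", "tert", tertile=True)
        or3 = r.table.set_index("term").loc["tert[T3]", "effect"]
        assert abs(or3 - np.exp(-0.5)) < 0.1

    def test_single_tertile_errors(self):
        df = _ordinal_data(200, 0.0, 1)
        df["tert"] = 1
        with pytest.raises(FitError, match="tertile"):
            dm.fit_proportional_odds(df, "gms", "tert", tertile=True)

    def test_crude_equals_adjusted_with_empty_set(self):
        df = _ordinal_data(800, -0.4, 2)
        r1 = dm.fit_proportional_odds(df, "gms", "tert", adjust=None,
                                      tertile=True)
        r2 = dm.fit_proportional_odds(df, "gms", "tert", adjust=[],
                                      tertile=True)
        pd.testing.assert_frame_equal(r1.table, r2.table)


class TestPairLogit:
    def _pair_data(self, n, logor, seed):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-1.0 + logor * z)))
        y = np.where(rng.random(n) < p, 2, 1)
        return pd.DataFrame({"gms": y, "z": z})

    def test_planted_log_or_recovered(self):
        df = self._pair_data(4000, 0.4, 3)
        r = dm.fit_pair_logit(df, "gms", (1, 2), "z")
        assert abs(np.log(r.effect("z")) - 0.4) < 0.1

    def test_null_ci_covers_one(self):
        df = self._pair_data(3000, 0.0, 5)
        r = dm.fit_pair_logit(df, "gms", (1, 2), "z")
        row = r.table.iloc[0]
        assert row["ci_low"] < 1.0 < row["ci_high"]

    def test_single_class_errors(self):
        df = self._pair_data(200, 0.0, 1)
        df["gms"] = 2
        with pytest.raises(FitError):
            dm.fit_pair_logit(df, "gms", (1, 2), "z")

    def test_collapsed_2x2_matches_cross_product_ratio(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 2, 500).astype(float)
        y = np.where(rng.random(500) < np.where(x == 1, 0.6, 0.3), 1, 0)
        df = pd.DataFrame({"gms": y, "x": x})
        r = dm.fit_pair_logit(df, "gms", (0, 1), "x")
        tab = pd.crosstab(x, y).to_numpy().astype(float)
        cpr = (tab[1, 1] * tab[0, 0]) / (tab[1, 0] * tab[0, 1])
        assert r.effect("x") == pytest.approx(cpr, rel=1e-4)


class TestLinear:
    def test_identity_outcome(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"y": rng.normal(size=500)})
        df["x"] = df["y"]
        r = dm.fit_linear_assoc(df, "y", "x")
        assert r.effect("x") == pytest.approx(1.0)

    def test_planted_standardized_beta(self):
        """HOMA-IR-like trait regressed on a diet score: planted stdβ −0.09
        recovered within ±0.03 at n=3000."""
        rng = np.random.default_rng(12)
        n = 3000
        score = rng.normal(size=n)
        trait = -0.09 * score + np.sqrt(1 - 0.09 ** 2) * rng.normal(size=n)
        df = pd.DataFrame({"homa": trait, "med": score})
        r = dm.fit_linear_assoc(df, "homa", "med")
        assert abs(r.effect("med") + 0.09) < 0.03

    def test_stratified_fit(self):
        rng = np.random.default_rng(3)
        n = 600
        sex = np.where(rng.random(n) < 0.5, "male", "female")
        x = rng.normal(size=n)
        y = np.where(sex == "male", 0.5, -0.5) * x + rng.normal(size=n)
        df = pd.DataFrame({"y": y, "x": x, "sex": sex})
        rm = dm.fit_linear_assoc(df, "y", "x", stratum=df["sex"] == "male")
        rf = dm.fit_linear_assoc(df, "y", "x", stratum=df["sex"] == "female")
        assert rm.effect("x") > 0 > rf.effect("x")

    def test_small_stratum_errors(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "x": [0.0, 1.0]})
        with pytest.raises(FitError, match="n="):
            dm.fit_linear_assoc(df, "y", "x",
                                stratum=pd.Series([True, False]))

    def test_rank_deficient_design_errors(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"y": rng.normal(size=50),
                           "x": rng.normal(size=50)})
        df["x2"] = df["x"]
        with pytest.raises(FitError, match="rank"):
            dm.fit_linear_assoc(df, "y", "x", adjust=["x2"],
                                standardize=False)


class TestTrend:
    def test_monotone_effect_detected(self):
        df = _ordinal_data(5000, beta3=-0.6, beta2=-0.3, seed=9)
        p = dm.trend_test(df, "gms", "tert", "score")
        assert p < 0.05

    def test_null_p_uniform(self):
        """Trend p under the null is uniform (KS over 200 replicates,
        linear outcome family for speed)."""
        rng = np.random.default_rng(17)
        ps = []
        for _ in range(200):
            n = 150
            tert = rng.integers(1, 4, n)
            df = pd.DataFrame({
                "y": rng.normal(size=n),
                "tert": tert,
                "score": tert + rng.normal(0, 0.1, n),
            })
            ps.append(dm.trend_test(df, "y", "tert", "score",
                                    family="linear"))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_equal_medians_still_defined(self):
        df = _ordinal_data(900, -0.4, 2)
        df["score"] = np.where(df["tert"] == 1, 1.0, 2.0)  # two equal medians
        p = dm.trend_test(df, "gms", "tert", "score")
        assert 0.0 <= p <= 1.0


class TestInteraction:
    def _interacting(self, n, gamma, seed):
        rng = np.random.default_rng(seed)
        sex = np.where(rng.random(n) < 0.5, "male", "female")
        x = rng.normal(size=n)
        female = (sex == "female").astype(float)
        latent = 0.3 * x + gamma * x * female + rng.logistic(size=n)
        cuts = np.quantile(latent, [0.5, 0.8])
        y = (latent > cuts[0]).astype(int) + (latent > cuts[1]).astype(int)
        return pd.DataFrame({"gms": y, "x": x, "sex": sex})

    def test_planted_interaction_detected(self):
        df = self._interacting(5000, gamma=0.5, seed=21)
        p = dm.interaction_pvalue(df, "gms", "x", "sex")
        assert p < 0.05

    def test_null_interaction_rarely_flagged(self):
        hits = 0
        for seed in range(30):
            df = self._interacting(400, gamma=0.0, seed=100 + seed)
            if dm.interaction_pvalue(df, "gms", "x", "sex") < 0.05:
                hits += 1
        assert hits <= 5  # expectation 1.5 of 30 at the 5% level

    def test_constant_modifier_errors(self):
        df = self._interacting(300, 0.0, 2)
        df["sex"] = "male"
        with pytest.raises(FitError, match="constant"):
            dm.interaction_pvalue(df, "gms", "x", "sex")


class TestBhFdr:
    def test_spec_example(self):
        q, flags = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert flags.all()

    def test_all_ones(self):
        q, flags = bh_fdr([1.0, 1.0, 1.0])
        assert (q == 1.0).all() and not flags.any()

    def test_single_p(self):
        q, _ = bh_fdr([0.03])
        assert q[0] == pytest.approx(0.03)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_fdr([-0.1])

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(33)
        for _ in range(500):
            m = rng.integers(1, 40)
            p = rng.random(m)
            q, _ = bh_fdr(p)
            np.testing.assert_allclose(q, bh_bruteforce(p), atol=1e-12)

    def test_q_monotone_and_at_least_p(self):
        rng = np.random.default_rng(4)
        p = rng.random(50)
        q, _ = bh_fdr(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestIntersect:
    def test_disjoint_empty(self):
        assert intersect_signatures({"a": {"m1"}, "b": {"m2"}}, {"m1"},
                                    ["m1", "m2"]) == []

    def test_set_algebra(self):
        sets = {"med": {"A", "B", "C"}, "dash": {"B", "C"},
                "dhd": {"B", "C", "D"}}
        out = intersect_signatures(sets, {"C"}, ["A", "B", "C", "D"])
        assert out == ["C"]

    def test_registry_ordering(self):
        sets = {"d": {"x", "y", "z"}}
        out = intersect_signatures(sets, {"z", "x", "y"}, ["z", "y", "x"])
        assert out == ["z", "y", "x"]
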