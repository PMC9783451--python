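"""Correlation, Welch, Levene, MANOVA, and the decoupling report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from morphsong import formfunction_stats as ff
from morphsong import synthetic_cohort as sc


class TestPearsonWithP:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        entry = ff.pearson_with_p(x, 2 * x + 1)
        assert entry.r == pytest.approx(1.0)
        assert entry.p_two_sided == 0.0

    def test_hand_computed_example(self):
        entry = ff.pearson_with_p([1, 2, 3], [1, 3, 2])
        assert entry.r == pytest.approx(0.5, abs=1e-12)
        assert entry.p_two_sided is None  # n = 3 < 4: r only

    def test_constant_vector_gives_na_with_reason(self):
        entry = ff.pearson_with_p([1, 2, 3, 4], [5, 5, 5, 5])
        assert entry.is_na
        assert entry.na_reason == "insufficient variation"

    def test_nan_pairs_dropped(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.1, 6.0, 8.2, 9.9]
        entry = ff.pearson_with_p(x, y)
        assert entry.n == 4

    @given(st.integers(0, 500))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_scipy_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = 0.4 * x + rng.normal(size=12)
        mine = ff.pearson_with_p(x, y)
        ref_r, ref_p = stats.pearsonr(x, y)
        assert mine.r == pytest.approx(ref_r, abs=1e-10)
        assert mine.p_two_sided == pytest.approx(ref_p, abs=1e-10)
        swapped = ff.pearson_with_p(y, x)
        assert swapped.r == pytest.approx(mine.r, abs=1e-12)

    def test_affine_invariance_positive_slope(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = ff.pearson_with_p(x, y)
        shifted = ff.pearson_with_p(3.0 * x + 7.0, y)
        assert shifted.r == pytest.approx(base.r, abs=1e-12)


class TestWelch:
    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        result = ff.welch_t_test(x, x)
        assert result.statistic == pytest.approx(0.0)
        assert result.p_two_sided == pytest.approx(1.0)

    def test_hand_formula_oracle(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0])
        result = ff.welch_t_test(x, y)
        sx, sy = x.var(ddof=1) / 3, y.var(ddof=1) / 3
        t_oracle = (x.mean() - y.mean()) / np.sqrt(sx + sy)
        df_oracle = (sx + sy) ** 2 / (sx**2 / 2 + sy**2 / 2)
        assert result.statistic == pytest.approx(t_oracle, abs=1e-10)
        assert result.statistic == pytest.approx(-1.549, abs=1e-3)
        assert result.df == pytest.approx(df_oracle, abs=1e-10)
        assert result.df == pytest.approx(2.94, abs=0.01)

    def test_scraper_cohorts_significant_across_seeds(self):
        # scraper-present vs scraperless purring carriers, generator truth
        archetype = sc.default_archetypes()["purring"]
        for seed in range(20):
            rng = np.random.default_rng([seed, 77])
            with_scraper = rng.normal(
                archetype.carrier_hz_mean, archetype.carrier_hz_sd, 15
            )
            without = rng.normal(
                archetype.scraperless_carrier_hz_mean,
                archetype.scraperless_carrier_hz_sd,
                15,
            )
            result = ff.welch_t_test(with_scraper, without)
            assert result.statistic < 0
            assert result.p_two_sided < 0.01

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            ff.welch_t_test([1.0], [1.0, 2.0])


class TestLevene:
    def test_mirror_image_groups_equal_spread(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        result = ff.levene_test([x, -x])
        assert result.statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_two_sided == pytest.approx(1.0)

    def test_unequal_variances_detected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng([seed, 13])
            a = rng.normal(0, 1, 50)
            b = rng.normal(0, 2, 50)
            if ff.levene_test([a, b]).p_two_sided < 0.01:
                hits += 1
        assert hits >= 19

    def test_hand_anova_oracle(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(0, s, 12) for s in (1.0, 1.5, 3.0)]
        result = ff.levene_test(groups, center="median")
        # one-way ANOVA F on |x - group median|, computed from scratch
        devs = [np.abs(g - np.median(g)) for g in groups]
        alldev = np.concatenate(devs)
        grand = alldev.mean()
        ssb = sum(len(d) * (d.mean() - grand) ** 2 for d in devs)
        ssw = sum(((d - d.mean()) ** 2).sum() for d in devs)
        f_oracle = (ssb / 2) / (ssw / (len(alldev) - 3))
        assert result.statistic == pytest.approx(f_oracle, abs=1e-8)
        assert result.df == (2.0, 33.0)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n < 2"):
            ff.levene_test([[1.0, 2.0], [3.0]])


class TestManova:
    def test_null_simulation_rarely_significant(self):
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng([seed, 21])
            Y = rng.normal(size=(36, 2))
            groups = np.repeat(["a", "b", "c"], 12)
            if ff.manova_pillai(Y, groups).p < 0.05:
                rejections += 1
        assert 20 - rejections >= 17

    def test_extreme_separation(self):
        rng = np.random.default_rng(2)
        Y = np.vstack([rng.normal(0, 1, (15, 2)), rng.normal([10, 0], 1, (15, 2))])
        groups = np.repeat(["a", "b"], 15)
        assert ff.manova_pillai(Y, groups).p < 1e-6

    def test_matches_statsmodels_reference(self):
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(3)
        Y = rng.normal(size=(30, 2))
        Y[10:20] += 1.5
        Y[20:] += [0.0, 2.0]
        groups = np.repeat(["a", "b", "c"], 10)
        mine = ff.manova_pillai(Y, groups)
        frame = pd.DataFrame({"y1": Y[:, 0], "y2": Y[:, 1], "g": groups})
        ref = (
            MANOVA.from_formula("y1 + y2 ~ g", data=frame)
            .mv_test()
            .results["g"]["stat"]
            .loc["Pillai's trace"]
        )
        assert mine.statistic_value == pytest.approx(ref["Value"], abs=1e-8)
        assert mine.approx_f == pytest.approx(ref["F Value"], abs=1e-8)
        assert (mine.df1, mine.df2) == (ref["Num DF"], ref["Den DF"])

    def test_single_response_reduces_to_anova_f(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=24)
        y[8:16] += 1.0
        groups = np.repeat(["a", "b", "c"], 8)
        mine = ff.manova_pillai(y, groups)
        f_ref, p_ref = stats.f_oneway(y[:8], y[8:16], y[16:])
        assert mine.approx_f == pytest.approx(f_ref, abs=1e-8)
        assert mine.p == pytest.approx(p_ref, abs=1e-8)


class TestFormFunctionReport:
    def coupled_features(self, n_per=40, seed=0):
        """Dominant frequency tracks mirror size only in rattling."""
        rng = np.random.default_rng(seed)
        rows = []
        morphs = {}
        for m in ("ancestral", "purring", "rattling"):
            for i in range(n_per):
                rid = f"{m}{i}"
                mirror = rng.normal(1.8, 0.2)
                freq = rng.normal(6000.0, 200.0)
                if m == "rattling":
                    freq += 3000.0 * (mirror - 1.8)
                rows.append(
                    {
                        "individual_id": rid,
                        "mirror_size": mirror if m != "purring" else np.nan,
                        "harp_width": rng.normal(2.4, 0.2),
                        "scraper_present": 1,
                        "calling_dominant_frequency": freq,
                        "calling_amplitude_db": rng.normal(-15.0, 2.0),
                        "calling_frequency_evenness": rng.normal(-0.25, 0.03),
                    }
                )
                morphs[rid] = m
        return pd.DataFrame(rows).set_index("individual_id"), pd.Series(morphs)

    def test_generator_coupling_flagged_only_in_rattling(self):
        features, morphs = self.coupled_features()
        grid, summary = ff.formfunction_report(features, morphs)
        cell = grid.query(
            "trait_x == 'mirror_size' and trait_y == 'calling_dominant_frequency'"
        ).set_index("morph")
        assert cell.loc["rattling", "p"] < 0.05
        assert cell.loc["ancestral", "p"] > 0.05
        assert np.isnan(cell.loc["purring", "r"])  # no mirrors at all
        pair = next(
            p
            for p in summary["pairs"]
            if p["trait_x"] == "mirror_size"
            and p["trait_y"] == "calling_dominant_frequency"
        )
        assert pair["decoupled"]
        assert pair["per_morph"]["rattling"] == "+"
        assert pair["per_morph"]["purring"] == "NA"

    def test_single_morph_grid_only(self):
        features, morphs = self.coupled_features()
        only = morphs[morphs == "rattling"]
        grid, summary = ff.formfunction_report(features.loc[only.index], only)
        assert set(grid["morph"]) == {"rattling"}
        assert summary["n_decoupled_pairs"] == 0

    def test_shared_coupling_yields_no_flags(self):
        rng = np.random.default_rng(11)
        rows, morphs = [], {}
        for m in ("a", "b"):
            for i in range(50):
                rid = f"{m}{i}"
                harp = rng.normal(2.4, 0.3)
                rows.append(
                    {
                        "individual_id": rid,
                        "mirror_size": rng.normal(1.8, 0.2),
                        "harp_width": harp,
                        "scraper_present": 1,
                        "calling_dominant_frequency": 5000 - 800 * harp
                        + rng.normal(0, 100),
                        "calling_amplitude_db": rng.normal(-15, 2),
                        "calling_frequency_evenness": rng.normal(-0.25, 0.03),
                    }
                )
                morphs[rid] = m
        features = pd.DataFrame(rows).set_index("individual_id")
        grid, summary = ff.formfunction_report(features, pd.Series(morphs))
        pair = next(
            p
            for p in summary["pairs"]
            if p["trait_x"] == "harp_width"
            and p["trait_y"] == "calling_dominant_frequency"
        )
        assert pair["per_morph"] == {"a": "-", "b": "-"}
        assert not pair["decoupled"]

    def test_small_morph_warns_and_reports_na(self):
        features, morphs = self.coupled_features(n_per=3)
        with pytest.warns(UserWarning, match="n = 3"):
            grid, _ = ff.formfunction_report(features, morphs)
        assert grid["p"].isna().all()
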