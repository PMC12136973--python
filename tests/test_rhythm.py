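import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import dielomics as dl
from dielomics.synthetic_data import SimConfig, generate_truth, \
    simulate_gaussian_abundance
from dielomics.rhythm import (
    circular_difference,
    double_plot,
    fit_all,
    fit_cosinor,
    grid_search_acrophase,
    mrna_protein_lag,
    phase_concordance,
    rhythmic_fraction,
)

ZT = np.tile([2.0, 6.0, 10.0, 14.0, 22.0], 3)


def cosine(t, mesor, amp, phase):
    return mesor + amp * np.cos(2 * np.pi * (t - phase) / 24.0)


class TestFitCosinor:
    def test_noiseless_cosine_recovered_exactly(self):
        fit = fit_cosinor(cosine(ZT, 5.0, 2.0, 6.0), ZT)
        assert fit.mesor == pytest.approx(5.0)
        assert fit.amplitude == pytest.approx(2.0)
        assert fit.acrophase == pytest.approx(6.0)
        assert fit.p_value == pytest.approx(0.0, abs=1e-12)

    def test_constant_series_is_flat_not_failed(self):
        fit = fit_cosinor(np.full(15, 3.0), ZT)
        assert fit.defined
        assert fit.amplitude == 0.0
        assert fit.p_value == 1.0

    def test_too_few_points_undefined(self):
        fit = fit_cosinor([1.0, 2.0, 3.0], [2.0, 6.0, 10.0])
        assert not fit.defined

    def test_single_timepoint_rank_deficient(self):
        fit = fit_cosinor([1.0, 2.0, 1.5, 1.2], [2.0, 2.0, 2.0, 2.0])
        assert not fit.defined

    def test_constant_shift_moves_mesor_only(self, rng):
        y = cosine(ZT, 5.0, 2.0, 6.0) + rng.normal(0, 0.3, ZT.size)
        a, b = fit_cosinor(y, ZT), fit_cosinor(y + 7.5, ZT)
        assert b.mesor == pytest.approx(a.mesor + 7.5)
        assert b.amplitude == pytest.approx(a.amplitude)
        assert b.acrophase == pytest.approx(a.acrophase)
        assert b.p_value == pytest.approx(a.p_value)

    def test_time_origin_shift_moves_acrophase(self, rng):
        y = cosine(ZT, 5.0, 2.0, 6.0) + rng.normal(0, 0.3, ZT.size)
        a = fit_cosinor(y, ZT)
        s = 5.0
        b = fit_cosinor(y, np.mod(ZT + s, 24.0))
        assert b.acrophase == pytest.approx(np.mod(a.acrophase + s, 24.0))
        assert b.amplitude == pytest.approx(a.amplitude)
        assert b.p_value == pytest.approx(a.p_value)

    def test_grid_oracle_agrees_with_linear_fit(self, rng):
        for _ in range(20):
            phase = rng.uniform(0, 24)
            y = cosine(ZT, 5.0, 1.5, phase) + rng.normal(0, 0.5, ZT.size)
            fit = fit_cosinor(y, ZT)
            phi_grid, sse_grid = grid_search_acrophase(y, ZT)
            assert abs(circular_difference(fit.acrophase, phi_grid)) <= 0.2
            assert fit.rss <= sse_grid + 1e-9


class TestDoublePlot:
    def test_observation_count_doubles(self, small_dataset):
        m = small_dataset["fpkm"].subset(condition="ML")
        dp = double_plot(m)
        assert dp.values.shape[1] == 2 * m.values.shape[1]
        assert np.allclose(np.sort(dp.zt()),
                           np.sort(np.concatenate([m.zt(), m.zt() + 24.0])))

    def test_point_estimates_unchanged_p_deflated(self, small_dataset):
        m = small_dataset["fpkm"].subset(condition="ML")
        single = fit_all(m)
        doubled = fit_all(m, use_double_plot=True)
        np.testing.assert_allclose(single["mesor"], doubled["mesor"])
        np.testing.assert_allclose(single["amplitude"], doubled["amplitude"])
        np.testing.assert_allclose(single["acrophase"], doubled["acrophase"])
        informative = (single["p_value"] > 1e-12) & (single["p_value"] < 1)
        assert (
            doubled.loc[informative, "p_value"]
            <= single.loc[informative, "p_value"] + 1e-12
        ).all()


class TestFitAll:
    def test_all_constant_matrix_yields_no_rhythmic_calls(self, full_design):
        vals = pd.DataFrame(np.ones((5, 45)), index=list("abcde"),
                            columns=full_design["sample_id"])
        m = dl.OmicsMatrix("mrna", vals, full_design)
        fits = fit_all(m, condition="ML")
        assert fits["rhythmic"].sum() == 0
        assert (fits["p_value"] == 1.0).all()

    def test_bh_q_monotone_in_p_rank(self, small_dataset):
        fits = fit_all(small_dataset["fpkm"], condition="HL")
        d = fits[fits["defined"]].sort_values("p_value")
        assert (np.diff(d["q_value"].to_numpy()) >= -1e-15).all()
        assert (d["q_value"] >= d["p_value"] - 1e-15).all()

    def test_null_type_one_error_near_nominal(self, full_design):
        cfg = SimConfig(seed=31, n_genes=2000, frac_rhythmic=0.0,
                        frac_responsive=0.0)
        truth = generate_truth(cfg)
        m = simulate_gaussian_abundance(truth, full_design, cfg, noise_sd=0.5)
        fits = fit_all(m, condition="ML")
        rate = (fits["p_value"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_power_at_planted_rhythms(self, full_design):
        """High-SNR planted rhythms are detected at q < 0.05."""
        cfg = SimConfig(seed=32, n_genes=500, frac_rhythmic=0.91,
                        frac_responsive=0.0, amplitude_range=(1.5, 1.5))
        truth = generate_truth(cfg)
        m = simulate_gaussian_abundance(truth, full_design, cfg, noise_sd=0.5)
        fits = fit_all(m, condition="ML")
        detected = fits.set_index("feature_id")["rhythmic"]
        frac = detected[truth.loc[truth["is_rhythmic"],
                                  "feature_id"]].mean()
        assert frac >= 0.85

    def test_missing_values_fall_back_to_per_feature_path(self, full_design):
        cfg = SimConfig(seed=33, n_genes=20, frac_rhythmic=1.0,
                        amplitude_range=(2.0, 2.0))
        truth = generate_truth(cfg)
        m = simulate_gaussian_abundance(truth, full_design, cfg, noise_sd=0.2)
        vals = m.values.copy()
        ml_cols = full_design.loc[full_design["condition"] == "ML",
                                  "sample_id"].tolist()
        vals.loc[vals.index[0], ml_cols[:3]] = np.nan
        vals.loc[vals.index[1], ml_cols[:12]] = np.nan  # 3 ML obs -> undefined
        m2 = dl.OmicsMatrix("mrna", vals, full_design, raw=False)
        fits = fit_all(m2, condition="ML").set_index("feature_id")
        assert fits.iloc[0]["defined"]
        assert not fits.iloc[1]["defined"]


class TestCircularDifference:
    @pytest.mark.parametrize("a,b,expected",
                             [(6, 6, 0.0), (23, 1, -2.0), (2, 14, 12.0),
                              (1, 23, 2.0), (14, 2, 12.0)])
    def test_examples(self, a, b, expected):
        assert circular_difference(a, b) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            circular_difference(24.0, 3.0)

    @given(st.floats(0, 23.999), st.floats(0, 23.999))
    def test_range_and_consistency(self, a, b):
        d = circular_difference(a, b)
        assert -12.0 < d <= 12.0
        assert np.isclose(np.mod(b + d, 24.0), np.mod(a, 24.0), atol=1e-9)


class TestPhaseComparisons:
    def _fits(self, full_design, seed, shift=0.0, noise=0.4):
        cfg = SimConfig(seed=17, n_genes=300, frac_rhythmic=1.0,
                        frac_responsive=0.0, amplitude_range=(1.5, 1.5))
        truth = generate_truth(cfg)
        truth = truth.assign(
            phase_hours=np.mod(truth["phase_hours"] + shift, 24.0)
        )
        cfg2 = SimConfig(**{**cfg.__dict__, "seed": seed})
        m = simulate_gaussian_abundance(truth, full_design, cfg2, noise_sd=noise)
        return fit_all(m, condition="ML")

    def test_self_comparison_fully_concordant(self, full_design):
        fits = self._fits(full_design, seed=41)
        table, summary = phase_concordance(fits, fits)
        assert (table["delta"] == 0).all()
        assert summary["frac_within_2h"] == 1.0

    def test_independent_noise_same_phases_small_delta(self, full_design):
        a = self._fits(full_design, seed=42)
        b = self._fits(full_design, seed=43)
        _, summary = phase_concordance(a, b)
        assert summary["n"] > 200
        assert summary["median_abs_delta"] <= 1.0
        assert summary["circular_corr"] > 0.8

    def test_planted_six_hour_shift_recovered(self, full_design):
        a = self._fits(full_design, seed=44, shift=6.0)
        b = self._fits(full_design, seed=45, shift=0.0)
        _, summary = phase_concordance(a, b)
        assert summary["median_delta"] == pytest.approx(6.0, abs=0.5)

    def test_empty_intersection_flagged(self, full_design):
        fits = self._fits(full_design, seed=46)
        none = fits.assign(rhythmic=False)
        _, summary = phase_concordance(fits, none)
        assert not summary["defined"]

    def test_protein_equal_to_mrna_gives_zero_lag(self, full_design):
        fits = self._fits(full_design, seed=47)
        table, summary = mrna_protein_lag(fits, fits)
        assert (table["lag_hours"] == 0).all()
        assert summary["median_lag"] == 0.0

    def test_lag_convention_keeps_20h_as_20h(self, full_design):
        m = self._fits(full_design, seed=48)
        p = self._fits(full_design, seed=49, shift=20.0)
        _, summary = mrna_protein_lag(m, p)
        assert summary["median_lag"] == pytest.approx(20.0, abs=0.5)


class TestRhythmicFraction:
    def _annotation(self, feature_ids, compartments):
        return pd.DataFrame({"feature_id": feature_ids,
                             "compartment": compartments})

    def test_simple_fraction(self):
        fits = pd.DataFrame({
            "feature_id": [f"g{i}" for i in range(10)],
            "defined": True,
            "rhythmic": [True] * 9 + [False],
            "p_value": 0.01, "q_value": 0.01,
        })
        ann = self._annotation(fits["feature_id"], ["nucleus"] * 10)
        res = rhythmic_fraction({"ML": fits}, ann)
        row = res[(res["condition"] == "ML") & (res["compartment"] == "nucleus")]
        assert row["fraction"].iloc[0] == pytest.approx(0.9)

    def test_intersection_not_above_any_single_condition(self, rng):
        ids = [f"g{i}" for i in range(200)]
        ann = self._annotation(ids, ["nucleus"] * 200)
        conds = {}
        for cond in ("LL", "ML", "HL"):
            conds[cond] = pd.DataFrame({
                "feature_id": ids, "defined": True,
                "rhythmic": rng.random(200) < 0.6,
                "p_value": 0.01, "q_value": 0.01,
            })
        res = rhythmic_fraction(conds, ann).set_index("condition")
        inter = res.loc["all", "fraction"]
        singles = res.drop(index="all")["fraction"]
        assert inter <= singles.min() + 1e-12

    def test_unannotated_features_listed_and_excluded(self):
        fits = pd.DataFrame({"feature_id": ["a", "b"], "defined": True,
                             "rhythmic": [True, True],
                             "p_value": 0.01, "q_value": 0.01})
        ann = self._annotation(["a"], ["nucleus"])
        res = rhythmic_fraction({"ML": fits}, ann)
        assert res.attrs["excluded"] == ["b"]
        assert res["n_detected"].iloc[0] == 1
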