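import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import dielomics as dl
from dielomics.diffexp import (
    bh_adjust,
    call_mrna_de,
    default_loq,
    nb_wald_test,
    protein_de,
    protein_zscore_calls,
    size_factors,
)


# -- independent oracles ------------------------------------------------------

def bh_oracle(p):
    """Step-up BH recomputed literally from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = np.inf
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running_min = min(running_min, p[i] * m / (rank_from_top + 1))
        adj[i] = min(running_min, 1.0)
    return adj


def size_factor_oracle(counts):
    import statistics

    n_genes, n_samples = counts.shape
    gm = []
    for g in range(n_genes):
        row = counts[g]
        gm.append(np.exp(np.mean(np.log(row))) if (row > 0).all() else None)
    factors = []
    for j in range(n_samples):
        ratios = [counts[g, j] / gm[g] for g in range(n_genes)
                  if gm[g] is not None]
        factors.append(statistics.median(ratios))
    return np.array(factors)


def zscore_call_oracle(mean_test, mean_ctrl, loq, z_threshold=2.0):
    lfc = np.log2(mean_test) - np.log2(mean_ctrl)
    finite = np.isfinite(lfc)
    mu, sd = lfc[finite].mean(), lfc[finite].std(ddof=1)
    calls = []
    for i in range(len(lfc)):
        if not finite[i] or mean_test[i] <= loq or mean_ctrl[i] <= loq:
            calls.append("not_evaluable")
        elif (lfc[i] - mu) / sd > z_threshold:
            calls.append("up")
        elif (lfc[i] - mu) / sd < -z_threshold:
            calls.append("down")
        else:
            calls.append("unchanged")
    return calls


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    @pytest.mark.parametrize("p,expected", [([1.0, 1.0], [1.0, 1.0]),
                                            ([0.2], [0.2])])
    def test_degenerate_inputs(self, p, expected):
        assert np.allclose(bh_adjust(p), expected)

    def test_nan_propagated_and_excluded_from_family(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        # family size is 2, not 3
        assert np.allclose(q[[0, 2]], bh_oracle([0.01, 0.04]))

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), bh_oracle(p))

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame(np.tile([[10], [20], [5]], (1, 4)))
        assert np.allclose(size_factors(counts), 1.0)

    def test_doubled_sample_gets_doubled_factor(self):
        base = np.array([[10.0, 20.0], [40.0, 80.0], [5.0, 10.0]])
        sf = size_factors(pd.DataFrame(base))
        assert sf.iloc[1] / sf.iloc[0] == pytest.approx(2.0)

    def test_matches_brute_force_oracle(self, rng):
        counts = rng.integers(0, 200, size=(60, 8)).astype(float)
        counts[:5] = 0  # some genes excluded from the median
        sf = size_factors(pd.DataFrame(counts))
        assert np.allclose(sf, size_factor_oracle(counts))

    def test_fallback_when_no_gene_everywhere_nonzero(self, rng):
        counts = rng.integers(0, 50, size=(10, 4)).astype(float)
        counts[:, 0][counts[:, 0] > 0] = 0  # zero out a sample
        sf = size_factors(pd.DataFrame(counts))
        assert (sf > 0).all()


class TestNBWald:
    def _design(self):
        return dl.build_design(["ML", "HL"], ["+2"], 3)

    def test_identical_groups_null(self, rng):
        design = self._design()
        row = rng.integers(50, 500, size=30)
        counts = pd.DataFrame(
            np.tile(row[:, None], (1, 6)), columns=design["sample_id"]
        )
        res = nb_wald_test(counts, design, "HL", "+2")
        assert np.allclose(res["log2fc"], 0.0)
        assert (res["p_value"] > 0.99).all()

    def test_log2fc_sign_matches_mean_difference(self, rng):
        design = self._design()
        counts = pd.DataFrame(
            rng.poisson(100, size=(50, 6)).astype(float),
            columns=design["sample_id"],
        )
        res = nb_wald_test(counts, design, "HL", "+2")
        norm = counts.to_numpy() / size_factors(counts).to_numpy()
        diff = norm[:, 3:].mean(axis=1) - norm[:, :3].mean(axis=1)
        nonzero = np.abs(diff) > 1e-9
        assert (np.sign(res["log2fc"][nonzero]) == np.sign(diff[nonzero])).all()

    def test_all_zero_gene_not_evaluable(self):
        design = self._design()
        counts = pd.DataFrame(np.vstack([np.zeros(6), np.full(6, 100.0)]),
                              columns=design["sample_id"])
        res = nb_wald_test(counts, design, "HL", "+2")
        assert not res["evaluable"].iloc[0]
        calls = call_mrna_de(res)
        assert calls["call"].iloc[0] == "not_evaluable"

    def test_sensitivity_and_null_fdr(self, rng):
        """Planted 4-fold changes are caught; nulls rarely pass BH at 0.01."""
        design = self._design()
        r = 1 / 0.01
        n_planted, n_null = 200, 1800
        ctrl = rng.negative_binomial(r, r / (r + 500.0), size=(2000, 3))
        test_mean = np.r_[np.full(n_planted, 2000.0), np.full(n_null, 500.0)]
        test = rng.negative_binomial(r, r / (r + test_mean[:, None]),
                                     size=(2000, 3))
        counts = pd.DataFrame(np.hstack([ctrl, test]).astype(float),
                              columns=design["sample_id"])
        calls = call_mrna_de(nb_wald_test(counts, design, "HL", "+2"))
        sens = (calls["call"][:n_planted] == "up").mean()
        null_rate = (calls["p_adj"][n_planted:] < 0.01).mean()
        assert sens >= 0.9
        assert null_rate <= 0.02


class TestCallContract:
    @pytest.mark.parametrize(
        "lfc,padj,expected",
        [(1.5, 0.001, "up"), (0.9, 1e-10, "unchanged"),
         (-1.2, 0.02, "unchanged"), (-1.2, 0.001, "down"),
         (2.0, 0.5, "unchanged")],
    )
    def test_threshold_gates(self, lfc, padj, expected):
        res = pd.DataFrame({"feature_id": ["g"], "log2fc": [lfc],
                            "p_adj": [padj], "evaluable": [True]})
        assert call_mrna_de(res)["call"].iloc[0] == expected


class TestProteinZScore:
    def test_strong_outlier_called_up(self, rng):
        ctrl = np.full(100, 100.0)
        test = ctrl * 2 ** rng.normal(0, 0.2, 100)
        test[0] = ctrl[0] * 2**3  # far outside the fold-change spread
        res = protein_zscore_calls(pd.Series(test), pd.Series(ctrl), loq=1.0)
        assert res["call"].iloc[0] == "up"

    def test_loq_gate_vetoes_call(self, rng):
        ctrl = np.full(100, 100.0)
        test = ctrl * 2 ** rng.normal(0, 0.2, 100)
        test[0] = ctrl[0] * 2**3
        ctrl2 = ctrl.copy()
        ctrl2[0] = 0.5  # control mean at/below LOQ
        res = protein_zscore_calls(pd.Series(test), pd.Series(ctrl2), loq=1.0)
        assert res["call"].iloc[0] == "not_evaluable"

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(20, 200))
            ctrl = rng.lognormal(4, 1, n)
            test = ctrl * 2 ** rng.normal(0, 1, n)
            loq = float(np.percentile(np.r_[ctrl, test], rng.uniform(0, 30)))
            res = protein_zscore_calls(pd.Series(test), pd.Series(ctrl), loq)
            assert list(res["call"]) == zscore_call_oracle(test, ctrl, loq)

    def test_gaussian_null_call_rate_near_two_sided_2sd(self, rng):
        ctrl = np.full(5000, 1000.0)
        test = ctrl * 2 ** rng.normal(0, 0.5, 5000)
        res = protein_zscore_calls(pd.Series(test), pd.Series(ctrl), loq=0.0)
        rate = res["call"].isin(["up", "down"]).mean()
        assert 0.03 <= rate <= 0.06

    def test_scale_invariance_with_coscaled_loq(self, rng):
        ctrl = rng.lognormal(4, 1, 50)
        test = ctrl * 2 ** rng.normal(0, 1, 50)
        a = protein_zscore_calls(pd.Series(test), pd.Series(ctrl), loq=10.0)
        b = protein_zscore_calls(pd.Series(test * 7), pd.Series(ctrl * 7),
                                 loq=70.0)
        assert list(a["call"]) == list(b["call"])
        assert np.allclose(a["statistic"], b["statistic"], equal_nan=True)

    def test_zero_spread_warns_and_calls_nothing(self):
        res = protein_zscore_calls(pd.Series([10.0, 20.0]),
                                   pd.Series([5.0, 10.0]), loq=1.0)
        assert (res["call"] == "unchanged").all()

    def test_default_loq_is_first_percentile_of_control(self, small_dataset):
        m = small_dataset["protein"]
        loq = default_loq(m)
        ctrl = m.subset(condition="ML").values.to_numpy()
        assert loq == pytest.approx(np.nanpercentile(ctrl[np.isfinite(ctrl)], 1))

    def test_protein_de_wrapper_runs_per_contrast(self, small_dataset):
        res = protein_de(small_dataset["protein"], "HL", "+6")
        assert set(res["call"]) <= {"up", "down", "unchanged", "not_evaluable"}
        assert (res["timepoint_label"] == "+6").all()
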