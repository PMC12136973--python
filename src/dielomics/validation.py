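"""End-to-end validation experiments on synthetic data with known truth.

Each function simulates a dataset under stated conditions, runs the
relevant pipeline stages, and measures an operating characteristic:
type-I error of the cosinor test, acrophase recovery accuracy (with an
independent grid-search cross-check), mRNA-to-protein lag recovery,
differential-abundance sensitivity and null behaviour, core
light-response recovery, clustering recovery, and exactness of the
enrichment p-value against rational arithmetic. The analysis drivers,
the test suite and the reproduction script all call these functions so
the numbers they report come from one code path.
"""

from __future__ import annotations

import math
from dataclasses import replace as dc_replace
from fractions import Fraction

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .io_model import TIMEPOINT_LABELS, build_design
from .synthetic_data import (
    SimConfig,
    generate_truth,
    simulate_gaussian_abundance,
    simulate_mrna,
    simulate_protein,
)
from . import rhythm
from .diffexp import call_mrna_de, nb_wald_test, protein_zscore_calls
from .lightresponse import classify_core_table, core_union
from .cluster_enrich import hypergeom_enrich, hypergeom_tail, kmeans_merged, \
    zscore_by_feature


def design_arithmetic() -> dict:
    """Sample and cellular-state counts of the full factorial design."""
    return {
        "n_samples": len(build_design()),
        "n_states": len(
            build_design(n_replicates=1)[["condition", "timepoint_label"]]
            .drop_duplicates()
        ),
    }


def cosinor_type1(seed: int, n_genes: int = 2000, noise_sd: float = 0.5,
                  alpha: float = 0.05) -> dict:
    """Rejection rate of the cosinor F-test on flat genes (5 ZT x 3 reps)."""
    cfg = SimConfig(seed=seed, n_genes=n_genes, frac_rhythmic=0.0,
                    frac_responsive=0.0)
    truth = generate_truth(cfg)
    design = build_design()
    m = simulate_gaussian_abundance(truth, design, cfg, noise_sd=noise_sd)
    fits = rhythm.fit_all(m, condition="ML")
    rate = float((fits["p_value"] < alpha).mean())
    return {"rejection_rate": rate, "n": n_genes}


def phase_recovery(seed: int, n_genes: int = 500, amplitude: float = 1.5,
                   snr: float = 3.0) -> dict:
    """Acrophase accuracy at amplitude/noise = snr, plus grid-oracle check.

    Returns the circular mean absolute error of the fitted acrophase
    against the planted phase, and the largest circular gap between the
    closed-form linear fit and an independent brute-force phase grid
    search on the same series.
    """
    cfg = SimConfig(seed=seed, n_genes=n_genes, frac_rhythmic=1.0,
                    frac_responsive=0.0,
                    amplitude_range=(amplitude, amplitude))
    truth = generate_truth(cfg)
    design = build_design()
    m = simulate_gaussian_abundance(truth, design, cfg,
                                    noise_sd=amplitude / snr)
    sub = m.subset(condition="ML")
    fits = rhythm.fit_all(sub).set_index("feature_id")
    est = fits.loc[truth["feature_id"], "acrophase"].to_numpy()
    err = np.abs([rhythm.circular_difference(a, b)
                  for a, b in zip(est, truth["phase_hours"])])
    zt = sub.zt()
    Y = sub.values.to_numpy()
    gaps = []
    for i in range(n_genes):
        phi_grid, _ = rhythm.grid_search_acrophase(Y[i], zt)
        gaps.append(abs(rhythm.circular_difference(est[i], phi_grid)))
    return {
        "circular_mae_hours": float(np.mean(err)),
        "oracle_max_gap_hours": float(np.max(gaps)),
        "n": n_genes,
    }


def lag_recovery(seed: int, n_genes: int = 400, planted_lag: float = 4.0) -> dict:
    """Median recovered mRNA-to-protein acrophase lag for a planted lag."""
    cfg = SimConfig(seed=seed, n_genes=n_genes, frac_rhythmic=1.0,
                    frac_responsive=0.0,
                    protein_lag_range=(planted_lag, planted_lag))
    truth = generate_truth(cfg)
    design = build_design()
    _, fpkm = simulate_mrna(truth, design, cfg)
    protein = simulate_protein(truth, design, cfg)
    from .io_model import log2_transform

    fits_m = rhythm.fit_all(log2_transform(fpkm, 1.0), condition="ML")
    fits_p = rhythm.fit_all(log2_transform(protein, 1.0), condition="ML")
    _, summary = rhythm.mrna_protein_lag(fits_m, fits_p)
    return {"median_lag_hours": summary["median_lag"],
            "frac_lag_2_8": summary["frac_lag_2_8"], "n": summary["n"]}


def _zscore_call_bruteforce(mean_test, mean_ctrl, loq, z_threshold=2.0):
    """Literal reimplementation of the protein call rules, loop by loop."""
    lfc = [math.log2(t) - math.log2(c) if t > 0 and c > 0 else math.nan
           for t, c in zip(mean_test, mean_ctrl)]
    finite = [x for x in lfc if not math.isnan(x)]
    mu = sum(finite) / len(finite)
    sd = math.sqrt(sum((x - mu) ** 2 for x in finite) / (len(finite) - 1))
    calls = []
    for t, c, x in zip(mean_test, mean_ctrl, lfc):
        if math.isnan(x) or t <= loq or c <= loq:
            calls.append("not_evaluable")
        elif sd > 0 and (x - mu) / sd > z_threshold:
            calls.append("up")
        elif sd > 0 and (x - mu) / sd < -z_threshold:
            calls.append("down")
        else:
            calls.append("unchanged")
    return calls


def protein_z_validation(seed: int, n_vectors: int = 30,
                         n_null: int = 5000) -> dict:
    """Oracle equivalence on random fold-change vectors + Gaussian null rate."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    n_proteins = 0
    for _ in range(n_vectors):
        n = int(rng.integers(50, 500))
        ctrl = rng.lognormal(4, 1, n)
        test = ctrl * 2 ** rng.normal(0, 1, n)
        loq = float(np.percentile(np.r_[ctrl, test], rng.uniform(0, 30)))
        res = protein_zscore_calls(pd.Series(test), pd.Series(ctrl), loq)
        oracle = _zscore_call_bruteforce(test, ctrl, loq)
        mismatches += sum(a != b for a, b in zip(res["call"], oracle))
        n_proteins += n
    ctrl = np.full(n_null, 1000.0)
    test = ctrl * 2 ** rng.normal(0, 0.5, n_null)
    res = protein_zscore_calls(pd.Series(test), pd.Series(ctrl), loq=0.0)
    null_rate = float(res["call"].isin(["up", "down"]).mean())
    return {"oracle_mismatches": int(mismatches), "n_proteins": n_proteins,
            "null_call_rate": null_rate, "n_null": n_null}


def nb_de_operating(seed: int, n_planted: int = 200, n_null: int = 2000,
                    fold: float = 4.0, base_mean: float = 500.0,
                    dispersion: float = 0.01, n_reps: int = 3) -> dict:
    """Sensitivity at planted fold changes and null adjusted-call rate."""
    rng = np.random.default_rng(seed)
    design = build_design(["ML", "HL"], ["+2"], n_reps)
    r = 1.0 / dispersion

    def nb(mean, size):
        return rng.negative_binomial(r, r / (r + mean), size=size).astype(float)

    n_bg = n_null - n_planted
    ctrl = nb(base_mean, (n_null, n_reps))
    test_means = np.r_[np.full(n_planted, base_mean * fold),
                       np.full(n_bg, base_mean)]
    test = nb(test_means[:, None], (n_null, n_reps))
    counts = pd.DataFrame(np.hstack([ctrl, test]),
                          columns=design["sample_id"])
    calls = call_mrna_de(nb_wald_test(counts, design, "HL", "+2"))
    sensitivity = float((calls["call"][:n_planted] == "up").mean())

    null_counts = pd.DataFrame(nb(base_mean, (n_null, 2 * n_reps)),
                               columns=design["sample_id"])
    null_calls = nb_wald_test(null_counts, design, "HL", "+2")
    null_rate = float((null_calls["p_adj"] < 0.01).mean())
    return {"sensitivity": sensitivity, "null_padj_rate": null_rate,
            "n_planted": n_planted, "n_null": n_null}


def core_recovery(seed: int, n_genes: int = 1000) -> dict:
    """End-to-end recovery of planted HL-specific genes via core_union.

    120 HL-specific and 120 shared-response genes are planted at log2
    effect 2 under high SNR; the mRNA pipeline (counts -> NB Wald calls at
    both condition pairs and all five timepoints -> core classification ->
    gene-level union) is run and scored against the truth labels.
    """
    cfg = SimConfig(seed=seed, n_genes=n_genes, frac_responsive=0.24,
                    frac_shared=0.5, effect_size_log2=2.0,
                    mesor_log2_mean=8.0, mesor_log2_sd=1.0,
                    amplitude_range=(0.5, 1.5))
    truth = generate_truth(cfg)
    design = build_design()
    counts, _ = simulate_mrna(truth, design, cfg)
    tables = []
    for lab in TIMEPOINT_LABELS:
        hl = call_mrna_de(nb_wald_test(counts, test_condition="HL",
                                       timepoint_label=lab))
        ll = call_mrna_de(nb_wald_test(counts, test_condition="LL",
                                       timepoint_label=lab))
        tables.append(classify_core_table(hl, ll))
    union = core_union(tables)
    recovered = set(union["feature_id"])
    responsive = truth["response_mode"] != "none"
    specific = set(truth.loc[responsive & ~truth["shared_with_LL"],
                             "feature_id"])
    shared = set(truth.loc[responsive & truth["shared_with_LL"], "feature_id"])
    return {
        "recovery": len(recovered & specific) / len(specific),
        "contamination": len(recovered & shared) / len(shared),
        "n_specific": len(specific),
        "n_shared": len(shared),
        "n_recovered": len(recovered),
    }


def clustering_recovery(seed: int, n_per_group: int = 30) -> dict:
    """ARI of k-means on three planted profile groups, and determinism."""
    rng = np.random.default_rng(seed)
    t = np.arange(15)
    profiles = [np.cos(2 * np.pi * (t - s) / 15.0) for s in (0, 5, 10)]
    rows, labels = [], []
    for g, prof in enumerate(profiles):
        for _ in range(n_per_group):
            rows.append(prof + rng.normal(0, 0.05, t.size))
            labels.append(g)
    z = zscore_by_feature(
        pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])
    )
    a = kmeans_merged(z, z, k=3, seed=seed)
    b = kmeans_merged(z, z, k=3, seed=seed)
    ari = float(adjusted_rand_score(labels, a["cluster_id"]))
    deterministic = a.equals(b)
    return {"ari": ari, "deterministic": bool(deterministic),
            "n_genes": len(rows)}


def hypergeom_exhaustive(max_universe: int = 50) -> dict:
    """Exhaustive exactness check of the enrichment tail probability.

    Every (universe M <= max_universe, term size n, list size N, overlap k)
    instance is compared against the exact rational tail
    sum_{i>=k} C(n,i) C(M-n,N-i) / C(M,N). Also evaluates the worked
    4-of-5-in-10 case through the enrichment interface (p = 5/210).
    """
    max_err = 0.0
    n_instances = 0
    for M in range(1, max_universe + 1):
        for n in range(M + 1):
            for N in range(M + 1):
                total = math.comb(M, N)
                kmax = min(n, N)
                # suffix sums of the exact numerator terms
                terms = [math.comb(n, i) * math.comb(M - n, N - i)
                         for i in range(kmax + 1)]
                suffix = list(np.cumsum(terms[::-1])[::-1]) + [0]
                for k in range(kmax + 1):
                    exact = float(Fraction(int(suffix[k]), total))
                    got = hypergeom_tail(k, M, n, N)
                    max_err = max(max_err, abs(got - exact))
                    n_instances += 1
    worked = hypergeom_enrich(
        ["a", "b", "c", "d"],
        {"T": ["a", "b", "c", "d", "e"]},
        [chr(97 + i) for i in range(10)],
    )
    return {
        "max_abs_error": float(max_err),
        "n_instances": n_instances,
        "worked_case_p": float(worked["p"].iloc[0]),
    }


def physio_closed_forms() -> dict:
    """The canonical closed-form index evaluations."""
    from .physio import de_epoxidation_state, fv_over_fm, npq, srd

    return {
        "des_fully_deepoxidized": de_epoxidation_state(0, 0, 5),
        "des_fully_epoxidized": de_epoxidation_state(5, 0, 0),
        "des_equal_pools": de_epoxidation_state(1, 1, 1),
        "srd_800_4": srd(800.0, 4),
        "srd_unstacked_defined": not math.isnan(srd(50.0, 2))
        and math.isnan(srd(50.0, 1)),
        "fvfm_03_10": fv_over_fm(0.3, 1.0),
        "npq_10_05": npq(1.0, 0.5),
    }
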