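"""Fixed-period (24 h) cosinor rhythm detection and circular phase analytics.

The model per feature is

    y(t) = M + bc * cos(2*pi*t/T) + bs * sin(2*pi*t/T) + eps,   T = 24 h,

fit by ordinary least squares over all replicate observations at their
sampled ZT. Amplitude A = sqrt(bc^2 + bs^2), acrophase phi = the ZT of the
fitted maximum in [0, 24). Significance is the F-test of the joint null
bc = bs = 0 against the intercept-only model (2 numerator df), with
Benjamini-Hochberg control within one (layer, condition) family; features
with q < 0.05 are called rhythmic.

Phase comparisons (between light regimes, or protein vs cognate mRNA) use
minimal signed circular differences on the 24-h circle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import OmicsMatrix
from .diffexp import bh_adjust

PERIOD_H = 24.0


@dataclass
class CosinorFit:
    feature_id: str
    mesor: float
    amplitude: float
    acrophase: float
    p_value: float
    n_obs: int
    defined: bool
    rss: float = np.nan


def _design_columns(t: np.ndarray, period: float):
    w = 2.0 * np.pi / period
    return np.cos(w * t), np.sin(w * t)


def _phi_from_betas(bc: float, bs: float, period: float) -> float:
    # y = M + A*cos(w t - theta) with theta = atan2(bs, bc); max at t = theta/w
    theta = np.arctan2(bs, bc)
    return float(np.mod(theta * period / (2.0 * np.pi), period))


def fit_cosinor(y, t, period: float = PERIOD_H, feature_id: str = "") -> CosinorFit:
    """Least-squares cosinor fit of one abundance series.

    Requires >= 4 finite observations spanning at least 3 distinct times
    (full column rank); otherwise the fit is undefined and the feature is
    excluded downstream. A constant series is defined with amplitude 0 and
    p = 1 (there is no rhythm to detect, not a failure).
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    ok = np.isfinite(y) & np.isfinite(t)
    y, t = y[ok], t[ok]
    n = y.size
    if n < 4:
        return CosinorFit(feature_id, np.nan, np.nan, np.nan, np.nan, n, False)
    c, s = _design_columns(t, period)
    X = np.column_stack([np.ones(n), c, s])
    if np.linalg.matrix_rank(X) < 3:
        return CosinorFit(feature_id, np.nan, np.nan, np.nan, np.nan, n, False)
    if np.ptp(y) == 0.0:
        return CosinorFit(feature_id, float(y[0]), 0.0, np.nan, 1.0, n, True, 0.0)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss1 = float(resid @ resid)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    p = _f_pvalue(rss0, rss1, n)
    amp = float(np.hypot(beta[1], beta[2]))
    phi = _phi_from_betas(beta[1], beta[2], period)
    return CosinorFit(feature_id, float(beta[0]), amp, phi, p, n, True, rss1)


def _f_pvalue(rss0, rss1, n):
    df2 = n - 3
    if df2 <= 0:
        return np.nan
    if rss1 <= 0.0 or rss1 < 1e-14 * max(rss0, 1e-300):
        return 0.0  # (numerically) perfect cosine fit
    f = ((rss0 - rss1) / 2.0) / (rss1 / df2)
    return float(stats.f.sf(max(f, 0.0), 2, df2))


def double_plot(matrix: OmicsMatrix) -> OmicsMatrix:
    """Duplicate every observation 24 h later (classic double-plotting).

    Doubles the observation count; least-squares point estimates are
    unchanged but residual df are inflated, so p-values computed on
    double-plotted data are deflated — hence this is off by default in
    :func:`fit_all`.
    """
    design = matrix.design.copy()
    dup = design.copy()
    dup["sample_id"] = dup["sample_id"] + "_dp"
    dup["zt_hours"] = dup["zt_hours"] + PERIOD_H
    dup["replicate"] = dup["replicate"] + design["replicate"].max()
    new_design = pd.concat([design, dup], ignore_index=True)
    vals = matrix.values
    dup_vals = vals.copy()
    dup_vals.columns = [c + "_dp" for c in vals.columns]
    new_vals = pd.concat([vals, dup_vals], axis=1)
    return replace(matrix, values=new_vals, design=new_design)


def fit_all(
    matrix: OmicsMatrix,
    condition: str | None = None,
    q_threshold: float = 0.05,
    use_double_plot: bool = False,
    average_replicates: bool = False,
) -> pd.DataFrame:
    """Cosinor fit for every feature of a matrix (one condition family).

    Returns one row per feature with mesor, amplitude, acrophase, p_value,
    q_value (BH over the defined fits in this family), n_obs, ``defined``
    and the boolean ``rhythmic`` call at ``q < q_threshold``. Features
    failing the fit preconditions are retained with ``defined = False`` (the
    exclusion log).
    """
    m = matrix.subset(condition=condition) if condition is not None else matrix
    if use_double_plot:
        import logging

        logging.getLogger("dielomics").warning(
            "double-plotting duplicates observations and deflates p-values"
        )
        m = double_plot(m)
    t = m.zt()
    Y = m.values.to_numpy(dtype=float)
    if average_replicates:
        d = m.column_design()
        key = d["zt_hours"].to_numpy()
        uniq = np.unique(key)
        Y = np.column_stack([np.nanmean(Y[:, key == u], axis=1) for u in uniq])
        t = uniq

    n_feat = Y.shape[0]
    out = {
        "feature_id": np.asarray(m.feature_ids),
        "mesor": np.full(n_feat, np.nan),
        "amplitude": np.full(n_feat, np.nan),
        "acrophase": np.full(n_feat, np.nan),
        "p_value": np.full(n_feat, np.nan),
        "n_obs": np.zeros(n_feat, dtype=int),
        "defined": np.zeros(n_feat, dtype=bool),
    }

    complete = np.isfinite(Y).all(axis=1)
    c, s = _design_columns(t, PERIOD_H)
    X = np.column_stack([np.ones(t.size), c, s])
    if np.linalg.matrix_rank(X) < 3:
        complete = np.zeros_like(complete)  # per-feature path rejects properly
    if complete.any():
        Yc = Y[complete]
        beta, _, _, _ = np.linalg.lstsq(X, Yc.T, rcond=None)
        fitted = (X @ beta).T
        rss1 = np.sum((Yc - fitted) ** 2, axis=1)
        rss0 = np.sum((Yc - Yc.mean(axis=1, keepdims=True)) ** 2, axis=1)
        amp = np.hypot(beta[1], beta[2])
        phi = np.mod(
            np.arctan2(beta[2], beta[1]) * PERIOD_H / (2 * np.pi), PERIOD_H
        )
        p = np.array([_f_pvalue(r0, r1, t.size) for r0, r1 in zip(rss0, rss1)])
        const = np.ptp(Yc, axis=1) == 0.0
        amp[const], p[const], phi[const] = 0.0, 1.0, np.nan
        idx = np.where(complete)[0]
        out["mesor"][idx] = beta[0]
        out["amplitude"][idx] = amp
        out["acrophase"][idx] = phi
        out["p_value"][idx] = p
        out["n_obs"][idx] = t.size
        out["defined"][idx] = t.size >= 4

    for i in np.where(~complete)[0]:
        fit = fit_cosinor(Y[i], t, feature_id=str(m.feature_ids[i]))
        out["mesor"][i] = fit.mesor
        out["amplitude"][i] = fit.amplitude
        out["acrophase"][i] = fit.acrophase
        out["p_value"][i] = fit.p_value
        out["n_obs"][i] = fit.n_obs
        out["defined"][i] = fit.defined

    fits = pd.DataFrame(out)
    q = np.full(n_feat, np.nan)
    defined = fits["defined"].to_numpy()
    q[defined] = bh_adjust(fits.loc[defined, "p_value"].to_numpy())
    fits["q_value"] = q
    fits["rhythmic"] = defined & (fits["q_value"] < q_threshold)
    return fits


def grid_search_acrophase(y, t, period: float = PERIOD_H,
                          step: float = 0.1) -> tuple[float, float]:
    """Brute-force acrophase: scan phi over a grid, fit mesor+amplitude only.

    For each candidate phi the model y = M + A*cos(w*(t - phi)) is linear in
    (M, A); the phi minimizing residual SSE is returned with its SSE. This
    is an independent cross-check of the closed-form linear fit.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    ok = np.isfinite(y)
    y, t = y[ok], t[ok]
    w = 2.0 * np.pi / period
    phis = np.arange(0.0, period, step)
    regress = np.cos(w * (t[None, :] - phis[:, None]))  # grid x obs
    n = y.size
    sy = y.sum()
    best_sse, best_phi = np.inf, 0.0
    for phi, c in zip(phis, regress):
        sc, scc, scy = c.sum(), c @ c, c @ y
        det = n * scc - sc * sc
        if abs(det) < 1e-12:
            continue
        m_hat = (scc * sy - sc * scy) / det
        a_hat = (n * scy - sc * sy) / det
        resid = y - m_hat - a_hat * c
        sse = resid @ resid
        if a_hat < 0:  # negative amplitude is phi + half period
            phi = np.mod(phi + period / 2.0, period)
        if sse < best_sse - 1e-12:
            best_sse, best_phi = sse, phi
    return float(best_phi), float(best_sse)


def circular_difference(phase_a: float, phase_b: float,
                        period: float = PERIOD_H) -> float:
    """Minimal signed displacement a - b on the circle, in (-T/2, T/2].

    The antipodal boundary maps to +T/2 by convention.
    """
    a, b = float(phase_a), float(phase_b)
    if not (0.0 <= a < period and 0.0 <= b < period):
        raise ValueError(f"phases must lie in [0, {period}): got {a}, {b}")
    d = np.mod(a - b, period)
    return float(d if d <= period / 2.0 else d - period)


def _circular_corr(a_h: np.ndarray, b_h: np.ndarray) -> float:
    """Fisher-Lee circular correlation of two sets of phases in hours."""
    a = a_h * 2 * np.pi / PERIOD_H
    b = b_h * 2 * np.pi / PERIOD_H
    abar = np.arctan2(np.sin(a).sum(), np.cos(a).sum())
    bbar = np.arctan2(np.sin(b).sum(), np.cos(b).sum())
    sa, sb = np.sin(a - abar), np.sin(b - bbar)
    denom = np.sqrt((sa**2).sum() * (sb**2).sum())
    if denom == 0:
        return np.nan
    return float((sa * sb).sum() / denom)


def phase_concordance(fits_a: pd.DataFrame, fits_b: pd.DataFrame,
                      q_threshold: float = 0.05):
    """Compare acrophases of features rhythmic in both fit tables.

    Returns (per-feature table with signed delta hours, summary dict). The
    summary reports the concordant fraction (|delta| <= 2 h), median
    |delta| and a circular correlation coefficient; it is flagged undefined
    on an empty intersection.
    """
    ra = fits_a[fits_a["rhythmic"]].set_index("feature_id")
    rb = fits_b[fits_b["rhythmic"]].set_index("feature_id")
    common = ra.index.intersection(rb.index)
    if len(common) == 0:
        return (
            pd.DataFrame(columns=["feature_id", "phase_a", "phase_b", "delta"]),
            {"n": 0, "defined": False, "frac_within_2h": np.nan,
             "median_abs_delta": np.nan, "circular_corr": np.nan},
        )
    pa = ra.loc[common, "acrophase"].to_numpy()
    pb = rb.loc[common, "acrophase"].to_numpy()
    delta = np.array([circular_difference(x, y) for x, y in zip(pa, pb)])
    table = pd.DataFrame(
        {"feature_id": common, "phase_a": pa, "phase_b": pb, "delta": delta}
    )
    summary = {
        "n": int(len(common)),
        "defined": True,
        "frac_within_2h": float(np.mean(np.abs(delta) <= 2.0)),
        "median_abs_delta": float(np.median(np.abs(delta))),
        "median_delta": float(np.median(delta)),
        "circular_corr": _circular_corr(pa, pb),
    }
    return table, summary


def mrna_protein_lag(fits_mrna: pd.DataFrame, fits_protein: pd.DataFrame,
                     q_threshold: float = 0.05):
    """Protein-minus-mRNA acrophase lag for genes rhythmic in both layers.

    Lags are mapped to [0, 24) (a protein peaking 20 h after its mRNA is a
    20 h lag, not a -4 h one). The summary reports the median lag and the
    fraction of lags in the canonical 2-8 h window.
    """
    rm = fits_mrna[fits_mrna["rhythmic"]].set_index("feature_id")
    rp = fits_protein[fits_protein["rhythmic"]].set_index("feature_id")
    common = rm.index.intersection(rp.index)
    if len(common) == 0:
        return (
            pd.DataFrame(columns=["feature_id", "phase_mrna", "phase_protein",
                                  "lag_hours"]),
            {"n": 0, "defined": False, "median_lag": np.nan,
             "frac_lag_2_8": np.nan},
        )
    pm = rm.loc[common, "acrophase"].to_numpy()
    pp = rp.loc[common, "acrophase"].to_numpy()
    lag = np.mod(pp - pm, PERIOD_H)
    table = pd.DataFrame(
        {"feature_id": common, "phase_mrna": pm, "phase_protein": pp,
         "lag_hours": lag}
    )
    summary = {
        "n": int(len(common)),
        "defined": True,
        "median_lag": float(np.median(lag)),
        "frac_lag_2_8": float(np.mean((lag >= 2.0) & (lag <= 8.0))),
    }
    return table, summary


def rhythmic_fraction(fits_by_condition: dict, annotation: pd.DataFrame,
                      q_threshold: float = 0.05) -> pd.DataFrame:
    """Fraction of detected features called rhythmic, per genome compartment.

    ``fits_by_condition`` maps condition name -> fit table. Besides one row
    per (condition, compartment), an ``all`` pseudo-condition reports the
    intersection fraction (rhythmic in every supplied condition).
    Unannotated features are excluded and listed in the ``excluded`` frame
    attribute of the result.
    """
    ann = annotation.set_index("feature_id")["compartment"]
    rows, excluded = [], set()
    rhythmic_sets, detected_sets = {}, {}
    for cond, fits in fits_by_condition.items():
        det = fits[fits["defined"]]
        unknown = set(det["feature_id"]) - set(ann.index)
        excluded |= unknown
        det = det[det["feature_id"].isin(ann.index)]
        rhythmic_sets[cond] = set(det.loc[det["rhythmic"], "feature_id"])
        detected_sets[cond] = set(det["feature_id"])
        for comp, grp in det.groupby(det["feature_id"].map(ann)):
            n_det = len(grp)
            n_rhy = int(grp["rhythmic"].sum())
            rows.append({"condition": cond, "compartment": comp,
                         "n_detected": n_det, "n_rhythmic": n_rhy,
                         "fraction": n_rhy / n_det})
    if len(fits_by_condition) > 1:
        inter_rhy = set.intersection(*rhythmic_sets.values())
        inter_det = set.intersection(*detected_sets.values())
        comp_of = ann.to_dict()
        for comp in sorted({comp_of[f] for f in inter_det}):
            det_c = [f for f in inter_det if comp_of[f] == comp]
            rhy_c = [f for f in inter_rhy if comp_of[f] == comp]
            rows.append({"condition": "all", "compartment": comp,
                         "n_detected": len(det_c), "n_rhythmic": len(rhy_c),
                         "fraction": len(rhy_c) / len(det_c) if det_c else np.nan})
    result = pd.DataFrame(rows)
    result.attrs["excluded"] = sorted(excluded)
    return result
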