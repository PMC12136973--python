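"""Differential abundance calling for transcripts and proteins.

Transcripts: a simplified negative-binomial Wald test per timepoint against
the ML control (median-of-ratios size factors, method-of-moments gene-wise
dispersion floored at the across-gene median, normal Wald p-values,
Benjamini-Hochberg adjustment). The call contract is the conventional one
for this design: up if log2FC > 1 and adjusted p < 0.01, down if
log2FC < -1 and adjusted p < 0.01, else unchanged. No shrinkage or
independent filtering is attempted.

Proteins: replicate-mean abundances are compared as log2 fold changes and
scored against the fold-change distribution of all proteins in the same
contrast (Z-score); |Z| > 2 with both group means above the limit of
quantitation (LOQ) is a call, a mean at or below LOQ is not evaluable.
The Z distribution includes every finite fold change; the LOQ gate only
vetoes the final call.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import OmicsMatrix, normalize_label

logger = logging.getLogger("dielomics")

CALL_UP, CALL_DOWN = "up", "down"
CALL_UNCHANGED, CALL_NA = "unchanged", "not_evaluable"


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries are excluded from the family size m and propagated as NaN;
    output is clipped at 1 and order-preserving.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    q[ok] = out
    return q


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample scale factors.

    factor_j = median over genes (nonzero in every sample) of
    count_gj / geometric-mean_g(count). Falls back to library-size ratios
    (with a warning) if no gene is nonzero everywhere.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if positive.any():
        sub = mat[positive]
        gm = np.exp(np.log(sub).mean(axis=1, keepdims=True))
        factors = np.median(sub / gm, axis=0)
    else:
        logger.warning("no gene nonzero in all samples; "
                       "falling back to library-size ratios")
        lib = np.where(mat.sum(axis=0) > 0, mat.sum(axis=0), 1.0)
        factors = lib / np.exp(np.mean(np.log(lib)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _group_columns(design: pd.DataFrame, condition: str, timepoint_label: str):
    lab = normalize_label(timepoint_label)
    sel = (design["condition"] == condition) & (design["timepoint_label"] == lab)
    cols = design.loc[sel, "sample_id"].tolist()
    if not cols:
        raise ValueError(f"no samples for ({condition}, {timepoint_label})")
    return cols


def nb_wald_test(
    counts: OmicsMatrix | pd.DataFrame,
    design: pd.DataFrame | None = None,
    test_condition: str = "HL",
    timepoint_label: str = "+2",
    control_condition: str = "ML",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene NB Wald test of one condition pair at one timepoint.

    log2fc compares normalized group means (with pseudocount); the Wald
    statistic uses the NB variance mu + alpha*mu^2 with gene-wise
    method-of-moments dispersion floored at the across-gene median (raw
    per-gene moments at n = 3 are too noisy to be used alone). p-values are
    two-sided normal, BH-adjusted across all evaluable genes in the
    contrast. All-zero genes are not evaluable.
    """
    if isinstance(counts, OmicsMatrix):
        design = counts.design
        counts_df = counts.values
    else:
        if design is None:
            raise ValueError("design required when counts is a DataFrame")
        counts_df = counts
    cols_t = _group_columns(design, test_condition, timepoint_label)
    cols_c = _group_columns(design, control_condition, timepoint_label)
    sub = counts_df[cols_t + cols_c]
    sf = size_factors(sub)
    norm = sub.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    nt, nc = len(cols_t), len(cols_c)
    kt, kc = norm[:, :nt], norm[:, nt:]
    mt, mc = kt.mean(axis=1), kc.mean(axis=1)

    # method-of-moments dispersion per gene, pooled over the two groups,
    # floored at the across-gene median for stability at n = 3
    def _mom(group):
        mean = group.mean(axis=1)
        var = group.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mean) / mean**2
        return np.where(np.isfinite(a), a, 0.0)

    alpha_gene = np.clip((_mom(kt) + _mom(kc)) / 2.0, 0.0, None)
    evaluable = (mt + mc) > 0
    floor = np.median(alpha_gene[evaluable]) if evaluable.any() else 0.0
    alpha = np.maximum(alpha_gene, max(floor, 1e-8))

    log2fc = np.log2(mt + pseudocount) - np.log2(mc + pseudocount)

    sft, sfc = sf.to_numpy()[:nt], sf.to_numpy()[nt:]

    def _var_log2_mean(mean, group_sf, n):
        mu = mean[:, None] * group_sf[None, :]
        var_counts = mu + alpha[:, None] * mu**2
        var_norm_mean = (var_counts / group_sf[None, :] ** 2).sum(axis=1) / n**2
        with np.errstate(divide="ignore", invalid="ignore"):
            return var_norm_mean / ((mean + pseudocount) ** 2 * np.log(2.0) ** 2)

    se2 = _var_log2_mean(mt, sft, nt) + _var_log2_mean(mc, sfc, nc)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = log2fc / np.sqrt(se2)
    p = 2.0 * stats.norm.sf(np.abs(wald))
    p = np.where(evaluable, p, np.nan)
    res = pd.DataFrame(
        {
            "feature_id": np.asarray(counts_df.index),
            "base_mean": (mt + mc) / 2.0,
            "log2fc": np.where(evaluable, log2fc, np.nan),
            "statistic": np.where(evaluable, wald, np.nan),
            "p_value": p,
            "p_adj": bh_adjust(p),
            "evaluable": evaluable,
            "test_condition": test_condition,
            "timepoint_label": normalize_label(timepoint_label),
        }
    )
    return res


def call_mrna_de(results: pd.DataFrame, lfc_threshold: float = 1.0,
                 alpha: float = 0.01) -> pd.DataFrame:
    """Apply the transcript call contract to NB Wald results."""
    res = results.copy()
    call = np.full(len(res), CALL_UNCHANGED, dtype=object)
    sig = res["p_adj"].to_numpy() < alpha
    lfc = res["log2fc"].to_numpy()
    call[sig & (lfc > lfc_threshold)] = CALL_UP
    call[sig & (lfc < -lfc_threshold)] = CALL_DOWN
    call[~res["evaluable"].to_numpy()] = CALL_NA
    res["call"] = call
    res["layer"] = "mrna"
    return res


def de_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts of up/down calls per (test condition, timepoint)."""
    grp = calls.groupby(["test_condition", "timepoint_label"])["call"]
    return pd.DataFrame(
        {
            "n_up": grp.apply(lambda c: int((c == CALL_UP).sum())),
            "n_down": grp.apply(lambda c: int((c == CALL_DOWN).sum())),
        }
    ).reset_index()


def protein_zscore_calls(
    mean_test: pd.Series,
    mean_ctrl: pd.Series,
    loq: float,
    z_threshold: float = 2.0,
) -> pd.DataFrame:
    """Z-score outlier calls on protein replicate-mean fold changes.

    log2fc = log2(mean_test) - log2(mean_ctrl) per protein, standardized
    against the mean and SD of all finite fold changes in the contrast.
    A protein is up/down if |Z| exceeds ``z_threshold`` AND both group
    means exceed ``loq``; a mean at or below LOQ makes it not evaluable
    (but its fold change still shapes the Z distribution).
    """
    mean_test = pd.Series(mean_test, dtype=float)
    mean_ctrl = pd.Series(mean_ctrl, dtype=float).reindex(mean_test.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mean_test.to_numpy()) - np.log2(mean_ctrl.to_numpy())
    finite = np.isfinite(log2fc)
    z = np.full(log2fc.shape, np.nan)
    if finite.sum() >= 2:
        mu = log2fc[finite].mean()
        sd = log2fc[finite].std(ddof=1)
        if sd == 0:
            logger.warning("all protein fold changes identical; no calls made")
        else:
            z[finite] = (log2fc[finite] - mu) / sd
    above_loq = (mean_test.to_numpy() > loq) & (mean_ctrl.to_numpy() > loq)
    call = np.full(log2fc.shape, CALL_UNCHANGED, dtype=object)
    call[np.isfinite(z) & (z > z_threshold)] = CALL_UP
    call[np.isfinite(z) & (z < -z_threshold)] = CALL_DOWN
    not_eval = ~above_loq | ~finite
    call[not_eval & ((call == CALL_UP) | (call == CALL_DOWN))] = CALL_NA
    call[~finite] = CALL_NA
    call[~above_loq] = CALL_NA
    return pd.DataFrame(
        {
            "feature_id": mean_test.index,
            "mean_test": mean_test.to_numpy(),
            "mean_ctrl": mean_ctrl.to_numpy(),
            "log2fc": log2fc,
            "statistic": z,
            "call": call,
        }
    )


def default_loq(matrix: OmicsMatrix, control_condition: str = "ML") -> float:
    """Default LOQ: 1st percentile of nonmissing control-layer abundances."""
    ctrl = matrix.subset(condition=control_condition).values.to_numpy()
    vals = ctrl[np.isfinite(ctrl)]
    if vals.size == 0:
        raise ValueError("no finite control abundances to derive an LOQ")
    return float(np.percentile(vals, 1.0))


def protein_de(
    matrix: OmicsMatrix,
    test_condition: str,
    timepoint_label: str,
    control_condition: str = "ML",
    loq: float | None = None,
    z_threshold: float = 2.0,
) -> pd.DataFrame:
    """Protein differential-abundance calls for one contrast at one timepoint.

    Replicate means are means of per-replicate abundances (missing values
    skipped); the Z distribution is computed per (test vs control,
    timepoint) contrast.
    """
    if loq is None:
        loq = default_loq(matrix, control_condition)
    sub_t = matrix.subset(condition=test_condition,
                          timepoint_label=timepoint_label)
    sub_c = matrix.subset(condition=control_condition,
                          timepoint_label=timepoint_label)
    mean_t = sub_t.values.mean(axis=1, skipna=True)
    mean_c = sub_c.values.mean(axis=1, skipna=True)
    res = protein_zscore_calls(mean_t, mean_c, loq=loq, z_threshold=z_threshold)
    res["layer"] = "protein"
    res["test_condition"] = test_condition
    res["timepoint_label"] = normalize_label(timepoint_label)
    res["loq"] = loq
    return res
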