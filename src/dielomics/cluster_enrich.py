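"""Expression-pattern clustering, term enrichment and correlation analytics.

Per-gene Z-score normalization of state means, merged mRNA+protein k-means
(k = 16 by default, genes undetected in either layer excluded), upper-tail
hypergeometric term enrichment with Benjamini-Hochberg control, PCA with a
bottom-variance feature filter, and pairwise Pearson correlation with
complete / pairwise-complete missing-value handling (replicate QC and
protein co-expression).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .diffexp import bh_adjust

logger = logging.getLogger("dielomics")


def state_means(matrix, transform=None) -> pd.DataFrame:
    """Mean abundance per (condition, timepoint) cellular state.

    Columns are "<condition>_<timepoint>" in design order; replicate values
    are averaged with missing entries skipped.
    """
    d = matrix.column_design()
    key = d["condition"] + "_" + d["timepoint_label"]
    vals = matrix.values.to_numpy(dtype=float)
    cols, out = [], []
    import warnings

    for state in key.drop_duplicates():
        sel = (key == state).to_numpy()
        with warnings.catch_warnings():
            # all-missing states are legitimately NaN
            warnings.simplefilter("ignore", RuntimeWarning)
            out.append(np.nanmean(vals[:, sel], axis=1))
        cols.append(state)
    df = pd.DataFrame(np.column_stack(out), index=matrix.feature_ids, columns=cols)
    return transform(df) if transform else df


def zscore_by_feature(means: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z-scores of per-state means (mean 0, SD 1 per feature).

    Rows that are constant (SD 0) or contain non-finite values carry no
    pattern information and are excluded, with a log entry.
    """
    vals = means.to_numpy(dtype=float)
    finite = np.isfinite(vals).all(axis=1)
    sd = vals.std(axis=1, ddof=0)
    keep = finite & (sd > 0)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("zscore_by_feature: excluded %d constant/non-finite rows",
                    dropped)
    vals = vals[keep]
    z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(
        axis=1, ddof=0, keepdims=True
    )
    return pd.DataFrame(z, index=means.index[keep], columns=means.columns)


def _canonicalize_labels(labels: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k ordered by centroid peak position (ties by value).

    Makes cluster ids comparable across runs regardless of the arbitrary
    internal labelling of the optimizer.
    """
    order = sorted(
        range(centers.shape[0]),
        key=lambda c: (int(np.argmax(centers[c])), -float(np.max(centers[c]))),
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    return np.array([remap[l] for l in labels])


def kmeans_merged(
    z_mrna: pd.DataFrame,
    z_protein: pd.DataFrame,
    k: int = 16,
    max_iter: int = 1000,
    seed: int = 0,
    n_init: int = 10,
) -> pd.DataFrame:
    """k-means on concatenated mRNA ‖ protein Z-score profiles.

    Genes present in both layers (after Z-scoring) are clustered; the rest
    are dropped with a log entry. k-means++ initialization with a fixed
    seed makes assignments deterministic. Returns one row per gene with
    ``cluster_id`` in [1, k] (canonicalized by peak position) and the
    merged profile; total within-cluster SSE is in ``.attrs['sse']``.
    """
    common = z_mrna.index.intersection(z_protein.index)
    n_dropped = len(z_mrna.index.union(z_protein.index)) - len(common)
    if n_dropped:
        logger.info("kmeans_merged: dropped %d genes undetected in one layer",
                    n_dropped)
    if k > len(common):
        raise ValueError(f"k={k} exceeds the {len(common)} clusterable genes")
    merged = pd.concat(
        [z_mrna.loc[common].add_prefix("mrna_"),
         z_protein.loc[common].add_prefix("protein_")],
        axis=1,
    )
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                max_iter=max_iter, random_state=seed)
    raw_labels = km.fit_predict(merged.to_numpy())
    labels = _canonicalize_labels(raw_labels, km.cluster_centers_)
    out = merged.copy()
    out.insert(0, "cluster_id", labels)
    out.index.name = "feature_id"
    out = out.reset_index()
    out.attrs["sse"] = float(km.inertia_)
    return out


def hypergeom_tail(overlap: int, universe_size: int, term_size: int,
                   list_size: int) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap).

    Population ``universe_size`` with ``term_size`` successes, ``list_size``
    draws. This is the single p-value primitive used by
    :func:`hypergeom_enrich`.
    """
    if term_size == 0 or list_size == 0:
        return 1.0 if overlap <= 0 else 0.0
    return float(
        min(stats.hypergeom.sf(overlap - 1, universe_size, term_size, list_size),
            1.0)
    )


def hypergeom_enrich(
    gene_list,
    term_sets: dict,
    universe,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a gene list against term sets.

    For each term: population = universe size, successes = term members in
    the universe, draws = list size; p = P(X >= overlap). BH adjustment is
    across terms; ``significant`` marks p_adj < alpha.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_list = set(gene_list) & universe
    M, N = len(universe), len(gene_list)
    rows = []
    for term_id, members in term_sets.items():
        members = set(members) & universe
        n = len(members)
        k = len(members & gene_list)
        p = hypergeom_tail(k, M, n, N)
        rows.append(
            {
                "term_id": term_id,
                "overlap": k,
                "list_size": N,
                "term_size": n,
                "universe_size": M,
                "gene_ratio": (k / N) if N else np.nan,
                "p": min(p, 1.0),
            }
        )
    res = pd.DataFrame(rows)
    res["p_adj"] = bh_adjust(res["p"].to_numpy()) if len(res) else []
    res["significant"] = res["p_adj"] < alpha
    return res


def pca_scores(
    matrix: pd.DataFrame,
    var_filter: float = 0.10,
    center: bool = True,
    scale: bool = False,
):
    """PCA of samples after removing the lowest-variance features.

    ``matrix`` is feature x sample; the bottom ``var_filter`` fraction of
    features by variance is dropped before the decomposition (floor of
    n * var_filter features removed). Returns (scores DataFrame with one
    row per sample, explained-variance fractions).
    """
    vals = matrix.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise ValueError("need >= 2 samples for PCA")
    variances = vals.var(axis=1, ddof=1)
    n_remove = int(len(variances) * var_filter)
    if n_remove:
        keep = np.argsort(variances, kind="mergesort")[n_remove:]
        keep.sort()
    else:
        keep = np.arange(len(variances))
    if keep.size < 2:
        raise ValueError("fewer than 2 features retained after variance filter")
    X = vals[keep].T  # samples x features
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    scores = U * S
    total = float((S**2).sum())
    explained = S**2 / total if total > 0 else np.zeros_like(S)
    scores_df = pd.DataFrame(
        scores,
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(scores.shape[1])],
    )
    return scores_df, explained


def pairwise_pearson(
    matrix: pd.DataFrame,
    mode: str = "pairwise_complete",
    min_obs: int = 3,
) -> pd.DataFrame:
    """Pearson correlation between all column pairs of a feature x sample table.

    ``mode='complete'`` first drops every feature with any missing value;
    ``mode='pairwise_complete'`` uses, for each pair of columns, the
    features finite in both. Pairs with fewer than ``min_obs`` shared
    observations are undefined (NaN). Symmetric with unit diagonal.
    """
    if mode == "complete":
        df = matrix.dropna(axis=0, how="any")
    elif mode == "pairwise_complete":
        df = matrix
    else:
        raise ValueError(f"unknown mode {mode!r}")
    corr = df.corr(method="pearson", min_periods=min_obs)
    np.fill_diagonal(corr.to_numpy(), 1.0)
    return corr


def replicate_correlations(matrix, log2_pseudocount: float | None = None):
    """Replicate-QC: Pearson r between replicate pairs within each state.

    Optionally log2-transforms raw abundances first (pseudocount given).
    Returns a long table (condition, timepoint, rep_a, rep_b, r).
    """
    vals = matrix.values
    if log2_pseudocount is not None:
        vals = np.log2(vals + log2_pseudocount)
    d = matrix.column_design()
    rows = []
    for (cond, lab), grp in d.groupby(["condition", "timepoint_label"], sort=False):
        cols = grp["sample_id"].tolist()
        reps = grp["replicate"].tolist()
        sub = vals[cols]
        corr = pairwise_pearson(sub)
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                rows.append(
                    {"condition": cond, "timepoint_label": lab,
                     "rep_a": reps[i], "rep_b": reps[j],
                     "r": float(corr.iloc[i, j])}
                )
    return pd.DataFrame(rows)
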