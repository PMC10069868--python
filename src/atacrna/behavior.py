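"""Gene regulatory behaviors via variance partitioning.

Per gene, expression across samples is regressed on the accessibility
of its optimized promoter window (P) and on a distance-weighted sum of
its captured distal windows (E) using three ordinary least-squares
models:

    (1) expr ~ P + E + P:E        (full)
    (2) expr ~ P                  (promoter only)
    (3) expr ~ E                  (enhancer only)

Four variance metrics follow: m_enh = R2_full - R2_prom (information
lost dropping the enhancer terms), m_prom = R2_full - R2_enh,
m_combo = max(0, R2_full - R2_prom - R2_enh) (synergy beyond the two
single-predictor models; clipped when they share information), and
m_unexpl = 1 - R2_full. Genes are Ward-clustered on the four metrics
into k=4 behaviors, with each cluster labeled by its dominant metric
(greedy collision resolution). Direction-sharing chi-square tests and
cluster effect-size comparisons (one-way ANOVA + Tukey HSD) summarize
how the behaviors relate to differential expression.

Expression enters as log2(count / size_factor + 0.5), a monotone
variance-stabilizing surrogate; accessibility covariates are
median-ratio-normalized window coverages. Both choices are
flag-switchable at the pipeline level.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from atacrna.cisscore import distance_weight

logger = logging.getLogger(__name__)

BEHAVIOR_LABELS = {
    "m_enh": "enhancer_centric",
    "m_prom": "promoter_centric",
    "m_combo": "combo_centric",
    "m_unexpl": "unexplained",
}
METRIC_COLUMNS = list(BEHAVIOR_LABELS)


def vst_expression(counts: pd.DataFrame, sf: np.ndarray) -> pd.DataFrame:
    """log2(count / size_factor + 0.5) variance-stabilizing surrogate."""
    return np.log2(counts / np.asarray(sf, dtype=float) + 0.5)


def build_covariates(gene_id: str, expression: pd.DataFrame,
                     promoter_acc: pd.DataFrame, peak_acc: pd.DataFrame,
                     captured: pd.DataFrame) -> dict | None:
    """Per-sample expression / promoter / weighted-enhancer vectors.

    ``captured`` is the cis-score capture table (gene_id, region_id, d);
    the enhancer covariate is sum_r w(d_r) * acc_{r,s} with the same
    decay as the cis score. Genes missing from the expression or
    promoter tables are skipped (logged) and return None.
    """
    if gene_id not in expression.index or gene_id not in promoter_acc.index:
        logger.info("gene %s lacks expression or promoter window; skipped",
                    gene_id)
        return None
    if list(expression.columns) != list(promoter_acc.columns) or \
            list(expression.columns) != list(peak_acc.columns):
        raise ValueError("sample columns disagree across input tables")
    sub = captured[captured["gene_id"] == gene_id]
    sub = sub[sub["region_id"].isin(peak_acc.index)]
    enh = np.zeros(expression.shape[1])
    if len(sub):
        w = distance_weight(sub["d"].to_numpy())
        enh = w @ peak_acc.loc[sub["region_id"]].to_numpy(dtype=float)
    return {
        "gene_id": gene_id,
        "expression": expression.loc[gene_id].to_numpy(dtype=float),
        "promoter_acc": promoter_acc.loc[gene_id].to_numpy(dtype=float),
        "enhancer_acc": enh,
    }


def _r_squared(y: np.ndarray, design: np.ndarray) -> float:
    """OLS R^2 with intercept; equals the summed non-intercept
    sequential sums of squares over the total centered sum of squares."""
    X = np.column_stack([np.ones_like(y)] + list(design.T))
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        return np.nan
    return 1.0 - float(np.sum(resid ** 2)) / float(sst)


def variance_partition(cov: dict) -> dict | None:
    """Four variance metrics for one gene's covariates.

    Requires >= 5 samples (the full model spends 4 df). Zero-variance
    expression yields None (flagged, excluded from clustering).
    """
    y = cov["expression"]
    p_acc, e_acc = cov["promoter_acc"], cov["enhancer_acc"]
    if len(y) < 5:
        raise ValueError("variance partition requires >= 5 samples")
    if np.var(y) == 0:
        logger.info("gene %s has zero-variance expression; skipped",
                    cov["gene_id"])
        return None
    r2_full = _r_squared(y, np.column_stack([p_acc, e_acc, p_acc * e_acc]))
    r2_prom = _r_squared(y, p_acc[:, None])
    r2_enh = _r_squared(y, e_acc[:, None])
    return {
        "gene_id": cov["gene_id"],
        "r2_full": r2_full, "r2_promoter": r2_prom, "r2_enhancer": r2_enh,
        "m_enh": max(0.0, r2_full - r2_prom),
        "m_prom": max(0.0, r2_full - r2_enh),
        "m_combo": max(0.0, r2_full - r2_prom - r2_enh),
        "m_unexpl": 1.0 - r2_full,
    }


def profile_genes(gene_ids, expression, promoter_acc, peak_acc,
                  captured) -> pd.DataFrame:
    """Variance metrics for every profilable gene."""
    rows = []
    for g in gene_ids:
        cov = build_covariates(g, expression, promoter_acc, peak_acc,
                               captured)
        if cov is None:
            continue
        prof = variance_partition(cov)
        if prof is not None:
            rows.append(prof)
    return pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame()


def _assign_labels(cluster_means: pd.DataFrame) -> dict[int, str]:
    """Dominant-metric labeling as an optimal one-to-one assignment.

    Each cluster takes the label of a metric dominating its mean
    profile; contested metrics (two clusters sharing a dominant
    metric) are resolved globally by the assignment of labels to
    clusters that maximizes the total assigned cluster mean
    (Hungarian algorithm), which hands the contested label to the
    cluster carried furthest by it and the runner-up metric to the
    other. Collisions are logged.
    """
    from scipy.optimize import linear_sum_assignment

    mat = cluster_means[METRIC_COLUMNS].to_numpy(dtype=float)
    naive = {c: METRIC_COLUMNS[i]
             for c, i in zip(cluster_means.index, mat.argmax(axis=1))}
    rows, cols = linear_sum_assignment(mat, maximize=True)
    labels: dict[int, str] = {}
    for r, c in zip(rows, cols):
        cluster = cluster_means.index[r]
        metric = METRIC_COLUMNS[c]
        if naive[cluster] != metric:
            logger.info("cluster %s: dominant metric %s contested; "
                        "assigned %s", cluster, naive[cluster], metric)
        labels[cluster] = BEHAVIOR_LABELS[metric]
    return labels


def cluster_behaviors(profiles: pd.DataFrame, k: int = 4,
                      method: str = "ward",
                      seed: int = 0) -> pd.DataFrame:
    """Cluster the 4-metric matrix into k behaviors and label clusters.

    Default hierarchical clustering (Euclidean, Ward linkage) is fully
    deterministic; ``method="kmeans"`` uses seeded k-means instead.
    """
    if len(profiles) < k:
        raise ValueError(f"need at least k={k} genes, got {len(profiles)}")
    X = profiles[METRIC_COLUMNS].to_numpy(dtype=float)
    if method == "ward":
        Z = linkage(X, method="ward")
        ids = fcluster(Z, t=k, criterion="maxclust")
    elif method == "kmeans":
        from sklearn.cluster import KMeans
        ids = KMeans(n_clusters=k, n_init=10,
                     random_state=seed).fit_predict(X) + 1
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    out = profiles.copy()
    out["cluster_id"] = ids
    means = out.groupby("cluster_id")[METRIC_COLUMNS].mean()
    labels = _assign_labels(means)
    out["behavior_label"] = out["cluster_id"].map(labels)
    return out


def shared_direction_test(enh_bias: np.ndarray, prom_bias: np.ndarray,
                          expr_bias: np.ndarray,
                          correction: bool = False) -> dict:
    """Chi-square test of direction sharing within one gene cluster.

    Inputs are per-gene signs (+1/-1) of the condition-mean difference
    in distance-scaled enhancer accessibility, promoter accessibility,
    and expression. Builds the 2x2 table pairing (enhancer-RNA,
    promoter-RNA) x (shared, switched); Yates correction off by default.
    """
    enh_bias = np.sign(np.asarray(enh_bias, dtype=float))
    prom_bias = np.sign(np.asarray(prom_bias, dtype=float))
    expr_bias = np.sign(np.asarray(expr_bias, dtype=float))
    enh_shared = int(np.sum(enh_bias == expr_bias))
    prom_shared = int(np.sum(prom_bias == expr_bias))
    n = len(expr_bias)
    table = np.array([[enh_shared, n - enh_shared],
                      [prom_shared, n - prom_shared]])
    return chi_square_2x2(table, correction=correction)


def chi_square_2x2(table: np.ndarray, correction: bool = False) -> dict:
    """Pearson chi-square on a 2x2 table; statistic 0 / p 1 when a
    margin is empty."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return {"table": table, "statistic": 0.0, "p": 1.0}
    stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return {"table": table, "statistic": float(stat), "p": float(p)}


def cross_dataset_direction_test(lfc1: pd.Series, lfc2: pd.Series,
                                 top_n: int = 100,
                                 correction: bool = False) -> dict:
    """Direction sharing between two differential datasets.

    Takes the top ``top_n`` most up- and most down-regulated genes of
    dataset 1 (by signed logFC), looks their logFCs up in dataset 2
    (absentees dropped, logged), and tests the 2x2 direction table.
    """
    up = lfc1.sort_values(ascending=False).head(top_n)
    down = lfc1.sort_values(ascending=True).head(top_n)
    sel = pd.concat([up, down])
    present = sel.index.intersection(lfc2.index)
    if len(present) < len(sel):
        logger.info("%d genes absent from dataset 2; dropped",
                    len(sel) - len(present))
    d1 = np.sign(sel.loc[present].to_numpy())
    d2 = np.sign(lfc2.loc[present].to_numpy())
    table = np.array([
        [int(np.sum((d1 > 0) & (d2 > 0))), int(np.sum((d1 > 0) & (d2 <= 0)))],
        [int(np.sum((d1 <= 0) & (d2 > 0))), int(np.sum((d1 <= 0) & (d2 <= 0)))],
    ])
    res = chi_square_2x2(table, correction=correction)
    res["n_genes"] = int(len(present))
    res["shared_fraction"] = float(np.mean(d1 == d2)) if len(present) else np.nan
    return res


def cluster_effect_size_summary(cluster_labels: pd.Series,
                                lfc: pd.Series,
                                significant: pd.Series | None = None) -> dict:
    """Compare |log2FC| across behavior clusters.

    One-way ANOVA plus Tukey-HSD pairwise comparisons on absolute
    logFC; also reports per-cluster mean |logFC| and, when provided,
    the fraction of significant DEGs. Singleton clusters are excluded
    from Tukey (logged); a single usable cluster skips the tests.
    """
    common = cluster_labels.index.intersection(lfc.index)
    lab = cluster_labels.loc[common]
    absfc = lfc.loc[common].abs()
    summary = absfc.groupby(lab).agg(["mean", "count"])
    summary.columns = ["mean_abs_log2FC", "n_genes"]
    if significant is not None:
        summary["frac_significant"] = (
            significant.loc[common].astype(float).groupby(lab).mean())
    sizes = lab.value_counts()
    usable = sizes[sizes >= 2].index
    dropped = sizes[sizes < 2].index.tolist()
    if dropped:
        logger.info("clusters %s have < 2 genes; excluded from tests",
                    dropped)
    out: dict = {"summary": summary, "anova_p": np.nan, "tukey": None}
    if len(usable) < 2:
        logger.info("fewer than 2 usable clusters; ANOVA skipped")
        return out
    groups = [absfc[lab == c].to_numpy() for c in usable]
    out["anova_F"], out["anova_p"] = stats.f_oneway(*groups)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    mask = lab.isin(usable)
    tk = pairwise_tukeyhsd(absfc[mask].to_numpy(),
                           lab[mask].to_numpy().astype(str))
    out["tukey"] = pd.DataFrame(tk.summary().data[1:],
                                columns=tk.summary().data[0])
    return out
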