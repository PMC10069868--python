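"""Signed, distance-weighted per-gene cis-regulatory scores.

For each gene, all optimized accessibility windows whose midpoint lies
within 100 kb of the TSS -- excluding windows overlapping optimized
promoter regions -- contribute their differential-accessibility log2
fold change weighted by the distance decay

    w(d) = exp(-(0.5 + 4 * d / 100000))

and the contributions are summed into a single signed score per gene.
The sign convention follows the differential module's orientation. For
visualization, scores beyond two standard deviations of the cross-gene
mean are capped at mean +/- 2 SD.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from atacrna.intervals import overlap_mask

SPAN = 100_000
WEIGHT_OFFSET = 0.5
WEIGHT_SLOPE = 4.0


def distance_weight(d, offset: float = WEIGHT_OFFSET,
                    slope: float = WEIGHT_SLOPE,
                    scale: float = float(SPAN)) -> np.ndarray:
    """exp(-(offset + slope * d / scale)); d in bp."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    return np.exp(-(offset + slope * d / scale))


def capture_regions(tss: pd.DataFrame, windows: pd.DataFrame,
                    promoter_windows: pd.DataFrame, span: int = SPAN,
                    exclude: str = "any") -> pd.DataFrame:
    """Distal windows captured per gene.

    Parameters
    ----------
    tss : table with gene_id, chrom, tss columns.
    windows : optimized peak windows (chrom, start, end, name).
    promoter_windows : optimized promoter windows (chrom, start, end,
        name = gene_id).
    span : capture half-width around the TSS; the boundary is inclusive.
    exclude : "any" drops windows overlapping any gene's optimized
        promoter window (default, stricter reading); "own" drops only
        windows overlapping the captured gene's own promoter window.

    Returns a table (gene_id, region_id, chrom, start, end, d) with d
    the TSS-to-window-midpoint distance in bp.
    """
    if exclude not in ("any", "own"):
        raise ValueError("exclude must be 'any' or 'own'")
    win = windows.reset_index(drop=True).copy()
    win["midpoint"] = (win["start"] + win["end"]) // 2
    if exclude == "any" and len(promoter_windows):
        keep = ~overlap_mask(win, promoter_windows)
        win = win[keep].reset_index(drop=True)
    prom_by_gene = (promoter_windows.set_index("name")
                    if len(promoter_windows) else None)
    recs = []
    for g in tss.itertuples(index=False):
        sub = win[(win["chrom"] == g.chrom)
                  & (win["midpoint"] >= g.tss - span)
                  & (win["midpoint"] <= g.tss + span)]
        if exclude == "own" and prom_by_gene is not None \
                and g.gene_id in prom_by_gene.index:
            pw = prom_by_gene.loc[g.gene_id]
            ov = (sub["start"] < pw["end"]) & (sub["end"] > pw["start"])
            sub = sub[~ov]
        for r in sub.itertuples(index=False):
            recs.append((g.gene_id, r.name, r.chrom, r.start, r.end,
                         abs(int(r.midpoint) - int(g.tss))))
    return pd.DataFrame(recs, columns=["gene_id", "region_id", "chrom",
                                       "start", "end", "d"])


def score_genes(captured: pd.DataFrame, da_table: pd.DataFrame,
                gene_ids=None, span: int = SPAN) -> pd.DataFrame:
    """Sum distance-weighted logFC contributions per gene.

    captured : output of :func:`capture_regions`.
    da_table : differential-accessibility results indexed by feature_id
        with a log2FC column (regions missing from it contribute 0 and
        are not counted).
    gene_ids : optional full gene universe; genes without captured
        regions get score 0 with n_regions 0.
    """
    if len(captured) and (captured["d"] > span).any():
        raise ValueError("captured region beyond span; capture bug")
    scores: dict[str, float] = {}
    counts: dict[str, int] = {}
    if len(captured):
        lfc = da_table["log2FC"]
        sub = captured[captured["region_id"].isin(lfc.index)].copy()
        sub["contribution"] = (lfc.loc[sub["region_id"]].to_numpy()
                               * distance_weight(sub["d"].to_numpy()))
        grp = sub.groupby("gene_id")["contribution"]
        scores = grp.sum().to_dict()
        counts = sub.groupby("gene_id").size().to_dict()
    if gene_ids is None:
        gene_ids = sorted(scores)
    out = pd.DataFrame({
        "gene_id": list(gene_ids),
        "n_regions": [counts.get(g, 0) for g in gene_ids],
        "score": [scores.get(g, 0.0) for g in gene_ids],
    }).set_index("gene_id")
    out["capped_score"] = cap_scores(out["score"].to_numpy())
    return out


def cap_scores(scores: np.ndarray) -> np.ndarray:
    """Truncate to mean +/- 2 SD (computed over uncapped scores).

    Used for visualization only; fewer than 2 values pass through.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        return scores.copy()
    mu, sd = scores.mean(), scores.std(ddof=1)
    return np.clip(scores, mu - 2 * sd, mu + 2 * sd)
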