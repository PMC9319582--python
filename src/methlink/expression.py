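"""Expression deciles and their relation to TSS-window methylation.

Genes are ranked by mean RPKM (all samples pooled) into ten equal-size
deciles (1 = lowest expressed).  Window methylation is the unweighted mean
over (site, sample) methylation levels of a gene's assigned CpGs inside a
TSS-relative window; genes without a covered CpG in the window are excluded
from correlations rather than imputed.  Correlations treat the decile as a
numeric 1..10 score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profiling import CGI_STRATA


@dataclass
class WindowCorrelation:
    region: str
    n: int
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    flagged: bool = False  # zero variance -> correlation undefined


def compute_deciles(expression: pd.DataFrame) -> pd.DataFrame:
    """Assign each gene an expression decile 1..10 by mean RPKM rank.

    Ties are broken by gene_id (lexicographic) so the assignment is a pure
    function of the table; the gene at 1-based rank k of n receives decile
    ceil(10 k / n), which balances decile sizes to within one gene.
    """
    if len(expression) < 10:
        raise ValueError(f"need >=10 genes for deciles, got {len(expression)}")
    srt = expression.sort_values(
        ["mean_rpkm", "gene_id"], kind="mergesort"
    ).reset_index(drop=True)
    k = np.arange(1, len(srt) + 1)
    decile = -(-10 * k // len(srt))  # ceil(10k/n)
    return pd.DataFrame({"gene_id": srt["gene_id"], "decile": decile.astype(int)})


def window_methylation(
    assignments: pd.DataFrame,
    calls: pd.DataFrame,
    d_lo: int,
    d_hi: int,
    min_coverage: int = 10,
) -> pd.Series:
    """Per-gene mean methylation % over (site, sample) pairs with d in window.

    Genes with no qualifying pair are absent from the result (undefined).
    """
    if d_lo > d_hi:
        raise ValueError(f"empty window: d_lo {d_lo} > d_hi {d_hi}")
    sub = assignments[(assignments["d"] >= d_lo) & (assignments["d"] <= d_hi)]
    merged = sub.merge(
        calls[["chrom", "pos", "sample_id", "n_meth", "n_unmeth"]],
        on=["chrom", "pos"],
        how="inner",
    )
    cov = merged["n_meth"] + merged["n_unmeth"]
    merged = merged[cov >= min_coverage]
    if merged.empty:
        return pd.Series(dtype=float, name="mean_meth_pct")
    m = 100.0 * merged["n_meth"] / (merged["n_meth"] + merged["n_unmeth"])
    out = m.groupby(merged["gene_id"]).mean()
    out.name = "mean_meth_pct"
    return out


def gene_window_methylation(
    gene_id: str,
    assignments: pd.DataFrame,
    calls: pd.DataFrame,
    d_lo: int,
    d_hi: int,
    min_coverage: int = 10,
) -> float:
    """Single-gene convenience wrapper; NaN when undefined."""
    series = window_methylation(
        assignments[assignments["gene_id"] == gene_id], calls, d_lo, d_hi, min_coverage
    )
    return float(series.get(gene_id, np.nan))


def correlate_meth_expression(
    deciles: pd.DataFrame, window_meth: pd.Series, region: str = ""
) -> WindowCorrelation:
    """Pearson and Spearman correlation of decile score vs window methylation."""
    joined = deciles.merge(
        window_meth.rename("meth"), left_on="gene_id", right_index=True, how="inner"
    )
    n = len(joined)
    if n < 3:
        raise ValueError(f"need >=3 genes with defined window methylation, got {n}")
    x = joined["decile"].to_numpy(dtype=float)
    y = joined["meth"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return WindowCorrelation(region, n, np.nan, np.nan, np.nan, np.nan, flagged=True)
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return WindowCorrelation(
        region, n, float(pr.statistic), float(pr.pvalue),
        float(sr.statistic), float(sr.pvalue),
    )


def per_kb_correlations(
    deciles: pd.DataFrame,
    assignments: pd.DataFrame,
    calls: pd.DataFrame,
    window_nt: int = 10_000,
    min_coverage: int = 10,
) -> pd.DataFrame:
    """1-kb bin sweep of decile/methylation correlations across +/-window."""
    rows = []
    for lo in range(-window_nt, window_nt, 1000):
        hi = lo + 999
        wm = window_methylation(assignments, calls, lo, hi, min_coverage)
        if len(wm) < 3:
            continue
        wc = correlate_meth_expression(deciles, wm, region=f"{lo}:{hi}")
        rows.append(vars(wc))
    return pd.DataFrame(rows)


def decile_meth_summary(
    deciles: pd.DataFrame, window_meth: pd.Series
) -> pd.DataFrame:
    """Mean and standard error (sd/sqrt(n)) of window methylation per decile."""
    joined = deciles.merge(
        window_meth.rename("meth"), left_on="gene_id", right_index=True, how="inner"
    )
    rows = []
    for dec in range(1, 11):
        vals = joined.loc[joined["decile"] == dec, "meth"].to_numpy()
        n = len(vals)
        if n == 0:
            rows.append({"decile": dec, "n": 0, "mean_meth_pct": np.nan, "stderr": np.nan})
        elif n == 1:
            rows.append(
                {"decile": dec, "n": 1, "mean_meth_pct": float(vals[0]), "stderr": 0.0}
            )
        else:
            rows.append(
                {
                    "decile": dec,
                    "n": n,
                    "mean_meth_pct": float(vals.mean()),
                    "stderr": float(vals.std(ddof=1) / np.sqrt(n)),
                }
            )
    return pd.DataFrame(rows)


def cgi_class_by_decile(
    classes: pd.DataFrame, deciles: pd.DataFrame
) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Count CGIs per (region stratum, methylation class, expression decile).

    Returns the full zero-filled matrix and the silenced-vs-expressed
    contrast: hypermethylated promoter-stratum CGIs of decile-1 genes versus
    decile-10 genes.
    """
    regions = [s[0] for s in CGI_STRATA]
    cls_levels = ["hypo", "moderate", "hyper"]
    index = pd.MultiIndex.from_product(
        [regions, cls_levels, range(1, 11)], names=["region", "cls", "decile"]
    )
    if classes.empty:
        matrix = pd.DataFrame({"n": 0}, index=index).reset_index()
        return matrix, (0, 0)
    joined = classes.merge(deciles, on="gene_id", how="inner")
    counts = (
        joined.groupby(["region", "cls", "decile"])
        .size()
        .reindex(index, fill_value=0)
        .rename("n")
        .reset_index()
    )
    promoter = "[-2,0)kb"
    sel = counts[(counts["region"] == promoter) & (counts["cls"] == "hyper")]
    c1 = int(sel.loc[sel["decile"] == 1, "n"].sum())
    c10 = int(sel.loc[sel["decile"] == 10, "n"].sum())
    return counts, (c1, c10)
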