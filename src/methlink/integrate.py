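"""Integration of differentially methylated CpGs with differential gene
expression, producing the epigenetic-marker table.

DM CpGs are restricted to the -1 kb..+10 kb TSS flank (the region with a
plausible cis effect on expression), joined to genes passing the fold-change
and FDR cuts of the supplied DE table, and each (site, gene) pair is scored
with a per-sample Pearson correlation R between methylation % at the site
and RPKM of the gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import methylation_level


@dataclass
class IntegrationConfig:
    dm_region: tuple[int, int] = (-1000, 10_000)
    de_abs_fold_cut: float = 2.0
    #: The marker table is reproduced with an FDR cut of 0.1: published
    #: marker rows carry expression FDRs up to 9.8e-2, above the DE
    #: screen's own 0.05. Both are plain configuration.
    de_fdr_cut: float = 0.1
    r_samples_min: int = 3
    log2_expression: bool = False

    def __post_init__(self) -> None:
        if self.de_abs_fold_cut < 1:
            raise ValueError("de_abs_fold_cut must be >= 1")


def restrict_dm_region(
    dm: pd.DataFrame, assignments: pd.DataFrame, config: IntegrationConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Keep (DM site, gene) pairs with a non-ns call and offset in region.

    A site within the region of several genes pairs with each.  The report
    counts distinct DM CpGs and distinct genes harboring them.
    """
    if config is None:
        config = IntegrationConfig()
    lo, hi = config.dm_region
    called = dm[dm["call"] != "ns"]
    cand = called.merge(assignments[["chrom", "pos", "gene_id", "d"]], on=["chrom", "pos"])
    cand = cand[(cand["d"] >= lo) & (cand["d"] <= hi)]
    cand = cand.sort_values(["chrom", "pos", "gene_id"]).reset_index(drop=True)
    report = {
        "n_dm_cpgs_in_region": int(cand[["chrom", "pos"]].drop_duplicates().shape[0]),
        "n_genes_with_dm": int(cand["gene_id"].nunique()),
    }
    return cand, report


def join_dm_de(
    candidates: pd.DataFrame,
    de: pd.DataFrame,
    config: IntegrationConfig | None = None,
    known_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Join DM candidates with DE genes passing the fold and FDR cuts."""
    if config is None:
        config = IntegrationConfig()
    de_pass = de[
        (de["fold_change"].abs() > config.de_abs_fold_cut)
        & (de["fdr"] < config.de_fdr_cut)
    ]
    if known_genes is not None:
        missing = set(de_pass["gene_id"]) - set(known_genes)
        if missing:
            warnings.warn(
                f"{len(missing)} DE genes absent from annotation; dropped",
                stacklevel=2,
            )
            de_pass = de_pass[de_pass["gene_id"].isin(known_genes)]
    pairs = candidates.merge(de_pass, on="gene_id", how="inner")
    return pairs.sort_values(["chrom", "pos", "gene_id"]).reset_index(drop=True)


def per_pair_r(
    site_calls: pd.DataFrame,
    gene_rpkm: pd.Series,
    r_samples_min: int = 3,
    log2_expression: bool = False,
) -> float:
    """Pearson R across samples between site methylation % and gene RPKM.

    ``site_calls`` holds one site's calls (one row per sample);
    ``gene_rpkm`` maps sample_id -> RPKM.  NaN (flagged undefined) below the
    sample floor or at zero variance.
    """
    m = 100.0 * methylation_level(site_calls)
    meth = pd.Series(m.to_numpy(), index=site_calls["sample_id"].to_numpy()).dropna()
    common = meth.index.intersection(gene_rpkm.dropna().index)
    if len(common) < r_samples_min:
        return float("nan")
    x = meth.loc[common].to_numpy(dtype=float)
    y = gene_rpkm.loc[common].to_numpy(dtype=float)
    if log2_expression:
        y = np.log2(y + 1e-9)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def add_pair_correlations(
    pairs: pd.DataFrame,
    calls: pd.DataFrame,
    expression: pd.DataFrame,
    config: IntegrationConfig | None = None,
) -> pd.DataFrame:
    """Attach r_value and the sign-concordance flag to every pair.

    Concordance: sign(meth_diff * r_value) equals sign(fold_change) — a
    hypermethylated-in-group-1 site whose methylation tracks expression
    negatively should accompany a down-regulated gene, and so on.
    """
    if config is None:
        config = IntegrationConfig()
    sample_cols = [c for c in expression.columns if c not in ("gene_id", "mean_rpkm")]
    expr_by_gene = expression.set_index("gene_id")[sample_cols]
    out = pairs.copy()
    r_values = []
    for _, row in out.iterrows():
        site_calls = calls[(calls["chrom"] == row["chrom"]) & (calls["pos"] == row["pos"])]
        gene_rpkm = (
            expr_by_gene.loc[row["gene_id"]]
            if row["gene_id"] in expr_by_gene.index
            else pd.Series(dtype=float)
        )
        r_values.append(
            per_pair_r(
                site_calls,
                gene_rpkm,
                r_samples_min=config.r_samples_min,
                log2_expression=config.log2_expression,
            )
        )
    out["r_value"] = r_values
    with np.errstate(invalid="ignore"):
        out["concordant"] = (
            np.sign(out["meth_diff"] * out["r_value"]) == np.sign(out["fold_change"])
        ) & out["r_value"].notna()
    return out


def emit_marker_table(pairs: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Final marker rows (one per site x gene) plus the summary counts."""
    summary = {
        "n_dm_cpgs": 0 if pairs.empty else int(pairs[["chrom", "pos"]].drop_duplicates().shape[0]),
        "n_genes": 0 if pairs.empty else int(pairs["gene_id"].nunique()),
    }
    cols = [
        "chrom", "pos", "strand", "gene_id", "d", "meth_diff", "p_value",
        "q_value", "fold_change", "fdr", "r_value", "concordant",
    ]
    present = [c for c in cols if c in pairs.columns]
    rows = pairs[present].sort_values(["chrom", "pos", "gene_id"]).reset_index(drop=True) \
        if not pairs.empty else pd.DataFrame(columns=cols)
    return rows, summary
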