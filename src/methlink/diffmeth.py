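"""Per-CpG differential methylation: filter cascade, logistic-regression
likelihood-ratio test, Benjamini-Hochberg q-values, and hyper/hypo calls.

The test models the methylated count at a site as binomial with a logistic
link on a two-level group factor.  Because the factor is saturated, the
alternative's MLE is the group-wise pooled proportion and the null's the
overall pooled proportion, so the likelihood-ratio (deviance) statistic has
the closed form of a G-statistic on the 2x2 pooled count table, referred to
chi-square with 1 df.  The deviance stays finite under complete separation
(all-0% vs all-100% sites), unlike a Wald z.

The binomial model ignores replicate overdispersion; with overdispersed data
the p-values are anti-conservative.  That is a documented property of the
approach, not corrected here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SITE_KEY = ["chrom", "pos", "strand"]


@dataclass
class FilterConfig:
    """The coverage/presence filter cascade applied before testing."""

    min_coverage: int = 10
    max_coverage_percentile: float = 99.9
    min_samples_per_group: int = 3
    n_samples_per_group: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.min_samples_per_group <= self.n_samples_per_group:
            raise ValueError("require 0 < min_samples_per_group <= n_samples_per_group")
        if not 0 < self.max_coverage_percentile <= 100:
            raise ValueError("max_coverage_percentile must be in (0, 100]")


def filter_calls(
    calls: pd.DataFrame, groups: dict[str, str], config: FilterConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Apply the three-step filter cascade; returns (surviving calls, report).

    1. Drop (site, sample) records below ``min_coverage`` reads.
    2. Per sample, drop records above that sample's ``max_coverage_percentile``
       coverage quantile (linear-interpolation quantile on the post-step-1
       coverage vector) — a PCR-duplicate guard.
    3. Keep sites observed in at least ``min_samples_per_group`` surviving
       samples in *each* group.
    """
    if config is None:
        config = FilterConfig()
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"exactly two group labels required, got {labels}")
    unknown = set(calls["sample_id"]) - set(groups)
    if unknown:
        raise ValueError(f"samples without a group label: {sorted(unknown)}")

    n0 = len(calls)
    cov = calls["n_meth"] + calls["n_unmeth"]
    step1 = calls[cov >= config.min_coverage]
    removed_low = n0 - len(step1)

    cov1 = step1["n_meth"] + step1["n_unmeth"]
    cutoffs = cov1.groupby(step1["sample_id"]).quantile(
        config.max_coverage_percentile / 100.0
    )
    keep = cov1 <= step1["sample_id"].map(cutoffs)
    step2 = step1[keep]
    removed_high = len(step1) - len(step2)

    grp = step2["sample_id"].map(groups)
    present = (
        step2.assign(group=grp)
        .groupby(SITE_KEY + ["group"])["sample_id"]
        .nunique()
        .unstack("group", fill_value=0)
        .reindex(columns=labels, fill_value=0)
    )
    ok_sites = present[(present >= config.min_samples_per_group).all(axis=1)].index
    idx = pd.MultiIndex.from_frame(step2[SITE_KEY])
    step3 = step2[idx.isin(ok_sites)]
    removed_presence = len(step2) - len(step3)

    report = {
        "n_input": n0,
        "removed_low_coverage": removed_low,
        "removed_high_coverage": removed_high,
        "removed_group_presence": removed_presence,
        "n_output": len(step3),
        "coverage_cutoffs": {k: float(v) for k, v in cutoffs.items()},
    }
    assert report["n_input"] - report["n_output"] == (
        removed_low + removed_high + removed_presence
    )
    return step3.reset_index(drop=True), report


def _binom_ll(m: np.ndarray, u: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood kernel with the 0*log(0) := 0 convention."""
    with np.errstate(divide="ignore", invalid="ignore"):
        lm = np.where(m > 0, m * np.log(p, where=p > 0, out=np.zeros_like(p)), 0.0)
        lu = np.where(u > 0, u * np.log1p(-p, where=p < 1, out=np.zeros_like(p)), 0.0)
    return lm + lu


def dm_test_frame(
    calls: pd.DataFrame, groups: dict[str, str], weighting: str = "pooled"
) -> pd.DataFrame:
    """Group difference and LRT p-value for every site, vectorized.

    ``meth_diff`` is 100 * (group1 proportion - group2 proportion); groups
    are ordered by sorted label.  ``weighting='pooled'`` pools read counts
    across a group's samples (the logistic model's sufficient statistics);
    ``'mean'`` averages per-sample proportions instead (difference only —
    the test itself always uses pooled counts).
    """
    if weighting not in ("pooled", "mean"):
        raise ValueError("weighting must be 'pooled' or 'mean'")
    labels = sorted(set(groups.values()))
    df = calls.assign(group=calls["sample_id"].map(groups))
    sums = (
        df.groupby(SITE_KEY + ["group"])[["n_meth", "n_unmeth"]]
        .sum()
        .unstack("group")
        .fillna(0)
    )
    m1 = sums[("n_meth", labels[0])].to_numpy(dtype=float)
    u1 = sums[("n_unmeth", labels[0])].to_numpy(dtype=float)
    m2 = sums[("n_meth", labels[1])].to_numpy(dtype=float)
    u2 = sums[("n_unmeth", labels[1])].to_numpy(dtype=float)

    with np.errstate(invalid="ignore"):
        p1 = m1 / np.maximum(m1 + u1, 1e-300)
        p2 = m2 / np.maximum(m2 + u2, 1e-300)
        p0 = (m1 + m2) / np.maximum(m1 + u1 + m2 + u2, 1e-300)
    stat = 2.0 * (
        _binom_ll(m1, u1, p1) + _binom_ll(m2, u2, p2) - _binom_ll(m1 + m2, u1 + u2, p0)
    )
    stat = np.maximum(stat, 0.0)  # guard tiny negative round-off
    pval = stats.chi2.sf(stat, df=1)
    pval = np.where(stat == 0, 1.0, pval)

    if weighting == "pooled":
        diff = 100.0 * (p1 - p2)
    else:
        persample = df.copy()
        cov = persample["n_meth"] + persample["n_unmeth"]
        persample["prop"] = persample["n_meth"] / cov
        mp = (
            persample.groupby(SITE_KEY + ["group"])["prop"]
            .mean()
            .unstack("group")
            .reindex(sums.index)
        )
        diff = 100.0 * (mp[labels[0]] - mp[labels[1]]).to_numpy()

    out = sums.index.to_frame(index=False)
    out["meth_diff"] = diff
    out["lrt_stat"] = stat
    out["p_value"] = pval
    return out.sort_values(["chrom", "pos", "strand"]).reset_index(drop=True)


def dm_test(site_calls: pd.DataFrame, groups: dict[str, str]) -> tuple[float, float]:
    """Single-site convenience wrapper: (meth_diff, p_value)."""
    res = dm_test_frame(site_calls, groups)
    if len(res) != 1:
        raise ValueError("dm_test expects calls from exactly one site")
    return float(res.loc[0, "meth_diff"]), float(res.loc[0, "p_value"])


def adjust_q(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_dm(
    results: pd.DataFrame, q_cut: float = 0.01, diff_cut: float = 25.0
) -> tuple[pd.DataFrame, dict]:
    """Attach q-values and hyper/hypo/ns calls (strict inequalities)."""
    out = results.copy()
    if "q_value" not in out.columns:
        out["q_value"] = adjust_q(out["p_value"].to_numpy())
    sig = out["q_value"] < q_cut
    out["call"] = np.where(
        sig & (out["meth_diff"] > diff_cut),
        "hyper",
        np.where(sig & (out["meth_diff"] < -diff_cut), "hypo", "ns"),
    )
    counts = out["call"].value_counts().to_dict()
    counts = {k: int(counts.get(k, 0)) for k in ("hyper", "hypo", "ns")}
    return out, counts


def destrand(calls: pd.DataFrame) -> pd.DataFrame:
    """Merge '-'-strand calls of a symmetric CpG onto the '+'-strand cytosine.

    The '-'-strand cytosine of a CpG sits one base downstream of the '+'
    one, so its counts are added at (chrom, pos - 1) and the merged record
    is reported on '+'.  Off by default in the pipeline: the input's strand
    resolution is preserved unless explicitly requested.
    """
    df = calls.copy()
    minus = df["strand"] == "-"
    df.loc[minus, "pos"] = df.loc[minus, "pos"] - 1
    df["strand"] = "+"
    merged = (
        df.groupby(["chrom", "pos", "strand", "context", "sample_id"], as_index=False)[
            ["n_meth", "n_unmeth"]
        ].sum()
    )
    return merged[calls.columns.tolist()]
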