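"""TSS-anchored CpG profiling: context composition, genic assignment,
per-offset density/methylation profiles, and CpG-island census/classes.

All offsets are measured in the gene's transcription orientation: negative =
upstream (promoter side), positive = downstream (gene-body side).  For a
'+'-strand gene ``d = pos - tss``; for a '-'-strand gene ``d = tss - pos``.
A CpG within the window of several genes is assigned to each (profile
stacking requires multi-assignment); CpGs assigned to no gene are intergenic
and excluded downstream.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import methylation_level

WINDOW_NT = 10_000

#: CpG-island region strata relative to the TSS (labels -> closed/open bounds).
#: An island belongs to a stratum through its CpGs' offsets, not its interval.
CGI_STRATA: list[tuple[str, int, int, bool, bool]] = [
    # label, lo, hi, lo_inclusive, hi_inclusive
    ("[-10,-2)kb", -10_000, -2_000, True, False),
    ("[-2,0)kb", -2_000, 0, True, False),
    ("[0,+2]kb", 0, 2_000, True, True),
    ("(+2,+10]kb", 2_000, 10_000, False, True),
]

#: CpG-island methylation classes: hypomethylated up to and including 44%,
#: hypermethylated strictly above 97%, moderate between.
HYPO_MAX = 44.0
HYPER_MIN = 97.0


def classify_meth(mean_pct: float) -> str:
    if mean_pct <= HYPO_MAX:
        return "hypo"
    if mean_pct > HYPER_MIN:
        return "hyper"
    return "moderate"


# ---------------------------------------------------------------------------
# context composition
# ---------------------------------------------------------------------------

def context_composition(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-sample share of covered cytosines and mean methylation % by context.

    Shares are site-weighted (each covered cytosine counts once); the mean
    methylation is the unweighted mean of per-site levels, skipping
    zero-coverage records.  Empty input yields an empty summary.
    """
    if calls.empty:
        return pd.DataFrame(columns=["sample_id", "context", "n", "share", "mean_meth_pct"])
    df = calls.copy()
    df["m"] = methylation_level(df)
    grp = df.groupby(["sample_id", "context"])
    out = grp.agg(n=("pos", "size"), mean_meth_pct=("m", "mean")).reset_index()
    out["mean_meth_pct"] *= 100.0
    totals = out.groupby("sample_id")["n"].transform("sum")
    out["share"] = out["n"] / totals
    return out[["sample_id", "context", "n", "share", "mean_meth_pct"]]


# ---------------------------------------------------------------------------
# genic assignment
# ---------------------------------------------------------------------------

def assign_genic(
    sites: pd.DataFrame, genes: pd.DataFrame, window_nt: int = WINDOW_NT
) -> pd.DataFrame:
    """Assign each site to every gene whose TSS lies within ``window_nt``.

    ``sites`` needs columns chrom/pos (strand optional and carried through);
    returns one row per (site, gene) pair with the signed offset ``d``.
    """
    cols = ["chrom", "pos"] + (["strand"] if "strand" in sites.columns else [])
    sites = sites[cols].drop_duplicates()
    out_frames = []
    for chrom, s_chr in sites.groupby("chrom", sort=True):
        g_chr = genes[genes["chrom"] == chrom]
        if g_chr.empty:
            continue
        g_chr = g_chr.sort_values("tss", kind="mergesort")
        tss = g_chr["tss"].to_numpy()
        pos = s_chr["pos"].to_numpy()
        lo = np.searchsorted(tss, pos - window_nt, side="left")
        hi = np.searchsorted(tss, pos + window_nt, side="right")
        counts = hi - lo
        if counts.sum() == 0:
            continue
        site_idx = np.repeat(np.arange(len(pos)), counts)
        # gene index within the window for every (site, gene) pair
        gene_idx = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi) if b > a])
        pair_pos = pos[site_idx]
        pair_tss = tss[gene_idx]
        pair_strand = g_chr["strand"].to_numpy()[gene_idx]
        d = np.where(pair_strand == "+", pair_pos - pair_tss, pair_tss - pair_pos)
        frame = pd.DataFrame(
            {
                "chrom": chrom,
                "pos": pair_pos,
                "gene_id": g_chr["gene_id"].to_numpy()[gene_idx],
                "d": d.astype(np.int64),
            }
        )
        if "strand" in s_chr.columns:
            frame.insert(2, "strand", s_chr["strand"].to_numpy()[site_idx])
        out_frames.append(frame)
    if not out_frames:
        base = ["chrom", "pos"] + (["strand"] if "strand" in sites.columns else [])
        return pd.DataFrame(columns=base + ["gene_id", "d"])
    return pd.concat(out_frames, ignore_index=True)


def flag_islands(sites: pd.DataFrame, islands: pd.DataFrame) -> pd.DataFrame:
    """Add ``in_island``/``island_id`` columns by interval membership.

    Islands use BED convention (0-based half-open); a 1-based position ``pos``
    is inside [start, end) iff start < pos <= end.  Assumes non-overlapping
    islands (first match wins otherwise).
    """
    out = sites.copy()
    out["in_island"] = False
    out["island_id"] = pd.NA
    for chrom, idx in out.groupby("chrom").groups.items():
        isl = islands[islands["chrom"] == chrom].sort_values("start")
        if isl.empty:
            continue
        starts = isl["start"].to_numpy()
        ends = isl["end"].to_numpy()
        ids = isl["island_id"].to_numpy()
        pos = out.loc[idx, "pos"].to_numpy()
        j = np.searchsorted(starts, pos - 1, side="right") - 1
        ok = (j >= 0) & (pos - 1 < ends[np.maximum(j, 0)]) & (pos - 1 >= starts[np.maximum(j, 0)])
        out.loc[idx[ok], "in_island"] = True
        out.loc[idx[ok], "island_id"] = ids[j[ok]]
    return out


# ---------------------------------------------------------------------------
# per-offset profiles
# ---------------------------------------------------------------------------

def per_nt_density(n_cpgs: int, window_nt: int = 2 * WINDOW_NT) -> float:
    """Mean per-nucleotide CpG density over a whole window.

    The published whole-window figures divide the total assignment count by
    the 20,000-nt span of the +/-10 kb frame.
    """
    return n_cpgs / window_nt


def _bin_offsets(d: np.ndarray, bin_nt: int, window_nt: int) -> np.ndarray:
    """Window-aligned bin key: bin 0 starts at -window_nt."""
    if bin_nt <= 0:
        raise ValueError("bin width must be positive")
    return np.floor_divide(np.asarray(d) + window_nt, bin_nt)


def position_profile(
    assignments: pd.DataFrame,
    calls: pd.DataFrame | None = None,
    bin_nt: int = 1,
    window_nt: int = WINDOW_NT,
    min_coverage: int = 10,
) -> pd.DataFrame:
    """Per-offset-bin CpG count, density, and mean methylation %.

    Bins partition offsets by ``floor(d / bin_nt)``; a bin's density is its
    assignment count divided by its inclusive width ``d_hi - d_lo + 1``.  The
    methylation mean is unweighted over (assigned site, sample) pairs whose
    coverage passes ``min_coverage`` (NaN where no pair qualifies).
    """
    if bin_nt <= 0:
        raise ValueError("bin width must be positive")
    d = assignments["d"].to_numpy()
    keys = _bin_offsets(d, bin_nt, window_nt)
    hi_key = (2 * window_nt) // bin_nt
    all_keys = np.arange(0, hi_key + 1)
    counts = pd.Series(keys).value_counts().reindex(all_keys, fill_value=0)

    d_lo = -window_nt + all_keys * bin_nt
    d_hi = np.minimum(d_lo + bin_nt - 1, window_nt)
    width = d_hi - d_lo + 1
    prof = pd.DataFrame(
        {
            "d_lo": d_lo,
            "d_hi": d_hi,
            "n_cpgs": counts.to_numpy(),
            "density": counts.to_numpy() / width,
        }
    )
    prof["mean_meth_pct"] = np.nan
    if calls is not None and not calls.empty:
        merged = assignments.merge(
            calls[["chrom", "pos", "sample_id", "n_meth", "n_unmeth"]],
            on=["chrom", "pos"],
            how="inner",
        )
        cov = merged["n_meth"] + merged["n_unmeth"]
        merged = merged[cov >= min_coverage]
        if not merged.empty:
            m = 100.0 * merged["n_meth"] / (merged["n_meth"] + merged["n_unmeth"])
            bykey = m.groupby(_bin_offsets(merged["d"].to_numpy(), bin_nt, window_nt)).mean()
            prof["mean_meth_pct"] = bykey.reindex(all_keys).to_numpy()
    return prof


def site_mean_methylation(
    calls: pd.DataFrame, min_coverage: int = 10
) -> pd.DataFrame:
    """Across-sample unweighted mean methylation % per site.

    Per-sample levels below the coverage floor are skipped; sites with no
    qualifying sample are dropped (their mean is undefined).
    """
    cov = calls["n_meth"] + calls["n_unmeth"]
    ok = calls[cov >= min_coverage].copy()
    if ok.empty:
        return pd.DataFrame(columns=["chrom", "pos", "mean_meth_pct", "n_samples"])
    ok["m"] = 100.0 * ok["n_meth"] / (ok["n_meth"] + ok["n_unmeth"])
    agg = (
        ok.groupby(["chrom", "pos"])["m"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "mean_meth_pct", "size": "n_samples"})
    )
    return agg


def methylation_interval_profile(
    assignments: pd.DataFrame,
    calls: pd.DataFrame,
    offset_bin_nt: int = 1000,
    n_intervals: int = 10,
    window_nt: int = WINDOW_NT,
    min_coverage: int = 10,
) -> pd.DataFrame:
    """CpG counts per (offset bin, methylation interval).

    Each assigned site falls in the interval of its across-sample mean
    methylation; intervals are equal-width with a closed top ([90, 100] for
    the default ten).  Interval counts per offset bin sum to that bin's
    assigned-site count (sites lacking any covered sample are excluded).
    """
    means = site_mean_methylation(calls, min_coverage=min_coverage)
    merged = assignments.merge(means, on=["chrom", "pos"], how="inner")
    if merged.empty:
        return pd.DataFrame(columns=["offset_bin", "d_lo", "d_hi", "interval", "n_cpgs"])
    width = 100.0 / n_intervals
    iv = np.minimum(
        np.floor(merged["mean_meth_pct"].to_numpy() / width).astype(int), n_intervals - 1
    )
    ob = _bin_offsets(merged["d"].to_numpy(), offset_bin_nt, window_nt)
    tab = (
        pd.DataFrame({"offset_bin": ob, "interval": iv})
        .value_counts()
        .rename("n_cpgs")
        .reset_index()
        .sort_values(["offset_bin", "interval"])
        .reset_index(drop=True)
    )
    tab["d_lo"] = -window_nt + tab["offset_bin"] * offset_bin_nt
    tab["d_hi"] = np.minimum(tab["d_lo"] + offset_bin_nt - 1, window_nt)
    tab["interval_label"] = [
        f"[{int(i * width)},{int((i + 1) * width)}{']' if i == n_intervals - 1 else ')'}"
        for i in tab["interval"]
    ]
    return tab[["offset_bin", "d_lo", "d_hi", "interval", "interval_label", "n_cpgs"]]


# ---------------------------------------------------------------------------
# CpG-island census and classification
# ---------------------------------------------------------------------------

def _stratum_of(d: np.ndarray) -> np.ndarray:
    lab = np.full(d.shape, "", dtype=object)
    for name, lo, hi, lo_inc, hi_inc in CGI_STRATA:
        lo_ok = d >= lo if lo_inc else d > lo
        hi_ok = d <= hi if hi_inc else d < hi
        lab[lo_ok & hi_ok] = name
    return lab


def cgi_census_and_classify(
    sites: pd.DataFrame,
    islands: pd.DataFrame,
    genes: pd.DataFrame,
    calls: pd.DataFrame,
    promoter_kb: int = 2,
    window_nt: int = WINDOW_NT,
    min_coverage: int = 10,
) -> tuple[dict, pd.DataFrame]:
    """Census of island CpGs around TSSs and per-(island, gene, stratum) classes.

    Census keys: ``n_island_cpgs`` (distinct island CpGs within the window),
    ``n_islands``, ``n_genes_with_cgi``, ``n_promoter_islands`` /
    ``n_promoter_genes`` (island CpGs at [-promoter_kb, 0) of a TSS), and
    ``promoter_cgi_gene_pct``.  Classification averages methylation over each
    island's CpGs (and samples) within a region stratum.
    """
    assigned = assign_genic(sites, genes, window_nt=window_nt)
    assigned = flag_islands(assigned, islands)
    isl = assigned[assigned["in_island"]].copy()

    absent = set(islands["chrom"]) - set(sites["chrom"]) if not islands.empty else set()
    if absent:
        warnings.warn(
            f"islands on chromosomes with no observed CpGs ({sorted(absent)}); "
            "counted with zero CpGs",
            stacklevel=2,
        )

    prom_lo = -promoter_kb * 1000
    in_prom = isl[(isl["d"] >= prom_lo) & (isl["d"] < 0)]
    census = {
        "n_island_cpgs": int(isl[["chrom", "pos"]].drop_duplicates().shape[0]),
        "n_islands": int(isl["island_id"].nunique()),
        "n_genes_with_cgi": int(isl["gene_id"].nunique()),
        "n_promoter_islands": int(in_prom["island_id"].nunique()),
        "n_promoter_genes": int(in_prom["gene_id"].nunique()),
    }
    census["promoter_cgi_gene_pct"] = (
        100.0 * census["n_promoter_genes"] / census["n_genes_with_cgi"]
        if census["n_genes_with_cgi"]
        else float("nan")
    )

    if isl.empty:
        classes = pd.DataFrame(
            columns=["island_id", "gene_id", "region", "n_cpgs", "mean_meth_pct", "cls"]
        )
        return census, classes

    isl["region"] = _stratum_of(isl["d"].to_numpy())
    merged = isl.merge(
        calls[["chrom", "pos", "sample_id", "n_meth", "n_unmeth"]],
        on=["chrom", "pos"],
        how="inner",
    )
    cov = merged["n_meth"] + merged["n_unmeth"]
    merged = merged[cov >= min_coverage]
    merged["m"] = 100.0 * merged["n_meth"] / (merged["n_meth"] + merged["n_unmeth"])
    grp = merged.groupby(["island_id", "gene_id", "region"])
    classes = grp.agg(
        n_cpgs=("pos", "nunique"), mean_meth_pct=("m", "mean")
    ).reset_index()
    classes["cls"] = classes["mean_meth_pct"].map(classify_meth)
    return census, classes.sort_values(["island_id", "gene_id", "region"]).reset_index(
        drop=True
    )
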