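"""Seeded, truth-annotated synthetic datasets for the whole pipeline.

The generator emulates the statistical structure of a reduced-representation
bisulfite + RNA-Seq muscle study on two groups of four fish each: CpG sites
are enriched around gene TSSs while their methylation dips there; methylated
read counts are beta-binomially overdispersed between biological replicates;
a known set of sites carries a >25-percentage-point between-group methylation
shift; and log-normal RPKM expression is weakly coupled to realized promoter
(negative) and gene-body (positive) methylation.

The per-site true methylation follows a piecewise-linear TSS profile

    mu(d) = dip + (baseline - dip) * min(1, |d| / halfwidth)

for the signed TSS offset ``d``; this reproduces the qualitative metagene
shape (baseline ~58%, dip ~13% at the TSS) with the fewest parameters.

Every function is deterministic given ``params.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .io import CALL_COLUMNS, GENE_COLUMNS, ISLAND_COLUMNS

_WINDOW = 10_000  # TSS flank used throughout the analysis (nt)


@dataclass
class SimulationParams:
    """Knobs of the generative model; defaults are the study's conditions."""

    n_genes: int = 1000
    chrom_length: int | None = None  # default: n_genes * 25 kb + margin
    chrom: str = "chrSim1"
    n_samples_per_group: int = 4
    baseline_meth: float = 0.58
    tss_dip_meth: float = 0.13
    dip_halfwidth_nt: int = 1000
    cpg_rate_background: float = 0.007
    cpg_rate_tss: float = 0.015
    coverage_mean: float = 30.0
    coverage_dispersion: float = 8.0  # NB size; larger = closer to Poisson
    overdispersion_rho: float = 0.05  # beta-binomial intra-group correlation
    n_dm_sites: int = 100
    dm_shift: float = 0.35
    cgi_gene_fraction: float = 0.15
    cgi_length_nt: int = 800
    promoter_coupling: float = -0.2
    genebody_coupling: float = 0.15
    de_coupled_fraction: float = 0.5
    de_log2_shift: float = 1.5
    expr_log2_intercept: float = 4.0
    expr_log2_scale: float = 2.0
    expr_sample_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_meth", "tss_dip_meth", "overdispersion_rho",
                     "cgi_gene_fraction", "de_coupled_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.chrom_length is None:
            self.chrom_length = self.n_genes * 25_000 + 2 * _WINDOW

    @property
    def sample_ids(self) -> list[str]:
        n = self.n_samples_per_group
        return [f"g1s{i + 1}" for i in range(n)] + [f"g2s{i + 1}" for i in range(n)]

    @property
    def groups(self) -> dict[str, str]:
        n = self.n_samples_per_group
        return {s: ("group1" if i < n else "group2") for i, s in enumerate(self.sample_ids)}

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthTable:
    """Ground truth injected by the generator, for downstream verification."""

    dm_sites: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["chrom", "pos", "gene_id", "d", "true_diff"]
        )
    )
    couplings: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene_id", "region", "coupling_sign", "de_injected", "expr_sign"]
        )
    )
    report: dict = field(default_factory=dict)


def tss_profile_mu(d: np.ndarray, params: SimulationParams) -> np.ndarray:
    """True methylation level at signed TSS offset ``d`` (piecewise linear)."""
    frac = np.minimum(1.0, np.abs(d) / params.dip_halfwidth_nt)
    mu = params.tss_dip_meth + (params.baseline_meth - params.tss_dip_meth) * frac
    return np.clip(mu, 0.02, 0.98)


def simulate_annotation(params: SimulationParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene models on alternating strands with TSSs >=25 kb apart, plus CGIs.

    A configurable fraction of genes carries one CpG island inside the first
    2 kb of the gene body ([0, +2 kb] in TSS offset coordinates).
    """
    n = params.n_genes
    if n == 0:
        return (
            pd.DataFrame(columns=GENE_COLUMNS),
            pd.DataFrame(columns=ISLAND_COLUMNS),
        )
    if params.chrom_length < n * 25_000:
        raise ValueError(
            f"chrom_length {params.chrom_length} cannot hold {n} genes at >=25 kb spacing"
        )
    rng = np.random.default_rng([params.seed, 1])
    stride = params.chrom_length // n
    tss = stride // 2 + stride * np.arange(n)
    strand = np.where(np.arange(n) % 2 == 0, "+", "-")
    genes = pd.DataFrame(
        {
            "gene_id": [f"gene{i + 1:05d}" for i in range(n)],
            "chrom": params.chrom,
            "strand": strand,
            "tss": tss.astype(np.int64),
        }
    )

    n_cgi = int(round(params.cgi_gene_fraction * n))
    cgi_genes = np.sort(rng.choice(n, size=n_cgi, replace=False))
    length = params.cgi_length_nt
    offs = rng.integers(0, 2000 - length + 1, size=n_cgi)  # genic offset of island start
    starts = np.empty(n_cgi, dtype=np.int64)
    ends = np.empty(n_cgi, dtype=np.int64)
    for k, (gi, o) in enumerate(zip(cgi_genes, offs)):
        t = tss[gi]
        if strand[gi] == "+":
            starts[k] = t - 1 + o          # 0-based
            ends[k] = starts[k] + length
        else:  # offsets run against the genome for '-' genes
            ends[k] = t - o
            starts[k] = ends[k] - length
    islands = pd.DataFrame(
        {
            "island_id": [f"island{k + 1:04d}" for k in range(n_cgi)],
            "chrom": params.chrom,
            "start": starts,
            "end": ends,
        }
    )
    return genes, islands


def _place_sites(genes: pd.DataFrame, params: SimulationParams, rng) -> pd.DataFrame:
    """Bernoulli site placement over each gene's +/-10 kb window."""
    d_axis = np.arange(-_WINDOW, _WINDOW + 1)
    rate = np.where(
        np.abs(d_axis) <= 1000, params.cpg_rate_tss, params.cpg_rate_background
    )
    frames = []
    for _, g in genes.iterrows():
        hit = rng.random(d_axis.size) < rate
        d = d_axis[hit]
        pos = g.tss + d if g.strand == "+" else g.tss - d
        frames.append(
            pd.DataFrame(
                {"chrom": g.chrom, "pos": pos, "gene_id": g.gene_id, "d": d}
            )
        )
    sites = pd.concat(frames, ignore_index=True)
    sites["pos"] = sites["pos"].astype(np.int64)
    return sites


def simulate_methylome(
    genes: pd.DataFrame, islands: pd.DataFrame, params: SimulationParams
) -> tuple[pd.DataFrame, TruthTable]:
    """Emit per-sample CpG calls for all genes plus the DM truth table.

    Counts are beta-binomial: per (site, sample), the success probability is
    drawn from a Beta with mean ``mu`` and variance ``mu(1-mu)*rho``; coverage
    is 1 + NegBinom(mean coverage_mean - 1).  Group-2 samples at the
    ``n_dm_sites`` truth sites have ``mu`` shifted by +/- ``dm_shift``
    (clamped to [0.02, 0.98], the shift direction chosen so the full shift
    survives clamping).
    """
    if genes.empty:
        raise ValueError("simulate_methylome requires a non-empty gene set")
    if params.dm_shift <= 0:
        raise ValueError("dm_shift must be positive")
    rng = np.random.default_rng([params.seed, 2])

    sites = _place_sites(genes, params, rng)
    n_sites = len(sites)
    mu1 = tss_profile_mu(sites["d"].to_numpy(), params)

    # --- choose truth DM sites inside the -1..+10 kb integration region,
    #     at most one per gene so expression coupling stays interpretable
    region = (sites["d"] >= -1000) & (sites["d"] <= _WINDOW)
    cand = sites.index[region].to_numpy()
    cand_genes = sites.loc[cand, "gene_id"].to_numpy()
    order = rng.permutation(len(cand))
    seen: set[str] = set()
    picked: list[int] = []
    skipped: list[int] = []
    for j in order:
        if len(picked) >= params.n_dm_sites:
            break
        if cand_genes[j] in seen:
            skipped.append(j)
            continue
        seen.add(cand_genes[j])
        picked.append(cand[j])
    # second pass: allow several DM sites per gene when genes run out
    for j in skipped:
        if len(picked) >= params.n_dm_sites:
            break
        picked.append(cand[j])
    picked = np.sort(np.array(picked, dtype=np.int64))
    if len(picked) < params.n_dm_sites:
        raise ValueError("not enough candidate sites for the requested n_dm_sites")

    shift = params.dm_shift
    mu2 = mu1.copy()
    base = mu1[picked]
    can_up = base + shift <= 0.98
    can_dn = base - shift >= 0.02
    s = np.where(can_up & can_dn, rng.choice([-1.0, 1.0], size=len(picked)),
                 np.where(can_up, 1.0, -1.0))
    mu2[picked] = np.clip(base + s * shift, 0.02, 0.98)
    true_diff = mu1[picked] - mu2[picked]  # group1 - group2 orientation

    truth = TruthTable()
    truth.dm_sites = pd.DataFrame(
        {
            "chrom": sites.loc[picked, "chrom"].to_numpy(),
            "pos": sites.loc[picked, "pos"].to_numpy(),
            "gene_id": sites.loc[picked, "gene_id"].to_numpy(),
            "d": sites.loc[picked, "d"].to_numpy(),
            "true_diff": np.round(100.0 * true_diff, 6),
        }
    )

    # --- draw counts sample by sample (deterministic order)
    n_per_group = params.n_samples_per_group
    rho = params.overdispersion_rho
    cov_mean = max(params.coverage_mean - 1.0, 1e-9)
    k = params.coverage_dispersion
    p_nb = k / (k + cov_mean)

    frames = []
    n_low_cov = 0
    for si, sample in enumerate(params.sample_ids):
        mu = mu1 if si < n_per_group else mu2
        cov = 1 + rng.negative_binomial(k, p_nb, size=n_sites)
        if rho > 0:
            a = mu * (1 - rho) / rho
            b = (1 - mu) * (1 - rho) / rho
            p = rng.beta(a, b)
        else:
            p = mu
        n_meth = rng.binomial(cov, p)
        n_low_cov += int((cov < 10).sum())
        frames.append(
            pd.DataFrame(
                {
                    "chrom": sites["chrom"],
                    "pos": sites["pos"],
                    "strand": "+",
                    "context": "CpG",
                    "sample_id": sample,
                    "n_meth": n_meth,
                    "n_unmeth": cov - n_meth,
                }
            )
        )
    calls = pd.concat(frames, ignore_index=True)[CALL_COLUMNS]
    truth.report = {
        "n_sites": int(n_sites),
        "n_call_rows": int(len(calls)),
        "frac_coverage_lt10": n_low_cov / max(len(calls), 1),
    }
    return calls, truth


def _window_mean_meth(
    sites: pd.DataFrame, calls: pd.DataFrame, d_lo: int, d_hi: int
) -> pd.Series:
    """Across-(site, sample) mean methylation %% per gene for d in [d_lo, d_hi]."""
    sub = sites[(sites["d"] >= d_lo) & (sites["d"] <= d_hi)]
    merged = sub.merge(calls, on=["chrom", "pos"], how="left")
    cov = merged["n_meth"] + merged["n_unmeth"]
    merged = merged[cov > 0]
    m = merged["n_meth"] / (merged["n_meth"] + merged["n_unmeth"])
    return 100.0 * m.groupby(merged["gene_id"]).mean()


def simulate_expression(
    genes: pd.DataFrame,
    calls: pd.DataFrame,
    params: SimulationParams,
    truth: TruthTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Per-sample RPKM coupled to realized methylation, plus a DE table.

    log2 RPKM = intercept + scale * (c_p * z_p + c_g * z_g + e * eta_gene)
    + sample noise, where z_p / z_g are across-gene z-scores of the realized
    promoter (+/-1 kb) and gene-body (+3..+10 kb) mean methylation,
    e = sqrt(1 - c_p^2 - c_g^2), and eta is gene-level so the configured
    couplings are recovered as gene-level correlations.  A fraction of the
    DM-truth genes additionally receives a >=2-fold between-group shift whose
    direction follows the configured coupling sign.  The DE table is a
    two-sample t-test on log2 RPKM with Benjamini-Hochberg FDR — a clearly
    labelled stand-in for whatever DE caller a real analysis uses.
    """
    cp, cg = params.promoter_coupling, params.genebody_coupling
    if abs(cp) >= 1 or abs(cg) >= 1:
        raise ValueError("coupling magnitudes must be < 1 (z-scale correlations)")
    if cp**2 + cg**2 >= 1:
        raise ValueError("coupling magnitudes jointly too large (c_p^2 + c_g^2 >= 1)")
    if truth is None:
        truth = TruthTable()
    rng = np.random.default_rng([params.seed, 3])

    # realized window methylation needs the site->gene offsets; recompute the
    # deterministic site placement geometry from gene TSSs and call positions
    site_pos = calls[["chrom", "pos"]].drop_duplicates()
    from .profiling import assign_genic  # local import to avoid cycle at load

    assigned = assign_genic(site_pos, genes, window_nt=_WINDOW)
    prom = _window_mean_meth(assigned, calls, -1000, 1000)
    body = _window_mean_meth(assigned, calls, 3000, _WINDOW)

    gid = genes["gene_id"].to_numpy()

    def zscore(s: pd.Series) -> np.ndarray:
        v = s.reindex(gid)
        filled = v.fillna(v.mean())
        sd = filled.std(ddof=0)
        if sd == 0 or np.isnan(sd):
            return np.zeros(len(gid))
        return ((filled - filled.mean()) / sd).to_numpy()

    z_p, z_g = zscore(prom), zscore(body)
    e = np.sqrt(max(1.0 - cp**2 - cg**2, 0.0))
    eta = rng.standard_normal(len(gid))
    gene_level = params.expr_log2_intercept + params.expr_log2_scale * (
        cp * z_p + cg * z_g + e * eta
    )

    n = params.n_samples_per_group
    samples = params.sample_ids
    noise = params.expr_sample_noise_sd * rng.standard_normal((len(gid), 2 * n))
    log2 = gene_level[:, None] + noise

    # --- inject DE on a subset of DM-truth genes, direction per coupling sign
    couplings = []
    dm = truth.dm_sites
    if not dm.empty and params.de_coupled_fraction > 0:
        n_c = int(round(params.de_coupled_fraction * len(dm)))
        chosen = rng.choice(len(dm), size=n_c, replace=False)
        chosen_mask = np.zeros(len(dm), dtype=bool)
        chosen_mask[chosen] = True
        gidx = pd.Index(gid)
        for (_, row), injected in zip(dm.iterrows(), chosen_mask):
            region = "promoter" if row.d <= 1000 else "genebody"
            c = cp if region == "promoter" else cg
            expr_sign = float(np.sign(c) * np.sign(row.true_diff))
            couplings.append(
                {
                    "gene_id": row.gene_id,
                    "region": region,
                    "coupling_sign": float(np.sign(c)),
                    "de_injected": bool(injected),
                    "expr_sign": expr_sign,
                }
            )
            if injected and expr_sign != 0:
                i = gidx.get_loc(row.gene_id)
                log2[i, :n] += expr_sign * params.de_log2_shift / 2
                log2[i, n:] -= expr_sign * params.de_log2_shift / 2
    truth.couplings = pd.DataFrame(
        couplings,
        columns=["gene_id", "region", "coupling_sign", "de_injected", "expr_sign"],
    )

    rpkm = np.power(2.0, log2)
    expr = pd.DataFrame(rpkm, columns=samples)
    expr.insert(0, "gene_id", gid)
    expr["mean_rpkm"] = expr[samples].mean(axis=1)

    # --- DE stand-in: two-sample t-test on log2 RPKM + BH
    t = stats.ttest_ind(log2[:, :n], log2[:, n:], axis=1)
    from statsmodels.stats.multitest import multipletests

    fdr = multipletests(t.pvalue, method="fdr_bh")[1]
    m1 = rpkm[:, :n].mean(axis=1)
    m2 = rpkm[:, n:].mean(axis=1)
    ratio = m1 / m2
    fold = np.where(ratio >= 1, ratio, -1.0 / ratio)
    de = pd.DataFrame({"gene_id": gid, "fold_change": fold, "fdr": fdr})
    return expr, de, truth


def simulate_dataset(
    params: SimulationParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthTable]:
    """Convenience wrapper: (genes, islands, calls, expression, de, truth)."""
    genes, islands = simulate_annotation(params)
    calls, truth = simulate_methylome(genes, islands, params)
    expr, de, truth = simulate_expression(genes, calls, params, truth)
    return genes, islands, calls, expr, de, truth
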