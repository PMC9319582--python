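"""End-to-end orchestration: configuration, logging, seeding, staged runs.

Stages (simulate -> profile -> correlate -> dmtest -> integrate) communicate
only through files under ``out_dir``, so any stage can be rerun from saved
intermediates and reproduce its outputs bit for bit.  ``run_all`` returns a
manifest mapping every produced file to its SHA-256 digest; two runs with the
same seed and configuration yield identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from . import profiling, expression as expr_mod, diffmeth, integrate as integ_mod
from .synthetic import SimulationParams, simulate_dataset

logger = logging.getLogger("methlink")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    out_dir: str = "methlink_out"
    seed: int = 0
    simulate: bool = True
    sim: SimulationParams = field(default_factory=SimulationParams)
    #: sample_id -> group label; empty = use the simulation's groups
    groups: dict = field(default_factory=dict)
    filters: diffmeth.FilterConfig = field(default_factory=diffmeth.FilterConfig)
    integration: integ_mod.IntegrationConfig = field(
        default_factory=integ_mod.IntegrationConfig
    )
    # inputs for non-simulated runs (paths); calls maps sample_id -> path
    genes_path: str | None = None
    cgi_path: str | None = None
    calls_paths: dict = field(default_factory=dict)
    expression_path: str | None = None
    de_path: str | None = None
    window_nt: int = 10_000
    density_bin_nt: int = 1
    meth_bin_nt: int = 1000
    min_coverage_profile: int = 10
    q_cut: float = 0.01
    diff_cut: float = 25.0
    destrand: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimulationParams(**self.sim)
        if isinstance(self.filters, dict):
            self.filters = diffmeth.FilterConfig(**self.filters)
        if isinstance(self.integration, dict):
            integ = dict(self.integration)
            if "dm_region" in integ:
                integ["dm_region"] = tuple(integ["dm_region"])
            self.integration = integ_mod.IntegrationConfig(**integ)
        self.sim.seed = self.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["integration"]["dm_region"] = list(d["integration"]["dm_region"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    # resolved paths -------------------------------------------------------
    def path(self, name: str) -> Path:
        return Path(self.out_dir) / name

    def resolved_groups(self) -> dict:
        return dict(self.groups) if self.groups else self.sim.groups


def _require(path: Path | str | None, what: str) -> Path:
    if path is None:
        raise StageError(f"missing input: no path configured for {what}")
    p = Path(path)
    if not p.exists():
        raise StageError(f"missing input file for {what}: {p}")
    return p


def _load_calls(config: PipelineConfig) -> pd.DataFrame:
    if config.calls_paths:
        frames = [
            mio.read_bismark_cov(_require(p, f"calls[{s}]"), s)
            for s, p in sorted(config.calls_paths.items())
        ]
    else:
        frames = []
        for s in sorted(config.resolved_groups()):
            frames.append(
                mio.read_bismark_cov(_require(config.path(f"calls_{s}.cov"), f"calls[{s}]"), s)
            )
    calls = pd.concat(frames, ignore_index=True)
    if config.destrand:
        calls = diffmeth.destrand(calls)
    return calls


def _load_genes(config: PipelineConfig) -> pd.DataFrame:
    p = config.genes_path or config.path("genes.bed")
    return mio.read_gene_annotation(_require(p, "gene annotation"), "bed")


def _load_islands(config: PipelineConfig) -> pd.DataFrame:
    p = config.cgi_path or config.path("cgi.bed")
    return mio.read_cgi_bed(_require(p, "CpG islands"))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(config: PipelineConfig) -> list[Path]:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes, islands, calls, expr, de, truth = simulate_dataset(config.sim)
    produced = []
    mio.write_genes_bed(genes, out / "genes.bed")
    produced.append(out / "genes.bed")
    mio.write_cgi_bed(islands, out / "cgi.bed")
    produced.append(out / "cgi.bed")
    for s, sub in calls.groupby("sample_id"):
        p = out / f"calls_{s}.cov"
        mio.write_bismark_cov(sub, p)
        produced.append(p)
    mio.write_expression_tsv(expr, out / "expression.tsv")
    produced.append(out / "expression.tsv")
    mio.write_de_tsv(de, out / "de.tsv")
    produced.append(out / "de.tsv")
    truth.dm_sites.to_csv(out / "truth_dm_sites.tsv", sep="\t", index=False)
    produced.append(out / "truth_dm_sites.tsv")
    truth.couplings.to_csv(out / "truth_couplings.tsv", sep="\t", index=False)
    produced.append(out / "truth_couplings.tsv")
    logger.info(
        "simulate: %d genes, %d islands, %d call rows (%.1f%% below 10x)",
        len(genes), len(islands), len(calls),
        100 * truth.report.get("frac_coverage_lt10", 0),
    )
    return produced


def run_profile(config: PipelineConfig) -> list[Path]:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    calls = _load_calls(config)
    genes = _load_genes(config)
    islands = _load_islands(config)
    sites = calls[["chrom", "pos"]].drop_duplicates()
    assigned = profiling.assign_genic(sites, genes, window_nt=config.window_nt)
    assigned = profiling.flag_islands(assigned, islands)
    nonisland = assigned[~assigned["in_island"]]

    produced = []
    comp = profiling.context_composition(calls)
    comp.to_csv(out / "context_composition.tsv", sep="\t", index=False)
    produced.append(out / "context_composition.tsv")

    dens = profiling.position_profile(
        nonisland, calls=None, bin_nt=config.density_bin_nt, window_nt=config.window_nt
    )
    dens.to_csv(out / "profile_density.tsv", sep="\t", index=False)
    produced.append(out / "profile_density.tsv")

    meth = profiling.position_profile(
        nonisland, calls, bin_nt=config.meth_bin_nt, window_nt=config.window_nt,
        min_coverage=config.min_coverage_profile,
    )
    meth.to_csv(out / "profile_meth.tsv", sep="\t", index=False)
    produced.append(out / "profile_meth.tsv")

    ivp = profiling.methylation_interval_profile(
        nonisland, calls, offset_bin_nt=config.meth_bin_nt,
        window_nt=config.window_nt, min_coverage=config.min_coverage_profile,
    )
    ivp.to_csv(out / "interval_profile.tsv", sep="\t", index=False)
    produced.append(out / "interval_profile.tsv")

    census, classes = profiling.cgi_census_and_classify(
        sites, islands, genes, calls, window_nt=config.window_nt,
        min_coverage=config.min_coverage_profile,
    )
    with open(out / "cgi_census.json", "w") as fh:
        json.dump(census, fh, indent=2, sort_keys=True)
        fh.write("\n")
    produced.append(out / "cgi_census.json")
    classes.to_csv(out / "cgi_classes.tsv", sep="\t", index=False)
    produced.append(out / "cgi_classes.tsv")
    logger.info(
        "profile: %d assignments (%d non-island), %d islands with CpGs",
        len(assigned), len(nonisland), census["n_islands"],
    )
    return produced


def run_correlate(config: PipelineConfig) -> list[Path]:
    out = Path(config.out_dir)
    calls = _load_calls(config)
    genes = _load_genes(config)
    islands = _load_islands(config)
    expr = mio.read_expression_tsv(
        _require(config.expression_path or config.path("expression.tsv"), "expression")
    )
    sites = calls[["chrom", "pos"]].drop_duplicates()
    assigned = profiling.assign_genic(sites, genes, window_nt=config.window_nt)
    assigned = profiling.flag_islands(assigned, islands)
    nonisland = assigned[~assigned["in_island"]]
    deciles = expr_mod.compute_deciles(expr)

    produced = []
    rows = []
    for label, lo, hi in (("+/-1kb", -1000, 1000), ("+3..+10kb", 3000, config.window_nt)):
        wm = expr_mod.window_methylation(
            nonisland, calls, lo, hi, min_coverage=config.min_coverage_profile
        )
        wc = expr_mod.correlate_meth_expression(deciles, wm, region=label)
        rows.append(vars(wc))
    pd.DataFrame(rows).to_csv(out / "correlations.tsv", sep="\t", index=False)
    produced.append(out / "correlations.tsv")

    wm1 = expr_mod.window_methylation(
        nonisland, calls, -1000, 1000, min_coverage=config.min_coverage_profile
    )
    summ = expr_mod.decile_meth_summary(deciles, wm1)
    summ.to_csv(out / "decile_summary.tsv", sep="\t", index=False)
    produced.append(out / "decile_summary.tsv")

    _, classes = profiling.cgi_census_and_classify(
        sites, islands, genes, calls, window_nt=config.window_nt,
        min_coverage=config.min_coverage_profile,
    )
    matrix, contrast = expr_mod.cgi_class_by_decile(classes, deciles)
    matrix.to_csv(out / "cgi_class_by_decile.tsv", sep="\t", index=False)
    produced.append(out / "cgi_class_by_decile.tsv")
    logger.info(
        "correlate: %d genes in deciles; promoter-hyper CGI contrast d1=%d d10=%d",
        len(deciles), contrast[0], contrast[1],
    )
    return produced


def run_dmtest(config: PipelineConfig) -> list[Path]:
    out = Path(config.out_dir)
    calls = _load_calls(config)
    groups = config.resolved_groups()
    filtered, report = diffmeth.filter_calls(calls, groups, config.filters)
    res = diffmeth.dm_test_frame(filtered, groups)
    res, counts = diffmeth.call_dm(res, q_cut=config.q_cut, diff_cut=config.diff_cut)

    produced = []
    res.to_csv(out / "dm_results.tsv", sep="\t", index=False)
    produced.append(out / "dm_results.tsv")
    mio.write_dm_bed(res, out / "dm.bed")
    produced.append(out / "dm.bed")
    with open(out / "filter_report.json", "w") as fh:
        json.dump({**report, "calls": counts}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    produced.append(out / "filter_report.json")
    logger.info("dmtest: %d sites tested, %s", len(res), counts)
    return produced


def run_integrate(config: PipelineConfig) -> list[Path]:
    out = Path(config.out_dir)
    calls = _load_calls(config)
    genes = _load_genes(config)
    de = mio.read_de_tsv(_require(config.de_path or config.path("de.tsv"), "DE table"))
    expr = mio.read_expression_tsv(
        _require(config.expression_path or config.path("expression.tsv"), "expression")
    )
    dm_path = _require(config.path("dm_results.tsv"), "DM results")
    dm = pd.read_csv(dm_path, sep="\t", dtype={"chrom": str})

    sites = calls[["chrom", "pos"]].drop_duplicates()
    assigned = profiling.assign_genic(sites, genes, window_nt=config.window_nt)
    cand, report = integ_mod.restrict_dm_region(dm, assigned, config.integration)
    pairs = integ_mod.join_dm_de(
        cand, de, config.integration, known_genes=set(genes["gene_id"])
    )
    pairs = integ_mod.add_pair_correlations(pairs, calls, expr, config.integration)
    rows, summary = integ_mod.emit_marker_table(pairs)
    mio.write_marker_table(rows, out / "markers.tsv")
    logger.info("integrate: %s; %s", report, summary)
    return [out / "markers.tsv"]


STAGES = {
    "simulate": run_simulate,
    "profile": run_profile,
    "correlate": run_correlate,
    "dmtest": run_dmtest,
    "integrate": run_integrate,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict[str, str]:
    """Run every stage in dependency order; return the digest manifest.

    A stage failure raises :class:`StageError` naming the stage.  The
    manifest (also written to ``manifest.json``) maps each produced file's
    name to its SHA-256 digest.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    produced: list[Path] = []
    order = ["simulate"] if config.simulate else []
    order += ["profile", "correlate", "dmtest", "integrate"]
    for stage in order:
        try:
            produced += STAGES[stage](config)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
    manifest = {p.name: _sha256(p) for p in sorted(set(produced))}
    with open(Path(config.out_dir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
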