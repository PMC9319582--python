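"""Readers and writers for every external file the pipeline touches.

Coordinate conventions
----------------------
* In-memory positions (``pos``, ``tss``) are 1-based, as in the Bismark
  coverage dialect.
* BED input/output is 0-based half-open, per the BED standard.
* Methylation level ``m = n_meth / (n_meth + n_unmeth)`` is recomputed from
  counts; the percentage column of a coverage file is never trusted.  At zero
  coverage ``m`` is NaN (undefined), never silently 0.

In-memory containers
--------------------
Per-sample methylation calls travel as a :class:`pandas.DataFrame` with the
columns in :data:`CALL_COLUMNS`; gene models, CpG islands, expression and
differential-expression tables are DataFrames with the schemas documented on
their readers.  Small frozen dataclasses (:class:`GeneModel`,
:class:`CpGIsland`) are provided for record-at-a-time use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Column schema of a methylation-call frame.
CALL_COLUMNS = ["chrom", "pos", "strand", "context", "sample_id", "n_meth", "n_unmeth"]

#: Column schema of a gene-model frame.
GENE_COLUMNS = ["gene_id", "chrom", "strand", "tss"]

#: Column schema of a CpG-island frame (BED convention: 0-based half-open).
ISLAND_COLUMNS = ["island_id", "chrom", "start", "end"]

#: Marker-table columns, mirroring the published epigenetic-marker layout
#: (chromosome position, gene, TSS offset, group methylation difference in
#: percentage points with diploid-minus-triploid orientation, the logistic
#: LRT p-value, signed expression fold change, expression FDR, and the
#: per-sample methylation/expression Pearson R).
MARKER_COLUMNS = [
    "chrom_position",
    "gene",
    "position_to_tss",
    "meth_diff",
    "meth_p_value",
    "exp_fold_change",
    "exp_fdr",
    "exp_meth_r",
]


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    tss: int  # 1-based transcription start site


@dataclass(frozen=True)
class CpGIsland:
    island_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive


def methylation_level(calls: pd.DataFrame) -> pd.Series:
    """Per-row methylation level in [0, 1]; NaN where coverage is zero."""
    cov = calls["n_meth"] + calls["n_unmeth"]
    with np.errstate(invalid="ignore"):
        m = calls["n_meth"] / cov.where(cov > 0)
    return m


# ---------------------------------------------------------------------------
# methylation calls
# ---------------------------------------------------------------------------

def read_bismark_cov(path: str | Path, sample_id: str) -> pd.DataFrame:
    """Read a Bismark coverage file (6-column TSV) into a call frame.

    Columns: chrom, start (1-based), end, methylation %, count methylated,
    count unmethylated.  An optional 7th column gives the strand; otherwise
    '+' is recorded.  Context defaults to CpG.  Counts are authoritative: a
    percentage column off by more than 0.5 points triggers a warning and is
    discarded.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse as TSV: {exc}") from exc
    if raw.shape[1] not in (6, 7):
        raise ParseError(f"{path}: expected 6 or 7 columns, found {raw.shape[1]}")
    for col in (1, 2, 4, 5):
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() | (vals != vals.astype("Int64").astype(float))
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ParseError(f"{path}: malformed integer field on line {line}")
        raw[col] = vals.astype(np.int64)
    neg = (raw[4] < 0) | (raw[5] < 0)
    if neg.any():
        line = int(neg.idxmax()) + 1
        raise ParseError(f"{path}: negative count on line {line}")
    cov = raw[4] + raw[5]
    with np.errstate(invalid="ignore"):
        pct = np.where(cov > 0, 100.0 * raw[4] / cov.where(cov > 0), np.nan)
    stated = pd.to_numeric(raw[3], errors="coerce")
    off = (cov > 0) & stated.notna() & ((stated - pct).abs() > 0.5)
    if off.any():
        line = int(off.idxmax()) + 1
        warnings.warn(
            f"{path}: methylation %% inconsistent with counts by >0.5 points "
            f"(first at line {line}); counts win",
            stacklevel=2,
        )
    strand = raw[6].astype(str) if raw.shape[1] == 7 else "+"
    out = pd.DataFrame(
        {
            "chrom": raw[0].astype(str),
            "pos": raw[1],
            "strand": strand,
            "context": "CpG",
            "sample_id": sample_id,
            "n_meth": raw[4],
            "n_unmeth": raw[5],
        }
    )
    return out[CALL_COLUMNS]


def read_cpg_report(path: str | Path, sample_id: str) -> pd.DataFrame:
    """Read the per-cytosine Bismark "CpG report" dialect.

    Columns: chrom, pos (1-based), strand, count methylated, count
    unmethylated, context, trinucleotide context.  Duplicate (chrom, pos,
    strand) rows are merged by summing counts.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if raw.shape[1] < 6:
        raise ParseError(f"{path}: expected >=6 columns, found {raw.shape[1]}")
    out = pd.DataFrame(
        {
            "chrom": raw[0].astype(str),
            "pos": raw[1].astype(np.int64),
            "strand": raw[2].astype(str),
            "context": raw[5].astype(str),
            "sample_id": sample_id,
            "n_meth": raw[3].astype(np.int64),
            "n_unmeth": raw[4].astype(np.int64),
        }
    )
    if (out["n_meth"] < 0).any() or (out["n_unmeth"] < 0).any():
        raise ParseError(f"{path}: negative count")
    out = (
        out.groupby(["chrom", "pos", "strand", "context", "sample_id"], as_index=False)[
            ["n_meth", "n_unmeth"]
        ].sum()
    )
    return out[CALL_COLUMNS]


def write_bismark_cov(calls: pd.DataFrame, path: str | Path) -> None:
    """Write a single-sample call frame as a 7-column coverage file.

    The 7th column records the strand so that a write/read round trip is
    lossless.  The percentage column is derived from counts (0 at zero
    coverage, by convention of the format).
    """
    if calls["sample_id"].nunique() > 1:
        raise ValueError("write_bismark_cov expects calls from a single sample")
    cov = calls["n_meth"] + calls["n_unmeth"]
    pct = np.where(cov > 0, 100.0 * calls["n_meth"] / np.maximum(cov, 1), 0.0)
    out = pd.DataFrame(
        {
            0: calls["chrom"],
            1: calls["pos"],
            2: calls["pos"],
            3: np.round(pct, 6),
            4: calls["n_meth"],
            5: calls["n_unmeth"],
            6: calls["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def read_gene_annotation(path: str | Path, format: str = "bed") -> pd.DataFrame:
    """Read gene models from BED6 or GFF3 into a frame with GENE_COLUMNS.

    The TSS is strand-resolved to 1-based coordinates: ``start + 1`` for '+'
    genes, ``end`` for '-' genes (BED end is exclusive, so it equals the
    1-based last base).  Strand is mandatory; duplicate gene ids are an error.
    """
    path = Path(path)
    if format == "bed":
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
        if raw.shape[1] < 6:
            raise ParseError(f"{path}: BED6 requires 6 columns (strand missing?)")
        genes = pd.DataFrame(
            {
                "gene_id": raw[3].astype(str),
                "chrom": raw[0].astype(str),
                "strand": raw[5].astype(str),
                "start": raw[1].astype(np.int64),
                "end": raw[2].astype(np.int64),
            }
        )
    elif format == "gff3":
        raw = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype={0: str}, names=range(9)
        )
        raw = raw[raw[2] == "gene"]
        ids = raw[8].astype(str).str.extract(r"ID=([^;]+)")[0]
        if ids.isna().any():
            raise ParseError(f"{path}: GFF3 gene line without ID attribute")
        genes = pd.DataFrame(
            {
                "gene_id": ids,
                "chrom": raw[0].astype(str),
                "strand": raw[6].astype(str),
                # GFF3 is 1-based inclusive; convert to BED-like 0-based start
                "start": raw[3].astype(np.int64) - 1,
                "end": raw[4].astype(np.int64),
            }
        )
    else:
        raise ValueError(f"unknown annotation format: {format!r}")
    bad_strand = ~genes["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise ParseError(
            f"{path}: gene {genes.loc[bad_strand.idxmax(), 'gene_id']!r} lacks a "
            "valid strand ('+'/'-'); strand is required to orient TSS offsets"
        )
    dup = genes["gene_id"].duplicated()
    if dup.any():
        raise ParseError(f"{path}: duplicate gene_id {genes.loc[dup.idxmax(), 'gene_id']!r}")
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"] + 1, genes["end"])
    return genes[GENE_COLUMNS].reset_index(drop=True)


def write_genes_bed(genes: pd.DataFrame, path: str | Path, body_nt: int = 1000) -> None:
    """Write gene models as BED6 with ``body_nt``-long intervals.

    The interval is anchored so the strand-resolved TSS round-trips exactly:
    '+' genes span [tss-1, tss-1+body_nt), '-' genes span [tss-body_nt, tss).
    """
    plus = genes["strand"] == "+"
    start = np.where(plus, genes["tss"] - 1, np.maximum(genes["tss"] - body_nt, 0))
    end = np.where(plus, genes["tss"] - 1 + body_nt, genes["tss"])
    out = pd.DataFrame(
        {
            0: genes["chrom"],
            1: start.astype(np.int64),
            2: end.astype(np.int64),
            3: genes["gene_id"],
            4: 0,
            5: genes["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# CpG islands
# ---------------------------------------------------------------------------

def read_cgi_bed(path: str | Path) -> pd.DataFrame:
    """Read CpG islands from BED3/BED4 (0-based half-open)."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if raw.shape[1] < 3:
        raise ParseError(f"{path}: BED requires >=3 columns")
    name = (
        raw[3].astype(str)
        if raw.shape[1] >= 4
        else pd.Series([f"island{i + 1}" for i in range(len(raw))])
    )
    islands = pd.DataFrame(
        {
            "island_id": name,
            "chrom": raw[0].astype(str),
            "start": raw[1].astype(np.int64),
            "end": raw[2].astype(np.int64),
        }
    )
    if (islands["end"] <= islands["start"]).any():
        raise ParseError(f"{path}: island with end <= start")
    srt = islands.sort_values(["chrom", "start"])
    same = srt["chrom"].eq(srt["chrom"].shift())
    if (same & (srt["start"] < srt["end"].shift())).any():
        warnings.warn(f"{path}: overlapping islands; membership uses first match", stacklevel=2)
    return islands[ISLAND_COLUMNS].reset_index(drop=True)


def write_cgi_bed(islands: pd.DataFrame, path: str | Path) -> None:
    out = islands[["chrom", "start", "end", "island_id"]]
    out.to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path, samples: list[str] | None = None) -> pd.DataFrame:
    """Read a gene x RPKM table (TSV, header: gene_id then sample columns).

    Returns a frame with ``gene_id``, one column per sample, and a computed
    ``mean_rpkm`` (arithmetic mean over samples).  If ``samples`` is given,
    the file's sample columns must match it exactly.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype={0: str})
    if raw.columns[0] != "gene_id":
        raise ParseError(f"{path}: first column must be 'gene_id'")
    sample_cols = [c for c in raw.columns[1:] if c != "mean_rpkm"]
    if samples is not None and set(sample_cols) != set(samples):
        unknown = sorted(set(sample_cols) - set(samples))
        missing = sorted(set(samples) - set(sample_cols))
        raise ParseError(
            f"{path}: sample columns do not match configured samples "
            f"(unknown: {unknown}, missing: {missing})"
        )
    if (raw[sample_cols] < 0).any().any():
        raise ParseError(f"{path}: negative RPKM")
    out = raw[["gene_id"] + sample_cols].copy()
    out["mean_rpkm"] = out[sample_cols].mean(axis=1)
    return out


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    cols = ["gene_id"] + [c for c in expr.columns if c not in ("gene_id", "mean_rpkm")]
    expr[cols].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_de_tsv(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression table: gene_id, fold_change, fdr.

    ``fold_change`` uses the signed convention (-2 means 2-fold down in
    group 1 relative to group 2); magnitudes below 1 (and exact zeros) are
    rejected because they have no meaning in that encoding.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "fold_change", "fdr"}
    if not required.issubset(raw.columns):
        raise ParseError(f"{path}: required columns {sorted(required)}")
    bad = raw["fold_change"].abs() < 1
    if bad.any():
        raise ParseError(
            f"{path}: fold_change magnitude < 1 for gene "
            f"{raw.loc[bad.idxmax(), 'gene_id']!r} (signed convention requires |fc| >= 1)"
        )
    if ((raw["fdr"] < 0) | (raw["fdr"] > 1)).any():
        raise ParseError(f"{path}: fdr outside [0, 1]")
    return raw[["gene_id", "fold_change", "fdr"]]


def write_de_tsv(de: pd.DataFrame, path: str | Path) -> None:
    de[["gene_id", "fold_change", "fdr"]].to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# pipeline outputs
# ---------------------------------------------------------------------------

def write_dm_bed(dm: pd.DataFrame, path: str | Path) -> None:
    """Write called DM CpGs as 0-based half-open single-base BED intervals.

    The name field carries the call (hyper/hypo); score is -log10(q) capped
    at 1000 for viewability.
    """
    called = dm[dm["call"] != "ns"]
    with np.errstate(divide="ignore"):
        score = np.minimum(-np.log10(np.maximum(called["q_value"], 1e-300)), 1000.0)
    out = pd.DataFrame(
        {
            0: called["chrom"],
            1: called["pos"] - 1,
            2: called["pos"],
            3: called["call"],
            4: np.round(score, 3),
            5: called["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")


def read_dm_bed(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    return pd.DataFrame(
        {
            "chrom": raw[0].astype(str),
            "pos": raw[2].astype(np.int64),  # 1-based position of the cytosine
            "call": raw[3].astype(str),
            "strand": raw[5].astype(str) if raw.shape[1] > 5 else "+",
        }
    )


def write_marker_table(pairs: pd.DataFrame, path: str | Path) -> None:
    """Write the epigenetic-marker table (one row per DM CpG x DE gene pair).

    A leading comment line carries the summary: counts of distinct DM CpGs
    and distinct genes.
    """
    n_cpgs = 0 if pairs.empty else pairs[["chrom", "pos"]].drop_duplicates().shape[0]
    n_genes = 0 if pairs.empty else pairs["gene_id"].nunique()
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# dm_cpgs={n_cpgs}\tgenes={n_genes}\n")
        if pairs.empty:
            fh.write("\t".join(MARKER_COLUMNS) + "\n")
            return
        out = pd.DataFrame(
            {
                "chrom_position": pairs["chrom"].astype(str)
                + "_"
                + pairs["pos"].astype(str),
                "gene": pairs["gene_id"],
                "position_to_tss": pairs["d"],
                "meth_diff": np.round(pairs["meth_diff"], 4),
                "meth_p_value": pairs["p_value"],
                "exp_fold_change": pairs["fold_change"],
                "exp_fdr": pairs["fdr"],
                "exp_meth_r": np.round(pairs["r_value"], 4),
            }
        )
        out.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_marker_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a marker table back; returns (rows, summary dict)."""
    with open(path) as fh:
        header = fh.readline()
    summary = {}
    if header.startswith("#"):
        for field in header[1:].strip().split("\t"):
            k, v = field.split("=")
            summary[k] = int(v)
    rows = pd.read_csv(path, sep="\t", comment=None, skiprows=1)
    return rows, summary
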