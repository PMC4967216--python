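"""Readers, writers and preprocessing for the pipeline's file formats.

The on-disk formats are deliberately plain text:

* expression matrices — TSV, genes in rows, first column ``gene_id``,
  header row of sample ids, values on the log2 intensity scale;
* sample metadata — TSV with columns ``sample_id`` and ``condition``;
* genomic intervals — BED3 (peaks) or BED6 (TSS annotation), 0-based
  half-open; the TSS of a '+' gene is ``start``, of a '−' gene ``end − 1``;
* regulon tables — TSV with columns
  ``regulator, target, mi, p_perm, bootstrap_support, r, mode``.

Expression matrices are written with 17 significant digits so that a
write→read round trip reproduces every float bit-for-bit; derived result
tables elsewhere in the package use 9 significant digits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

EXPR_FLOAT_FMT = "%.17g"
RESULT_FLOAT_FMT = "%.9g"


class DataFormatError(ValueError):
    """Malformed input file or inconsistent in-memory container."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of log2-scale expression values.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.
    condition
        Optional mapping sample id → condition label (as a Series) for
        two-condition designs.
    """

    values: pd.DataFrame
    condition: pd.Series | None = None

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        dup_g = idx[idx.duplicated()].unique().tolist()
        if dup_g:
            raise DataFormatError(f"duplicate gene ids: {dup_g}")
        dup_s = cols[cols.duplicated()].unique().tolist()
        if dup_s:
            raise DataFormatError(f"duplicate sample ids: {dup_s}")
        if self.condition is not None:
            self.condition = pd.Series(self.condition)
            missing = [s for s in cols if s not in self.condition.index]
            if missing:
                raise DataFormatError(
                    f"samples missing from condition metadata: {missing}"
                )
            self.condition = self.condition.reindex(cols)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_for(self, condition: str) -> list[str]:
        """Sample ids carrying the given condition label."""
        if self.condition is None:
            raise DataFormatError("matrix carries no condition metadata")
        labels = set(self.condition)
        if condition not in labels:
            raise DataFormatError(
                f"unknown condition {condition!r}; available: {sorted(labels)}"
            )
        return list(self.condition.index[self.condition == condition])


def read_expression(path, metadata_path=None) -> ExpressionMatrix:
    """Read a TSV expression matrix (and optional sample metadata)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    dups = sorted({s for s in samples if samples.count(s) > 1})
    if dups:
        raise DataFormatError(f"duplicate sample ids in {path}: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = None
    df = df.astype(float)  # expression values are floats by contract
    dup_g = df.index[df.index.duplicated()].unique().tolist()
    if dup_g:
        raise DataFormatError(f"duplicate gene ids in {path}: {dup_g}")
    if df.isna().any().any():
        bad_rows = np.where(df.isna().any(axis=1))[0]
        lines = [int(r) + 2 for r in bad_rows[:5]]  # +1 header, +1 one-based
        raise DataFormatError(
            f"ragged/missing values in {path} at line(s) {lines}"
        )
    condition = read_sample_metadata(metadata_path) if metadata_path else None
    return ExpressionMatrix(values=df, condition=condition)


def write_expression(matrix: ExpressionMatrix, path, metadata_path=None) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id",
                         float_format=EXPR_FLOAT_FMT)
    if metadata_path is not None:
        if matrix.condition is None:
            raise DataFormatError("matrix has no condition metadata to write")
        write_sample_metadata(matrix.condition, metadata_path)


def read_sample_metadata(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "condition"]:
        raise DataFormatError(
            f"metadata {path} must have columns sample_id, condition "
            f"(got {list(df.columns)})"
        )
    dup = df["sample_id"][df["sample_id"].duplicated()].unique().tolist()
    if dup:
        raise DataFormatError(f"duplicate sample ids in metadata: {dup}")
    return pd.Series(df["condition"].values, index=df["sample_id"].values,
                     name="condition")


def write_sample_metadata(condition: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": condition.index, "condition": condition.values}
                 ).to_csv(path, sep="\t", index=False)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the mean-of-sorted-columns reference distribution.

    Ties within a sample receive the mean of the reference values their
    average rank spans (the common microarray convention). Idempotent to
    floating tolerance.
    """
    if matrix.n_samples < 2:
        raise DataFormatError("quantile normalization needs ≥ 2 samples")
    X = matrix.values.to_numpy(dtype=float)
    ref = np.sort(X, axis=0).mean(axis=1)
    n = X.shape[0]
    out = np.empty_like(X)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(X.shape[1]):
        ranks = rankdata(X[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, ref)
    values = pd.DataFrame(out, index=matrix.values.index,
                          columns=matrix.values.columns)
    return ExpressionMatrix(values=values, condition=matrix.condition)


# ---------------------------------------------------------------------------
# Genomic intervals
# ---------------------------------------------------------------------------

@dataclass
class PeakSet:
    """Sorted set of 0-based half-open genomic intervals."""

    intervals: pd.DataFrame  # columns chrom, start, end [, score]

    def __post_init__(self) -> None:
        df = self.intervals
        required = ["chrom", "start", "end"]
        if list(df.columns[:3]) != required:
            raise DataFormatError(
                f"peak table needs columns {required}, got {list(df.columns)}"
            )
        if len(df) and (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]].tolist()[:5]
            raise DataFormatError(f"peaks with start ≥ end at rows {bad}")
        self.intervals = (
            df.sort_values(["chrom", "start", "end"], kind="mergesort")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class TssAnnotation:
    """Per-gene chromosome, strand and transcription start site (0-based)."""

    table: pd.DataFrame  # columns gene_id, chrom, strand, tss
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        df = self.table
        required = ["gene_id", "chrom", "strand", "tss"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise DataFormatError(f"annotation missing columns {missing}")
        dup = df["gene_id"][df["gene_id"].duplicated()].unique().tolist()
        if dup:
            raise DataFormatError(f"duplicate gene ids in annotation: {dup}")
        bad_strand = sorted(set(df["strand"]) - {"+", "-"})
        if bad_strand:
            raise DataFormatError(f"unknown strand symbols: {bad_strand}")
        if self.chrom_lengths is not None:
            for _, row in df.iterrows():
                L = self.chrom_lengths.get(row["chrom"])
                if L is not None and not (0 <= row["tss"] < L):
                    raise DataFormatError(
                        f"TSS of {row['gene_id']} outside {row['chrom']} bounds"
                    )
        self.table = df.reset_index(drop=True)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])

    def __len__(self) -> int:
        return len(self.table)


def read_bed(path):
    """Read a BED3 file as a :class:`PeakSet` or BED6 as :class:`TssAnnotation`.

    BED is 0-based half-open. For BED6 the TSS is ``start`` on '+' and
    ``end − 1`` on '−'; the name column holds the gene id.
    """
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if ncols is None:
                if len(parts) not in (3, 6):
                    raise DataFormatError(
                        f"{path}:{lineno}: expected 3 or 6 BED columns, "
                        f"got {len(parts)}"
                    )
                ncols = len(parts)
            elif len(parts) != ncols:
                raise DataFormatError(
                    f"{path}:{lineno}: ragged row ({len(parts)} columns, "
                    f"expected {ncols})"
                )
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise DataFormatError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise DataFormatError(
                    f"{path}:{lineno}: start {start} ≥ end {end}"
                )
            if ncols == 6:
                strand = parts[5]
                if strand not in ("+", "-"):
                    raise DataFormatError(
                        f"{path}:{lineno}: unknown strand {strand!r}"
                    )
                rows.append((parts[0], start, end, parts[3], strand))
            else:
                rows.append((parts[0], start, end))
    if ncols == 6:
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id",
                                         "strand"])
        tss = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
        return TssAnnotation(table=pd.DataFrame({
            "gene_id": df["gene_id"], "chrom": df["chrom"],
            "strand": df["strand"], "tss": tss,
        }))
    return PeakSet(intervals=pd.DataFrame(rows or [],
                                          columns=["chrom", "start", "end"]))


def write_bed(obj, path) -> None:
    """Write a PeakSet as BED3 or a TssAnnotation as BED6 (width-1 intervals)."""
    if isinstance(obj, PeakSet):
        obj.intervals[["chrom", "start", "end"]].to_csv(
            path, sep="\t", header=False, index=False)
    elif isinstance(obj, TssAnnotation):
        df = obj.table
        out = pd.DataFrame({
            "chrom": df["chrom"],
            "start": df["tss"],
            "end": df["tss"] + 1,
            "name": df["gene_id"],
            "score": 0,
            "strand": df["strand"],
        })
        out.to_csv(path, sep="\t", header=False, index=False)
    else:
        raise TypeError(f"cannot write {type(obj).__name__} as BED")


# ---------------------------------------------------------------------------
# Regulon tables
# ---------------------------------------------------------------------------

REGULON_COLUMNS = ["regulator", "target", "mi", "p_perm",
                   "bootstrap_support", "r", "mode"]


def write_regulon(regulon, path) -> None:
    """Write a SignedRegulon as a TSV edge table."""
    t = regulon.table
    df = pd.DataFrame({
        "regulator": regulon.regulator,
        "target": t.index,
        "mi": t["mi"].values,
        "p_perm": t["p_perm"].values if "p_perm" in t else np.nan,
        "bootstrap_support": (t["bootstrap_support"].values
                              if "bootstrap_support" in t else np.nan),
        "r": t["r"].values,
        "mode": t["mode"].values.astype(int),
    })
    df.to_csv(path, sep="\t", index=False, float_format=RESULT_FLOAT_FMT)


def read_regulon(path):
    """Read a TSV regulon table back as a SignedRegulon."""
    from .inference import SignedRegulon

    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REGULON_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"regulon table missing columns {missing}")
    regs = df["regulator"].unique()
    if len(regs) != 1:
        raise DataFormatError(
            f"regulon table must hold one regulator, found {list(regs)}"
        )
    table = df.set_index("target")[["mi", "p_perm", "bootstrap_support",
                                    "r", "mode"]]
    return SignedRegulon(regulator=str(regs[0]), table=table)
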