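"""Ranked phenotypes: per-gene differential-expression scores for GSEA.

The phenotype score is the plain log2 fold change — a difference of
per-condition means, since the expression values are already on the
log2 scale. Welch t statistics with Benjamini–Hochberg adjustment are
provided as a secondary differential-expression call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataio import ExpressionMatrix, RESULT_FLOAT_FMT


@dataclass
class RankedPhenotype:
    """All assayed genes ordered by a differential-expression score.

    Descending by score; exact ties are broken by gene id lexicographic
    order and flagged in ``tie_break``.
    """

    table: pd.DataFrame  # columns gene_id, score (sorted descending)
    contrast: str = ""
    tie_break: bool = False

    def __post_init__(self) -> None:
        s = self.table["score"].to_numpy()
        if np.any(np.diff(s) > 0):
            raise ValueError("scores are not in descending order")
        if self.table["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids in ranked phenotype")

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene_id"])

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False,
                          float_format=RESULT_FLOAT_FMT)

    @classmethod
    def read(cls, path, contrast: str = "") -> "RankedPhenotype":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        return rank_genes(pd.Series(df["score"].values,
                                    index=df["gene_id"].values),
                          contrast=contrast)


def log_fold_change(matrix: ExpressionMatrix, condition_a: str,
                    condition_b: str) -> pd.Series:
    """Per-gene logFC = mean(condition_b) − mean(condition_a).

    Values are assumed log2, so the difference of means is the log2
    fold change of condition_b over condition_a.
    """
    a = matrix.samples_for(condition_a)
    b = matrix.samples_for(condition_b)
    score = matrix.values[b].mean(axis=1) - matrix.values[a].mean(axis=1)
    score.name = "score"
    return score


def rank_genes(scores: pd.Series, contrast: str = "") -> RankedPhenotype:
    """Sort genes descending by score, ties broken lexicographically."""
    scores = pd.Series(scores)
    bad = scores.index[~np.isfinite(scores.values)].tolist()
    if bad:
        raise ValueError(f"non-finite scores for genes: {bad[:10]}")
    df = pd.DataFrame({"gene_id": scores.index.astype(str),
                       "score": scores.values.astype(float)})
    tie = bool(df["score"].duplicated().any())
    df = df.sort_values(["score", "gene_id"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    return RankedPhenotype(table=df, contrast=contrast, tie_break=tie)


def ordinary_t(matrix: ExpressionMatrix, condition_a: str,
               condition_b: str) -> pd.DataFrame:
    """Per-gene Welch t (condition_b vs condition_a) with BH adjustment.

    Degenerate genes with zero variance in both groups get t = 0, p = 1
    when the means agree and t = ±inf, p = 0 otherwise.
    """
    a = matrix.samples_for(condition_a)
    b = matrix.samples_for(condition_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("ordinary_t needs ≥ 2 replicates per condition")
    A = matrix.values[a].to_numpy(dtype=float)
    B = matrix.values[b].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(B, A, axis=1, equal_var=False)
    diff = B.mean(axis=1) - A.mean(axis=1)
    degenerate = (A.var(axis=1) == 0) & (B.var(axis=1) == 0)
    t = np.where(degenerate & (diff == 0), 0.0, t)
    p = np.where(degenerate & (diff == 0), 1.0, p)
    t = np.where(degenerate & (diff != 0), np.sign(diff) * np.inf, t)
    p = np.where(degenerate & (diff != 0), 0.0, p)
    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"t": t, "p": p, "p_adj": p_adj},
                        index=matrix.values.index)
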