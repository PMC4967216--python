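"""Two-tailed gene set enrichment analysis for signed regulons.

Classic GSEA measures the skew of one gene set S in a ranked list L by
a weighted Kolmogorov–Smirnov running sum: walking down the list, hits
add ``|score|^w`` (normalised over the hits), misses subtract
``1/(N − |S|)``, and the enrichment score (ES) is the signed maximum
deviation from zero.

A signed regulon supplies two sets — activated targets A and repressed
targets B — and each gets an independent ES against the same ranked
phenotype. Coherent modulation of the regulon shows as the two running
curves peaking near opposite extremes, summarised by the differential
enrichment score ``dES = ES(A) − ES(B)``. Significance comes from a
gene-label permutation null: hit positions are redrawn uniformly
(|A| and |B| disjoint positions), dES recomputed each time, and the
two-sided p-value uses the add-one rule so it is never exactly zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import RESULT_FLOAT_FMT
from .inference import SignedRegulon
from .ranking import RankedPhenotype

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentCurve:
    """One gene set's running enrichment along a ranked list.

    ``running[i]`` is the value after the first ``i`` ranks, so the
    curve has length N + 1 and starts at 0.
    """

    es: float
    running: np.ndarray
    hit_positions: np.ndarray  # 0-based ranks of the set's genes
    n_missing: int  # set members absent from the ranked list


@dataclass
class GseaTwoTailResult:
    es_pos: float
    es_neg: float
    d_es: float
    p_perm: float
    p_one_sided: float
    n_permutations: int
    running_pos: np.ndarray
    running_neg: np.ndarray
    hit_positions_pos: np.ndarray
    hit_positions_neg: np.ndarray
    weight_exponent: float
    seed: int
    separation: bool  # es_pos and es_neg on opposite sides of zero

    def __post_init__(self) -> None:
        for name, v in (("es_pos", self.es_pos), ("es_neg", self.es_neg)):
            if abs(v) > 1 + 1e-9:
                raise ValueError(f"|{name}| > 1")
        if abs(self.d_es - (self.es_pos - self.es_neg)) > 1e-12:
            raise ValueError("d_es must equal es_pos − es_neg")
        if not 0 < self.p_perm <= 1:
            raise ValueError("p_perm must lie in (0, 1]")


def _hit_weights(weights: np.ndarray, hits: np.ndarray,
                 exponent: float) -> np.ndarray:
    w = weights[hits]
    total = w.sum()
    if total == 0:
        if exponent > 0:
            warnings.warn("all hit scores are zero; falling back to "
                          "uniform hit weights", stacklevel=3)
        return np.full(len(hits), 1.0 / len(hits))
    return w / total


def enrichment_score(ranked: RankedPhenotype, gene_set,
                     weight_exponent: float = 1.0) -> EnrichmentCurve:
    """Weighted KS running sum and signed maximum deviation for one set.

    Set members absent from the ranked list are ignored (their count is
    logged); the set must intersect the list without covering it.
    """
    if weight_exponent < 0:
        raise ValueError("weight_exponent must be ≥ 0")
    gene_set = set(gene_set)
    genes = ranked.genes
    pos_of = {g: i for i, g in enumerate(genes)}
    hits = np.array(sorted(pos_of[g] for g in gene_set if g in pos_of),
                    dtype=np.int64)
    n_missing = len(gene_set) - len(hits)
    if n_missing:
        logger.info("enrichment_score: %d set gene(s) absent from the "
                    "ranked list", n_missing)
    N = len(genes)
    if len(hits) == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if len(hits) == N:
        raise ValueError("gene set covers the entire ranked list; "
                         "misses are required")
    weights = np.abs(ranked.scores) ** weight_exponent
    hit_w = _hit_weights(weights, hits, weight_exponent)
    miss = 1.0 / (N - len(hits))
    delta = np.full(N, -miss)
    delta[hits] = hit_w
    running = np.concatenate([[0.0], np.cumsum(delta)])
    es = _signed_max_deviation(running)
    return EnrichmentCurve(es=es, running=running, hit_positions=hits,
                           n_missing=n_missing)


def _signed_max_deviation(running: np.ndarray, tol: float = 1e-12) -> float:
    """Signed extreme of the running sum; magnitude ties go positive."""
    hi = float(running.max())
    lo = float(running.min())
    return hi if hi >= -lo - tol else lo


def _es_rows(weights: np.ndarray, hits: np.ndarray) -> np.ndarray:
    """Vectorised signed-max-deviation ES for many hit-position rows."""
    c, k = hits.shape
    N = len(weights)
    hw = weights[hits]
    totals = hw.sum(axis=1, keepdims=True)
    safe = np.where(totals == 0, 1.0, totals)
    hw = np.where(totals == 0, 1.0 / k, hw / safe)
    miss = 1.0 / (N - k)
    Z = np.full((c, N), -miss)
    Z[np.arange(c)[:, None], hits] = hw
    run = np.cumsum(Z, axis=1)
    hi = run.max(axis=1)
    lo = run.min(axis=1)
    return np.where(hi >= -lo, hi, lo)


def _null_d_es(weights: np.ndarray, k_pos: int, k_neg: int,
               n_permutations: int, rng: np.random.Generator,
               chunk: int = 256) -> np.ndarray:
    N = len(weights)
    out = np.empty(n_permutations)
    done = 0
    while done < n_permutations:
        c = min(chunk, n_permutations - done)
        r = rng.random((c, N))
        order = np.argsort(r, axis=1)
        a = order[:, :k_pos]
        b = order[:, k_pos:k_pos + k_neg]
        out[done:done + c] = _es_rows(weights, a) - _es_rows(weights, b)
        done += c
    return out


def two_tailed_gsea(
    ranked: RankedPhenotype,
    regulon: SignedRegulon,
    n_permutations: int = 1000,
    weight_exponent: float = 1.0,
    seed: int = 0,
) -> GseaTwoTailResult:
    """Independent ES for activated/repressed subgroups plus a dES test.

    Subgroup A holds the regulon's mode +1 targets, B its mode −1
    targets. The null redraws both hit-position sets (disjoint,
    label-permutation equivalent) ``n_permutations`` times;
    ``p_perm = (1 + #{|dES_null| ≥ |dES|}) / (1 + n_permutations)``.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be ≥ 100")
    in_list = set(ranked.genes)
    A = [g for g in regulon.positive_targets if g in in_list]
    B = [g for g in regulon.negative_targets if g in in_list]
    if not A:
        raise ValueError("positive-target subgroup A is empty after "
                         "intersection with the ranked list")
    if not B:
        raise ValueError("negative-target subgroup B is empty after "
                         "intersection with the ranked list")
    if set(A) == set(B):
        raise ValueError("subgroups A and B are identical")
    curve_pos = enrichment_score(ranked, A, weight_exponent)
    curve_neg = enrichment_score(ranked, B, weight_exponent)
    d_obs = curve_pos.es - curve_neg.es

    rng = np.random.default_rng(seed)
    weights = np.abs(ranked.scores) ** weight_exponent
    null = _null_d_es(weights, len(curve_pos.hit_positions),
                      len(curve_neg.hit_positions), n_permutations, rng)
    p_two = (1.0 + np.sum(np.abs(null) >= abs(d_obs))) / (1.0 + n_permutations)
    if d_obs >= 0:
        p_one = (1.0 + np.sum(null >= d_obs)) / (1.0 + n_permutations)
    else:
        p_one = (1.0 + np.sum(null <= d_obs)) / (1.0 + n_permutations)
    return GseaTwoTailResult(
        es_pos=curve_pos.es,
        es_neg=curve_neg.es,
        d_es=d_obs,
        p_perm=float(p_two),
        p_one_sided=float(p_one),
        n_permutations=n_permutations,
        running_pos=curve_pos.running,
        running_neg=curve_neg.running,
        hit_positions_pos=curve_pos.hit_positions,
        hit_positions_neg=curve_neg.hit_positions,
        weight_exponent=weight_exponent,
        seed=seed,
        separation=bool(curve_pos.es * curve_neg.es < 0),
    )


def result_table(result: GseaTwoTailResult, contrast: str = "") -> pd.DataFrame:
    return pd.DataFrame([{
        "contrast": contrast,
        "es_pos": result.es_pos,
        "es_neg": result.es_neg,
        "d_es": result.d_es,
        "p_perm": result.p_perm,
        "p_one_sided": result.p_one_sided,
        "n_permutations": result.n_permutations,
        "separation": result.separation,
    }])


def gsea2_report(result: GseaTwoTailResult, ranked: RankedPhenotype,
                 regulon: SignedRegulon, out_prefix) -> dict:
    """Three-panel GSEA figure (PNG) plus a one-row TSV of statistics.

    Panels: ranked phenotype scores; a hit barcode (activated marks in
    red above the axis, repressed in blue below); the two running ES
    curves. Returns the paths written.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_prefix = str(out_prefix)
    tsv_path = out_prefix + ".tsv"
    png_path = out_prefix + ".png"
    result_table(result, ranked.contrast).to_csv(
        tsv_path, sep="\t", index=False, float_format=RESULT_FLOAT_FMT)

    N = len(ranked)
    fig, axes = plt.subplots(3, 1, figsize=(7, 7), sharex=True,
                             gridspec_kw={"height_ratios": [2, 0.6, 2]})
    axes[0].plot(np.arange(N), ranked.scores, color="0.3", lw=1)
    axes[0].axhline(0, color="0.7", lw=0.8)
    axes[0].set_ylabel(f"score ({ranked.contrast})" if ranked.contrast
                       else "score")
    axes[1].vlines(result.hit_positions_pos, 0, 1, color="crimson", lw=0.6)
    axes[1].vlines(result.hit_positions_neg, -1, 0, color="royalblue", lw=0.6)
    axes[1].set_yticks([])
    axes[1].set_ylabel("targets")
    x = np.arange(N + 1)
    axes[2].plot(x, result.running_pos, color="crimson",
                 label=f"activated (ES={result.es_pos:.3f})")
    axes[2].plot(x, result.running_neg, color="royalblue",
                 label=f"repressed (ES={result.es_neg:.3f})")
    axes[2].axhline(0, color="0.7", lw=0.8)
    axes[2].set_xlabel("rank in phenotype")
    axes[2].set_ylabel("running ES")
    axes[2].legend(loc="best", fontsize=8, frameon=False)
    fig.suptitle(
        f"{regulon.regulator}: dES={result.d_es:.3f}, "
        f"p={result.p_perm:.2e} ({result.n_permutations} permutations)",
        fontsize=10)
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return {"tsv": tsv_path, "png": png_path}
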