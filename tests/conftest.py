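import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import regulon2t as r2t
from regulon2t.inference import SignedRegulon

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def small_matrix():
    """4×3 toy expression matrix with two condition labels."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0],
         [2.0, 2.0, 2.0]],
        index=["GA", "GB", "GC", "GD"], columns=["s1", "s2", "s3"])
    return r2t.ExpressionMatrix(values=values)


@pytest.fixture
def planted():
    """Medium planted-regulon compendium shared across tests."""
    matrix, truth = r2t.simulate_expression(
        n_genes=600, n_samples=200, n_pos=40, n_neg=40, seed=11)
    return matrix, truth


def make_signed_regulon(pos, neg, regulator="TF1"):
    """Hand-built SignedRegulon from explicit target lists."""
    genes = list(pos) + list(neg)
    table = pd.DataFrame({
        "mi": 1.0,
        "p_perm": 0.001,
        "bootstrap_support": 1.0,
        "r": [1.0] * len(pos) + [-1.0] * len(neg),
        "mode": [1] * len(pos) + [-1] * len(neg),
    }, index=pd.Index(genes, name="target"))
    return SignedRegulon(regulator=regulator, table=table)


def brute_force_running_sum(genes, scores, gene_set, weight_exponent):
    """Independent loop-based GSEA running sum (oracle).

    Returns (es, running) with running of length N+1 starting at 0; the
    ES is the running extreme of largest magnitude, ties (to 1e-12)
    resolved toward the positive extreme.
    """
    gene_set = set(gene_set)
    hits = [i for i, g in enumerate(genes) if g in gene_set]
    n_hits = len(hits)
    N = len(genes)
    w = [abs(s) ** weight_exponent for s in scores]
    w_sum = sum(w[i] for i in hits)
    miss = 1.0 / (N - n_hits)
    running = [0.0]
    total = 0.0
    hitset = set(hits)
    for i in range(N):
        if i in hitset:
            total += (w[i] / w_sum) if w_sum > 0 else 1.0 / n_hits
        else:
            total -= miss
        running.append(total)
    running = np.array(running)
    hi, lo = max(running), min(running)
    es = hi if hi >= -lo - 1e-12 else lo
    return es, running
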