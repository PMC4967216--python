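"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the three kinds of input the analysis consumes:

1. a quantile-normalisable log2 expression compendium in which one
   regulator linearly drives disjoint sets of activated and repressed
   targets (a stand-in for a tumour expression compendium used to infer
   a transcription factor's regulon);
2. a paired two-condition stimulation design whose log fold changes are
   known exactly (a stand-in for hormone / growth-factor stimulation
   arrays); and
3. a genome annotation plus ChIP-seq-like peak intervals planted near
   the TSS of chosen genes over a uniform genomic background.

Every generator is a pure function of its parameters and seed: the same
seed yields byte-identical output.

Model choices
-------------
Expression is linear-Gaussian: the regulator is standard normal across
samples and each target is ``coupling × regulator + N(0, noise_sd²)``,
shifted to a log2-intensity-like baseline. Coupling magnitudes follow a
shifted half-normal, ``|c| = coupling_sd · (0.5 + |N(0,1)|)``, so that
every planted target has a regulatory effect bounded away from zero — a
gene with vanishing coupling would not operationally be a target at all.
Planted peak displacements around the TSS are Laplace distributed
(double exponential), matching the sharply-peaked-at-TSS shape that
binding-density validation expects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dataio import ExpressionMatrix, PeakSet, TssAnnotation

GENE_ID_FMT = "G{:06d}"

# minimum coupling magnitude, as a multiple of coupling_sd
_COUPLING_FLOOR = 0.5
# baseline log2 intensity around which simulated values sit
_BASELINE = 8.0


def gene_ids(n_genes: int) -> list[str]:
    return [GENE_ID_FMT.format(i + 1) for i in range(n_genes)]


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth of a simulated regulon.

    ``coupling`` maps each target to its linear coefficient (sign matches
    membership); ``effect_log2fc`` maps genes to the planted between-
    condition log2 fold change used by :func:`simulate_two_condition`.
    """

    regulator_id: str
    positive_targets: frozenset[str]
    negative_targets: frozenset[str]
    null_genes: frozenset[str]
    coupling: dict[str, float]
    effect_log2fc: dict[str, float]
    peak_offset_scale: float
    seed: int

    def __post_init__(self) -> None:
        sets = [self.positive_targets, self.negative_targets, self.null_genes]
        total = sum(len(s) for s in sets)
        union = set().union(*sets)
        if len(union) != total:
            raise ValueError("truth gene sets are not pairwise disjoint")
        if self.regulator_id in union:
            raise ValueError("regulator appears in a target/null set")
        for g in self.positive_targets:
            if self.coupling[g] <= 0:
                raise ValueError(f"positive target {g} has coupling ≤ 0")
        for g in self.negative_targets:
            if self.coupling[g] >= 0:
                raise ValueError(f"negative target {g} has coupling ≥ 0")

    @property
    def targets(self) -> frozenset[str]:
        return self.positive_targets | self.negative_targets

    @property
    def all_genes(self) -> list[str]:
        """Gene universe in id order (regulator included)."""
        return sorted({self.regulator_id} | self.targets | self.null_genes)

    def with_effects(self, effects: dict[str, float]) -> "SimTruth":
        """Copy of the truth with a replacement planted-effect vector."""
        return replace(self, effect_log2fc=dict(effects))

    def scaled_effects(self, factor: float) -> "SimTruth":
        """Attenuate or reverse every planted effect by ``factor``.

        ``factor = -1`` yields the reversal contrast (growth-factor-like
        antagonism of the planted response); ``0 < factor < 1`` emulates
        a receptor knock-down that dampens the response.
        """
        return self.with_effects(
            {g: factor * v for g, v in self.effect_log2fc.items()}
        )


def _check_positive(**params: float) -> None:
    for name, value in params.items():
        if value is None or value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")


def simulate_expression(
    n_genes: int,
    n_samples: int,
    n_pos: int,
    n_neg: int,
    coupling_sd: float = 0.8,
    noise_sd: float = 0.5,
    seed: int = 0,
    effect_size: float = 1.0,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Simulate a one-regulator compendium with planted targets.

    The first gene id is the regulator, the next ``n_pos`` are activated
    targets, the following ``n_neg`` repressed targets, the rest null.
    ``noise_sd = 0`` is the deterministic zero-noise limit (|r| = 1 for
    every target). The default planted condition effect is
    ``+effect_size`` for activated and ``−effect_size`` for repressed
    targets — the stimulated-by-the-regulator's-hormone response.
    """
    _check_positive(n_genes=n_genes, n_samples=n_samples, n_pos=n_pos,
                    n_neg=n_neg, coupling_sd=coupling_sd)
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be ≥ 0, got {noise_sd}")
    if n_pos + n_neg + 1 > n_genes:
        raise ValueError(
            f"n_pos + n_neg + 1 = {n_pos + n_neg + 1} exceeds n_genes={n_genes}"
        )
    rng = np.random.default_rng(seed)
    ids = gene_ids(n_genes)
    regulator = ids[0]
    pos = ids[1:1 + n_pos]
    neg = ids[1 + n_pos:1 + n_pos + n_neg]
    null = ids[1 + n_pos + n_neg:]

    magnitudes = coupling_sd * (_COUPLING_FLOOR
                                + np.abs(rng.standard_normal(n_pos + n_neg)))
    signs = np.concatenate([np.ones(n_pos), -np.ones(n_neg)])
    coupling = dict(zip(pos + neg, signs * magnitudes))

    reg_expr = rng.standard_normal(n_samples)
    X = np.empty((n_genes, n_samples))
    X[0] = reg_expr
    noise = (rng.standard_normal((n_genes - 1, n_samples)) * noise_sd
             if noise_sd > 0 else np.zeros((n_genes - 1, n_samples)))
    c = np.array([coupling.get(g, 0.0) for g in ids[1:]])
    X[1:] = c[:, None] * reg_expr[None, :] + noise
    X += _BASELINE

    effects = {g: effect_size for g in pos}
    effects.update({g: -effect_size for g in neg})
    effects.update({g: 0.0 for g in null})
    effects[regulator] = 0.0

    truth = SimTruth(
        regulator_id=regulator,
        positive_targets=frozenset(pos),
        negative_targets=frozenset(neg),
        null_genes=frozenset(null),
        coupling=coupling,
        effect_log2fc=effects,
        peak_offset_scale=0.0,
        seed=seed,
    )
    matrix = ExpressionMatrix(values=pd.DataFrame(
        X, index=ids, columns=[f"S{j + 1:04d}" for j in range(n_samples)]))
    return matrix, truth


def simulate_two_condition(
    truth: SimTruth,
    n_reps: int,
    residual_sd: float = 0.3,
    seed: int = 0,
    labels: tuple[str, str] = ("ref", "stim"),
) -> ExpressionMatrix:
    """Simulate a paired stimulation design from planted effects.

    Condition ``labels[1]`` has each gene's mean shifted by its planted
    ``effect_log2fc``; both conditions get ``n_reps`` replicates with
    i.i.d. Gaussian residual noise ``residual_sd`` (0 allowed: noise-free
    limit in which the measured logFC equals the planted effect exactly).
    """
    if n_reps < 2:
        raise ValueError(f"n_reps must be ≥ 2 (got {n_reps}); "
                         "downstream variance is undefined otherwise")
    if residual_sd < 0:
        raise ValueError(f"residual_sd must be ≥ 0, got {residual_sd}")
    rng = np.random.default_rng(seed)
    genes = truth.all_genes
    eff = np.array([truth.effect_log2fc.get(g, 0.0) for g in genes])
    n = 2 * n_reps
    noise = (rng.standard_normal((len(genes), n)) * residual_sd
             if residual_sd > 0 else np.zeros((len(genes), n)))
    X = _BASELINE + noise
    X[:, n_reps:] += eff[:, None]
    samples = ([f"{labels[0]}_{i + 1}" for i in range(n_reps)]
               + [f"{labels[1]}_{i + 1}" for i in range(n_reps)])
    condition = pd.Series([labels[0]] * n_reps + [labels[1]] * n_reps,
                          index=samples, name="condition")
    return ExpressionMatrix(
        values=pd.DataFrame(X, index=genes, columns=samples),
        condition=condition,
    )


def simulate_tss_annotation(
    n_genes: int,
    n_chroms: int = 5,
    chrom_length: int = 50_000_000,
    seed: int = 0,
) -> TssAnnotation:
    """Place ``n_genes`` TSS uniformly on ``n_chroms`` chromosomes.

    Gene ids follow the same ``G000001…`` scheme as the expression
    simulator, so annotation and expression line up when built for the
    same gene universe.
    """
    _check_positive(n_genes=n_genes, n_chroms=n_chroms,
                    chrom_length=chrom_length)
    margin = 1000
    if chrom_length <= 2 * margin * max(1, n_genes // n_chroms):
        raise ValueError("chrom_length too small to place genes")
    rng = np.random.default_rng(seed)
    ids = gene_ids(n_genes)
    chroms = [f"chr{i + 1}" for i in rng.integers(0, n_chroms, n_genes)]
    tss = rng.integers(margin, chrom_length - margin, n_genes)
    strand = np.where(rng.random(n_genes) < 0.5, "+", "-")
    table = pd.DataFrame({"gene_id": ids, "chrom": chroms,
                          "strand": strand, "tss": tss})
    lengths = {f"chr{i + 1}": chrom_length for i in range(n_chroms)}
    return TssAnnotation(table=table, chrom_lengths=lengths)


def simulate_peaks(
    annotation: TssAnnotation,
    enriched_genes,
    n_peaks_per_gene: int = 1,
    offset_scale: float = 5000.0,
    n_background: int = 0,
    seed: int = 0,
    peak_width: int = 200,
) -> PeakSet:
    """Plant peaks near chosen TSS plus a uniform genomic background.

    Each enriched gene receives ``n_peaks_per_gene`` peaks centred at
    ``TSS + Laplace(0, offset_scale)`` (``offset_scale = 0`` puts the
    peak exactly on the TSS). Background peaks are uniform over the
    genome, chromosomes weighted by length. All intervals have width
    ``peak_width`` and are clipped inside chromosome bounds.
    """
    if offset_scale < 0 or n_background < 0 or n_peaks_per_gene < 0:
        raise ValueError("offset_scale, n_background, n_peaks_per_gene "
                         "must be ≥ 0")
    _check_positive(peak_width=peak_width)
    if annotation.chrom_lengths is None:
        raise ValueError("annotation must carry chromosome lengths")
    enriched = list(enriched_genes)
    known = set(annotation.gene_ids)
    for g in enriched:
        if g not in known:
            raise KeyError(f"enriched gene {g!r} not in annotation")
    rng = np.random.default_rng(seed)
    tab = annotation.table.set_index("gene_id")
    rows = []
    for g in enriched:
        chrom = tab.at[g, "chrom"]
        tss = int(tab.at[g, "tss"])
        L = annotation.chrom_lengths[chrom]
        for _ in range(n_peaks_per_gene):
            disp = rng.laplace(0.0, offset_scale) if offset_scale > 0 else 0.0
            center = tss + disp
            start = int(round(center - peak_width / 2))
            start = min(max(start, 0), L - peak_width)
            rows.append((chrom, start, start + peak_width))
    if n_background:
        names = list(annotation.chrom_lengths)
        lengths = np.array([annotation.chrom_lengths[c] for c in names],
                           dtype=float)
        probs = lengths / lengths.sum()
        picks = rng.choice(len(names), size=n_background, p=probs)
        for k in picks:
            L = int(lengths[k])
            start = int(rng.integers(0, L - peak_width))
            rows.append((names[k], start, start + peak_width))
    return PeakSet(intervals=pd.DataFrame(
        rows or [], columns=["chrom", "start", "end"]))


def simulate_cascade_expression(
    n_direct: int = 50,
    n_indirect: int = 50,
    n_null: int = 400,
    n_samples: int = 200,
    coupling_sd: float = 0.8,
    noise_sd: float = 0.5,
    mediator_coupling: float = 1.5,
    seed: int = 0,
):
    """Two-regulator cascade for testing indirect-edge removal.

    Gene 1 is the primary regulator, gene 2 a mediator strongly driven
    by it; ``n_direct`` targets couple to the primary regulator,
    ``n_indirect`` targets couple to the mediator only (hence indirect
    for the primary regulator), the rest are null. Returns
    ``(matrix, info)`` where ``info`` records the planted sets.
    """
    _check_positive(n_direct=n_direct, n_indirect=n_indirect,
                    n_samples=n_samples, coupling_sd=coupling_sd,
                    noise_sd=noise_sd, mediator_coupling=mediator_coupling)
    rng = np.random.default_rng(seed)
    n_genes = 2 + n_direct + n_indirect + n_null
    ids = gene_ids(n_genes)
    reg, med = ids[0], ids[1]
    direct = ids[2:2 + n_direct]
    indirect = ids[2 + n_direct:2 + n_direct + n_indirect]
    null = ids[2 + n_direct + n_indirect:]

    reg_expr = rng.standard_normal(n_samples)
    med_expr = (mediator_coupling * reg_expr
                + noise_sd * rng.standard_normal(n_samples))
    med_expr = med_expr / med_expr.std()  # keep unit scale downstream

    def couple(driver, k):
        mags = coupling_sd * (_COUPLING_FLOOR + np.abs(rng.standard_normal(k)))
        signs = rng.choice([-1.0, 1.0], size=k)
        return (signs * mags)[:, None] * driver[None, :] \
            + noise_sd * rng.standard_normal((k, n_samples))

    X = np.empty((n_genes, n_samples))
    X[0] = reg_expr
    X[1] = med_expr
    X[2:2 + n_direct] = couple(reg_expr, n_direct)
    X[2 + n_direct:2 + n_direct + n_indirect] = couple(med_expr, n_indirect)
    X[2 + n_direct + n_indirect:] = rng.standard_normal((n_null, n_samples))
    X += _BASELINE
    matrix = ExpressionMatrix(values=pd.DataFrame(
        X, index=ids, columns=[f"S{j + 1:04d}" for j in range(n_samples)]))
    info = {
        "regulator": reg,
        "mediator": med,
        "direct": frozenset(direct),
        "indirect": frozenset(indirect),
        "null": frozenset(null),
    }
    return matrix, info


def simulation_config(**params) -> dict:
    """Provenance block (serialise as YAML next to generated outputs)."""
    out = {}
    for k, v in sorted(params.items()):
        if isinstance(v, (np.integer,)):
            v = int(v)
        elif isinstance(v, (np.floating,)):
            v = float(v)
        elif isinstance(v, (set, frozenset)):
            v = sorted(v)
        out[k] = v
    return out
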