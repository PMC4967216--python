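"""End-to-end orchestration: simulate → normalize → infer → rank →
two-tailed GSEA → peak validation, driven by a single YAML config.

A run is fully reproducible: every stage seed is derived from the
global seed and the stage name (adding a stage never perturbs earlier
ones), all artifacts are plain text with fixed float formatting, and
the manifest records a SHA-256 digest of every output so a rerun can be
verified byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import dataio, gsea2, inference, peaks, ranking, synthetic

logger = logging.getLogger(__name__)


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed < 2^31 from the global seed and stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class ConfigError(ValueError):
    """Invalid run configuration (reported before any stage runs)."""


_SCHEMA = {
    "seed": None,
    "out_dir": None,
    "simulation": {"n_genes", "n_samples", "n_pos", "n_neg", "coupling_sd",
                   "noise_sd", "effect_size"},
    "inputs": {"expression", "metadata", "tss", "peaks", "regulator"},
    "contrast": {"n_reps", "residual_sd", "labels", "reverse",
                 "knockdown_factor"},
    "inference": {"alpha", "n_permutations", "n_bootstraps", "min_support",
                  "dpi_tolerances", "n_bins"},
    "gsea": {"n_permutations", "weight_exponent"},
    "peaks": {"n_chroms", "chrom_length", "offset_scale", "n_peaks_per_gene",
              "n_background", "peak_width", "window", "n_null", "null_type"},
    "lines": None,
}

_DEFAULTS = {
    "simulation": dict(n_genes=1000, n_samples=200, n_pos=50, n_neg=50,
                       coupling_sd=0.8, noise_sd=0.5, effect_size=1.0),
    "contrast": dict(n_reps=4, residual_sd=0.3, labels=["ref", "stim"],
                     reverse=True, knockdown_factor=None),
    "inference": dict(alpha=0.01, n_permutations=1000, n_bootstraps=50,
                      min_support=0.6, dpi_tolerances=[0.2, 0.1, 0.0],
                      n_bins=None),
    "gsea": dict(n_permutations=1000, weight_exponent=1.0),
    "peaks": dict(n_chroms=5, chrom_length=50_000_000, offset_scale=5000,
                  n_peaks_per_gene=1, n_background=100, peak_width=200,
                  window=250_000, n_null=999, null_type="random_regulon"),
}


def validate_config(config: dict) -> dict:
    """Schema-check a run config and fill stage defaults.

    Unknown keys anywhere are rejected; either a ``simulation`` block or
    an ``inputs.expression`` path must be present; the error is raised
    before any stage executes.
    """
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(config) - set(_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    for section, allowed in _SCHEMA.items():
        block = config.get(section)
        if block is None or allowed is None:
            continue
        if not isinstance(block, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        extra = set(block) - allowed
        if extra:
            raise ConfigError(
                f"unknown key(s) in {section!r}: {sorted(extra)}")
    if "seed" not in config:
        raise ConfigError("config must set a global 'seed'")
    if "out_dir" not in config:
        raise ConfigError("config must set 'out_dir'")
    has_sim = "simulation" in config
    has_expr = "inputs" in config and "expression" in (config["inputs"] or {})
    if not has_sim and not has_expr:
        raise ConfigError("config needs a 'simulation' block or an "
                          "'inputs.expression' path")
    out = dict(config)
    for section, defaults in _DEFAULTS.items():
        if section == "simulation" and not has_sim:
            continue
        merged = dict(defaults)
        merged.update(out.get(section) or {})
        out[section] = merged
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def default_demo_config(out_dir, seed: int = 1) -> dict:
    """Small-but-complete config used by the demo and determinism checks."""
    return validate_config({
        "seed": seed,
        "out_dir": str(out_dir),
        "simulation": dict(n_genes=400, n_samples=150, n_pos=40, n_neg=40),
        "inference": dict(n_permutations=500, n_bootstraps=25),
        "gsea": dict(n_permutations=500),
        "peaks": dict(n_background=60, n_null=199),
    })


class _Manifest:
    def __init__(self, config: dict):
        self.stages: list[dict] = []
        self.config = config

    def record(self, name: str, seed: int | None, params: dict,
               outputs: dict[str, Path], t0: float) -> None:
        self.stages.append({
            "stage": name,
            "status": "ok",
            "seed": seed,
            "params": params,
            "wall_seconds": round(time.monotonic() - t0, 3),
            "outputs": {str(p): _sha256(Path(p)) for p in outputs.values()},
        })

    def fail(self, name: str, error: Exception) -> None:
        self.stages.append({"stage": name, "status": "failed",
                            "error": f"{type(error).__name__}: {error}"})

    def write(self, path: Path) -> None:
        doc = {"config": _jsonable(self.config), "stages": self.stages}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_pipeline(config: dict) -> dict:
    """Execute all stages from a validated config; return the manifest.

    Stage order: simulate, normalize, infer, rank, gsea2, validate. Any
    stage failure aborts the run; the manifest (written regardless)
    flags the failing stage and the partial outputs before it.
    """
    config = validate_config(config)
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("regulon2t")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    manifest = _Manifest(config)
    manifest_path = out_dir / "manifest.json"
    seed = int(config["seed"])

    state: dict = {}
    stage_fns = [
        ("simulate", _stage_simulate),
        ("normalize", _stage_normalize),
        ("infer", _stage_infer),
        ("rank", _stage_rank),
        ("gsea2", _stage_gsea2),
        ("validate", _stage_validate),
    ]
    try:
        for name, fn in stage_fns:
            t0 = time.monotonic()
            stage_seed = derive_seed(seed, name)
            logger.info("stage %s starting (seed %d)", name, stage_seed)
            params, outputs = fn(config, state, out_dir, stage_seed)
            manifest.record(name, stage_seed, _jsonable(params), outputs, t0)
    except Exception as exc:
        manifest.fail(name, exc)
        manifest.write(manifest_path)
        root.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    manifest.write(manifest_path)
    root.removeHandler(handler)
    handler.close()
    doc = {"config": _jsonable(config), "stages": manifest.stages,
           "manifest_path": str(manifest_path)}
    return doc


def _stage_simulate(config, state, out_dir, seed):
    if "simulation" not in config:
        # externally supplied data: load instead of simulating
        inputs = config["inputs"]
        state["expression"] = dataio.read_expression(
            inputs["expression"], inputs.get("metadata"))
        state["regulator"] = inputs.get("regulator")
        if "tss" in inputs:
            state["annotation"] = dataio.read_bed(inputs["tss"])
        if "peaks" in inputs:
            state["peaks"] = dataio.read_bed(inputs["peaks"])
        state["two_condition"] = state["expression"]
        return {"loaded": True}, {}
    sim = config["simulation"]
    con = config["contrast"]
    pk = config["peaks"]
    matrix, truth = synthetic.simulate_expression(
        n_genes=sim["n_genes"], n_samples=sim["n_samples"],
        n_pos=sim["n_pos"], n_neg=sim["n_neg"],
        coupling_sd=sim["coupling_sd"], noise_sd=sim["noise_sd"],
        effect_size=sim["effect_size"], seed=seed)
    two_cond = synthetic.simulate_two_condition(
        truth, n_reps=con["n_reps"], residual_sd=con["residual_sd"],
        seed=derive_seed(seed, "two_condition"),
        labels=tuple(con["labels"]))
    annotation = synthetic.simulate_tss_annotation(
        n_genes=sim["n_genes"], n_chroms=pk["n_chroms"],
        chrom_length=pk["chrom_length"], seed=derive_seed(seed, "tss"))
    peak_set = synthetic.simulate_peaks(
        annotation, sorted(truth.targets),
        n_peaks_per_gene=pk["n_peaks_per_gene"],
        offset_scale=pk["offset_scale"], n_background=pk["n_background"],
        peak_width=pk["peak_width"], seed=derive_seed(seed, "peaks"))
    state.update(expression=matrix, truth=truth, two_condition=two_cond,
                 annotation=annotation, peaks=peak_set,
                 regulator=truth.regulator_id)
    outputs = {
        "expression": out_dir / "expression.tsv",
        "two_condition": out_dir / "stimulation.tsv",
        "metadata": out_dir / "stimulation_samples.tsv",
        "tss": out_dir / "tss.bed",
        "peaks": out_dir / "peaks.bed",
        "sim_config": out_dir / "simulation.yaml",
    }
    dataio.write_expression(matrix, outputs["expression"])
    dataio.write_expression(two_cond, outputs["two_condition"],
                            outputs["metadata"])
    dataio.write_bed(annotation, outputs["tss"])
    dataio.write_bed(peak_set, outputs["peaks"])
    with open(outputs["sim_config"], "w") as fh:
        yaml.safe_dump(synthetic.simulation_config(
            **sim, **{f"contrast_{k}": v for k, v in con.items()},
            **{f"peaks_{k}": v for k, v in pk.items()}, seed=seed), fh)
    return dict(sim), outputs


def _stage_normalize(config, state, out_dir, seed):
    state["expression"] = dataio.quantile_normalize(state["expression"])
    path = out_dir / "expression_qnorm.tsv"
    dataio.write_expression(state["expression"], path)
    return {}, {"expression_qnorm": path}


def _stage_infer(config, state, out_dir, seed):
    inf = config["inference"]
    regulator = state["regulator"]
    network = inference.infer_network(
        state["expression"], [regulator],
        n_permutations=inf["n_permutations"], alpha=inf["alpha"],
        n_bootstraps=inf["n_bootstraps"], min_support=inf["min_support"],
        n_bins=inf["n_bins"], seed=seed)
    tolerances = sorted(inf["dpi_tolerances"], reverse=True)
    filtered = {tol: inference.dpi_filter(network, tol) for tol in tolerances}
    # the most stringent (smallest tolerance) regulon feeds the analysis
    final = filtered[tolerances[-1]]
    regulon = inference.split_regulon(state["expression"], final, regulator)
    state["network"] = network
    state["regulon"] = regulon
    state["regulons_by_tolerance"] = {
        tol: inference.split_regulon(state["expression"], net, regulator)
        for tol, net in filtered.items()}
    path = out_dir / "regulon.tsv"
    dataio.write_regulon(regulon, path)
    return dict(inf, n_edges=network.n_edges,
                n_final=len(regulon)), {"regulon": path}


def _stage_rank(config, state, out_dir, seed):
    con = config["contrast"]
    a, b = con["labels"]
    scores = ranking.log_fold_change(state["two_condition"], a, b)
    ranked = ranking.rank_genes(scores, contrast=f"{b} vs {a}")
    state["ranked"] = ranked
    path = out_dir / "ranked_phenotype.tsv"
    ranked.write(path)
    outputs = {"ranked": path}
    if con.get("reverse") and "truth" in state:
        factor = con.get("knockdown_factor") or 1.0
        rev_truth = state["truth"].scaled_effects(-factor)
        rev = synthetic.simulate_two_condition(
            rev_truth, n_reps=con["n_reps"], residual_sd=con["residual_sd"],
            seed=derive_seed(seed, "reversal"), labels=(a, f"{b}_mod"))
        rev_scores = ranking.log_fold_change(rev, a, f"{b}_mod")
        state["ranked_reversal"] = ranking.rank_genes(
            rev_scores, contrast=f"{b}_mod vs {a}")
        rev_path = out_dir / "ranked_phenotype_reversal.tsv"
        state["ranked_reversal"].write(rev_path)
        outputs["ranked_reversal"] = rev_path
    return {"contrast": f"{b} vs {a}"}, outputs


def _stage_gsea2(config, state, out_dir, seed):
    g = config["gsea"]
    results = {}
    outputs = {}
    for label, key in (("stimulation", "ranked"),
                       ("reversal", "ranked_reversal")):
        if key not in state:
            continue
        res = gsea2.two_tailed_gsea(
            state[key], state["regulon"],
            n_permutations=g["n_permutations"],
            weight_exponent=g["weight_exponent"],
            seed=derive_seed(seed, label))
        results[label] = res
        paths = gsea2.gsea2_report(res, state[key], state["regulon"],
                                   out_dir / f"gsea2_{label}")
        outputs[f"{label}_tsv"] = Path(paths["tsv"])
        outputs[f"{label}_png"] = Path(paths["png"])
    state["gsea_results"] = results
    return {k: dict(d_es=v.d_es, p_perm=v.p_perm)
            for k, v in results.items()}, outputs


def _stage_validate(config, state, out_dir, seed):
    if "annotation" not in state or "peaks" not in state:
        return {"skipped": "no annotation/peaks supplied"}, {}
    pk = config["peaks"]
    regulon_genes = list(state["regulon"].table.index)
    verdict = peaks.regulon_peak_enrichment(
        state["annotation"], state["peaks"], regulon_genes,
        window=pk["window"], null_type=pk["null_type"],
        n_null=pk["n_null"], seed=seed)
    dist = peaks.nearest_peak_distance(state["annotation"], state["peaks"],
                                       pk["window"])
    profile = peaks.binding_density(dist.loc[regulon_genes], pk["window"])
    state["verdict"] = verdict
    outputs = {"density": out_dir / "binding_density.tsv",
               "verdict": out_dir / "peak_enrichment.json"}
    profile.write(outputs["density"])
    with open(outputs["verdict"], "w") as fh:
        json.dump(verdict.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"window": pk["window"],
            "p_empirical": verdict.p_empirical}, outputs


def run_contrast_suite(config: dict) -> "pd.DataFrame":
    """GSEA of one regulon across synthetic 'cell lines' with varying
    receptor coupling.

    Each line block (``{name, coupling_scale}``) scales the planted
    modulation response: the stimulation contrast is shared, the
    modulation contrast reverses the planted effects scaled by the
    line's coupling. Lines with near-zero coupling are negative
    controls and should fail significance.
    """
    import pandas as pd

    config = validate_config(config)
    lines = config.get("lines")
    if not lines or len(lines) < 2:
        raise ConfigError("contrast suite needs ≥ 2 'lines' blocks")
    for block in lines:
        extra = set(block) - {"name", "coupling_scale"}
        if extra:
            raise ConfigError(f"unknown key(s) in line block: {sorted(extra)}")
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    sim = config["simulation"]
    con = config["contrast"]
    g = config["gsea"]
    inf = config["inference"]

    matrix, truth = synthetic.simulate_expression(
        n_genes=sim["n_genes"], n_samples=sim["n_samples"],
        n_pos=sim["n_pos"], n_neg=sim["n_neg"],
        coupling_sd=sim["coupling_sd"], noise_sd=sim["noise_sd"],
        effect_size=sim["effect_size"], seed=derive_seed(seed, "compendium"))
    network = inference.infer_network(
        matrix, [truth.regulator_id],
        n_permutations=inf["n_permutations"], alpha=inf["alpha"],
        n_bootstraps=inf["n_bootstraps"], min_support=inf["min_support"],
        seed=derive_seed(seed, "network"))
    regulon = inference.split_regulon(matrix, network, truth.regulator_id)

    a, b = con["labels"]
    rows = []
    for block in lines:
        name = str(block["name"])
        scale = float(block["coupling_scale"])
        for contrast, factor in (("stimulation", 1.0),
                                 ("modulation", -scale)):
            line_truth = truth.scaled_effects(factor)
            data = synthetic.simulate_two_condition(
                line_truth, n_reps=con["n_reps"],
                residual_sd=con["residual_sd"],
                seed=derive_seed(seed, f"{name}:{contrast}"),
                labels=(a, b))
            ranked = ranking.rank_genes(
                ranking.log_fold_change(data, a, b),
                contrast=f"{name}:{contrast}")
            res = gsea2.two_tailed_gsea(
                ranked, regulon, n_permutations=g["n_permutations"],
                weight_exponent=g["weight_exponent"],
                seed=derive_seed(seed, f"gsea:{name}:{contrast}"))
            expected_sign = 1.0 if factor > 0 else -1.0
            rows.append({
                "line": name,
                "coupling_scale": scale,
                "contrast": contrast,
                "es_pos": res.es_pos,
                "es_neg": res.es_neg,
                "d_es": res.d_es,
                "p_perm": res.p_perm,
                "expected_direction": bool(np.sign(res.d_es)
                                           == expected_sign),
            })
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "contrast_suite.tsv", sep="\t", index=False,
                 float_format=dataio.RESULT_FLOAT_FMT)
    return table
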