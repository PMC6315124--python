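"""End-to-end orchestration: simulate -> preprocess -> selection frequency ->
QTL/eQTL mapping -> qPCR association, with a machine-readable run summary.

A run is reproducible from its configuration and seed alone: every stage
draws from a seed-derived RNG stream and every artifact is written as TSV or
JSON (floats at 6 significant digits in TSV; the summary holds counts, paths
and wall-clock per stage)."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datatypes import InvalidParameterError, SyntheticTruth
from .mapping import (
    PermutationConfig,
    call_qtl,
    cim_scan,
    eqtl_scan,
    impute_pseudomarker_genotypes,
    permutation_threshold,
    select_cofactors,
)
from .preprocess import PreprocessConfig, filter_low_expression, log_transform
from .selection import SelectionConfig, report_selected_genes, run_selection_frequency
from .simulate import (
    BilDataset,
    default_truth,
    read_dataset,
    simulate_dataset,
    simulate_qpcr,
    write_dataset,
)
from .stats import fit_standard_curve, pearson_correlation, quantify_samples

log = logging.getLogger("bilfreqsel")

_TSV_FLOAT = "%.6g"


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "bilfreqsel_run"
    # dataset
    n_lines: int = 104
    n_rnaseq_lines: int = 20
    n_genes: int = 37043
    n_replicates: int = 3
    n_backcrosses: int = 1
    n_selfing_generations: int = 5
    n_causal_genes: int = 20
    fresh_weight_scale: float = 5.0
    # preprocessing
    min_mean_fpkm: float = 0.01
    pseudocount: float = 0.01
    # selection frequency
    subset_fraction: float = 0.10
    n_trials: int = 10000
    model_size: int = 8
    frequency_threshold: float = 0.01
    n_jobs: int = 1
    # QTL mapping
    window_cm: float = 10.0
    step_cm: float = 1.0
    entry_p: float = 0.05
    exit_p: float = 0.10
    max_cofactors: int = 5
    use_cofactors: bool = True
    n_permutations: int = 1000
    alpha: float = 0.05
    reselect_cofactors_in_permutations: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        # out_dir is a storage location, not part of the run's identity
        d = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunSummary:
    version: str
    config_hash: str
    seed: int
    counts: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    elapsed_s: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _write_tsv(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t", index=False, float_format=_TSV_FLOAT)
    return str(path)


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute all stages in order, writing every artifact under out_dir."""
    if config.n_trials < 1:
        raise InvalidParameterError("n_trials must be >= 1")
    if config.n_permutations < 1:
        raise InvalidParameterError("n_permutations must be >= 1")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = RunSummary(__version__, config.config_hash(), config.seed)
    t_all = time.perf_counter()

    def _stage(name):
        log.info("stage=%s seed=%d", name, config.seed)
        return time.perf_counter()

    # --- simulate -----------------------------------------------------------
    t0 = _stage("simulate")
    truth = default_truth(n_genes=config.n_genes, n_causal=config.n_causal_genes)
    dataset, fresh = simulate_dataset(
        seed=config.seed,
        n_lines=config.n_lines,
        n_rnaseq_lines=config.n_rnaseq_lines,
        n_genes=config.n_genes,
        n_replicates=config.n_replicates,
        n_backcrosses=config.n_backcrosses,
        n_selfing_generations=config.n_selfing_generations,
        truth=truth,
        fresh_weight_scale=config.fresh_weight_scale,
    )
    for p in write_dataset(dataset, out / "dataset", fresh_trait=fresh):
        summary.artifacts[Path(p).name] = p
    summary.counts["n_lines"] = len(dataset.genotypes.line_ids)
    summary.counts["n_genes_simulated"] = len(dataset.expression.gene_ids)
    summary.counts["n_expression_samples"] = len(dataset.expression.sample_ids)
    summary.elapsed_s["simulate"] = round(time.perf_counter() - t0, 3)

    # --- preprocess ---------------------------------------------------------
    t0 = _stage("preprocess")
    pcfg = PreprocessConfig(config.min_mean_fpkm, config.pseudocount)
    filtered = filter_low_expression(dataset.expression, pcfg)
    expr_log = log_transform(filtered, pcfg)
    out_log = expr_log.copy()
    out_log.insert(0, "gene_id", out_log.index)
    summary.artifacts["expression.log2.tsv"] = _write_tsv(out_log, out / "expression.log2.tsv")
    summary.counts["n_genes_filtered"] = int(expr_log.shape[0])
    summary.elapsed_s["preprocess"] = round(time.perf_counter() - t0, 3)

    # --- selection frequency ------------------------------------------------
    t0 = _stage("freqsel")
    scfg = SelectionConfig(
        subset_fraction=config.subset_fraction,
        n_trials=config.n_trials,
        model_size=config.model_size,
        frequency_threshold=config.frequency_threshold,
        seed=config.seed,
        n_jobs=config.n_jobs,
    )
    freq = run_selection_frequency(expr_log, fresh, scfg)
    summary.artifacts["freq.tsv"] = _write_tsv(freq.table, out / "freq.tsv")
    report = report_selected_genes(freq, expr_log, fresh, scfg)
    summary.artifacts["selected_genes.tsv"] = _write_tsv(report, out / "selected_genes.tsv")
    summary.counts["n_genes_selected"] = int(report.shape[0])
    summary.elapsed_s["freqsel"] = round(time.perf_counter() - t0, 3)

    # --- QTL mapping (shoot dry weight, all lines) --------------------------
    t0 = _stage("qtlscan")
    gmap, geno = dataset.genetic_map, dataset.genotypes
    y = dataset.trait.means
    grid = impute_pseudomarker_genotypes(geno, gmap, config.step_cm)
    cof = (
        tuple(
            select_cofactors(
                geno, gmap, y, config.entry_p, config.exit_p, config.max_cofactors
            )
        )
        if config.use_cofactors
        else ()
    )
    profile = cim_scan(
        geno, gmap, y, cof, config.window_cm, config.step_cm, grid=grid,
        trait_name=dataset.trait.name,
    )
    perm_cfg = PermutationConfig(config.n_permutations, config.alpha, config.seed)
    rule = (
        "reselect"
        if (config.use_cofactors and config.reselect_cofactors_in_permutations)
        else "none"
    )
    threshold = permutation_threshold(
        geno, gmap, y, perm_cfg, cofactor_rule=rule,
        window_cm=config.window_cm, step_cm=config.step_cm, grid=grid,
        entry_p=config.entry_p, exit_p=config.exit_p,
        max_cofactors=config.max_cofactors,
    )
    profile.threshold = threshold
    qtl = call_qtl(profile, gmap, threshold, qtl_prefix="qSW")
    summary.artifacts["profile.tsv"] = _write_tsv(profile.table, out / "profile.tsv")
    qtl_df = pd.DataFrame(
        [
            (
                c.trait, c.qtl_id, c.chromosome, c.nearest_marker,
                c.lod, c.additive_effect, c.r2_percent,
            )
            for c in qtl
        ],
        columns=[
            "trait", "qtl_id", "chromosome", "nearest_marker",
            "lod", "additive_effect", "r2_percent",
        ],
    )
    summary.artifacts["qtl.tsv"] = _write_tsv(qtl_df, out / "qtl.tsv")
    summary.counts["n_qtl_called"] = int(qtl_df.shape[0])
    summary.counts["lod_threshold"] = round(float(threshold), 4)
    summary.elapsed_s["qtlscan"] = round(time.perf_counter() - t0, 3)

    # --- qPCR quantification and eQTL scan ----------------------------------
    t0 = _stage("qpcr_eqtl")
    standards, cq_df, _ = simulate_qpcr(
        geno, gmap, dataset.trait, truth, seed=config.seed
    )
    summary.artifacts["standards.tsv"] = _write_tsv(standards, out / "standards.tsv")
    summary.artifacts["cq.tsv"] = _write_tsv(cq_df, out / "cq.tsv")
    curve = fit_standard_curve(standards["copies"], standards["cq"])
    quant = quantify_samples(curve, cq_df)
    expr_trait = quant.per_line
    trait_df = expr_trait.reset_index()
    summary.artifacts["expr_trait.tsv"] = _write_tsv(trait_df, out / "expr_trait.tsv")
    corr = pearson_correlation(
        expr_trait.loc[y.index].to_numpy(), y.to_numpy()
    )
    summary.counts["qpcr_trait_r"] = round(corr.r, 4)
    summary.counts["qpcr_trait_p"] = float(corr.p)
    e_profile, e_thr, e_calls = eqtl_scan(
        geno, gmap, expr_trait, pcfg=perm_cfg,
        window_cm=config.window_cm, step_cm=config.step_cm,
    )
    summary.artifacts["eqtl_profile.tsv"] = _write_tsv(e_profile.table, out / "eqtl_profile.tsv")
    eqtl_df = pd.DataFrame(
        [
            (
                "focal_gene_expression", c.qtl_id, c.chromosome, c.nearest_marker,
                c.lod, c.additive_effect, c.r2_percent,
            )
            for c in e_calls
        ],
        columns=[
            "trait", "qtl_id", "chromosome", "nearest_marker",
            "lod", "additive_effect", "r2_percent",
        ],
    )
    summary.artifacts["eqtl.tsv"] = _write_tsv(eqtl_df, out / "eqtl.tsv")
    summary.counts["n_eqtl_called"] = int(eqtl_df.shape[0])
    summary.counts["eqtl_lod_threshold"] = round(float(e_thr), 4)
    summary.elapsed_s["qpcr_eqtl"] = round(time.perf_counter() - t0, 3)

    summary.elapsed_s["total"] = round(time.perf_counter() - t_all, 3)
    (out / "summary.json").write_text(json.dumps(summary.to_dict(), indent=1))
    summary.artifacts["summary.json"] = str(out / "summary.json")
    return summary


def compare_to_truth(run_dir, truth: SyntheticTruth | None = None) -> dict:
    """Evaluate a synthetic run against its planted ground truth.

    Reports planted-gene recovery (median causal frequency vs the null 95th
    percentile), QTL localization error in cM, and additive-effect bias.
    """
    run_dir = Path(run_dir)
    if truth is None:
        truth_path = run_dir / "dataset" / "truth.json"
        if not truth_path.exists():
            raise FileNotFoundError(f"no ground truth at {truth_path}")
        truth = SyntheticTruth.from_dict(json.loads(truth_path.read_text()))
    ev: dict = {}

    freq = pd.read_csv(run_dir / "freq.tsv", sep="\t").set_index("gene_id")
    causal = [g for g in truth.causal_genes if g in freq.index]
    null = freq.drop(index=causal)
    if causal:
        causal_f = freq.loc[causal, "frequency"]
        q95 = float(np.quantile(null["frequency"], 0.95)) if len(null) else 0.0
        ev["causal_median_frequency"] = float(causal_f.median())
        ev["null_q95_frequency"] = q95
        ev["frac_causal_above_null_q95"] = float((causal_f > q95).mean())

    qtl = pd.read_csv(run_dir / "qtl.tsv", sep="\t")
    loc_errors, effect_bias, detected = [], [], 0
    for q in truth.qtls:
        same_chr = qtl[qtl["chromosome"] == q.chromosome]
        if same_chr.empty:
            loc_errors.append(None)
            continue
        profile = pd.read_csv(run_dir / "profile.tsv", sep="\t")
        # peak position of the called QTL = profile argmax within chromosome
        sub = profile[profile["chromosome"] == q.chromosome]
        peak = sub.loc[sub["lod"].idxmax()]
        err = abs(float(peak["pos_cm"]) - q.position_cm)
        loc_errors.append(err)
        if err <= 10.0:
            detected += 1
        best = same_chr.loc[same_chr["lod"].idxmax()]
        effect_bias.append(float(best["additive_effect"]) - q.additive_effect)
    ev["qtl_localization_errors_cm"] = loc_errors
    ev["qtl_detected_within_10cm"] = detected
    ev["n_planted_qtl"] = len(truth.qtls)
    if effect_bias:
        ev["additive_effect_mean_bias"] = float(np.mean(effect_bias))
    return ev
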