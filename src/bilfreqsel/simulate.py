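"""Synthetic backcrossed-inbred-line (BIL) datasets with planted ground truth.

Emulates the study design of a rice seedling-growth experiment: 104 BILs
(donor Arroz da Terra backcrossed once into recipient Ouu365, then selfed)
genotyped at 124 SSR-like markers on 12 chromosomes, shoot-weight traits with
planted additive QTL, and a 22-sample FPKM matrix (20 BILs + 2 parents) in
which a subset of genes is linearly coupled to shoot weight on the log scale.

Meiosis is modelled marker-to-marker: a gamete picks a starting homolog at
random on each chromosome and switches homolog between adjacent markers with
probability equal to the Kosambi inverse of their map distance.  Crossover
interference beyond the Kosambi marginal is not modelled, so the simulated
recombination fractions match the map function assumed by the downstream
interval mapping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    Eqtl,
    ExpressionMatrix,
    GeneticMap,
    GenotypeMatrix,
    InvalidParameterError,
    ParseError,
    Qtl,
    SyntheticTruth,
    TraitVector,
    ValidationError,
)
from .mapping import expected_dosages, kosambi_inverse

# Approximate per-chromosome genetic lengths (cM) of the rice framework map.
RICE_CHROMOSOME_LENGTHS_CM = (
    181.0, 157.0, 166.0, 129.0, 122.0, 125.0, 118.0, 121.0, 93.0, 83.0, 117.0, 109.0
)

#: per-chromosome marker counts totalling 124 over 12 chromosomes
DEFAULT_MARKERS_PER_CHROMOSOME = (11, 11, 11, 11, 10, 10, 10, 10, 10, 10, 10, 10)

PARENT_RECIPIENT = "Ouu365"
PARENT_DONOR = "ArrozDaTerra"

# stream labels for the counter-based RNG scheme (SeedSequence spawn keys)
_STREAM_MAP, _STREAM_GENO, _STREAM_TRAIT, _STREAM_EXPR, _STREAM_QPCR = range(5)

_TRAIT_FLOOR_MG = 0.01  # measurement floor; replicates are clipped here


def _rng(seed: int, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream, *extra]))


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

def simulate_genetic_map(
    n_chromosomes: int = 12,
    markers_per_chromosome=DEFAULT_MARKERS_PER_CHROMOSOME,
    chromosome_lengths_cm=RICE_CHROMOSOME_LENGTHS_CM,
    seed: int = 0,
) -> GeneticMap:
    """Random marker map: terminal markers at 0 and L, interior uniform."""
    if n_chromosomes < 1:
        raise InvalidParameterError("n_chromosomes must be >= 1")
    if np.isscalar(markers_per_chromosome):
        markers_per_chromosome = (int(markers_per_chromosome),) * n_chromosomes
    if np.isscalar(chromosome_lengths_cm):
        chromosome_lengths_cm = (float(chromosome_lengths_cm),) * n_chromosomes
    markers_per_chromosome = tuple(markers_per_chromosome)[:n_chromosomes]
    chromosome_lengths_cm = tuple(chromosome_lengths_cm)[:n_chromosomes]
    if len(markers_per_chromosome) != n_chromosomes or len(
        chromosome_lengths_cm
    ) != n_chromosomes:
        raise InvalidParameterError("per-chromosome settings shorter than n_chromosomes")
    if any(m < 2 for m in markers_per_chromosome):
        raise InvalidParameterError("need at least 2 markers per chromosome")
    if any(l <= 0 for l in chromosome_lengths_cm):
        raise InvalidParameterError("chromosome lengths must be positive")
    rng = _rng(seed, _STREAM_MAP)
    rows = []
    for c in range(n_chromosomes):
        m, length = markers_per_chromosome[c], chromosome_lengths_cm[c]
        interior = np.sort(rng.uniform(0.0, length, size=m - 2))
        pos = np.concatenate(([0.0], interior, [length]))
        for k, p in enumerate(pos):
            rows.append((f"RM{c + 1:02d}{k + 1:02d}", c + 1, float(p)))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chromosome", "position_cm"]))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _switch_probs(gmap: GeneticMap) -> np.ndarray:
    """Per-marker homolog-switch probabilities; 0.5 at each chromosome start."""
    probs = []
    for chrom in gmap.chromosomes:
        pos = gmap.positions_on(chrom)
        probs.append(0.5)
        probs.extend(kosambi_inverse(np.diff(pos)).tolist())
    return np.asarray(probs)


def _gametes(H1: np.ndarray, H2: np.ndarray, p_switch: np.ndarray, rng) -> np.ndarray:
    """One gamete per line under the marker-to-marker crossover process."""
    n, m = H1.shape
    switches = rng.random((n, m)) < p_switch[None, :]
    pick = np.logical_xor.accumulate(switches, axis=1)
    return np.where(pick, H2, H1)


def simulate_bil_genotypes(
    gmap: GeneticMap,
    n_lines: int = 104,
    n_backcrosses: int = 1,
    n_selfing_generations: int = 5,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """BIL genotypes from F1 x recipient backcross(es) followed by selfing.

    With one backcross the expected donor-allele dosage is 0.25 and, after
    ``t`` selfing generations, the expected heterozygous fraction is
    0.5 * (1/2)**t.
    """
    if n_lines < 1:
        raise InvalidParameterError("n_lines must be >= 1")
    if n_backcrosses < 1:
        raise InvalidParameterError("n_backcrosses must be >= 1")
    if n_selfing_generations < 0:
        raise InvalidParameterError("n_selfing_generations must be >= 0")
    if not 0 <= missing_rate < 1:
        raise InvalidParameterError("missing_rate must lie in [0, 1)")
    rng = _rng(seed, _STREAM_GENO)
    p_switch = _switch_probs(gmap)
    m = len(gmap.markers)
    # F1: one recipient homolog (0) and one donor homolog (1) at every marker
    H1 = np.zeros((n_lines, m), dtype=np.int8)
    H2 = np.ones((n_lines, m), dtype=np.int8)
    for _ in range(n_backcrosses):
        gam = _gametes(H1, H2, p_switch, rng)
        H1, H2 = gam, np.zeros_like(gam)
    for _ in range(n_selfing_generations):
        g1 = _gametes(H1, H2, p_switch, rng)
        g2 = _gametes(H1, H2, p_switch, rng)
        H1, H2 = g1, g2
    counts = H1 + H2
    codes = np.array(["OU", "HET", "AR"])[counts]
    if missing_rate > 0:
        mask = rng.random(codes.shape) < missing_rate
        codes = np.where(mask, "NA", codes)
    lines = [f"BIL{i + 1:03d}" for i in range(n_lines)]
    return GenotypeMatrix(pd.DataFrame(codes, index=lines, columns=gmap.markers))


def parental_genotypes(gmap: GeneticMap) -> GenotypeMatrix:
    """Two fully homozygous parent lines (recipient all OU, donor all AR)."""
    m = len(gmap.markers)
    calls = pd.DataFrame(
        [["OU"] * m, ["AR"] * m],
        index=[PARENT_RECIPIENT, PARENT_DONOR],
        columns=gmap.markers,
    )
    return GenotypeMatrix(calls)


# ---------------------------------------------------------------------------
# trait
# ---------------------------------------------------------------------------

def default_truth(n_genes: int = 37043, n_causal: int = 20) -> SyntheticTruth:
    """Default planted architecture for the standard 12-chromosome map.

    Four additive QTL on chromosomes 3, 6, 7 and 10 (one with a negative,
    recipient-favouring effect) whose effects sum to 1.10 mg so the parental
    dry-weight means land at 2.91 and 5.11 mg around a 4.01 mg baseline.
    """
    qtls = [
        Qtl(3, 40.0, 0.35),
        Qtl(6, 60.0, -0.28),
        Qtl(7, 55.0, 0.55),
        Qtl(10, 40.0, 0.48),
    ]
    causal_idx = np.linspace(0, n_genes - 1, n_causal).astype(int)
    causal = {
        f"gene_{i + 1:05d}": (1.2 if k % 2 == 0 else -1.2)
        for k, i in enumerate(causal_idx)
    }
    focal = sorted(causal)[1]  # a negatively coupled gene, SG1-like
    eqtls = [Eqtl(focal, 1, 40.0, -0.5), Eqtl(focal, 7, 55.0, -0.4)]
    return SyntheticTruth(qtls=qtls, causal_genes=causal, eqtls=eqtls)


def simulate_trait(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    truth: SyntheticTruth,
    n_replicates: int = 3,
    seed: int = 0,
    scale: float = 1.0,
    trait_name: str = "shoot_dry_weight_mg",
) -> TraitVector:
    """Shoot weight per line: baseline + sum of QTL effects x dosage + noise.

    Noise is Gaussian per biological replicate; its standard deviation is
    derived from ``truth.heritability`` (broad-sense, on the scale of line
    means over ``n_replicates`` replicates) or taken directly from
    ``truth.trait_noise_sd``.  ``scale`` converts to another unit (e.g. a
    fresh-weight multiple of dry weight).
    """
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    points = [(q.chromosome, q.position_cm) for q in truth.qtls]
    if points:
        dose = expected_dosages(genotypes, gmap, points)
        effects = np.array([q.additive_effect for q in truth.qtls])
        g = dose @ effects
    else:
        g = np.zeros(len(genotypes.line_ids))
    var_g = float(np.var(g))
    if truth.heritability is not None and var_g > 0:
        h2 = truth.heritability
        sd_mean = np.sqrt(var_g * (1.0 - h2) / h2)
        noise_sd = sd_mean * np.sqrt(n_replicates)
    elif truth.trait_noise_sd is not None:
        noise_sd = float(truth.trait_noise_sd)
    else:
        noise_sd = 0.0
    rng = _rng(seed, _STREAM_TRAIT)
    rows = []
    for i, line in enumerate(genotypes.line_ids):
        base = truth.trait_baseline + g[i]
        for rep in range(1, n_replicates + 1):
            v = scale * (base + rng.normal(0.0, noise_sd)) if noise_sd > 0 else scale * base
            rows.append((line, rep, max(v, _TRAIT_FLOOR_MG)))
    return TraitVector(
        pd.DataFrame(rows, columns=["line_id", "replicate", "value"]), name=trait_name
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    trait: TraitVector,
    n_genes: int,
    truth: SyntheticTruth,
    seed: int = 0,
    baseline_log2_mean: float = 0.7,
    baseline_log2_sd: float = 2.6,
) -> ExpressionMatrix:
    """FPKM matrix with trait-coupled causal genes and planted eQTL.

    Per gene g and sample i: FPKM = 2**(mu_g + a_g*dosage_i + c_g*z_i + eps),
    with z the standardized trait, eps Gaussian on the log2 scale.  A
    configurable fraction of genes is near-silent (mean FPKM <= 0.01) to
    exercise the expression filter.
    """
    if n_genes < 0:
        raise InvalidParameterError("n_genes must be nonnegative")
    if n_genes < len(truth.causal_genes):
        raise InvalidParameterError("n_genes smaller than the planted causal set")
    samples = genotypes.line_ids
    y = trait.means.loc[samples].to_numpy(float)
    sd = y.std()
    z = (y - y.mean()) / sd if sd > 0 else np.zeros_like(y)
    gene_ids = [f"gene_{i + 1:05d}" for i in range(n_genes)]
    missing_causal = set(truth.causal_genes) - set(gene_ids)
    if missing_causal:
        raise ValidationError(f"causal genes not in generated id range: {sorted(missing_causal)[:3]}")
    rng = _rng(seed, _STREAM_EXPR)
    mu = rng.normal(baseline_log2_mean, baseline_log2_sd, size=n_genes)
    c = np.array([truth.causal_genes.get(gid, 0.0) for gid in gene_ids])
    # planted near-silent genes, never overlapping the causal set
    n_zero = int(round(truth.near_zero_fraction * n_genes))
    null_pool = np.array([i for i, gid in enumerate(gene_ids) if c[i] == 0.0])
    zero_idx = rng.choice(null_pool, size=min(n_zero, null_pool.size), replace=False)
    mu[zero_idx] = rng.normal(np.log2(0.002), 0.5, size=zero_idx.size)
    c[zero_idx] = 0.0
    log2x = mu[:, None] + c[:, None] * z[None, :]
    if truth.eqtls:
        points = [(e.chromosome, e.position_cm) for e in truth.eqtls]
        dose = expected_dosages(genotypes, gmap, points)  # samples x eqtls
        idx = {gid: i for i, gid in enumerate(gene_ids)}
        for k, e in enumerate(truth.eqtls):
            log2x[idx[e.gene_id], :] += e.effect * dose[:, k]
    log2x += rng.normal(0.0, truth.expression_noise_sd_log2, size=log2x.shape)
    fpkm = np.exp2(log2x)
    fpkm[zero_idx, :] = np.minimum(fpkm[zero_idx, :], 0.009)
    return ExpressionMatrix(pd.DataFrame(fpkm, index=gene_ids, columns=samples))


# ---------------------------------------------------------------------------
# qPCR measurements for a focal gene across all lines
# ---------------------------------------------------------------------------

def simulate_qpcr(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    trait: TraitVector,
    truth: SyntheticTruth,
    gene_id: str | None = None,
    seed: int = 0,
    slope: float = -3.3219280948873623,  # -1/log10(2): 100% efficiency
    intercept: float = 38.0,
    base_log2_copies: float = 12.0,
    bio_sd_log2: float = 0.3,
    tech_sd_cq: float = 0.0,
    n_bio: int = 3,
    n_tech: int = 3,
    standard_copies=(1e3, 1e4, 1e5, 1e6, 1e7, 1e8),
):
    """Standard-curve and Cq tables for one gene's absolute quantification.

    Per-line true log2 copies follow the focal gene's planted trait coupling
    and eQTL effects; biological replicates add log2-scale noise and
    technical replicates add Cq-scale noise.  Returns
    ``(standards_df, cq_df, true_log2_copies)``.
    """
    if gene_id is None:
        with_eqtl = [e.gene_id for e in truth.eqtls]
        gene_id = with_eqtl[0] if with_eqtl else sorted(truth.causal_genes)[0]
    samples = genotypes.line_ids
    y = trait.means.loc[samples].to_numpy(float)
    sd = y.std()
    z = (y - y.mean()) / sd if sd > 0 else np.zeros_like(y)
    c = truth.causal_genes.get(gene_id, 0.0)
    log2copies = base_log2_copies + c * z
    eq = [e for e in truth.eqtls if e.gene_id == gene_id]
    if eq:
        dose = expected_dosages(genotypes, gmap, [(e.chromosome, e.position_cm) for e in eq])
        for k, e in enumerate(eq):
            log2copies = log2copies + e.effect * dose[:, k]
    rng = _rng(seed, _STREAM_QPCR)
    standards = pd.DataFrame(
        {
            "copies": standard_copies,
            "cq": [intercept + slope * np.log10(cp) for cp in standard_copies],
        }
    )
    rows = []
    for i, line in enumerate(samples):
        for b in range(1, n_bio + 1):
            lc = log2copies[i] + (rng.normal(0.0, bio_sd_log2) if bio_sd_log2 > 0 else 0.0)
            cq_true = intercept + slope * (lc * np.log10(2.0))
            for t in range(1, n_tech + 1):
                cq = cq_true + (rng.normal(0.0, tech_sd_cq) if tech_sd_cq > 0 else 0.0)
                rows.append((line, b, t, cq))
    cq_df = pd.DataFrame(rows, columns=["line_id", "bio_rep", "tech_rep", "cq"])
    true_series = pd.Series(log2copies, index=samples, name=f"log2_copies_{gene_id}")
    return standards, cq_df, true_series


# ---------------------------------------------------------------------------
# dataset container and TSV/JSON round trip
# ---------------------------------------------------------------------------

@dataclass
class BilDataset:
    genetic_map: GeneticMap
    genotypes: GenotypeMatrix
    trait: TraitVector
    expression: ExpressionMatrix
    truth: SyntheticTruth


def simulate_dataset(
    seed: int = 0,
    n_lines: int = 104,
    n_rnaseq_lines: int = 20,
    n_genes: int = 37043,
    n_replicates: int = 3,
    n_backcrosses: int = 1,
    n_selfing_generations: int = 5,
    truth: SyntheticTruth | None = None,
    fresh_weight_scale: float = 5.0,
    **map_kwargs,
) -> tuple[BilDataset, TraitVector]:
    """Full study-shaped dataset plus the fresh-weight trait of the RNA-Seq
    samples (``n_rnaseq_lines`` BILs and both parents)."""
    gmap = simulate_genetic_map(seed=seed, **map_kwargs)
    geno = simulate_bil_genotypes(
        gmap, n_lines, n_backcrosses, n_selfing_generations, seed=seed
    )
    if truth is None:
        truth = default_truth(n_genes=n_genes)
    trait = simulate_trait(geno, gmap, truth, n_replicates=n_replicates, seed=seed)
    rng = _rng(seed, _STREAM_EXPR, 999)
    chosen = sorted(rng.choice(len(geno.line_ids), size=n_rnaseq_lines, replace=False))
    rna_lines = [geno.line_ids[i] for i in chosen]
    parents = parental_genotypes(gmap)
    rna_geno = GenotypeMatrix(pd.concat([geno.calls.loc[rna_lines], parents.calls]))
    fresh = simulate_trait(
        rna_geno, gmap, truth, n_replicates=1, seed=seed + 1,
        scale=fresh_weight_scale, trait_name="shoot_fresh_weight_mg",
    )
    expr = simulate_expression(rna_geno, gmap, fresh, n_genes, truth, seed=seed)
    return BilDataset(gmap, geno, trait, expr, truth), fresh


_FLOAT_FMT = "%.10g"


def write_dataset(dataset: BilDataset, directory, fresh_trait: TraitVector | None = None) -> list[str]:
    """Write map/genotypes/trait/expression TSVs and truth JSON; return paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = []
    dataset.genetic_map.table.to_csv(d / "map.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    paths.append(str(d / "map.tsv"))
    g = dataset.genotypes.calls.copy()
    g.insert(0, "line_id", g.index)
    g.to_csv(d / "genotypes.tsv", sep="\t", index=False)
    paths.append(str(d / "genotypes.tsv"))
    dataset.trait.replicates.to_csv(d / "trait.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    paths.append(str(d / "trait.tsv"))
    e = dataset.expression.values.copy()
    e.insert(0, "gene_id", e.index)
    e.to_csv(d / "expression.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    paths.append(str(d / "expression.tsv"))
    (d / "truth.json").write_text(json.dumps(dataset.truth.to_dict(), indent=1))
    paths.append(str(d / "truth.json"))
    if fresh_trait is not None:
        fresh_trait.replicates.to_csv(
            d / "trait_fresh.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
        paths.append(str(d / "trait_fresh.tsv"))
    return paths


def read_genotypes(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "line_id" not in df.columns:
        raise ParseError(f"{path}: missing line_id column")
    df = df.set_index("line_id")
    arr = df.to_numpy(str)
    bad = ~np.isin(arr, ("OU", "AR", "HET", "NA"))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ParseError(
            f"{path}: line {i + 2}: illegal genotype code {arr[i, j]!r} "
            f"for line {df.index[i]!r}, marker {df.columns[j]!r}"
        )
    return GenotypeMatrix(df)


def read_expression(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: missing gene_id column")
    df = df.set_index("gene_id")
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: expression matrix is empty")
    try:
        return ExpressionMatrix(df.astype(float))
    except (ValueError, ValidationError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_trait(path, name: str = "shoot_dry_weight_mg") -> TraitVector:
    df = pd.read_csv(path, sep="\t")
    try:
        return TraitVector(df, name=name)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    try:
        return GeneticMap(df)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_dataset(directory) -> BilDataset:
    d = Path(directory)
    gmap = read_map(d / "map.tsv")
    geno = read_genotypes(d / "genotypes.tsv")
    trait = read_trait(d / "trait.tsv")
    expr = read_expression(d / "expression.tsv")
    truth = SyntheticTruth.from_dict(json.loads((d / "truth.json").read_text()))
    return BilDataset(gmap, geno, trait, expr, truth)
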