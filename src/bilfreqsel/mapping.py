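"""Regression-based composite interval mapping for backcrossed inbred lines.

The scan is Haley-Knott style: at every test position the trait is regressed
on the expected additive dosage of a pseudomarker conditional on flanking
marker genotypes, optionally together with background cofactor markers
selected by forward-backward stepwise regression.  LOD is defined through the
residual-sum-of-squares ratio, LOD = (n/2) * log10(RSS_reduced / RSS_full),
which for inbred-line populations is nearly identical to the mixture
likelihood used by classical interval mapping while remaining a plain linear
model.  Genome-wide significance thresholds come from trait permutations.

Map distances use the Kosambi function, d = 25 * ln((1+2r)/(1-2r)) cM, whose
inverse r = tanh(d/50)/2 also parameterises the crossover process of the
synthetic genotype generator, so simulated and assumed recombination agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import (
    GeneticMap,
    GenotypeMatrix,
    InvalidParameterError,
    TraitVector,
    ValidationError,
    align_trait_to_lines,
)

_R_CAP = 0.5 - 1e-9  # recombination fractions are capped below 1/2
_RSS_FLOOR_REL = 1e-12  # RSS_full floored at this fraction of TSS


# ---------------------------------------------------------------------------
# map functions
# ---------------------------------------------------------------------------

def kosambi_cm(r):
    """Kosambi map distance in cM for recombination fraction ``r`` in [0, 0.5)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise InvalidParameterError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d_cm):
    """Recombination fraction for a Kosambi map distance ``d_cm`` >= 0."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise InvalidParameterError("map distance must be nonnegative")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# pairwise recombination
# ---------------------------------------------------------------------------

@dataclass
class RecombinationEstimate:
    marker_a: str
    marker_b: str
    recombinant: int
    informative: int
    r: float


class UndefinedEstimateError(ValueError):
    """No informative lines were available for a pairwise estimate."""


def estimate_recombination_fraction(
    genotypes: GenotypeMatrix, marker_a: str, marker_b: str
) -> RecombinationEstimate:
    """Recombinant fraction between two markers from homozygous calls.

    Heterozygous and missing calls are non-informative for line-level
    recombination and are excluded.  The estimate is capped just below 0.5 so
    that the Kosambi conversion stays finite.
    """
    a = genotypes.calls[marker_a].to_numpy(str)
    b = genotypes.calls[marker_b].to_numpy(str)
    informative = np.isin(a, ("OU", "AR")) & np.isin(b, ("OU", "AR"))
    n_inf = int(informative.sum())
    if n_inf == 0:
        raise UndefinedEstimateError(
            f"no informative lines for markers {marker_a!r}/{marker_b!r}"
        )
    recomb = int(np.sum(a[informative] != b[informative]))
    r = min(recomb / n_inf, _R_CAP)
    return RecombinationEstimate(marker_a, marker_b, recomb, n_inf, r)


# ---------------------------------------------------------------------------
# pseudomarker dosage imputation
# ---------------------------------------------------------------------------

def _trans(x: int, y: int, r: float) -> float:
    return 1.0 - r if x == y else r


def _homolog_eq1(a: int, b: int, r1: float, r2: float, r12: float) -> float:
    """P(allele at Q is donor | flank alleles a, b) on one homolog."""
    den = _trans(a, b, r12)
    if den <= 0:
        return 0.5
    num = (1.0 - r1 if a == 1 else r1) * (1.0 - r2 if b == 1 else r2)
    return num / den


_PHASES = {0: ((0, 0),), 1: ((0, 1), (1, 0)), 2: ((1, 1),)}


def _expected_dosage(nL, nR, r1: float, r2: float) -> float:
    """Expected additive dosage at Q given flanking donor-allele counts.

    ``nL``/``nR`` are 0/1/2 donor counts or ``None`` when that side has no
    informative marker.  Homologs are modelled as independent two-state
    crossover chains; unknown phase at double heterozygotes is marginalised
    with weights proportional to each phased configuration's probability.
    """
    if nL is None and nR is None:
        return 0.0
    if nR is None:
        return nL * (1.0 - r1) + (2 - nL) * r1 - 1.0
    if nL is None:
        return nR * (1.0 - r2) + (2 - nR) * r2 - 1.0
    r12 = r1 + r2 - 2.0 * r1 * r2
    tot_w = 0.0
    acc = 0.0
    for a1, a2 in _PHASES[nL]:
        for b1, b2 in _PHASES[nR]:
            w = _trans(a1, b1, r12) * _trans(a2, b2, r12)
            if w == 0.0:
                continue
            e = _homolog_eq1(a1, b1, r1, r2, r12) + _homolog_eq1(a2, b2, r1, r2, r12)
            acc += w * e
            tot_w += w
    if tot_w <= 0.0:  # contradictory flanks under r12 = 0; fall back one-sided
        left = nL * (1.0 - r1) + (2 - nL) * r1 - 1.0
        right = nR * (1.0 - r2) + (2 - nR) * r2 - 1.0
        return 0.5 * (left + right)
    return acc / tot_w - 1.0


@dataclass
class PseudomarkerGrid:
    """Expected dosages for every line at a grid of test positions."""

    positions: pd.DataFrame  # columns: chromosome, pos_cm
    dosages: np.ndarray  # n_lines x n_positions, in [-1, 1]
    line_ids: list


def _chromosome_grid(pos: np.ndarray, step_cm: float) -> np.ndarray:
    lo, hi = pos[0], pos[-1]
    grid = np.arange(lo, hi, step_cm)
    grid = np.union1d(np.round(grid, 9), np.round(pos, 9))
    return grid[(grid >= lo - 1e-9) & (grid <= hi + 1e-9)]


def _dosage_column(counts: np.ndarray, pos: np.ndarray, t: float) -> np.ndarray:
    """Expected dosage at position ``t`` for each line on one chromosome.

    ``counts`` is lines x markers donor counts with -1 for missing; missing
    calls are handled by conditioning on the nearest non-missing flanks.
    """
    n_lines, m = counts.shape
    out = np.empty(n_lines, dtype=float)
    iL = int(np.searchsorted(pos, t + 1e-9)) - 1
    iR = int(np.searchsorted(pos, t - 1e-9))
    iL = max(iL, 0)
    iR = min(iR, m - 1)
    at_marker = abs(pos[iR] - t) < 1e-9 or abs(pos[iL] - t) < 1e-9
    k = iR if abs(pos[iR] - t) < 1e-9 else iL

    missing_rows = np.unique(np.nonzero(counts < 0)[0])
    clean = np.ones(n_lines, dtype=bool)
    clean[missing_rows] = False

    if at_marker:
        out[clean] = counts[clean, k] - 1.0
    else:
        r1 = kosambi_inverse(t - pos[iL])
        r2 = kosambi_inverse(pos[iR] - t)
        table = np.array(
            [[_expected_dosage(a, b, r1, r2) for b in (0, 1, 2)] for a in (0, 1, 2)]
        )
        nl = counts[clean, iL].astype(int)
        nr = counts[clean, iR].astype(int)
        out[clean] = table[nl, nr]

    for i in missing_rows:
        ok = np.nonzero(counts[i] >= 0)[0]
        left = ok[pos[ok] <= t + 1e-9]
        right = ok[pos[ok] >= t - 1e-9]
        jL = int(left[-1]) if left.size else None
        jR = int(right[0]) if right.size else None
        if jL is not None and jR is not None and jL == jR:
            out[i] = counts[i, jL] - 1.0
            continue
        nL = int(counts[i, jL]) if jL is not None else None
        nR = int(counts[i, jR]) if jR is not None else None
        r1 = kosambi_inverse(t - pos[jL]) if jL is not None else 0.0
        r2 = kosambi_inverse(pos[jR] - t) if jR is not None else 0.0
        out[i] = _expected_dosage(nL, nR, r1, r2)
    return out


def impute_pseudomarker_genotypes(
    genotypes: GenotypeMatrix, gmap: GeneticMap, step_cm: float = 1.0
) -> PseudomarkerGrid:
    """Expected additive dosage on a cM grid (marker positions included)."""
    if step_cm <= 0:
        raise InvalidParameterError("step_cm must be positive")
    counts_all = genotypes.donor_counts()
    chrom_blocks = []
    dose_blocks = []
    for chrom in gmap.chromosomes:
        sub = gmap.chromosome_table(chrom)
        markers = list(sub["marker"])
        pos = sub["position_cm"].to_numpy(float)
        if len(markers) < 2:
            warnings.warn(f"chromosome {chrom} has a single marker; using it directly")
            grid = pos
        else:
            grid = _chromosome_grid(pos, step_cm)
        counts = counts_all[markers].to_numpy()
        block = np.column_stack([_dosage_column(counts, pos, t) for t in grid])
        chrom_blocks.append(pd.DataFrame({"chromosome": chrom, "pos_cm": grid}))
        dose_blocks.append(block)
    positions = pd.concat(chrom_blocks, ignore_index=True)
    dosages = np.hstack(dose_blocks)
    return PseudomarkerGrid(positions, dosages, genotypes.line_ids)


def expected_dosages(
    genotypes: GenotypeMatrix, gmap: GeneticMap, points: list[tuple]
) -> np.ndarray:
    """Expected dosage at arbitrary (chromosome, cM) points; lines x points."""
    counts_all = genotypes.donor_counts()
    cols = []
    for chrom, t in points:
        sub = gmap.chromosome_table(chrom)
        pos = sub["position_cm"].to_numpy(float)
        if not (pos[0] - 1e-9 <= t <= pos[-1] + 1e-9):
            raise InvalidParameterError(
                f"position {t} cM outside marker span of chromosome {chrom}"
            )
        counts = counts_all[list(sub["marker"])].to_numpy()
        cols.append(_dosage_column(counts, pos, float(np.clip(t, pos[0], pos[-1]))))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# cofactor selection (forward-backward stepwise regression)
# ---------------------------------------------------------------------------

def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _partial_f_p(rss0: float, rss1: float, df_resid: int, scale: float = 1.0) -> float:
    if df_resid <= 0:
        return 1.0
    # a term that does not reduce RSS beyond round-off is never significant,
    # even when the base model already fits perfectly (rss0 ~ rss1 ~ 0);
    # ``scale`` should be on the order of the trait's total sum of squares
    tol = 1e-10 * max(scale, 1e-300)
    if rss0 - rss1 <= tol:
        return 1.0
    if rss1 <= tol:
        return 0.0
    f = (rss0 - rss1) / (rss1 / df_resid)
    if f <= 0:
        return 1.0
    return float(stats.f.sf(f, 1, df_resid))


def _marker_dosage_matrix(genotypes: GenotypeMatrix, gmap: GeneticMap) -> pd.DataFrame:
    d = genotypes.dosage()[gmap.markers]
    return d.fillna(d.mean())


def select_cofactors(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    trait,
    entry_p: float = 0.05,
    exit_p: float = 0.10,
    max_cofactors: int = 5,
) -> list[str]:
    """Forward-backward stepwise marker selection on additive dosages.

    Markers enter on the smallest partial-F p-value <= ``entry_p`` and leave
    when their p-value exceeds ``exit_p``.  Ties are broken by map order, so
    of two perfectly redundant markers the earlier one is kept.
    """
    y = align_trait_to_lines(trait, genotypes.line_ids) if not isinstance(
        trait, np.ndarray
    ) else np.asarray(trait, float)
    D = _marker_dosage_matrix(genotypes, gmap)
    markers = list(D.columns)
    X = D.to_numpy()
    n = len(y)
    tss = float(np.sum((y - y.mean()) ** 2))
    included: list[str] = []
    seen_states = set()
    while True:
        state = tuple(sorted(included))
        if state in seen_states:
            break
        seen_states.add(state)
        changed = False
        # forward step
        if len(included) < max_cofactors:
            base = np.column_stack(
                [np.ones(n)] + [X[:, markers.index(m)] for m in included]
            )
            rss0 = _rss(base, y)
            best_p, best_m = None, None
            for m in markers:
                if m in included:
                    continue
                Xc = np.column_stack([base, X[:, markers.index(m)]])
                p = _partial_f_p(rss0, _rss(Xc, y), n - Xc.shape[1], scale=tss)
                if best_p is None or p < best_p:
                    best_p, best_m = p, m
            if best_m is not None and best_p <= entry_p:
                included.append(best_m)
                changed = True
        # backward step
        while len(included) > 0:
            full = np.column_stack(
                [np.ones(n)] + [X[:, markers.index(m)] for m in included]
            )
            rss1 = _rss(full, y)
            worst_p, worst_m = None, None
            for m in included:
                others = [mm for mm in included if mm != m]
                Xr = np.column_stack(
                    [np.ones(n)] + [X[:, markers.index(mm)] for mm in others]
                )
                p = _partial_f_p(_rss(Xr, y), rss1, n - full.shape[1], scale=tss)
                if worst_p is None or p > worst_p:
                    worst_p, worst_m = p, m
            if worst_p is not None and worst_p > exit_p:
                included.remove(worst_m)
                changed = True
            else:
                break
        if not changed:
            break
    return sorted(included, key=markers.index)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

@dataclass
class LodProfile:
    trait_name: str
    table: pd.DataFrame  # chromosome, pos_cm, lod, additive_effect, r2_percent,
    # n_cofactors_used
    cofactors: tuple = ()
    threshold: float | None = None
    window_cm: float = 10.0
    step_cm: float = 1.0


@dataclass
class QtlCall:
    trait: str
    qtl_id: str
    chromosome: object
    peak_cm: float
    nearest_marker: str
    lod: float
    additive_effect: float
    r2_percent: float


def _fast_scan(D: np.ndarray, y: np.ndarray):
    """Single-marker regression statistics for all positions at once."""
    n = len(y)
    yc = y - y.mean()
    tss = float(yc @ yc)
    Dc = D - D.mean(axis=0)
    ssd = np.einsum("ij,ij->j", Dc, Dc)
    cross = Dc.T @ yc
    if tss <= 0:
        z = np.zeros(D.shape[1])
        return z, z.copy(), z.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        explained = np.where(ssd > 0, cross**2 / np.where(ssd > 0, ssd, 1.0), 0.0)
        beta = np.where(ssd > 0, cross / np.where(ssd > 0, ssd, 1.0), 0.0)
    rss_full = np.maximum(tss - explained, _RSS_FLOOR_REL * tss)
    lod = (n / 2.0) * np.log10(tss / rss_full)
    r2 = 100.0 * (tss - rss_full) / tss
    return lod, beta, r2


def max_lod_null(D: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Genome-wide max LOD of single-dosage scans for each trait column of Y."""
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    tss = np.einsum("ij,ij->j", Yc, Yc)
    Dc = D - D.mean(axis=0)
    ssd = np.einsum("ij,ij->j", Dc, Dc)
    cross = Dc.T @ Yc  # positions x traits
    ssd_safe = np.where(ssd > 0, ssd, 1.0)[:, None]
    explained = np.where(ssd[:, None] > 0, cross**2 / ssd_safe, 0.0)
    tss_safe = np.where(tss > 0, tss, 1.0)[None, :]
    rss = np.maximum(tss[None, :] - explained, _RSS_FLOOR_REL * tss_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = np.where(tss[None, :] > 0, (n / 2.0) * np.log10(tss_safe / rss), 0.0)
    return lod.max(axis=0)


def cim_scan(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    trait,
    cofactors: tuple = (),
    window_cm: float = 10.0,
    step_cm: float = 1.0,
    grid: PseudomarkerGrid | None = None,
    trait_name: str | None = None,
) -> LodProfile:
    """Composite interval mapping scan over the pseudomarker grid.

    Cofactors within ``window_cm`` of the test position (same chromosome) are
    dropped from that position's local model so the tested locus does not
    compete with itself.
    """
    y = (
        np.asarray(trait, float)
        if isinstance(trait, np.ndarray)
        else align_trait_to_lines(trait, genotypes.line_ids)
    )
    if trait_name is None:
        trait_name = getattr(trait, "name", None) or (
            trait.name if isinstance(trait, TraitVector) else "trait"
        )
    if grid is None:
        grid = impute_pseudomarker_genotypes(genotypes, gmap, step_cm)
    D = grid.dosages
    n = len(y)
    cof_list = list(cofactors)

    if not cof_list:
        lod, beta, r2 = _fast_scan(D, y)
        table = grid.positions.copy()
        table["lod"] = lod
        table["additive_effect"] = beta
        table["r2_percent"] = r2
        table["n_cofactors_used"] = 0
        return LodProfile(trait_name, table, (), None, window_cm, step_cm)

    dos = _marker_dosage_matrix(genotypes, gmap)
    cof_X = {m: dos[m].to_numpy() for m in cof_list}
    cof_pos = {
        m: (
            gmap.table.loc[gmap.table["marker"] == m, "chromosome"].iloc[0],
            float(gmap.table.loc[gmap.table["marker"] == m, "position_cm"].iloc[0]),
        )
        for m in cof_list
    }
    yc = y - y.mean()
    tss = float(yc @ yc)
    ones = np.ones(n)
    rows = []
    warned_rank = False
    for j, (chrom, t) in enumerate(
        zip(grid.positions["chromosome"], grid.positions["pos_cm"])
    ):
        used = [
            m
            for m in cof_list
            if not (cof_pos[m][0] == chrom and abs(cof_pos[m][1] - t) < window_cm)
        ]
        Xr = np.column_stack([ones] + [cof_X[m] for m in used])
        Xf = np.column_stack([Xr, D[:, j]])
        if not warned_rank and np.linalg.matrix_rank(Xf) < Xf.shape[1]:
            warnings.warn("rank-deficient CIM design; dependent columns ignored")
            warned_rank = True
        rss_r = _rss(Xr, y)
        beta, _, _, _ = np.linalg.lstsq(Xf, y, rcond=None)
        resid = y - Xf @ beta
        rss_f = max(float(resid @ resid), _RSS_FLOOR_REL * tss if tss > 0 else 1e-300)
        if tss <= 0:
            lod, eff, r2 = 0.0, 0.0, 0.0
        else:
            lod = (n / 2.0) * np.log10(rss_r / rss_f) if rss_r > 0 else 0.0
            lod = max(lod, 0.0)
            eff = float(beta[-1])
            r2 = 100.0 * (rss_r - rss_f) / tss
        rows.append((chrom, t, lod, eff, r2, len(used)))
    table = pd.DataFrame(
        rows,
        columns=[
            "chromosome",
            "pos_cm",
            "lod",
            "additive_effect",
            "r2_percent",
            "n_cofactors_used",
        ],
    )
    return LodProfile(trait_name, table, tuple(cof_list), None, window_cm, step_cm)


@dataclass
class PermutationConfig:
    n_permutations: int = 1000
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise InvalidParameterError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1:
            raise InvalidParameterError("alpha must lie in (0, 1)")


def permutation_threshold(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    trait,
    pcfg: PermutationConfig,
    cofactor_rule: str = "none",
    window_cm: float = 10.0,
    step_cm: float = 1.0,
    grid: PseudomarkerGrid | None = None,
    entry_p: float = 0.05,
    exit_p: float = 0.10,
    max_cofactors: int = 5,
    return_max_lods: bool = False,
):
    """Empirical (1 - alpha) quantile of genome-wide max LOD under permutation.

    ``cofactor_rule``: "none" scans without cofactors (simple interval
    mapping); "reselect" re-runs stepwise cofactor selection inside every
    permutation replicate so the threshold accounts for selection.
    """
    if pcfg.n_permutations < 20:
        warnings.warn("fewer than 20 permutations: threshold quantile is unstable")
    y = (
        np.asarray(trait, float)
        if isinstance(trait, np.ndarray)
        else align_trait_to_lines(trait, genotypes.line_ids)
    )
    if grid is None:
        grid = impute_pseudomarker_genotypes(genotypes, gmap, step_cm)
    rng = np.random.default_rng(np.random.SeedSequence([0x5EED, pcfg.seed or 0]))
    B = pcfg.n_permutations
    if cofactor_rule == "none":
        Y = np.column_stack([rng.permutation(y) for _ in range(B)])
        max_lods = max_lod_null(grid.dosages, Y)
    elif cofactor_rule == "reselect":
        max_lods = np.empty(B)
        for b in range(B):
            yp = rng.permutation(y)
            cof = select_cofactors(
                genotypes, gmap, yp, entry_p, exit_p, max_cofactors
            )
            prof = cim_scan(
                genotypes, gmap, yp, tuple(cof), window_cm, step_cm, grid=grid
            )
            max_lods[b] = prof.table["lod"].max()
    else:
        raise InvalidParameterError(f"unknown cofactor_rule {cofactor_rule!r}")
    threshold = empirical_quantile(max_lods, 1.0 - pcfg.alpha)
    if return_max_lods:
        return threshold, max_lods
    return threshold


def empirical_quantile(values, q: float) -> float:
    """Type-7 (linear interpolation) empirical quantile."""
    return float(np.quantile(np.asarray(values, float), q, method="linear"))


def call_qtl(
    profile: LodProfile,
    gmap: GeneticMap,
    threshold: float,
    qtl_prefix: str = "q",
) -> list[QtlCall]:
    """One call per contiguous supra-threshold region, at its LOD peak."""
    calls: list[QtlCall] = []
    tab = profile.table
    for chrom in gmap.chromosomes:
        sub = tab[tab["chromosome"] == chrom].reset_index(drop=True)
        if sub.empty:
            continue
        above = (sub["lod"] >= threshold).to_numpy()
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
        region_idx = 0
        for start, stop in zip(edges[::2], edges[1::2]):
            reg = sub.iloc[start:stop]
            peak_lod = reg["lod"].max()
            peak = reg[reg["lod"] == peak_lod].nsmallest(1, "pos_cm").iloc[0]
            mpos = gmap.positions_on(chrom)
            mnames = gmap.markers_on(chrom)
            nearest = mnames[int(np.argmin(np.abs(mpos - peak["pos_cm"])))]
            region_idx += 1
            suffix = f".{region_idx}" if region_idx > 1 else ""
            calls.append(
                QtlCall(
                    trait=profile.trait_name,
                    qtl_id=f"{qtl_prefix}-{chrom}{suffix}",
                    chromosome=chrom,
                    peak_cm=float(peak["pos_cm"]),
                    nearest_marker=nearest,
                    lod=float(peak["lod"]),
                    additive_effect=float(peak["additive_effect"]),
                    r2_percent=float(peak["r2_percent"]),
                )
            )
    return calls


def eqtl_scan(
    genotypes: GenotypeMatrix,
    gmap: GeneticMap,
    expression_trait,
    pcfg: PermutationConfig | None = None,
    cofactors: tuple = (),
    window_cm: float = 10.0,
    step_cm: float = 1.0,
    threshold: float | None = None,
    qtl_prefix: str = "eq",
):
    """QTL scan with a per-line expression phenotype (eQTL mapping).

    Identical machinery to :func:`cim_scan`/:func:`call_qtl`; the expression
    vector (e.g. mean log2 copy number over biological replicates) is the
    trait.  Returns (profile, threshold, calls).
    """
    grid = impute_pseudomarker_genotypes(genotypes, gmap, step_cm)
    profile = cim_scan(
        genotypes, gmap, expression_trait, cofactors, window_cm, step_cm, grid=grid
    )
    if threshold is None:
        if pcfg is None:
            raise InvalidParameterError("provide either a threshold or a PermutationConfig")
        rule = "none" if not cofactors else "reselect"
        threshold = permutation_threshold(
            genotypes, gmap, expression_trait, pcfg, cofactor_rule=rule,
            window_cm=window_cm, step_cm=step_cm, grid=grid,
        )
    profile.threshold = threshold
    calls = call_qtl(profile, gmap, threshold, qtl_prefix=qtl_prefix)
    return profile, threshold, calls


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class CompositeIntervalMapper(BaseEstimator):
    """Composite interval mapping as a fit-shaped estimator.

    Parameters mirror the scan functions; ``fit(genotypes, y)`` selects
    cofactors, scans, optionally computes a permutation threshold and calls
    QTL, exposing ``lod_profile_``, ``cofactors_``, ``threshold_`` and
    ``qtl_`` attributes.
    """

    def __init__(
        self,
        genetic_map: GeneticMap = None,
        window_cm: float = 10.0,
        step_cm: float = 1.0,
        entry_p: float = 0.05,
        exit_p: float = 0.10,
        max_cofactors: int = 5,
        use_cofactors: bool = True,
        n_permutations: int = 0,
        alpha: float = 0.05,
        reselect_cofactors_in_permutations: bool = True,
        random_state: int | None = None,
    ):
        self.genetic_map = genetic_map
        self.window_cm = window_cm
        self.step_cm = step_cm
        self.entry_p = entry_p
        self.exit_p = exit_p
        self.max_cofactors = max_cofactors
        self.use_cofactors = use_cofactors
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.reselect_cofactors_in_permutations = reselect_cofactors_in_permutations
        self.random_state = random_state

    def fit(self, X: GenotypeMatrix, y, trait_name: str = "trait"):
        if self.genetic_map is None:
            raise InvalidParameterError("genetic_map is required")
        gmap = self.genetic_map
        yv = (
            np.asarray(y, float)
            if isinstance(y, np.ndarray)
            else align_trait_to_lines(y, X.line_ids)
        )
        if self.use_cofactors:
            self.cofactors_ = tuple(
                select_cofactors(
                    X, gmap, yv, self.entry_p, self.exit_p, self.max_cofactors
                )
            )
        else:
            self.cofactors_ = ()
        grid = impute_pseudomarker_genotypes(X, gmap, self.step_cm)
        self.lod_profile_ = cim_scan(
            X, gmap, yv, self.cofactors_, self.window_cm, self.step_cm,
            grid=grid, trait_name=trait_name,
        )
        self.threshold_ = None
        self.qtl_ = []
        if self.n_permutations > 0:
            pcfg = PermutationConfig(self.n_permutations, self.alpha, self.random_state)
            rule = (
                "reselect"
                if (self.use_cofactors and self.reselect_cofactors_in_permutations)
                else "none"
            )
            self.threshold_ = permutation_threshold(
                X, gmap, yv, pcfg, cofactor_rule=rule,
                window_cm=self.window_cm, step_cm=self.step_cm, grid=grid,
                entry_p=self.entry_p, exit_p=self.exit_p,
                max_cofactors=self.max_cofactors,
            )
            self.lod_profile_.threshold = self.threshold_
            self.qtl_ = call_qtl(self.lod_profile_, gmap, self.threshold_)
        return self
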