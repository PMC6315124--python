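"""Gene selection frequency via repeated random-subset L1 regression.

The procedure: draw a random 10% subset of the (filtered, log2) transcriptome,
fit an L1-penalized linear regression of shoot weight on the subset's
standardized expression, record which genes receive non-zero coefficients
(by default the model size is pinned to eight along the regularization path),
and repeat many times.  A gene's selection frequency is the number of trials
in which it was designated an explanatory variable divided by the total
number of trials, so it is bounded above by the gene's appearance fraction
(~ the subset fraction).

The coordinate-descent LASSO path solves, per penalty value,
    min_b (1/2n) * ||y - X b||^2 + lambda * ||b||_1,
starting at lambda_max = max_j |x_j' y| / n where every coefficient is zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LassoCV, lasso_path
from sklearn.utils.validation import check_is_fitted

from .datatypes import ExpressionMatrix, InvalidParameterError, ValidationError
from .stats import pearson_correlation

_STREAM_TRIAL = 11  # RNG stream label for per-trial draws


@dataclass
class SelectionConfig:
    subset_fraction: float = 0.10
    n_trials: int = 10000
    model_size: int = 8
    frequency_threshold: float = 0.01
    penalty_rule: str = "fixed_size"  # or "cv"
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-3
    tol: float = 1e-7
    seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.subset_fraction <= 1:
            raise InvalidParameterError("subset_fraction must lie in (0, 1]")
        if self.n_trials < 1:
            raise InvalidParameterError("n_trials must be >= 1")
        if self.model_size < 0:
            raise InvalidParameterError("model_size must be >= 0")
        if not 0 <= self.frequency_threshold <= 1:
            raise InvalidParameterError("frequency_threshold must lie in [0, 1]")
        if self.penalty_rule not in ("fixed_size", "cv"):
            raise InvalidParameterError("penalty_rule must be 'fixed_size' or 'cv'")


@dataclass
class LassoPath:
    """A regularization path: decreasing penalties with coefficient vectors."""

    lambdas: np.ndarray  # decreasing
    coefs: np.ndarray  # p x len(lambdas)
    intercepts: np.ndarray
    n_samples: int

    @property
    def active_sizes(self) -> np.ndarray:
        return (self.coefs != 0).sum(axis=0)


def draw_subset(gene_ids, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform sample without replacement of size floor(fraction * G)."""
    gene_ids = np.asarray(gene_ids)
    if gene_ids.size == 0:
        raise InvalidParameterError("gene list is empty")
    size = int(np.floor(fraction * gene_ids.size))
    if size == 0:
        raise InvalidParameterError(
            f"subset fraction {fraction} yields an empty subset of {gene_ids.size} genes"
        )
    idx = rng.choice(gene_ids.size, size=size, replace=False)
    return gene_ids[np.sort(idx)]


def fit_lasso_path(
    X: np.ndarray,
    y: np.ndarray,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    tol: float = 1e-7,
    lambdas=None,
) -> LassoPath:
    """Coordinate-descent LASSO path on standardized X and centered y.

    The path starts at lambda_max (all-zero solution) and descends
    geometrically to lambda_min_ratio * lambda_max unless explicit penalty
    values are given.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite values in LASSO inputs")
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValidationError("X and y shapes disagree")
    if X.shape[0] < 3:
        raise ValidationError("need at least 3 samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # alpha=0 and tiny-penalty convergence chatter
        if lambdas is not None:
            alphas, coefs, _ = lasso_path(X, y, alphas=np.sort(lambdas)[::-1], tol=tol)
        else:
            alphas, coefs, _ = lasso_path(
                X, y, eps=lambda_min_ratio, n_alphas=n_lambdas, tol=tol
            )
    intercepts = np.full(alphas.shape, float(y.mean()))
    return LassoPath(alphas, coefs, intercepts, X.shape[0])


def select_explanatory(path: LassoPath, model_size: int) -> np.ndarray:
    """Column indices active at the largest penalty reaching ``model_size``.

    If the active set jumps past the target size between consecutive
    penalties, the set is truncated to the genes with the largest |beta|
    (ties broken by column index).  If the path never reaches the target,
    the final (smallest-penalty) active set is returned.
    """
    if model_size == 0:
        return np.array([], dtype=int)
    cap = path.n_samples - 1
    if model_size > cap:
        warnings.warn(f"model size {model_size} capped at n - 1 = {cap}")
        model_size = cap
    sizes = path.active_sizes
    reach = np.flatnonzero(sizes >= model_size)
    k = reach[0] if reach.size else len(sizes) - 1
    beta = path.coefs[:, k]
    active = np.flatnonzero(beta)
    if active.size <= model_size:
        return active
    order = np.lexsort((active, -np.abs(beta[active])))
    return np.sort(active[order[:model_size]])


def _lambda_grid(X: np.ndarray, y: np.ndarray, n_lambdas: int, eps: float) -> np.ndarray:
    lmax = np.max(np.abs(X.T @ y)) / X.shape[0]
    return lmax * np.power(eps, np.arange(n_lambdas) / (n_lambdas - 1))


def _pick_active(beta: np.ndarray, model_size: int) -> np.ndarray:
    active = np.flatnonzero(beta)
    if active.size <= model_size:
        return active
    order = np.lexsort((active, -np.abs(beta[active])))
    return np.sort(active[order[:model_size]])


def _fixed_size_active(Xs: np.ndarray, yc: np.ndarray, cfg: SelectionConfig) -> np.ndarray:
    """Active set of the fixed-model-size rule, computing only the upper path.

    Evaluates the same geometric penalty grid as :func:`fit_lasso_path` in
    chunks from lambda_max downwards and stops at the first penalty whose
    active set reaches the target size, which gives decisions identical to
    scanning the full path.
    """
    model_size = min(cfg.model_size, Xs.shape[0] - 1)
    if model_size == 0:
        return np.array([], dtype=int)
    alphas = _lambda_grid(Xs, yc, cfg.n_lambdas, cfg.lambda_min_ratio)
    chunk = max(10, cfg.n_lambdas // 5)
    coefs = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in range(0, len(alphas), chunk):
            _, coefs, _ = lasso_path(Xs, yc, alphas=alphas[s : s + chunk], tol=cfg.tol)
            sizes = (coefs != 0).sum(axis=0)
            reach = np.flatnonzero(sizes >= model_size)
            if reach.size:
                return _pick_active(coefs[:, reach[0]], model_size)
    return np.flatnonzero(coefs[:, -1])  # path never reached the target size


def _cv_active(X: np.ndarray, y: np.ndarray, cfg: SelectionConfig, trial_seed) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = LassoCV(
            eps=cfg.lambda_min_ratio,
            n_alphas=cfg.n_lambdas,
            cv=min(5, X.shape[0]),
            tol=max(cfg.tol, 1e-6),
            random_state=abs(hash(trial_seed)) % (2**31),
        ).fit(X, y)
    return np.flatnonzero(model.coef_)


def _run_trial(trial: int, X_full: np.ndarray, y: np.ndarray, cfg: SelectionConfig):
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, _STREAM_TRIAL, trial]))
    idx = draw_subset(np.arange(X_full.shape[1]), cfg.subset_fraction, rng)
    Xs = X_full[:, idx]
    sd = Xs.std(axis=0)
    keep = sd > 0
    if not keep.all():
        idx, Xs, sd = idx[keep], Xs[:, keep], sd[keep]
    if idx.size == 0:
        return idx, np.array([], dtype=int)
    Xs = (Xs - Xs.mean(axis=0)) / sd
    yc = y - y.mean()
    if cfg.penalty_rule == "cv":
        sel_local = _cv_active(Xs, yc, cfg, (cfg.seed, trial))
    else:
        sel_local = _fixed_size_active(Xs, yc, cfg)
    return idx, idx[sel_local]


@dataclass
class SelectionFrequencyTable:
    """Per-gene appearance/selection counts over all trials."""

    table: pd.DataFrame  # gene_id, appearance_count, selected_count, frequency
    n_trials: int
    trial_sizes: np.ndarray = field(default=None)


def run_selection_frequency(
    expr_log: pd.DataFrame | ExpressionMatrix,
    trait,
    config: SelectionConfig = SelectionConfig(),
) -> SelectionFrequencyTable:
    """Execute the full random-subset selection-frequency procedure.

    ``expr_log`` is genes x samples (already filtered and log2-transformed);
    ``trait`` is a per-sample Series aligned by sample id.  Trials use
    per-trial RNG streams keyed by trial index, so results are independent of
    the number of parallel workers.
    """
    values = expr_log.values if isinstance(expr_log, ExpressionMatrix) else expr_log
    samples = list(values.columns)
    if len(samples) < 3:
        raise ValidationError("need at least 3 samples")
    yser = trait.means if hasattr(trait, "means") else trait
    missing = [s for s in samples if s not in yser.index]
    if missing:
        raise ValidationError(f"samples missing from trait: {missing[:5]}")
    y = yser.loc[samples].to_numpy(float)
    if y.std() == 0:
        raise ValidationError("trait is constant across samples")
    gene_ids = np.asarray(values.index)
    X_full = values.to_numpy(float).T  # samples x genes

    results = Parallel(n_jobs=config.n_jobs, prefer="processes" if config.n_jobs != 1 else None)(
        delayed(_run_trial)(t, X_full, y, config) for t in range(config.n_trials)
    )
    appearance = np.zeros(gene_ids.size, dtype=np.int64)
    selected = np.zeros(gene_ids.size, dtype=np.int64)
    trial_sizes = np.empty(config.n_trials, dtype=np.int64)
    for t, (app_idx, sel_idx) in enumerate(results):
        np.add.at(appearance, app_idx, 1)
        np.add.at(selected, sel_idx, 1)
        trial_sizes[t] = sel_idx.size
    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "appearance_count": appearance,
            "selected_count": selected,
            "frequency": selected / config.n_trials,
        }
    )
    return SelectionFrequencyTable(table, config.n_trials, trial_sizes)


def report_selected_genes(
    freq: SelectionFrequencyTable,
    expr_log: pd.DataFrame | ExpressionMatrix,
    trait,
    config: SelectionConfig = SelectionConfig(),
) -> pd.DataFrame:
    """Genes above the frequency threshold, annotated with Pearson r and p.

    Sorted by descending frequency; ties broken by gene id.  The conditional
    frequency (selected / appearance) is reported as a secondary column.
    """
    values = expr_log.values if isinstance(expr_log, ExpressionMatrix) else expr_log
    yser = trait.means if hasattr(trait, "means") else trait
    y = yser.loc[list(values.columns)].to_numpy(float)
    hits = freq.table[freq.table["frequency"] > config.frequency_threshold].copy()
    rs, ps = [], []
    for gid in hits["gene_id"]:
        x = values.loc[gid].to_numpy(float)
        if x.std() == 0:
            rs.append(np.nan)
            ps.append(np.nan)
        else:
            res = pearson_correlation(x, y)
            rs.append(res.r)
            ps.append(res.p)
    hits["pearson_r"] = rs
    hits["pearson_p"] = ps
    with np.errstate(divide="ignore", invalid="ignore"):
        hits["conditional_frequency"] = np.where(
            hits["appearance_count"] > 0,
            hits["selected_count"] / hits["appearance_count"].replace(0, 1),
            0.0,
        )
    hits = hits.sort_values(
        ["frequency", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return hits


class StabilitySelectionLasso(SelectorMixin, BaseEstimator):
    """Random-subset LASSO selection frequency as a sklearn feature selector.

    ``fit(X, y)`` with X samples x genes (log2 expression) populates
    ``frequencies_``, ``appearance_counts_`` and ``selected_counts_``;
    ``get_support()`` marks genes whose frequency exceeds the threshold.
    """

    def __init__(
        self,
        subset_fraction: float = 0.10,
        n_trials: int = 10000,
        model_size: int = 8,
        frequency_threshold: float = 0.01,
        penalty_rule: str = "fixed_size",
        n_lambdas: int = 100,
        lambda_min_ratio: float = 1e-3,
        tol: float = 1e-7,
        random_state: int = 0,
        n_jobs: int = 1,
    ):
        self.subset_fraction = subset_fraction
        self.n_trials = n_trials
        self.model_size = model_size
        self.frequency_threshold = frequency_threshold
        self.penalty_rule = penalty_rule
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.tol = tol
        self.random_state = random_state
        self.n_jobs = n_jobs

    def _config(self) -> SelectionConfig:
        return SelectionConfig(
            subset_fraction=self.subset_fraction,
            n_trials=self.n_trials,
            model_size=self.model_size,
            frequency_threshold=self.frequency_threshold,
            penalty_rule=self.penalty_rule,
            n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
            tol=self.tol,
            seed=self.random_state,
            n_jobs=self.n_jobs,
        )

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            expr = X.T  # genes x samples for the functional core
        else:
            X = np.asarray(X, float)
            expr = pd.DataFrame(
                X.T,
                index=[f"f{i}" for i in range(X.shape[1])],
                columns=[f"s{i}" for i in range(X.shape[0])],
            )
        yser = pd.Series(np.asarray(y, float), index=list(expr.columns))
        result = run_selection_frequency(expr, yser, self._config())
        self.n_features_in_ = expr.shape[0]
        self.frequencies_ = result.table["frequency"].to_numpy()
        self.appearance_counts_ = result.table["appearance_count"].to_numpy()
        self.selected_counts_ = result.table["selected_count"].to_numpy()
        self.trial_sizes_ = result.trial_sizes
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "frequencies_")
        return self.frequencies_ > self.frequency_threshold
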