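"""Independent oracles used only by the test suite.

These deliberately avoid the code paths they check: a proximal-gradient
LASSO solver, a Monte Carlo three-point gamete simulator for conditional
dosages, and a permutation test for correlation p-values.
"""

from __future__ import annotations

import numpy as np


def proximal_gradient_lasso(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    max_iter: int = 200_000,
    tol: float = 1e-13,
) -> np.ndarray:
    """Minimize (1/2n)||y - Xb||^2 + lam*||b||_1 by ISTA with a fixed step."""
    n, p = X.shape
    L = np.linalg.norm(X.T @ X / n, 2)  # Lipschitz constant of the gradient
    step = 1.0 / L if L > 0 else 1.0
    beta = np.zeros(p)
    for _ in range(max_iter):
        grad = X.T @ (X @ beta - y) / n
        z = beta - step * grad
        new = np.sign(z) * np.maximum(np.abs(z) - step * lam, 0.0)
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    return beta


def mc_conditional_dosage(
    r1: float, r2: float, gL: int, gR: int, n_draws: int = 400_000, seed: int = 0
) -> float:
    """Monte Carlo expected dosage at Q given flanking genotypes.

    Simulates two independent homolog chains L -> Q -> R with Bernoulli
    switch probabilities r1 and r2, then averages the dosage at Q among
    draws whose unphased flank genotypes match (gL, gR) donor counts.
    """
    rng = np.random.default_rng(seed)
    hL = rng.integers(0, 2, size=(n_draws, 2))
    sw1 = rng.random((n_draws, 2)) < r1
    hQ = np.where(sw1, 1 - hL, hL)
    sw2 = rng.random((n_draws, 2)) < r2
    hR = np.where(sw2, 1 - hQ, hQ)
    match = (hL.sum(axis=1) == gL) & (hR.sum(axis=1) == gR)
    assert match.sum() > 1000, "too few matching draws for a stable estimate"
    return float((hQ.sum(axis=1)[match] - 1).mean())


def permutation_pearson_p(
    x: np.ndarray, y: np.ndarray, n_perm: int = 100_000, seed: int = 0
) -> float:
    """Two-sided permutation p-value for the Pearson correlation."""
    rng = np.random.default_rng(seed)
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    n = x.size
    r_obs = abs(float(xc @ yc) / n)
    perms = np.stack([rng.permutation(yc) for _ in range(n_perm)])
    r_perm = np.abs(perms @ xc) / n
    return float((np.sum(r_perm >= r_obs - 1e-12) + 1) / (n_perm + 1))


def type7_quantile(values: np.ndarray, q: float) -> float:
    """Sorting-based type-7 quantile (linear interpolation of order stats)."""
    v = np.sort(np.asarray(values, float))
    h = (len(v) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return float(v[lo] + (h - lo) * (v[hi] - v[lo]))
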