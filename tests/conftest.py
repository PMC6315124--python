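import numpy as np
import pandas as pd
import pytest

import bilfreqsel as bf


@pytest.fixture(scope="session")
def small_map() -> bf.GeneticMap:
    """Two chromosomes, evenly spaced markers."""
    rows = []
    for c, (n, length) in enumerate([(6, 100.0), (5, 80.0)], start=1):
        for k, p in enumerate(np.linspace(0, length, n)):
            rows.append((f"M{c}_{k + 1}", c, float(p)))
    return bf.GeneticMap(pd.DataFrame(rows, columns=["marker", "chromosome", "position_cm"]))


@pytest.fixture(scope="session")
def small_genotypes(small_map) -> bf.GenotypeMatrix:
    return bf.simulate_bil_genotypes(small_map, n_lines=80, seed=11)


@pytest.fixture(scope="session")
def study_map() -> bf.GeneticMap:
    """The default 12-chromosome, 124-marker map."""
    return bf.simulate_genetic_map(seed=5)


def make_expression(n_genes, n_samples, seed=0, causal=None, noise_sd=0.45):
    """Random log-normal FPKM with optional trait-coupled genes.

    Returns (expr_log2 DataFrame genes x samples, trait Series).
    """
    rng = np.random.default_rng(seed)
    trait = pd.Series(
        rng.normal(20.0, 4.0, size=n_samples),
        index=[f"s{i}" for i in range(n_samples)],
    )
    z = (trait - trait.mean()) / trait.std()
    mu = rng.normal(1.0, 2.0, size=n_genes)
    log2x = mu[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    if causal:
        for gi, c in causal.items():
            log2x[gi] += c * z.to_numpy()
    expr = pd.DataFrame(
        log2x, index=[f"g{i:04d}" for i in range(n_genes)], columns=trait.index
    )
    return expr, trait
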