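"""Small hand-built matrices used across test modules."""

import numpy as np

from rbdge.rcc import CodeSet, CountMatrix, Probe


def _codeset(n_genes: int) -> CodeSet:
    probes = (
        [Probe("Endogenous", f"G{i}") for i in range(n_genes)]
        + [Probe("Housekeeping", "H0")]
        + [Probe("Positive", "POS_A(128)", "", 128.0)]
        + [Probe("Negative", "N0"), Probe("Negative", "N1")]
    )
    return CodeSet(probes)


def constant_matrix(value: float, n_genes: int, n_samples: int) -> CountMatrix:
    values = np.full((n_genes + 4, n_samples), value)
    return CountMatrix(_codeset(n_genes), [f"S{j}" for j in range(n_samples)], values)


def two_sample_matrix() -> CountMatrix:
    rng = np.random.default_rng(0)
    genes = rng.integers(10, 1000, size=(5, 1)).astype(float)
    values = np.hstack([genes, genes * 4.0])
    values = np.vstack([values, np.full((4, 2), 10.0)])
    return CountMatrix(_codeset(5), ["S0", "S1"], values)


def duplicated_pair_matrix() -> CountMatrix:
    rng = np.random.default_rng(1)
    a = rng.integers(10, 1000, size=(6, 1)).astype(float)
    b = rng.integers(10, 1000, size=(6, 1)).astype(float)
    values = np.hstack([a, a, b])  # S0 and S1 identical
    values = np.vstack([values, np.full((4, 3), 10.0)])
    return CountMatrix(_codeset(6), ["S0", "S1", "S2"], values)
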