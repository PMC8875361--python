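"""Shared test-data builders."""

import numpy as np
import pandas as pd


def two_group_counts(rng, mu_test, mu_ref, n=3, alpha=0.05, n_genes=1):
    """Counts DataFrame + design for a plain two-group comparison."""
    r = 1.0 / alpha
    y_t = rng.negative_binomial(r, r / (r + mu_test), size=(n_genes, n))
    y_r = rng.negative_binomial(r, r / (r + mu_ref), size=(n_genes, n))
    counts = pd.DataFrame(
        np.hstack([y_t, y_r]),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"t{i}" for i in range(n)] + [f"r{i}" for i in range(n)],
    )
    design = pd.DataFrame(
        {
            "strain": ["M"] * n + ["CS"] * n,
            "condition": ["c"] * 2 * n,
            "replicate": list(range(1, n + 1)) * 2,
        },
        index=counts.columns,
    )
    return counts, design
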