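import numpy as np
import pandas as pd
import pytest

from seroscreen import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_matrix(values: np.ndarray, groups: dict[str, int] | None = None) -> ExpressionMatrix:
    """Wrap a raw array as an ExpressionMatrix with simple labels."""
    n_genes, n_samples = values.shape
    genes = [f"G{i:04d}" for i in range(n_genes)]
    if groups is None:
        groups = {"A": n_samples}
    samples, labels = [], {}
    i = 0
    for g, n in groups.items():
        for _ in range(n):
            sid = f"{g}_{i}"
            samples.append(sid)
            labels[sid] = g
            i += 1
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        sample_groups=pd.Series(labels),
    )


@pytest.fixture
def random_matrix(rng):
    """120 genes x 8 samples, heavy-tailed with scattered zeros."""
    vals = rng.lognormal(0.0, 1.5, size=(120, 8))
    vals[rng.random(vals.shape) < 0.2] = 0.0
    return make_matrix(vals, {"A": 5, "B": 3})
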