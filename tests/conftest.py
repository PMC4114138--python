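import numpy as np
import pandas as pd
import pytest

from regulonscan.expression_pipeline import ExpressionMatrix


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 features x 4 samples (2 conditions), fixed values."""
    values = pd.DataFrame(
        [[8.0, 8.2, 9.1, 9.3], [7.0, 7.1, 7.0, 6.9], [5.0, 5.5, 5.2, 5.1]],
        index=pd.Index(["f1", "f2", "f3"], name="feature_id"),
        columns=["a1", "a2", "b1", "b2"],
    )
    samples = pd.DataFrame(
        {
            "condition": ["ctl", "ctl", "kd", "kd"],
            "time_h": [0.0, 0.0, 36.0, 36.0],
            "replicate": [1, 2, 1, 2],
        },
        index=pd.Index(values.columns, name="sample_id"),
    )
    return ExpressionMatrix(values=values, samples=samples)


@pytest.fixture
def limma_matrix() -> ExpressionMatrix:
    """Deterministic 8x6 (3 vs 3) matrix whose moderated-t results were
    cross-computed with an independent empirical-Bayes implementation."""
    rng = np.random.default_rng(42)
    shift = np.concatenate(
        [np.zeros((4, 6)), np.tile([0, 0, 0, 1.2, 1.2, 1.2], (4, 1))]
    )
    vals = np.round(rng.normal(8, 1, size=(8, 6)) + shift, 4)
    values = pd.DataFrame(
        vals,
        index=pd.Index([f"g{i}" for i in range(8)], name="feature_id"),
        columns=[f"s{j}" for j in range(6)],
    )
    samples = pd.DataFrame(
        {
            "condition": ["A"] * 3 + ["B"] * 3,
            "time_h": [0.0] * 3 + [36.0] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
        },
        index=pd.Index(values.columns, name="sample_id"),
    )
    return ExpressionMatrix(values=values, samples=samples)
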