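import numpy as np
import pytest

from tfgmr import ExpressionMatrix, build_ranked_list


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_matrix():
    """3 genes × 4 samples, 2 treatment / 2 control."""
    import pandas as pd

    data = pd.DataFrame(
        {
            "s1": [1.0, 5.0, 2.0],
            "s2": [3.0, 6.0, 2.0],
            "s3": [2.0, 4.0, 2.0],
            "s4": [4.0, 5.0, 2.0],
        },
        index=["gA", "gB", "gC"],
    )
    groups = {"s1": "control", "s2": "control", "s3": "treatment", "s4": "treatment"}
    return ExpressionMatrix(data=data, sample_groups=groups)


def random_ranked_list(rng, n, prefix="g"):
    """Ranked list with continuous (tie-free w.p. 1) random scores."""
    scores = {f"{prefix}{i}": float(rng.normal()) for i in range(n)}
    return build_ranked_list(scores)
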