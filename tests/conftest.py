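import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_bulk_matrix():
    """A tiny raw bulk matrix with complete metadata."""
    from cgishift.io_formats import ExpressionMatrix

    values = pd.DataFrame(
        {
            "s1": [10, 0, 5, 100],
            "s2": [20, 0, 10, 200],
            "s3": [12, 1, 6, 110],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    meta = pd.DataFrame(
        {
            "age_group": ["young", "young", "aged"],
            "sex": ["F", "F", "F"],
            "tissue": ["kidney"] * 3,
            "total_mapped_reads": [1_000_000, 2_000_000, 1_100_000],
        },
        index=["s1", "s2", "s3"],
    )
    return ExpressionMatrix(values, meta, layer="raw")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
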