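import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def toy_expression():
    """3 samples x 2 genes, samples-in-rows."""
    return pd.DataFrame(
        {"PROS1": [1.5, 2.0, 3.25], "MMP2": [0.5, -1.0, 2.0]},
        index=pd.Index(["S1", "S2", "S3"], name="sample_id"),
    )


@pytest.fixture
def write_tsv(tmp_path):
    def _write(name, text):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write
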