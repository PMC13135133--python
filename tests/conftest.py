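import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_survey_tsv(tmp_path):
    """Three presence records in one 300-pinpoint plot (spec of the TSV dialect)."""
    path = tmp_path / "survey.tsv"
    pd.DataFrame(
        {"plot_id": ["P1", "P1", "P1"],
         "pinpoint_id": [0, 0, 1],
         "species_id": ["A", "B", "A"]}
    ).to_csv(path, sep="\t", index=False)
    manifest = tmp_path / "manifest.tsv"
    pd.DataFrame({"plot_id": ["P1"], "n_pinpoints": [300]}).to_csv(
        manifest, sep="\t", index=False)
    return path, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
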