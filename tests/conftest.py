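import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def elements_file(tmp_path):
    path = tmp_path / "elements.bed"
    path.write_text(
        "chr11\t2016406\t2022700\tICR1\tICR\n"
        "chr11\t2150000\t2155000\tIGF2\tgene\n"
        "chr11\t2720000\t2722000\tICR2\tICR\n"
        "chr11\t2000000\t2000500\tEnhA\tenhancer\n"
    )
    return path


def make_bands(truth, samples=("CTRL1",), n_reps=2, anchor="ICR1", ctrl=500.0):
    """Noise-free band table: intensity_3c = truth * ctrl exactly."""
    rows = []
    for sample in samples:
        for rep in range(1, n_reps + 1):
            for test, f in truth.items():
                rows.append(
                    dict(sample=sample, replicate=rep, anchor=anchor, test=test,
                         intensity_3c=f * ctrl, intensity_ctrl=ctrl)
                )
    return pd.DataFrame(rows)


@pytest.fixture
def bands_factory():
    return make_bands
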