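import numpy as np
import pandas as pd
import pytest

from methet import BetaMatrix, CohortSpec, synth_cohort


@pytest.fixture
def write_tsv(tmp_path):
    """Write raw text to a temp file and return its path."""

    def _write(text: str, name: str = "file.tsv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_beta():
    data = pd.DataFrame(
        [[0.1, 0.2], [0.5, np.nan], [0.9, 1.0]],
        index=pd.Index(["cg1", "cg2", "cg3"], name="probe_id"),
        columns=["s1", "s2"],
    )
    return BetaMatrix(data)


@pytest.fixture(scope="session")
def clean_cohort():
    """High-signal cohort: full purity, burden multiplier 1, mild noise."""
    spec = CohortSpec(
        n_tumor=50, n_normal=20, n_probes=2000,
        frac_hyper_probes=0.25, frac_hypo_probes=0.25,
        effect_hyper=0.5, effect_hypo=0.5,
        purity_dist=(1.0, 1.0), burden_range=(1.0, 1.0),
        burden_pattern="N1", noise_sd=0.02, seed=11,
    )
    return synth_cohort(spec)
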