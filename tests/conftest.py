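import numpy as np
import pandas as pd
import pytest

import surfquant as sq


@pytest.fixture(scope="session")
def small_noiseless():
    """Tiny noiseless experiment: areas recoverable exactly."""
    cfg = sq.SyntheticConfig(
        n_proteins=40,
        seed=11,
        noise_cv=0.0,
        missing_rate=0.0,
        n_replicates_biotin=2,
        n_replicates_mock=2,
        peptides_per_protein_mean=5.0,
    )
    return cfg, sq.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def small_noisy():
    """Small experiment with realistic 5% feature noise and missingness."""
    cfg = sq.SyntheticConfig(
        n_proteins=50,
        seed=5,
        noise_cv=0.05,
        missing_rate=0.1,
        n_replicates_biotin=3,
        n_replicates_mock=3,
        peptides_per_protein_mean=6.0,
    )
    return cfg, sq.simulate_experiment(cfg)


@pytest.fixture()
def two_group_design():
    return pd.DataFrame(
        {
            "sample_id": ["b1", "b2", "b3", "m1", "m2", "m3"],
            "run_id": [f"run_{s}" for s in ["b1", "b2", "b3", "m1", "m2", "m3"]],
            "group": ["biotin"] * 3 + ["mock"] * 3,
            "cell_line": ["X"] * 6,
            "replicate": [1, 2, 3, 1, 2, 3],
        }
    )


def make_triangle(apex_rt, apex_intensity, half_width=0.2, dt=0.05, mz=500.0):
    """Feature-map rows for one triangular peak sampled on a scan grid."""
    k = int(round(half_width / dt))
    offsets = np.arange(-k, k + 1) * dt
    t = apex_rt + offsets
    inten = apex_intensity * (1 - np.abs(offsets) / half_width)
    return pd.DataFrame({"rt_min": t, "mz": mz, "intensity": inten})
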