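import pandas as pd
import pytest

from phytokappa.bioactivity import build_activity_labels
from phytokappa.feature_table import PeakTable, binarize, filter_ubiquitous
from phytokappa.synthetic_data import SyntheticConfig, simulate_study


@pytest.fixture(scope="session")
def study_noiseless():
    """Small noiseless study: planted structure must be recovered exactly."""
    cfg = SyntheticConfig(
        n_features=300,
        flip_noise=0.0,
        n_causal_single=2,
        n_synergy_pairs=1,
        n_redundancy_pairs=1,
        seed=5,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def study_noisy():
    """Default-noise study (5% label flips) for rank-based recovery checks."""
    cfg = SyntheticConfig(n_features=400, flip_noise=0.05, seed=11)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def labels_noiseless(study_noiseless):
    labels, _ = build_activity_labels(study_noiseless.inhibition, study_noiseless.viability)
    return labels


@pytest.fixture(scope="session")
def binary_noiseless(study_noiseless):
    return filter_ubiquitous(binarize(study_noiseless.peak_table))


@pytest.fixture()
def toy_peak_table():
    """3 features x 2 species, hand-written values."""
    features = pd.DataFrame(
        {"mz": [101.11, 202.22, 303.33], "rt": [1.5, 2.5, 3.5]},
        index=pd.Index(["f1", "f2", "f3"], name="feature_id"),
    )
    intensity = pd.DataFrame(
        [[15000.0, 500.0, 10000.0], [9999.9, 20000.0, 0.0]],
        index=pd.Index(["sp_a", "sp_b"], name="species_id"),
        columns=["f1", "f2", "f3"],
    )
    return PeakTable(features=features, intensity=intensity)
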