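import numpy as np
import pandas as pd
import pytest

from ironsift import OTUTable, SampleMetadata, SimulationConfig, generate_cohort
from ironsift.filtering import rarefy


@pytest.fixture
def tiny_table() -> OTUTable:
    return OTUTable(
        ["s1", "s2"], ["Otu0001", "Otu0002", "Otu0003"],
        np.array([[5, 0, 7], [1, 2, 3]]),
    )


@pytest.fixture
def tiny_metadata() -> SampleMetadata:
    return SampleMetadata(pd.DataFrame({
        "sample_id": ["s1", "s2"],
        "mouse_id": ["m1", "m1"],
        "group": ["g1", "g1"],
        "cage": ["c1", "c1"],
        "sex": ["F", "F"],
        "timepoint": ["B14", "LI7"],
    }))


def make_metadata(sample_ids, mice, timepoints, group="g1", cage="c1"):
    n = len(sample_ids)
    return SampleMetadata(pd.DataFrame({
        "sample_id": sample_ids,
        "mouse_id": mice,
        "group": [group] * n,
        "cage": [cage] * n,
        "sex": ["F"] * n,
        "timepoint": timepoints,
    }))


@pytest.fixture
def metadata_factory():
    return make_metadata


def _planted(seed, **overrides):
    """A low-noise two-time-point cohort with 5 strongly suppressed OTUs."""
    kwargs = dict(
        n_otus=300, n_mice=10, n_sensitive=5, n_recovering=2,
        sensitivity_logfc=-20.0, sensitive_abundance_quantile=0.8,
        overdispersion=5000.0, mouse_effect_sd=0.2,
        timepoints=("B14", "LI7"), seed=seed,
    )
    kwargs.update(overrides)
    cfg = SimulationConfig(**kwargs)
    table, metadata, truth = generate_cohort(cfg)
    return rarefy(table, depth=10_000, seed=seed + 1), metadata, truth


@pytest.fixture
def planted_cohort_factory():
    return _planted


def _null(seed, n_otus=100, n_mice=10, timepoints=("B14", "LI7")):
    """An exchangeable (no-effect) cohort."""
    cfg = SimulationConfig(
        n_otus=n_otus, n_mice=n_mice, timepoints=timepoints,
        diet_shift_fraction=0.0, n_sensitive=0, n_recovering=0,
        mouse_effect_sd=0.0, cage_effect_sd=0.0, seed=seed,
    )
    table, metadata, truth = generate_cohort(cfg)
    return rarefy(table, depth=10_000, seed=seed + 1), metadata, truth


@pytest.fixture
def null_cohort_factory():
    return _null
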