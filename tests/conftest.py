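import numpy as np
import pytest

from mthvr.profile_io import (
    Polymorphism,
    ProfileDataset,
    RegionSet,
    SampleProfile,
    parse_polymorphism,
)
from mthvr.synthetic_data import SyntheticConfig, generate_dataset


def make_sample(sample_id, ranges, tokens, label=None, country=None):
    return SampleProfile(
        sample_id=sample_id,
        typed=RegionSet.from_pairs(ranges),
        polymorphisms=frozenset(parse_polymorphism(t) for t in tokens),
        label=label,
        country=country,
    )


@pytest.fixture
def toy_dataset():
    """Three fully typed samples over both HVRs with a handful of variants."""
    return ProfileDataset(
        (
            make_sample("S1", [(1, 576), (16024, 16569)],
                        ["16298C", "16311C", "73G"], label="Caucasian", country="US"),
            make_sample("S2", [(1, 576), (16024, 16569)],
                        ["16124.1C", "16189-"], label="African"),
            make_sample("S3", [(1, 576), (16024, 16569)], [], label="Asian"),
        )
    )


@pytest.fixture
def separable_config():
    """Identity mixing, disjoint motifs, no private noise, full coverage."""
    return SyntheticConfig(
        n_samples=150,
        class_labels=("A", "B", "C"),
        n_haplogroups=3,
        mixing=((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)),
        motif_size=5,
        motif_overlap=0.0,
        private_rate=0.0,
        coverage_model="full",
        seed=11,
    )


@pytest.fixture
def separable_dataset(separable_config):
    dataset, _ = generate_dataset(separable_config)
    return dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
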