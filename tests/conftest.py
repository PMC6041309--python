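import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import lowbiome as lb

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_table():
    """6 genotypes x 5 samples (2 controls), with a planted contaminant."""
    counts = pd.DataFrame(
        {
            "s1": [50, 30, 0, 10, 5, 5],
            "s2": [10, 60, 20, 0, 5, 5],
            "s3": [0, 0, 80, 10, 10, 0],
            "c1": [0, 2, 0, 0, 90, 8],
            "c2": [0, 0, 0, 0, 45, 5],
        },
        index=[f"gt{i}" for i in range(1, 7)],
    )
    lineages = {
        "gt1": ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus"),
        "gt2": ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides"),
        "gt3": ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides"),
        "gt4": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "unclassified_Lachnospiraceae"),
        "gt5": ("Bacteria", "Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Burkholderiaceae", "Ralstonia"),
        "gt6": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Clostridium-XlVa"),
    }
    return lb.FeatureTable(counts, lineages, "genotype")


@pytest.fixture
def toy_metadata():
    return lb.SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "c1", "c2"],
                "animal_id": ["a1", "a2", "a3", "k1", "k2"],
                "group": ["newborn", "newborn", "newborn", "control", "control"],
            }
        )
    )


@pytest.fixture(scope="session")
def study42():
    return lb.generate_study(lb.SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def decontam42(study42):
    return lb.decontaminate(study42.table, study42.metadata)


def random_table(rng, n_features=None, n_samples=None, n_controls=2):
    """Random integer FeatureTable plus metadata with control designations."""
    n_features = n_features or int(rng.integers(5, 51))
    n_samples = n_samples or int(rng.integers(n_controls + 1, 21))
    counts = rng.integers(0, 100, size=(n_features, n_samples))
    # ensure at least one control read so the profile is defined
    counts[rng.integers(n_features), n_samples - 1] += 1
    features = [f"f{i}" for i in range(n_features)]
    samples = [f"s{i}" for i in range(n_samples)]
    table = lb.FeatureTable(pd.DataFrame(counts, index=features, columns=samples))
    control_idx = rng.choice(n_samples - 1, size=n_controls - 1, replace=False).tolist()
    control_ids = [samples[i] for i in control_idx] + [samples[-1]]
    groups = ["control" if s in control_ids else "newborn" for s in samples]
    metadata = lb.SampleMetadata(
        pd.DataFrame({"sample_id": samples, "animal_id": samples, "group": groups})
    )
    return table, metadata
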