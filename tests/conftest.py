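import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from epiclock import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def linear_cohort():
    """400 samples x 300 loci, 60 planted age-linear loci, two tissues."""
    cfg = SimConfig(
        n_samples=400,
        n_loci=300,
        locus_class_counts={"age_linear": 60, "null": 240},
        noise_sd=0.01,
        seed=101,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def mixed_cohort():
    """All planted locus classes together, for classification-style checks."""
    cfg = SimConfig(
        n_samples=300,
        n_loci=400,
        locus_class_counts={
            "age_linear": 60,
            "age_parabolic": 40,
            "age_variance": 40,
            "tissue_identity": 60,
            "interaction": 40,
            "null": 160,
        },
        noise_sd=0.02,
        seed=202,
    )
    return generate_cohort(cfg)
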