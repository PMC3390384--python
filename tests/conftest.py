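import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pangrep.orthology import best_match, build_families, internal_similarity_search
from pangrep.synthetic_genomes import EffectorSpec, SyntheticConfig, simulate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def search_matrix(dataset, e_cutoff=1e-5, mode="reciprocal"):
    """Run the seeded similarity search over all ordered pairs and build the
    presence/absence matrix."""
    strains = sorted(dataset.proteins)
    maps = []
    for a in strains:
        for b in strains:
            if a == b:
                continue
            hits = internal_similarity_search(
                dataset.proteins[a], dataset.proteins[b], query_strain=a, subject_strain=b
            )
            maps.append(best_match(hits, e_cutoff))
    return build_families(maps, {s: sorted(dataset.proteins[s]) for s in strains}, mode)


@pytest.fixture(scope="session")
def default_dataset():
    """Default study conditions: 4 strains, 2 clades, REPs, deserts, RAYTs,
    effectors all planted."""
    return simulate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def clean_config():
    """Pan-genome-only conditions (no RAYT/effector accessory genes):
    core=120, two clades x 15, 25 unique per strain."""
    return SyntheticConfig(
        seed=11,
        divergence=0.1,
        rayt_per_strain=0,
        effector_spec=EffectorSpec(n_conforming=0, decoys=(), n_no_motif=0),
    )


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    return simulate_dataset(clean_config)


@pytest.fixture(scope="session")
def clean_matrix(clean_dataset):
    return search_matrix(clean_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
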