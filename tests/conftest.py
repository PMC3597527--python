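import warnings

import pytest

from fktransfer.ontology import OntologyDAG
from fktransfer.simulate import WorldConfig, generate_world

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)

#: canonical seed for every deterministic fixture
SEED = 1


def tiny_config(seed=7, **overrides):
    """A fast two-organism world for unit tests (~120 genes)."""
    base = dict(
        seed=seed,
        n_organisms=2,
        genes_per_organism=120,
        n_families=110,
        n_pathways=6,
        pathway_size_distribution=(6, 9),
        n_latent_modules=12,
    )
    base.update(overrides)
    return WorldConfig(**base)


@pytest.fixture(scope="session")
def tiny_world():
    return generate_world(tiny_config())


@pytest.fixture()
def diamond_dag():
    # child -> {left, right} -> root (two paths to one ancestor)
    return OntologyDAG(
        {
            "child": {"left", "right"},
            "left": {"root"},
            "right": {"root"},
            "root": set(),
        }
    )


@pytest.fixture(scope="session")
def default_benchmark():
    """Full three-classifier benchmark at the default study conditions.

    Shared session-wide: this is the expensive end-to-end run backing the
    comparative checks.
    """
    from fktransfer.pipeline import run_benchmark

    return run_benchmark(
        WorldConfig(seed=SEED),
        classifiers=("svm", "l1lr", "forest"),
        modes=("none", "fkt"),
    )


@pytest.fixture(scope="session")
def diverged_benchmark():
    """SVM benchmark with 30% of homolog pairs planted as diverged."""
    from fktransfer.pipeline import run_benchmark

    share = 0.30
    per_copy = share / (2.0 - share)  # pair-level share -> per-copy rate
    return run_benchmark(
        WorldConfig(seed=SEED, fraction_diverged_paralogs=per_copy),
        classifiers=("svm",),
        modes=("none", "fkt", "sequence_only"),
    )
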