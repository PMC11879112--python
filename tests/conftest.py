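import pytest

from mitotail.simulate import (
    GeneSpec,
    SimConfig,
    TailModel,
    build_toy_reference,
    simulate_library,
)


@pytest.fixture(scope="session")
def toy_ref():
    """Toy mitochondrial reference with one gene on each strand."""
    return build_toy_reference(
        seed=7,
        length=2000,
        gene_specs=[GeneSpec("ND3", 1200), GeneSpec("minusG", 400, strand="-")],
    )


@pytest.fixture(scope="session")
def plus_gene(toy_ref):
    return toy_ref.gene("ND3")


@pytest.fixture(scope="session")
def minus_gene(toy_ref):
    return toy_ref.gene("minusG")


@pytest.fixture(scope="session")
def error_free_library(toy_ref):
    """300 error-free pairs over both genes, mixed end usage, with truth."""
    cfg = SimConfig(
        n_pairs=300,
        end_usage={"canonical": 0.5, "alternate": 0.3, "other": 0.2},
        tail_model=TailModel("normal", mean=40, sd=10, min_length=5),
        seed=5,
    )
    pairs, truth = simulate_library(toy_ref, cfg)
    return cfg, pairs, truth
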