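import numpy as np
import pytest

from cooccur_tfbs import (
    ExpressionMatrix,
    ScanParams,
    SimulationConfig,
    build_model,
    make_foxo_like_matrices,
    simulate_expression,
    simulate_study,
)


@pytest.fixture(scope="session")
def foxo_matrices():
    return make_foxo_like_matrices(seed=11)


@pytest.fixture(scope="session")
def foxo_models(foxo_matrices):
    return [build_model(m) for m in foxo_matrices]


@pytest.fixture(scope="session")
def scan_params():
    return ScanParams()


@pytest.fixture(scope="session")
def small_study():
    """A compact ground-truthed study reused across modules."""
    cfg = SimulationConfig(
        n_genes_universe=300, n_de=30, promoter_length=1000, seed=42
    )
    return cfg, simulate_study(cfg, n_decoys=4)


@pytest.fixture()
def planted_expression():
    cfg = SimulationConfig(n_genes_universe=400, n_de=40, seed=5)
    values, design, truth = simulate_expression(cfg)
    return ExpressionMatrix(values, design), truth


def random_background(rng: np.random.Generator, length: int, gc: float = 0.45) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
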