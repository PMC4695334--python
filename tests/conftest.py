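import pytest

from epismad import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_dataset():
    """A compact simulated dataset shared by read-only tests."""
    cfg = SimulationConfig(seed=7, n_genes=120, n_chromosomes=2)
    return simulate(cfg)


@pytest.fixture(scope="session")
def default_run():
    """Full default-condition pipeline run (1000 genes, seed 42), shared by
    the recovery-oriented tests."""
    from epismad import run_all

    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        results = run_all({"seed": 42, "simulate": {}}, tmp)
        yield results
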