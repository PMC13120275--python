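import pytest
from hypothesis import HealthCheck, settings

import cwqsar as cq

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


#: The study conditions of the synthetic recovery benchmark: 300 compounds,
#: endpoint noise sd 0.1 log units, seed 1, default generator weights.
BENCHMARK_SPEC = cq.GeneratorSpec(n_compounds=300, noise_sd=0.1, seed=1)


@pytest.fixture(scope="session")
def benchmark_dataset() -> cq.Dataset:
    return cq.generate_dataset(BENCHMARK_SPEC)


@pytest.fixture(scope="session")
def benchmark_tf1(benchmark_dataset) -> cq.PipelineResult:
    """Full two-stage pipeline under TF1 with all defaults."""
    return cq.run_full_pipeline(benchmark_dataset, cq.PipelineConfig(seed=1))


@pytest.fixture(scope="session")
def benchmark_tf0(benchmark_dataset) -> cq.PipelineResult:
    return cq.run_full_pipeline(
        benchmark_dataset, cq.PipelineConfig(seed=1, target_function="TF0")
    )


@pytest.fixture(scope="session")
def small_labeled() -> cq.Dataset:
    """A quick 120-compound labeled dataset for optimizer-level tests."""
    ds = cq.generate_dataset(
        cq.GeneratorSpec(n_compounds=120, noise_sd=0.1, seed=7)
    )
    return cq.assign_splits(ds, seed=7)


def make_dataset(rows):
    """Dataset from (id, smiles, endpoint, label) tuples."""
    return cq.Dataset(
        [
            cq.CompoundRecord(id=i, smiles=s, endpoint=e, set_label=lab)
            for i, s, e, lab in rows
        ]
    )
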