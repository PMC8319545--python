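import pytest

from ffpesoma import generate_cohort, generate_reference, open_reference, run_filter_cascade
from ffpesoma.synthetic import GeneratorConfig


@pytest.fixture(scope="session")
def default_config():
    """The study-design defaults, seeded."""
    return GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def reference_path(tmp_path_factory, default_config):
    path = tmp_path_factory.mktemp("ref") / "ref.fa"
    generate_reference(default_config, path)
    return path


@pytest.fixture(scope="session")
def reference(reference_path):
    return open_reference(reference_path)


@pytest.fixture(scope="session")
def default_cohort(default_config, reference_path):
    return generate_cohort(default_config, reference_path)


@pytest.fixture(scope="session")
def cascade(default_cohort, reference):
    return run_filter_cascade(default_cohort.cohort, reference,
                              default_cohort.population)


@pytest.fixture(scope="session")
def small_cohort(reference_path):
    """A 6-patient cohort for faster structural tests."""
    config = GeneratorConfig(
        seed=11, n_visceral_patients=2, n_concurrent_pairs=2,
        n_canine_skin_patients=2, n_feline_skin_patients=2,
        n_uv_samples=1, n_uv_mutations=150,
        n_deamination_artifacts=40, n_oxidation_artifacts=20,
        n_recurrent_artifact_sites=6)
    return generate_cohort(config, reference_path)
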