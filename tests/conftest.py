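import numpy as np
import pytest

from tailatlas.simulate import (
    EmitConfig,
    ReferenceConfig,
    SampleSpec,
    default_maturation_model,
    generate_reference,
    make_barcodes,
    simulate,
)


@pytest.fixture(scope="session")
def small_genome():
    return generate_reference(ReferenceConfig(n_nuclear_genes=8, n_mt_genes=2), rng_seed=11)


@pytest.fixture(scope="session")
def small_model(small_genome):
    return default_maturation_model(small_genome, base_abundance=30.0, mt_abundance=20.0)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest error-free two-plus-one-condition dataset with exact counts."""
    return simulate(
        seed=7,
        reference_config=ReferenceConfig(n_nuclear_genes=8, n_mt_genes=2),
        emit_overrides={"p_concat": 0.08},
        model_overrides={"base_abundance": 30.0, "mt_abundance": 20.0},
    )


@pytest.fixture(scope="session")
def small_result(small_dataset, tmp_path_factory):
    from tailatlas.pipeline import run_from_dataset

    return run_from_dataset(small_dataset, tmp_path_factory.mktemp("pipeline"))


@pytest.fixture(scope="session")
def truth_with_ids(small_dataset):
    truth = small_dataset.truth.copy()
    truth["transcript_id"] = truth.read_id + "/" + truth.unit_index.astype(str)
    return truth


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
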