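import numpy as np
import pytest

import rnapath as rp


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale cohort spec for unit tests: 20 samples, 8x8 grid, 4 classes."""
    return rp.SyntheticSpec(
        n_samples=20,
        grid_rows=8,
        grid_cols=8,
        n_classes=4,
        n_region_seeds=5,
        embed_dim=16,
        n_genes=12,
        n_donors=10,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return rp.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_annotations(small_cohort, small_spec):
    ann, _ = rp.generate_annotations(
        small_cohort.bags, small_cohort.true_labels, small_spec.class_names, 40, seed=11
    )
    return ann


@pytest.fixture(scope="session")
def recovery_run():
    """Full-scale parameter-recovery run (spec defaults: 200 samples, 100 tiles,
    D=32, G=50, noise 5% of signal sd), trained once and shared."""
    spec = rp.SyntheticSpec(seed=7)
    cohort = rp.generate_cohort(spec)
    bags = {b.sample_id: b.embeddings for b in cohort.bags}
    config = rp.TrainConfig(max_epochs=200, seed=7)
    model, history = rp.train(bags, cohort.expression, cohort.donor_of, config=config)
    return {"spec": spec, "cohort": cohort, "bags": bags, "config": config,
            "model": model, "history": history}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
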