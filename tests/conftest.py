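import pytest

from barcodiv.simulate import SimulationConfig, generate_species_pool, sample_specimens


@pytest.fixture(scope="session")
def clean_config():
    """Identifiable, artifact-free config: clusters must equal species."""
    return SimulationConfig(
        n_species=40,
        truncation_rate=0.0,
        ambiguity_rate=0.0,
        per_group_success={},  # success 1.0 for every order
        seed=7,
    )


@pytest.fixture(scope="session")
def clean_survey(clean_config):
    pool = generate_species_pool(clean_config)
    seqs, records, truth = sample_specimens(pool, clean_config)
    return pool, seqs, records, truth


@pytest.fixture(scope="session")
def noisy_survey():
    """Scaled-down survey with dropout and QC artifacts, study-like rates."""
    cfg = SimulationConfig(n_species=60, seed=11)
    pool = generate_species_pool(cfg)
    seqs, records, truth = sample_specimens(pool, cfg)
    return cfg, pool, seqs, records, truth
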