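import pytest

from emvprofiler.synthetic_data import SimConfig, generate_emv_experiment


@pytest.fixture(scope="session")
def small_bundle():
    """One small synthetic experiment shared across read-only tests."""
    return generate_emv_experiment(SimConfig(seed=11, n_proteins=300))


@pytest.fixture(scope="session")
def bundle_dir(small_bundle, tmp_path_factory):
    """The small bundle serialized to disk, with its pipeline config."""
    from emvprofiler.synthetic_data import write_bundle

    outdir = tmp_path_factory.mktemp("bundle")
    config_path = write_bundle(small_bundle, outdir)
    return outdir, config_path
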