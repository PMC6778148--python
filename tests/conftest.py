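import pytest

from fn3kit.scaffold import default_scaffold


@pytest.fixture(scope="session")
def scaffold():
    return default_scaffold()


@pytest.fixture(scope="session")
def clean_fixture_run(scaffold):
    """96 error-free reads from 11 planted families, fully validated."""
    from fn3kit.clone_qc import validate_reads
    from fn3kit.simulate import gen_library_reads

    reads, truth = gen_library_reads(seed=1, error_rate=0.0)
    clones = validate_reads(reads, scaffold)
    return reads, truth, clones
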